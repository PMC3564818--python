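"""Readers and writers for the external formats the SCD pipeline touches.

Sequences come in as FASTA (UniProt-style ``db|ACC|NAME`` headers are
reduced to the accession), phosphosites as a three-column TSV, annotations
as GAF 2.x or a two-column TSV, and census regions go out as TSV with an
optional BED6 companion.

Coordinate convention: positions are 1-based inclusive everywhere in
memory; only the BED export converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino acids, alphabetical.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard characters tolerated in input sequences.  They
#: are retained verbatim and can never match S, T or Q in a motif scan.
AMBIGUOUS = "BZXUO"

_ALLOWED = frozenset(AA20) | frozenset(AMBIGUOUS)


class SeqioError(ValueError):
    """Raised for unrecoverable input problems (empty file, duplicate id)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One sequence entry: accession, free-text description and residues."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqioError("protein record with empty id")

    @property
    def length(self) -> int:
        return len(self.sequence)


class Proteome:
    """Ordered, id-unique collection of :class:`ProteinRecord`."""

    def __init__(self, records: Iterable[ProteinRecord], source_label: str = ""):
        self.records: list[ProteinRecord] = list(records)
        self.source_label = source_label
        self._index: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.id in self._index:
                raise SeqioError(f"duplicate protein id: {rec.id!r}")
            self._index[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        return self._index[protein_id]

    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Proteome):
            return NotImplemented
        return self.records == other.records


@dataclass
class PhosphositeTable:
    """Validated phosphosite rows (protein_id, 1-based position, residue S/T)."""

    sites: pd.DataFrame
    n_rejected_unknown: int = 0
    n_rejected_position: int = 0
    n_rejected_mismatch: int = 0

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def n_rejected(self) -> int:
        return (
            self.n_rejected_unknown
            + self.n_rejected_position
            + self.n_rejected_mismatch
        )


@dataclass
class AnnotationMap:
    """term_id -> set of protein ids, plus a display name per term."""

    terms: dict[str, frozenset[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.terms)


def parse_header_id(header: str) -> tuple[str, str]:
    """Split a FASTA header into (id, description).

    The id is the first whitespace-delimited token; UniProt-style
    ``db|ACC|NAME`` tokens are reduced to the accession ``ACC``.
    """
    parts = header.split(None, 1)
    token = parts[0]
    description = parts[1] if len(parts) > 1 else ""
    fields = token.split("|")
    if len(fields) == 3 and fields[1]:
        return fields[1], description
    return token, description


def normalize_sequence(raw: str) -> str:
    """Upper-case and strip a single terminal stop character."""
    seq = str(raw).upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    return seq


def read_fasta(path: str | Path, source_label: str | None = None) -> Proteome:
    """Read a protein FASTA file into a :class:`Proteome`.

    Records containing characters outside the 20 standard amino acids plus
    ``{B, Z, X, U, O}`` are rejected individually (the run continues, a
    summary is logged).  An empty file or a duplicate id is an error.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_rejected = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        rec_id, description = parse_header_id(entry.description or entry.id)
        seq = normalize_sequence(str(entry.seq))
        if rec_id in seen:
            raise SeqioError(f"duplicate protein id: {rec_id!r} in {path}")
        seen.add(rec_id)
        bad = set(seq) - _ALLOWED
        if bad:
            n_rejected += 1
            logger.warning(
                "rejecting record %s: illegal characters %s", rec_id, sorted(bad)
            )
            continue
        records.append(ProteinRecord(rec_id, description, seq))
    if not records and n_rejected == 0:
        raise SeqioError(f"no FASTA records found in {path}")
    if n_rejected:
        logger.info("rejected %d records with illegal characters", n_rejected)
    return Proteome(records, source_label=source_label or path.name)


def write_fasta(proteome: Proteome, path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.description)
        for rec in proteome
    ]
    SeqIO.write(entries, str(path), "fasta")


def read_phosphosites(path: str | Path, proteome: Proteome) -> PhosphositeTable:
    """Read and validate a phosphosite TSV (protein_id, position, residue).

    Rows referencing unknown proteins, with non-integer/out-of-range
    positions, or whose stated residue does not match the sequence are
    rejected and counted; valid rows additionally require the residue to
    be S or T.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"protein_id", "position", "residue"}
    missing = required - set(df.columns)
    if missing:
        raise SeqioError(f"phosphosite file missing columns: {sorted(missing)}")

    kept: list[tuple[str, int, str]] = []
    n_unknown = n_pos = n_mismatch = 0
    for protein_id, pos_str, residue in df[
        ["protein_id", "position", "residue"]
    ].itertuples(index=False):
        if protein_id not in proteome:
            n_unknown += 1
            logger.warning("phosphosite row for unknown protein %s", protein_id)
            continue
        try:
            pos = int(pos_str)
        except (TypeError, ValueError):
            n_pos += 1
            continue
        seq = proteome[protein_id].sequence
        if not 1 <= pos <= len(seq):
            n_pos += 1
            continue
        residue = str(residue).upper()
        if residue not in ("S", "T") or seq[pos - 1] != residue:
            n_mismatch += 1
            continue
        kept.append((protein_id, pos, residue))

    sites = pd.DataFrame(kept, columns=["protein_id", "position", "residue"])
    return PhosphositeTable(
        sites=sites,
        n_rejected_unknown=n_unknown,
        n_rejected_position=n_pos,
        n_rejected_mismatch=n_mismatch,
    )


def _looks_like_gaf(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("!"):
                return True
            return len(line.rstrip("\n").split("\t")) >= 15
    return False


def read_annotations(path: str | Path) -> AnnotationMap:
    """Read a term -> protein map from GAF 2.x or a two-column TSV.

    GAF rows with a ``NOT`` qualifier are skipped; unparseable lines are
    skipped with a count.  Protein sets are deduplicated and empty terms
    dropped.
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    n_skipped = 0
    is_gaf = _looks_like_gaf(path)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            cols = line.split("\t")
            if is_gaf:
                if len(cols) < 15:
                    n_skipped += 1
                    continue
                qualifier, protein_id, term_id = cols[3], cols[1], cols[4]
                if "NOT" in qualifier.split("|"):
                    continue
                term_name = term_id
            else:
                if len(cols) < 2 or not cols[0] or not cols[1]:
                    n_skipped += 1
                    continue
                term_id, protein_id = cols[0], cols[1]
                term_name = cols[2] if len(cols) > 2 and cols[2] else term_id
            if not protein_id or not term_id:
                n_skipped += 1
                continue
            terms.setdefault(term_id, set()).add(protein_id)
            names.setdefault(term_id, term_name)
    if n_skipped:
        logger.info("skipped %d unparseable annotation lines", n_skipped)
    return AnnotationMap(
        terms={t: frozenset(m) for t, m in terms.items() if m},
        names=names,
        n_skipped=n_skipped,
    )


CENSUS_COLUMNS = ["protein_id", "start", "end", "span", "n_motifs", "motif_positions"]


def write_census(regions, path: str | Path, bed_path: str | Path | None = None) -> None:
    """Write SCD regions as a TSV and optionally as BED6.

    TSV columns: protein_id, start, end, span, n_motifs, motif_positions
    (comma-joined, 1-based).  BED6 uses 0-based half-open coordinates
    (start-1, end), name ``SCD``, score = n_motifs, strand ``.``.
    """
    rows = [
        (
            r.protein_id,
            r.start,
            r.end,
            r.span,
            r.n_motifs,
            ",".join(str(p) for p in r.motif_positions),
        )
        for r in regions
    ]
    df = pd.DataFrame(rows, columns=CENSUS_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in regions:
                fh.write(f"{r.protein_id}\t{r.start - 1}\t{r.end}\tSCD\t{r.n_motifs}\t.\n")


def read_census(path: str | Path) -> pd.DataFrame:
    """Read back a census TSV written by :func:`write_census`."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = set(CENSUS_COLUMNS) - set(df.columns)
    if missing:
        raise SeqioError(f"census file missing columns: {sorted(missing)}")
    return df


def read_id_list(path: str | Path) -> list[str]:
    """Plain-text protein-id list, one id per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
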