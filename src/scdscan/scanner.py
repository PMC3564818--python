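"""Detection of S/T-Q cluster domains (SCDs).

An SCD is a protein region holding at least ``k`` S/T-Q dipeptide motifs
(a serine or threonine immediately followed by glutamine — the PIKK-kinase
consensus) within a span of at most ``W`` residues.  The default
definition is k=3, W=50.

Detection is exhaustive rather than regex-greedy: every motif occurrence
is enumerated, every window of ``k`` consecutive occurrences is tested
against the span rule, and overlapping qualifying windows are merged
transitively into maximal regions.  The span of a candidate window runs
from the S/T of its first motif through the Q of its last motif,
inclusive.  Because motif occurrences are already position-sorted, any
k-subset of occurrences spanning <= W contains k *consecutive*
occurrences spanning <= W, so consecutive-window testing loses nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import ProteinRecord, Proteome

DEFAULT_MOTIF = "[ST]Q"


def parse_motif(pattern: str) -> tuple[frozenset[str], ...]:
    """Parse a fixed-length class pattern like ``[ST]Q`` into residue sets.

    Supported syntax: plain residues and ``[...]`` classes.  General
    PROSITE syntax (gaps, repeats) is intentionally unsupported.
    """
    classes: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise ValueError(f"unclosed '[' in motif pattern {pattern!r}")
            members = pattern[i + 1 : j]
            if not members:
                raise ValueError(f"empty class in motif pattern {pattern!r}")
            classes.append(frozenset(members.upper()))
            i = j + 1
        elif ch.isalpha():
            classes.append(frozenset(ch.upper()))
            i += 1
        else:
            raise ValueError(f"unsupported character {ch!r} in motif pattern")
    if not classes:
        raise ValueError("empty motif pattern")
    return tuple(classes)


@dataclass(frozen=True)
class ScdDefinition:
    """Parameterized SCD definition: >= min_motifs motifs within max_span."""

    min_motifs: int = 3
    max_span: int = 50
    motif: str = DEFAULT_MOTIF

    def __post_init__(self) -> None:
        if self.min_motifs < 2:
            raise ValueError("min_motifs must be >= 2")
        if self.max_span < 2 * self.min_motifs:
            raise ValueError(
                "max_span must be >= 2 * min_motifs "
                f"(got W={self.max_span}, k={self.min_motifs})"
            )

    @property
    def motif_length(self) -> int:
        return len(parse_motif(self.motif))


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; position is the 1-based index of the S/T."""

    protein_id: str
    position: int
    dipeptide: str


@dataclass(frozen=True)
class SCDRegion:
    """A maximal cluster region, 1-based inclusive coordinates.

    ``start`` is the S/T position of the first member motif, ``end`` the Q
    position of the last member motif.
    """

    protein_id: str
    start: int
    end: int
    motif_positions: tuple[int, ...]

    @property
    def n_motifs(self) -> int:
        return len(self.motif_positions)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def motif_positions(sequence: str, motif: str = DEFAULT_MOTIF) -> np.ndarray:
    """All 1-based start positions of the motif in ``sequence`` (exhaustive)."""
    classes = parse_motif(motif)
    m = len(classes)
    n = len(sequence)
    if n < m:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(sequence.encode("latin-1"), dtype=np.uint8)
    mask = np.ones(n - m + 1, dtype=bool)
    for j, cls in enumerate(classes):
        lut = np.zeros(256, dtype=bool)
        lut[[ord(c) for c in cls]] = True
        mask &= lut[arr[j : n - m + 1 + j]]
    return np.flatnonzero(mask).astype(np.int64) + 1


def find_motifs(record: ProteinRecord, motif: str = DEFAULT_MOTIF) -> list[MotifHit]:
    """All motif occurrences in one protein, in increasing position order."""
    m = len(parse_motif(motif))
    return [
        MotifHit(record.id, int(p), record.sequence[p - 1 : p - 1 + m])
        for p in motif_positions(record.sequence, motif)
    ]


def _positions_of(hits: Sequence[MotifHit] | np.ndarray | Sequence[int]) -> np.ndarray:
    if len(hits) and isinstance(hits[0], MotifHit):
        return np.asarray([h.position for h in hits], dtype=np.int64)
    return np.asarray(hits, dtype=np.int64)


def find_scd_regions(
    hits: Sequence[MotifHit] | Sequence[int] | np.ndarray,
    definition: ScdDefinition = ScdDefinition(),
    protein_id: str | None = None,
) -> list[SCDRegion]:
    """Maximal SCD regions from one protein's sorted motif occurrences.

    A window of k consecutive occurrences (p_j .. p_{j+k-1}) qualifies iff
    its span (p_{j+k-1} + motif_length - 1) - p_j + 1 <= W.  Qualifying
    windows sharing occurrences are merged transitively.
    """
    pos = _positions_of(hits)
    if protein_id is None:
        protein_id = hits[0].protein_id if len(pos) and isinstance(hits[0], MotifHit) else ""
    k = definition.min_motifs
    if len(pos) < k:
        return []
    if np.any(np.diff(pos) <= 0):
        raise ValueError("motif positions must be strictly increasing")
    m = definition.motif_length
    spans = pos[k - 1 :] + (m - 1) - pos[: len(pos) - k + 1] + 1
    qualifying = np.flatnonzero(spans <= definition.max_span)
    if len(qualifying) == 0:
        return []
    regions: list[SCDRegion] = []
    first = int(qualifying[0])
    last_hit = first + k - 1
    for j in qualifying[1:]:
        j = int(j)
        if j <= last_hit:  # shares >= 1 occurrence with the open region
            last_hit = j + k - 1
        else:
            regions.append(_make_region(protein_id, pos, first, last_hit, m))
            first, last_hit = j, j + k - 1
    regions.append(_make_region(protein_id, pos, first, last_hit, m))
    return regions


def _make_region(
    protein_id: str, pos: np.ndarray, first: int, last: int, motif_len: int
) -> SCDRegion:
    members = tuple(int(p) for p in pos[first : last + 1])
    return SCDRegion(
        protein_id=protein_id,
        start=members[0],
        end=members[-1] + motif_len - 1,
        motif_positions=members,
    )


@dataclass
class CensusResult:
    """Per-protein SCD regions for a whole proteome under one definition."""

    definition: ScdDefinition
    regions_by_protein: dict[str, list[SCDRegion]] = field(default_factory=dict)

    @property
    def regions(self) -> list[SCDRegion]:
        return [r for regs in self.regions_by_protein.values() for r in regs]

    @property
    def census_ids(self) -> list[str]:
        return [pid for pid, regs in self.regions_by_protein.items() if regs]

    @property
    def census_size(self) -> int:
        return len(self.census_ids)

    @property
    def n_regions(self) -> int:
        return sum(len(regs) for regs in self.regions_by_protein.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.protein_id, r.start, r.end, r.span, r.n_motifs,
             ",".join(map(str, r.motif_positions)))
            for r in self.regions
        ]
        return pd.DataFrame(
            rows,
            columns=["protein_id", "start", "end", "span", "n_motifs", "motif_positions"],
        )


def census(proteome: Proteome, definition: ScdDefinition = ScdDefinition()) -> CensusResult:
    """Scan a whole proteome; deterministic given input order."""
    result = CensusResult(definition=definition)
    for rec in proteome:
        pos = motif_positions(rec.sequence, definition.motif)
        result.regions_by_protein[rec.id] = find_scd_regions(
            pos, definition, protein_id=rec.id
        )
    return result


def sweep_definitions(
    proteome: Proteome,
    k_values: Iterable[int] = (3, 4, 5),
    w_values: Iterable[int] = range(50, 101, 5),
    motif: str = DEFAULT_MOTIF,
) -> pd.DataFrame:
    """Census sizes over a (k, W) definition grid.

    Returns a table (k, W, census_size, n_regions).  Census size is
    non-decreasing in W at fixed k and non-increasing in k at fixed W.
    """
    k_values = sorted(set(int(k) for k in k_values))
    w_values = sorted(set(int(w) for w in w_values))
    if not k_values or not w_values:
        raise ValueError("k_values and w_values must be non-empty")
    positions = {rec.id: motif_positions(rec.sequence, motif) for rec in proteome}
    motif_len = len(parse_motif(motif))
    rows = []
    for k in k_values:
        for w in w_values:
            definition = ScdDefinition(min_motifs=k, max_span=max(w, 2 * k), motif=motif)
            size = 0
            n_regions = 0
            for pid, pos in positions.items():
                regs = find_scd_regions(pos, definition, protein_id=pid)
                if regs:
                    size += 1
                    n_regions += len(regs)
            rows.append((k, w, size, n_regions))
    return pd.DataFrame(rows, columns=["k", "W", "census_size", "n_regions"])


def min_span_statistic(
    hits_by_protein: dict[str, Sequence[MotifHit] | Sequence[int] | np.ndarray],
    k: int = 3,
    motif_length: int = 2,
) -> tuple[pd.DataFrame, int | None]:
    """Minimal qualifying span per protein and the set-wide maximum.

    For each protein with >= k motif occurrences, the minimum over windows
    of k consecutive occurrences of (p_last + motif_length - 1) - p_first + 1.
    Proteins with fewer than k occurrences are flagged (min_span is NA) and
    excluded from the maximum.  Returns (per-protein table, max or None).
    """
    rows = []
    spans_present: list[int] = []
    for pid, hits in hits_by_protein.items():
        pos = _positions_of(hits)
        if len(pos) < k:
            rows.append((pid, len(pos), pd.NA))
            continue
        spans = pos[k - 1 :] + (motif_length - 1) - pos[: len(pos) - k + 1] + 1
        best = int(spans.min())
        spans_present.append(best)
        rows.append((pid, len(pos), best))
    table = pd.DataFrame(rows, columns=["protein_id", "n_hits", "min_span"])
    return table, (max(spans_present) if spans_present else None)
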