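"""Synthetic proteomes, phosphosites and annotations with known ground truth.

The generator emulates the statistical features the census pipeline
depends on: log-normally distributed protein lengths, i.i.d. residues
from a configurable amino-acid composition (which fixes the background
S/T-Q rate at P(S or T) * P(Q) per residue), planted SCD clusters,
position-biased phosphosite flanks and planted enriched annotation
terms.  Every output is a pure function of the config including its
seed.

Planting overwrites residues rather than inserting, so the length model
stays exact.  Writing an S/T at p and a Q at p+1 can never create a motif
outside the planted set (a new motif would need an S/T immediately before
a Q, but the overwritten cells are S/T-then-Q themselves); it can at most
destroy background motifs, which a scan simply no longer sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scanner import motif_positions
from .seqio import AA20, AnnotationMap, ProteinRecord, Proteome

#: Yeast-like composition preset: S 9.0%, T 5.9%, Q 3.9%, the remaining
#: 17 residues uniform.  Config data, chosen for a realistic background
#: S/T-Q rate of about 5.8e-3 per residue.
YEAST_LIKE_FREQS: dict[str, float] = {
    **{aa: (1.0 - 0.090 - 0.059 - 0.039) / 17 for aa in AA20 if aa not in "STQ"},
    "S": 0.090,
    "T": 0.059,
    "Q": 0.039,
}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic proteome generator.

    Lengths are log-normal(mu, sigma) truncated to [min_len, max_len] by
    rejection; defaults give a median of ~400 residues, the scale of a
    typical yeast protein.  ``planted_scds`` is a list of (k, W, count)
    directives; each plant overwrites k S/T-Q dipeptides spanning <= W
    residues in a distinct protein.
    """

    n_proteins: int = 1000
    length_mu: float = 6.0
    length_sigma: float = 0.55
    min_len: int = 50
    max_len: int = 3000
    aa_frequencies: dict[str, float] | None = None
    planted_scds: tuple[tuple[int, int, int], ...] = ()
    seed: int = 0

    def frequencies(self) -> dict[str, float]:
        freqs = dict(self.aa_frequencies or YEAST_LIKE_FREQS)
        missing = set(AA20) - set(freqs)
        if missing:
            raise ValueError(f"composition missing residues: {sorted(missing)}")
        total = sum(freqs[aa] for aa in AA20)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"amino-acid frequencies sum to {total}, not 1")
        return freqs

    @property
    def true_lambda(self) -> float:
        """Background S/T-Q start rate implied by the composition."""
        f = self.frequencies()
        return (f["S"] + f["T"]) * f["Q"]


@dataclass(frozen=True)
class PlantedScd:
    protein_id: str
    start: int   # 1-based S/T of the first planted motif
    end: int     # 1-based Q of the last planted motif
    positions: tuple[int, ...]
    k: int
    W: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class GroundTruth:
    """What the generator actually planted, for recall/recovery checks."""

    planted_scds: dict[str, list[PlantedScd]] = field(default_factory=dict)
    true_lambda: float = 0.0

    @property
    def n_planted(self) -> int:
        return sum(len(v) for v in self.planted_scds.values())

    @property
    def planted_ids(self) -> set[str]:
        return {pid for pid, plants in self.planted_scds.items() if plants}


def _truncated_lognormal_lengths(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(config.n_proteins, dtype=np.int64)
    got = 0
    attempts = 0
    while got < config.n_proteins:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("length rejection sampling failed; widen [min_len, max_len]")
        draw = np.rint(
            rng.lognormal(config.length_mu, config.length_sigma, size=2 * config.n_proteins)
        ).astype(np.int64)
        draw = draw[(draw >= config.min_len) & (draw <= config.max_len)]
        take = min(len(draw), config.n_proteins - got)
        out[got : got + take] = draw[:take]
        got += take
    return out


def _spaced_offsets(k: int, W: int, rng: np.random.Generator) -> np.ndarray:
    """k sorted offsets in [0, W-2] with pairwise gaps >= 2 (non-overlapping
    dipeptides), uniform over all such combinations."""
    reduced = W - 1 - 2 * (k - 1)
    if reduced < 1:
        raise ValueError(f"cannot place {k} non-overlapping dipeptides in a span of {W}")
    base = np.sort(rng.choice(reduced, size=k, replace=False))
    return base + 2 * np.arange(k)


def generate_proteome(config: SynthConfig) -> tuple[Proteome, GroundTruth]:
    """Draw a synthetic proteome and record its planted SCDs.

    Residues are i.i.d. from the configured composition; SCDs are planted
    into distinct proteins of length >= W by overwriting k S/T-Q
    dipeptides at positions spanning <= W.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    freqs = config.frequencies()
    probs = np.array([freqs[aa] for aa in AA20])
    lengths = _truncated_lognormal_lengths(config, rng)
    aa_codes = np.frombuffer(AA20.encode("ascii"), dtype=np.uint8)
    flat = rng.choice(aa_codes, size=int(lengths.sum()), p=probs)
    bounds = np.concatenate(([0], np.cumsum(lengths)))
    seqs = [
        bytearray(flat[bounds[i] : bounds[i + 1]].tobytes())
        for i in range(config.n_proteins)
    ]
    ids = [f"SYN{i + 1:05d}" for i in range(config.n_proteins)]

    truth = GroundTruth(true_lambda=config.true_lambda)
    total_plants = sum(count for _, _, count in config.planted_scds)
    if total_plants:
        eligible_w = max(w for _, w, _ in config.planted_scds)
        eligible = [i for i in range(config.n_proteins) if lengths[i] >= eligible_w]
        if total_plants > len(eligible):
            raise ValueError(
                f"cannot plant {total_plants} SCDs: only {len(eligible)} proteins "
                f"of length >= {eligible_w}"
            )
        hosts = rng.choice(len(eligible), size=total_plants, replace=False)
        host_iter = iter(int(eligible[h]) for h in hosts)
        st_codes = np.frombuffer(b"ST", dtype=np.uint8)
        for k, W, count in config.planted_scds:
            for _ in range(count):
                i = next(host_iter)
                L = int(lengths[i])
                start0 = int(rng.integers(0, L - W + 1))  # 0-based window start
                offsets = _spaced_offsets(k, W, rng)
                positions = []
                for off in offsets:
                    p0 = start0 + int(off)
                    seqs[i][p0] = int(rng.choice(st_codes))
                    seqs[i][p0 + 1] = ord("Q")
                    positions.append(p0 + 1)  # 1-based
                plant = PlantedScd(
                    protein_id=ids[i],
                    start=positions[0],
                    end=positions[-1] + 1,
                    positions=tuple(positions),
                    k=k,
                    W=W,
                )
                truth.planted_scds.setdefault(ids[i], []).append(plant)

    records = [
        ProteinRecord(ids[i], f"synthetic protein len={int(lengths[i])}",
                      seqs[i].decode("ascii"))
        for i in range(config.n_proteins)
    ]
    return Proteome(records, source_label=f"synthetic(seed={config.seed})"), truth


@dataclass
class PhosphoTruth:
    """Planted flank biases and site placement bookkeeping."""

    flank_biases: dict[int, tuple[str, float]] = field(default_factory=dict)
    n_inside_planted: int = 0
    n_corrupted: int = 0


def generate_phosphosites(
    proteome: Proteome,
    ground_truth: GroundTruth,
    n_sites: int,
    flank_biases: dict[int, tuple[str, float]] | None = None,
    within_scd_preference: float = 0.0,
    n_corrupt: int = 0,
    flank: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, PhosphoTruth]:
    """Sample phosphosites at S/T-Q positions and bias their flanks.

    Sites are drawn without replacement from the proteome's S/T-Q
    positions, a fraction ``within_scd_preference`` of them from inside
    planted SCDs, spaced at least 2*flank+2 apart so rewritten flanks
    never collide.  ``flank_biases`` maps an offset (not 0 or +1) to
    (residue, probability): the flanking residue is rewritten so its
    marginal frequency at that offset is exactly the given probability
    (residue with probability q, otherwise a draw from the background
    composition excluding that residue).  ``n_corrupt`` rows get their
    stated residue flipped S<->T so that validation must reject them.

    Returns (rows DataFrame with columns protein_id/position/residue,
    truth record).  Raises when fewer admissible positions exist than
    requested, naming the shortfall.
    """
    rng = np.random.default_rng(seed)
    flank_biases = dict(flank_biases or {})
    for off in flank_biases:
        if off in (0, 1):
            raise ValueError("flank biases may not target offsets 0 or +1")

    candidates: list[tuple[str, int, bool]] = []  # (protein_id, position, inside)
    for rec in proteome:
        plants = ground_truth.planted_scds.get(rec.id, [])
        for p in motif_positions(rec.sequence):
            inside = any(pl.start <= p <= pl.end for pl in plants)
            candidates.append((rec.id, int(p), inside))

    min_dist = 2 * flank + 2
    n_inside = int(round(within_scd_preference * n_sites))
    inside_pool = [c for c in candidates if c[2]]
    outside_pool = [c for c in candidates if not c[2]]
    rng.shuffle(inside_pool)
    rng.shuffle(outside_pool)

    chosen: list[tuple[str, int]] = []
    taken: dict[str, list[int]] = {}

    def try_take(pool, want):
        got = 0
        for pid, pos, _ in pool:
            if got >= want:
                break
            positions = taken.setdefault(pid, [])
            if all(abs(pos - q) >= min_dist for q in positions):
                positions.append(pos)
                chosen.append((pid, pos))
                got += 1
        return got

    got_inside = try_take(inside_pool, n_inside)
    got_outside = try_take(outside_pool, n_sites - got_inside)
    shortfall = n_sites - got_inside - got_outside
    if shortfall > 0:
        raise ValueError(
            f"requested {n_sites} sites but only {n_sites - shortfall} admissible "
            f"S/T-Q positions are available (shortfall {shortfall})"
        )

    # rewrite flanks in place; background redraws use the yeast-like preset
    freqs = {aa: YEAST_LIKE_FREQS[aa] for aa in AA20}
    seqs = {rec.id: bytearray(rec.sequence, "ascii") for rec in proteome}
    for pid, pos in chosen:
        seq = seqs[pid]
        for off, (residue, q) in flank_biases.items():
            idx0 = pos - 1 + off
            if not 0 <= idx0 < len(seq):
                continue
            if rng.random() < q:
                seq[idx0] = ord(residue)
            else:
                others = [aa for aa in AA20 if aa != residue]
                w = np.array([freqs[aa] for aa in others])
                seq[idx0] = ord(rng.choice(others, p=w / w.sum()))

    new_records = [
        ProteinRecord(rec.id, rec.description, seqs[rec.id].decode("ascii"))
        for rec in proteome
    ]
    proteome.records = new_records
    proteome._index = {rec.id: rec for rec in new_records}

    rows = [
        (pid, pos, proteome[pid].sequence[pos - 1]) for pid, pos in chosen
    ]
    truth = PhosphoTruth(
        flank_biases=flank_biases,
        n_inside_planted=got_inside,
        n_corrupted=min(n_corrupt, len(rows)),
    )
    if n_corrupt:
        flip = rng.choice(len(rows), size=min(n_corrupt, len(rows)), replace=False)
        for i in flip:
            pid, pos, res = rows[i]
            rows[i] = (pid, pos, "T" if res == "S" else "S")
    df = pd.DataFrame(rows, columns=["protein_id", "position", "residue"])
    return df, truth


def write_phosphosites(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, sep="\t", index=False)


def generate_annotations(
    universe_ids: list[str],
    census_ids: set[str] | list[str],
    n_terms: int = 20,
    background_rate: float | tuple[float, float] = 0.1,
    planted: tuple[str, float, float] | None = None,
    seed: int = 0,
) -> tuple[AnnotationMap, dict]:
    """Random annotation map with an optional planted enriched term.

    Background terms annotate each universe protein independently at
    ``background_rate`` (a float, or a (low, high) range sampled per
    term), regardless of census membership.  The planted term
    ``(term_id, inside_rate, outside_rate)`` annotates census members at
    inside_rate and the rest at outside_rate.  Empty terms are dropped.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe_ids)
    census = set(census_ids)
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    truth: dict = {"background_terms": [], "planted": planted}
    arr = np.array(universe)
    for j in range(n_terms):
        if isinstance(background_rate, tuple):
            rate = float(rng.uniform(*background_rate))
        else:
            rate = float(background_rate)
        members = arr[rng.random(len(arr)) < rate]
        if len(members) == 0:
            continue
        term_id = f"BG{j + 1:04d}"
        terms[term_id] = frozenset(members.tolist())
        names[term_id] = f"background term {j + 1}"
        truth["background_terms"].append((term_id, rate))
    if planted is not None:
        term_id, inside_rate, outside_rate = planted
        if not (0 <= inside_rate <= 1 and 0 <= outside_rate <= 1):
            raise ValueError("planted rates must lie in [0, 1]")
        in_census = np.isin(arr, list(census))
        rate_vec = np.where(in_census, inside_rate, outside_rate)
        members = arr[rng.random(len(arr)) < rate_vec]
        if len(members):
            terms[term_id] = frozenset(members.tolist())
            names[term_id] = "planted enriched term"
    return AnnotationMap(terms=terms, names=names), truth


def write_annotations(annotations: AnnotationMap, path) -> None:
    """Two-column TSV (term_id, protein_id), deterministic row order."""
    with open(path, "w") as fh:
        for term_id in sorted(annotations.terms):
            name = annotations.names.get(term_id, term_id)
            for pid in sorted(annotations.terms[term_id]):
                fh.write(f"{term_id}\t{pid}\t{name}\n")
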