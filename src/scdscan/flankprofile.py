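"""Position-specific residue frequencies around phosphorylated S/T-Q sites.

The profile covers offsets -5..+5 with the phosphorylated S/T at offset 0
and (for S/T-Q sites) Q at offset +1.  Offsets falling outside a protein
(sites near a terminus) simply contribute nothing at that offset, so
per-offset denominators differ.  Non-standard residues at a flanking
offset are likewise excluded from that offset's total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scanner import SCDRegion
from .seqio import AA20, PhosphositeTable, Proteome

RESTRICT_MODES = ("any", "within_scd", "outside_scd")


@dataclass
class FlankProfile:
    """Counts and frequencies of amino acids at offsets around sites.

    ``counts`` and ``freqs`` are offset x amino-acid DataFrames (rows
    -flank..+flank, columns the 20 standard residues); every populated
    offset's frequencies sum to 1.
    """

    counts: pd.DataFrame
    n_sites: int
    n_excluded_not_q: int = 0

    @property
    def offsets(self) -> np.ndarray:
        return self.counts.index.to_numpy()

    @property
    def per_offset_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def freqs(self) -> pd.DataFrame:
        totals = self.per_offset_totals
        safe = totals.replace(0, np.nan)
        return self.counts.div(safe, axis=0).fillna(0.0)

    def __add__(self, other: "FlankProfile") -> "FlankProfile":
        if not self.counts.index.equals(other.counts.index):
            raise ValueError("profiles cover different offsets")
        return FlankProfile(
            counts=self.counts + other.counts,
            n_sites=self.n_sites + other.n_sites,
            n_excluded_not_q=self.n_excluded_not_q + other.n_excluded_not_q,
        )

    def to_tsv(self, path, what: str = "freqs") -> None:
        table = self.freqs if what == "freqs" else self.counts
        table.to_csv(path, sep="\t", index_label="offset")


def _regions_by_protein(regions) -> dict[str, list[SCDRegion]]:
    by: dict[str, list[SCDRegion]] = {}
    for r in regions or []:
        by.setdefault(r.protein_id, []).append(r)
    return by


def build_profile(
    sites: PhosphositeTable,
    proteome: Proteome,
    flank: int = 5,
    restrict_to: str = "any",
    regions=None,
    require_q: bool = True,
) -> FlankProfile:
    """Accumulate residue counts at offsets -flank..+flank around sites.

    ``restrict_to`` keeps only sites inside (``within_scd``) or outside
    (``outside_scd``) a provided region collection; a site is within an
    SCD iff its position lies in [start, end] of some region of its
    protein.  With ``require_q`` (the default, matching the pS/T-Q motif
    definition) sites whose following residue is not Q are excluded and
    counted.
    """
    if restrict_to not in RESTRICT_MODES:
        raise ValueError(f"restrict_to must be one of {RESTRICT_MODES}")
    if restrict_to != "any" and regions is None:
        raise ValueError("regions are required when restrict_to != 'any'")
    by_protein = _regions_by_protein(regions)
    offsets = np.arange(-flank, flank + 1)
    counts = pd.DataFrame(0, index=offsets, columns=list(AA20))
    aa_set = set(AA20)
    n_sites = 0
    n_excluded = 0
    for protein_id, pos in sites.sites[["protein_id", "position"]].itertuples(index=False):
        seq = proteome[protein_id].sequence
        if require_q and (pos >= len(seq) or seq[pos] != "Q"):
            n_excluded += 1
            continue
        if restrict_to != "any":
            inside = any(r.contains(pos) for r in by_protein.get(protein_id, []))
            if inside != (restrict_to == "within_scd"):
                continue
        n_sites += 1
        for off in offsets:
            idx = pos + int(off)
            if 1 <= idx <= len(seq):
                aa = seq[idx - 1]
                if aa in aa_set:
                    counts.at[int(off), aa] += 1
    return FlankProfile(counts=counts, n_sites=n_sites, n_excluded_not_q=n_excluded)


def compare_to_background(
    profile: FlankProfile, background: FlankProfile
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell log2 frequency ratio of a profile over a background.

    Ratios are log2((f + eps) / (g + eps)) with eps = 1 / (2 * max total);
    cells at offsets with a zero total in either profile are NaN.  The
    second returned frame holds delta-method standard errors of the log2
    ratio from the two binomial sampling variances.
    """
    if not profile.counts.index.equals(background.counts.index):
        raise ValueError("profiles cover different offsets")
    f = profile.freqs
    g = background.freqs
    tf = profile.per_offset_totals
    tg = background.per_offset_totals
    eps = 1.0 / (2.0 * max(tf.max(), tg.max(), 1))
    ratio = np.log2((f + eps) / (g + eps))
    var_f = (f * (1 - f)).div(tf.replace(0, np.nan), axis=0)
    var_g = (g * (1 - g)).div(tg.replace(0, np.nan), axis=0)
    se = np.sqrt(var_f / (f + eps) ** 2 + var_g / (g + eps) ** 2) / np.log(2)
    missing = (tf == 0) | (tg == 0)
    ratio.loc[missing, :] = np.nan
    se.loc[missing, :] = np.nan
    return ratio, se
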