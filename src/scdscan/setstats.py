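"""Set-level statistics for an SCD census.

Hypergeometric overlap tests against external protein lists, term
enrichment with Bonferroni and Benjamini-Hochberg correction, and a
Pearson chi-square goodness-of-fit of census protein lengths to a
log-normal distribution.

Tail convention: all over-representation p-values are inclusive upper
tails, P(X >= x).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .seqio import AnnotationMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap between a census and an external list.

    N proteins in the universe, K of them in the census, n in the external
    list, x in both.  ``expected`` is n*K/N and ``p_value`` the exact
    inclusive upper tail P(X >= x).
    """

    N: int
    K: int
    n: int
    x: int
    expected: float
    p_value: float


def overlap_test(
    census_ids: set[str] | list[str],
    external_ids: set[str] | list[str],
    universe_ids: set[str] | list[str],
) -> OverlapResult:
    """Test the overlap of the census with an external protein list.

    Ids outside the universe are dropped (with a logged count) before the
    hypergeometric calculation.
    """
    universe = set(universe_ids)
    if not universe:
        raise ValueError("empty universe")
    census = set(census_ids)
    external = set(external_ids)
    dropped = len(census - universe) + len(external - universe)
    if dropped:
        logger.info("dropped %d ids outside the universe", dropped)
    census &= universe
    external &= universe
    N, K, n = len(universe), len(census), len(external)
    x = len(census & external)
    expected = n * K / N
    p_value = float(stats.hypergeom.sf(x - 1, N, K, n))
    return OverlapResult(N=N, K=K, n=n, x=x, expected=expected, p_value=p_value)


ENRICHMENT_COLUMNS = [
    "term_id", "term_name", "x", "K_t", "n", "N",
    "p_value", "p_bonferroni", "q_bh", "significant",
]


def term_enrichment(
    census_ids: set[str] | list[str],
    annotations: AnnotationMap,
    universe_ids: set[str] | list[str],
    min_term_size: int = 2,
    p_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in the census.

    Terms are restricted to the universe; only terms annotating at least
    ``min_term_size`` universe proteins are tested.  Bonferroni uses the
    number of tested terms; BH FDR is computed over the same set.  Rows
    with p_bonferroni <= p_cutoff are flagged significant, and the table
    is sorted by raw p-value (term_id breaks ties).
    """
    universe = set(universe_ids)
    if not universe:
        raise ValueError("empty universe")
    census = set(census_ids) & universe
    N, n = len(universe), len(census)
    rows = []
    for term_id in sorted(annotations.terms):
        members = annotations.terms[term_id] & universe
        K_t = len(members)
        if K_t < min_term_size:
            continue
        x = len(members & census)
        p = float(stats.hypergeom.sf(x - 1, N, K_t, n))
        rows.append((term_id, annotations.names.get(term_id, term_id), x, K_t, p))
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    T = len(rows)
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "x", "K_t", "p_value"])
    df["n"] = n
    df["N"] = N
    df["p_bonferroni"] = np.minimum(1.0, df["p_value"] * T)
    df["q_bh"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["p_bonferroni"] <= p_cutoff
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return df[ENRICHMENT_COLUMNS]


@dataclass(frozen=True)
class GofResult:
    """Pearson chi-square fit of lengths against a fitted log-normal."""

    mu_hat: float
    sigma_hat: float
    n_bins: int
    chi2: float
    df: int
    p_value: float


def lognormal_gof(lengths, n_bins: int = 20) -> GofResult:
    """Goodness of fit of protein lengths to a log-normal distribution.

    (mu, sigma) are fit by maximum likelihood on natural-log lengths; the
    fitted distribution is partitioned into equal-probability bins,
    adjacent bins merged until every expected count is >= 5, and Pearson's
    chi-square compared to chi2 with df = bins - 3 (two fitted
    parameters).
    """
    x = np.log(np.asarray(list(lengths), dtype=float))
    if len(x) < 30:
        raise ValueError("need at least 30 lengths")
    if np.any(~np.isfinite(x)):
        raise ValueError("lengths must be positive")
    mu = float(x.mean())
    sigma = float(x.std(ddof=0))
    if sigma == 0.0:
        raise ValueError("all lengths identical; log-normal fit is degenerate")
    n = len(x)
    edges = mu + sigma * stats.norm.ppf(np.arange(1, n_bins) / n_bins)
    observed = np.histogram(x, bins=np.concatenate(([-np.inf], edges, [np.inf])))[0]
    expected = np.full(n_bins, n / n_bins, dtype=float)
    observed, expected = _merge_small_bins(observed.astype(float), expected)
    final_bins = len(expected)
    df = final_bins - 3
    if df < 1:
        raise ValueError("too few bins after merging for a chi-square test")
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df))
    return GofResult(mu_hat=mu, sigma_hat=sigma, n_bins=final_bins,
                     chi2=chi2, df=df, p_value=p)


def _merge_small_bins(observed: np.ndarray, expected: np.ndarray,
                      min_expected: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Merge the smallest-expectation bin into its smaller neighbour until
    every expected count reaches ``min_expected``."""
    obs = list(observed)
    exp = list(expected)
    while len(exp) > 1 and min(exp) < min_expected:
        i = int(np.argmin(exp))
        if i == 0:
            j = 1
        elif i == len(exp) - 1:
            j = i - 1
        else:
            j = i - 1 if exp[i - 1] <= exp[i + 1] else i + 1
        lo, hi = min(i, j), max(i, j)
        obs[lo] += obs[hi]
        exp[lo] += exp[hi]
        del obs[hi], exp[hi]
    return np.asarray(obs), np.asarray(exp)
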