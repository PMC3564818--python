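"""Null-model probabilities, rate estimation and Poisson-binomial tails."""

import itertools

import numpy as np
import pytest
from scipy import stats

from scdscan.nullmodel import (
    census_significance,
    estimate_rates,
    expected_census,
    poisson_binomial_pmf,
    poisson_binomial_sf,
    proteome_null_probs,
    scd_probability,
    scd_probability_curve,
)
from scdscan.scanner import ScdDefinition
from scdscan.seqio import ProteinRecord, Proteome


# ---------------------------------------------------------------- rates

def _proteome_with(counts_lengths):
    records = []
    for i, (m, L) in enumerate(counts_lengths):
        seq = list("A" * L)
        for j in range(m):  # spaced S/T-Q dipeptides
            seq[4 * j] = "S"
            seq[4 * j + 1] = "Q"
        records.append(ProteinRecord(f"P{i}", "", "".join(seq)))
    return Proteome(records)


def test_per_protein_rate():
    rates = estimate_rates(_proteome_with([(5, 100)]), mode="per_protein")
    assert rates["lam"].iloc[0] == pytest.approx(0.05)


def test_global_mean_per_protein_rate():
    rates = estimate_rates(
        _proteome_with([(2, 100), (4, 200)]), mode="global_mean_per_protein"
    )
    assert rates["lam"].tolist() == pytest.approx([3 / 100, 3 / 200])


def test_global_per_residue_rate():
    rates = estimate_rates(
        _proteome_with([(2, 100), (4, 200)]), mode="global_per_residue"
    )
    assert rates["lam"].tolist() == pytest.approx([0.02, 0.02])


def test_unknown_mode_rejected():
    with pytest.raises(ValueError):
        estimate_rates(_proteome_with([(1, 50)]), mode="bogus")


# ---------------------------------------------------------------- p_i basics

@pytest.mark.parametrize("model", ["indicator", "dipeptide"])
def test_zero_rate_gives_zero_probability(model):
    assert scd_probability(500, 0.0, model=model).p == 0.0


@pytest.mark.parametrize("model", ["indicator", "dipeptide"])
def test_protein_too_short_for_k_motifs(model):
    assert scd_probability(5, 0.1, k=3, model=model).p == 0.0


def test_rate_above_one_rejected():
    with pytest.raises(ValueError):
        scd_probability(100, 1.5)


def test_degenerate_window_reduces_to_binomial_tail():
    # W >= L: the event is simply ">= k events anywhere in L positions"
    L, lam, k = 12, 0.08, 3
    exact = scd_probability(L, lam, k=k, W=L, method="exact_small",
                            model="indicator").p
    assert exact == pytest.approx(float(stats.binom.sf(k - 1, L, lam)), abs=1e-12)


@pytest.mark.parametrize(
    "L,lam,k,W",
    [(20, 0.1, 3, 10), (18, 0.05, 2, 8), (15, 0.02, 2, 15)],
)
def test_monte_carlo_within_3se_of_enumeration_indicator(L, lam, k, W):
    exact = scd_probability(L, lam, k, W, method="exact_small", model="indicator").p
    mc = scd_probability(L, lam, k, W, method="monte_carlo", n_sims=100_000,
                         seed=123, model="indicator")
    assert abs(mc.p - exact) <= 3 * max(mc.mc_se, 1e-9)


@pytest.mark.parametrize(
    "L,lam,k,W",
    [(12, 0.04, 2, 6), (14, 0.09, 3, 10)],
)
def test_monte_carlo_within_3se_of_enumeration_dipeptide(L, lam, k, W):
    exact = scd_probability(L, lam, k, W, method="exact_small", model="dipeptide").p
    mc = scd_probability(L, lam, k, W, method="monte_carlo", n_sims=200_000,
                         seed=321, model="dipeptide")
    assert abs(mc.p - exact) <= 3 * max(mc.mc_se, 1e-9)


def test_dipeptide_model_never_exceeds_indicator_model():
    """The two-residue footprint forbids adjacent motifs, so the
    sequence-faithful event probability is below the independent-indicator
    idealization; the gap is the footprint error of the idealization."""
    for L, lam, k, W in [(14, 0.05, 2, 6), (13, 0.1, 3, 10), (12, 0.08, 2, 12)]:
        dip = scd_probability(L, lam, k, W, method="exact_small", model="dipeptide").p
        ind = scd_probability(L, lam, k, W, method="exact_small", model="indicator").p
        assert dip <= ind
        assert dip >= 0.5 * ind  # same order of magnitude


def test_approximation_tracks_monte_carlo_at_moderate_rates():
    for L, lam in [(400, 0.006), (800, 0.01)]:
        approx = scd_probability(L, lam, method="approximation", model="dipeptide").p
        mc = scd_probability(L, lam, method="monte_carlo", n_sims=100_000,
                             seed=7, model="dipeptide")
        assert approx == pytest.approx(mc.p, abs=max(6 * mc.mc_se, 0.2 * mc.p))


def test_probability_curve_is_monotone_and_matches_point_estimate():
    curve = scd_probability_curve(0.006, 3, 50, L_max=800, n_sims=50_000, seed=3)
    lengths = np.arange(1, 801)
    p = curve.p_at(lengths)
    assert np.all(np.diff(p) >= 0)
    assert curve.p_at(800) == p[-1]
    with pytest.raises(ValueError):
        curve.p_at(801)


def test_monotonicity_in_rate_window_and_k_with_shared_seeds():
    lams = [0.02, 0.05, 0.1]
    L = 20
    curves = {
        (lam, k, W): scd_probability_curve(lam, k, W, L_max=L, n_sims=50_000,
                                           seed=99, model="indicator")
        for lam in lams for k in (2, 3) for W in (5, 10)
    }
    for k in (2, 3):
        for W in (5, 10):
            ps = [curves[(lam, k, W)].p_at(L) for lam in lams]
            assert ps == sorted(ps)
    for lam in lams:
        for k in (2, 3):
            assert curves[(lam, k, 5)].p_at(L) <= curves[(lam, k, 10)].p_at(L)
        for W in (5, 10):
            assert curves[(lam, 3, W)].p_at(L) <= curves[(lam, 2, W)].p_at(L)


# ---------------------------------------------------------------- census level

def test_expected_census_examples():
    assert expected_census([]) == 0.0
    assert expected_census([0.25] * 10) == pytest.approx(2.5)


def test_proteome_null_probs_deduplicates_and_is_deterministic():
    proteome = _proteome_with([(3, 200), (3, 200), (5, 400)])
    rates = estimate_rates(proteome, mode="per_protein")
    probs1 = proteome_null_probs(rates, ScdDefinition(), n_sims=20_000, seed=42)
    probs2 = proteome_null_probs(rates, ScdDefinition(), n_sims=20_000, seed=42)
    assert probs1["p_i"].tolist() == probs2["p_i"].tolist()
    assert probs1["p_i"].iloc[0] == probs1["p_i"].iloc[1]  # shared (L, lam) class


def test_poisson_binomial_pmf_is_a_distribution():
    rng = np.random.default_rng(1)
    p = rng.random(50)
    pmf = poisson_binomial_pmf(p)
    assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
    assert poisson_binomial_sf(p, 0) == 1.0


def test_poisson_binomial_tail_matches_enumeration_n12():
    rng = np.random.default_rng(8)
    p = rng.random(12)
    brute = np.zeros(13)
    for bits in itertools.product((0, 1), repeat=12):
        w = 1.0
        for pi, b in zip(p, bits):
            w *= pi if b else 1.0 - pi
        brute[sum(bits)] += w
    for x in range(14):
        expected = brute[x:].sum() if x <= 12 else 0.0
        assert poisson_binomial_sf(p, x) == pytest.approx(expected, abs=1e-12)


def test_all_half_probs_observed_zero_tail_is_one():
    result = census_significance([0.5] * 4, observed=0)
    assert result.p_value == 1.0


def test_observed_at_expectation_gives_central_p_value():
    """Observing round(sum p_i) successes should not be surprising."""
    rng = np.random.default_rng(5)
    p = rng.uniform(0.01, 0.3, size=300)
    observed = int(round(p.sum()))
    result = census_significance(p, observed)
    assert 0.3 <= result.p_value <= 0.7


def test_normal_refined_close_to_exact_for_moderate_n():
    rng = np.random.default_rng(6)
    p = rng.uniform(0.05, 0.4, size=500)
    observed = int(round(p.sum() + 2 * np.sqrt(np.sum(p * (1 - p)))))
    exact = census_significance(p, observed, tail_method="exact_dp").p_value
    approx = census_significance(p, observed, tail_method="normal_refined").p_value
    assert approx == pytest.approx(exact, rel=0.2)


def test_tiny_p_values_display_as_floor():
    result = census_significance([1e-9] * 10, observed=10)
    assert result.p_value_display == "< 1e-15"
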