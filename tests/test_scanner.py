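"""Motif enumeration and SCD region detection against brute-force oracles."""

import itertools

import numpy as np
import pytest

from scdscan.scanner import (
    ScdDefinition,
    SCDRegion,
    census,
    find_motifs,
    find_scd_regions,
    min_span_statistic,
    motif_positions,
    parse_motif,
    sweep_definitions,
)
from scdscan.seqio import ProteinRecord, Proteome
from scdscan.synthdata import YEAST_LIKE_FREQS, SynthConfig, generate_proteome


# ---------------------------------------------------------------- oracles

def oracle_motif_positions(sequence: str) -> list[int]:
    """Test every index i for sequence[i] in {S,T} and sequence[i+1] == Q."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "ST" and sequence[i + 1] == "Q"
    ]


def oracle_regions(positions, k, W):
    """Union of the position intervals of ALL qualifying k-subsets."""
    intervals = []
    for subset in itertools.combinations(positions, k):
        span = (subset[-1] + 1) - subset[0] + 1
        if span <= W:
            intervals.append((subset[0], subset[-1] + 1))
    if not intervals:
        return []
    intervals.sort()
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(m) for m in merged]


def random_sequence(rng, length):
    aas = np.array(list(YEAST_LIKE_FREQS))
    probs = np.array(list(YEAST_LIKE_FREQS.values()))
    return "".join(rng.choice(aas, size=length, p=probs))


# ---------------------------------------------------------------- motifs

@pytest.mark.parametrize(
    "sequence,expected",
    [
        ("SQ", [1]),
        ("AAASQATQGG", [4, 7]),
        ("", []),
        ("Q", []),
        ("SQSQSQ", [1, 3, 5]),
        ("XQSQUQ", [3]),  # ambiguity characters never match S, T or Q
        ("TQQQ", [1]),
    ],
)
def test_motif_positions_examples(sequence, expected):
    assert motif_positions(sequence).tolist() == expected


def test_find_motifs_reports_dipeptide_and_protein_id():
    rec = ProteinRecord("P9", "", "AASQATQA")
    hits = find_motifs(rec)
    assert [(h.protein_id, h.position, h.dipeptide) for h in hits] == [
        ("P9", 3, "SQ"),
        ("P9", 6, "TQ"),
    ]


def test_motif_scan_matches_bruteforce_on_random_sequences():
    rng = np.random.default_rng(21)
    for _ in range(200):
        seq = random_sequence(rng, int(rng.integers(10, 500)))
        assert motif_positions(seq).tolist() == oracle_motif_positions(seq)


def test_parse_motif_rejects_bad_patterns():
    for bad in ("", "[ST", "[]Q", "S-Q"):
        with pytest.raises(ValueError):
            parse_motif(bad)


# ---------------------------------------------------------------- regions

def test_region_boundary_inclusion():
    regions = find_scd_regions([10, 30, 58], ScdDefinition(3, 50), "P")
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end, r.span, r.n_motifs) == (10, 59, 50, 3)


def test_region_boundary_exclusion():
    assert find_scd_regions([10, 30, 59], ScdDefinition(3, 50), "P") == []


def test_chained_qualifying_windows_merge():
    regions = find_scd_regions([5, 20, 40, 60], ScdDefinition(3, 50), "P")
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end, r.n_motifs) == (5, 61, 4)


def test_separated_clusters_stay_distinct():
    regions = find_scd_regions([1, 5, 9, 500, 504, 508], ScdDefinition(3, 50), "P")
    assert [(r.start, r.end) for r in regions] == [(1, 10), (500, 509)]


def test_fewer_hits_than_k_gives_no_region():
    assert find_scd_regions([3, 9], ScdDefinition(3, 50), "P") == []


def test_regions_match_exhaustive_subset_oracle_on_random_sequences():
    rng = np.random.default_rng(33)
    definition = ScdDefinition(3, 50)
    for _ in range(150):
        seq = random_sequence(rng, int(rng.integers(10, 2000)))
        pos = motif_positions(seq)
        got = [(r.start, r.end) for r in find_scd_regions(pos, definition, "P")]
        assert got == oracle_regions(pos.tolist(), 3, 50)


def test_merging_is_idempotent_on_member_hits():
    rng = np.random.default_rng(55)
    definition = ScdDefinition(3, 50)
    for _ in range(100):
        seq = random_sequence(rng, int(rng.integers(100, 1500)))
        regions = find_scd_regions(motif_positions(seq), definition, "P")
        for r in regions:
            again = find_scd_regions(list(r.motif_positions), definition, "P")
            assert again == [r]


# ---------------------------------------------------------------- census

def test_census_counts_proteins_with_planted_clusters_only():
    config = SynthConfig(
        n_proteins=10,
        aa_frequencies={
            **{aa: 1 / 17 for aa in "ACDEFGHIKLMNPRVWY"},
            "S": 0.0, "T": 0.0, "Q": 0.0,
        },
        planted_scds=((3, 50, 4),),
        seed=2,
    )
    proteome, truth = generate_proteome(config)
    result = census(proteome)
    assert result.census_size == 4
    assert set(result.census_ids) == truth.planted_ids


def test_census_empty_proteome():
    result = census(Proteome([]))
    assert result.census_size == 0
    assert result.regions == []


def test_unbounded_span_reduces_to_total_motif_count(synthetic_proteome):
    proteome, _, _ = synthetic_proteome
    L_max = max(rec.length for rec in proteome)
    result = census(proteome, ScdDefinition(3, max_span=L_max + 2))
    expected = {
        rec.id for rec in proteome if len(motif_positions(rec.sequence)) >= 3
    }
    assert set(result.census_ids) == expected


# ---------------------------------------------------------------- sweep

def test_sweep_single_protein_span_threshold():
    proteome = Proteome([ProteinRecord("P", "", "X" * 60)])
    # motifs planted by hand at 1, 25, 52 -> span 53
    seq = list("A" * 60)
    for p in (1, 25, 52):
        seq[p - 1] = "S"
        seq[p] = "Q"
    proteome = Proteome([ProteinRecord("P", "", "".join(seq))])
    table = sweep_definitions(proteome, k_values=[3], w_values=[50, 55])
    sizes = dict(zip(table["W"], table["census_size"]))
    assert sizes == {50: 0, 55: 1}


def test_sweep_monotonicity(synthetic_proteome):
    proteome, _, _ = synthetic_proteome
    table = sweep_definitions(proteome, k_values=[3, 4, 5],
                              w_values=range(50, 101, 5))
    for k in (3, 4, 5):
        sizes = table[table["k"] == k].sort_values("W")["census_size"].to_numpy()
        assert np.all(np.diff(sizes) >= 0)
    for w in range(50, 101, 5):
        sizes = table[table["W"] == w].sort_values("k")["census_size"].to_numpy()
        assert np.all(np.diff(sizes) <= 0)


# ---------------------------------------------------------------- min span

@pytest.mark.parametrize(
    "positions,expected",
    [([1, 10, 20], 21), ([1, 10, 20, 22], 14)],
)
def test_min_span_examples(positions, expected):
    table, mx = min_span_statistic({"p": positions}, k=3)
    assert table["min_span"].iloc[0] == expected
    assert mx == expected


def test_min_span_flags_proteins_with_too_few_hits():
    table, mx = min_span_statistic({"a": [1, 5], "b": [1, 10, 20]}, k=3)
    assert table.set_index("protein_id")["min_span"].isna()["a"]
    assert mx == 21


def test_min_span_matches_bruteforce():
    rng = np.random.default_rng(77)
    for _ in range(100):
        n = int(rng.integers(3, 12))
        pos = np.sort(rng.choice(2000, size=n, replace=False) + 1).tolist()
        table, _ = min_span_statistic({"p": pos}, k=3)
        brute = min(
            (c[-1] + 1) - c[0] + 1 for c in itertools.combinations(pos, 3)
        )
        assert table["min_span"].iloc[0] == brute


def test_definition_validation():
    with pytest.raises(ValueError):
        ScdDefinition(min_motifs=1)
    with pytest.raises(ValueError):
        ScdDefinition(min_motifs=3, max_span=5)
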