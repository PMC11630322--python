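"""Profile-comparison statistics: Jaccard, overlaps, PPI pairs, co-enrichment."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from isoora.annotations import DomainAnnotation
from isoora.compare import (
    ProfilePair,
    coenrichment_cooccurrence,
    jaccard,
    jaccard_profile_summary,
    load_interactions,
    overlap_significance,
    ppi_pair_proportion,
    ppi_proportion_compare,
)


# -- Jaccard ----------------------------------------------------------------


def test_jaccard_identical_sets():
    assert jaccard({"x", "y"}, {"x", "y"}) == 1.0


def test_jaccard_disjoint_sets():
    assert jaccard({"x"}, {"y"}) == 0.0


def test_jaccard_partial_overlap():
    assert jaccard({"x", "y", "z"}, {"y", "z", "w"}) == 0.5


def test_jaccard_empty_sets_defined_as_zero():
    assert jaccard(set(), set()) == 0.0


def test_jaccard_symmetric_and_one_iff_equal():
    rng = np.random.default_rng(0)
    universe = [f"t{i}" for i in range(20)]
    for _ in range(50):
        a = {t for t in universe if rng.random() < 0.4}
        b = {t for t in universe if rng.random() < 0.4}
        assert jaccard(a, b) == jaccard(b, a)
        if a or b:
            assert (jaccard(a, b) == 1.0) == (a == b)


def test_profile_summary_fraction_below_cutpoint():
    pairs = [
        ProfilePair(frozenset(a), frozenset(b))
        for a, b in [
            ({"1"}, {"2"}),                      # 0.0
            (set("abcdefghijklmnopqrs"), set("abcdefghijklmnopqrst")),  # 19/20
            ({"1", "2", "3", "4"}, {"4", "5", "6", "7", "8"}),  # 1/8
            ({"1", "2"}, {"2", "3"}),            # 1/3
        ]
    ]
    indices, fraction = jaccard_profile_summary(pairs, cutpoint=0.1)
    assert indices == pytest.approx([0.0, 19 / 20, 1 / 8, 1 / 3])
    assert fraction == 0.25


def test_profile_summary_identical_profiles():
    pairs = [ProfilePair(frozenset({"a"}), frozenset({"a"}))] * 3
    _, fraction = jaccard_profile_summary(pairs, cutpoint=0.1)
    assert fraction == 0.0


def test_profile_summary_planted_split():
    """100 synthetic datasets constructed so 75 have index < 0.1."""
    low = [ProfilePair(frozenset({"a", "b"}), frozenset({"c", "d"}))] * 75
    high = [ProfilePair(frozenset({"a", "b"}), frozenset({"b", "c"}))] * 25
    _, fraction = jaccard_profile_summary(low + high, cutpoint=0.1)
    assert fraction == 0.75


# -- overlap significance ---------------------------------------------------


def _brute_force_overlap(k, set1, set2, N) -> float:
    total = Fraction(0)
    for i in range(k, min(set1, set2) + 1):
        total += Fraction(math.comb(set1, i) * math.comb(N - set1, set2 - i))
    return float(total / math.comb(N, set2))


def test_overlap_zero_is_certain():
    assert overlap_significance(0, 5, 5, 20).linear_p == 1.0


def test_overlap_matches_brute_force_enumeration():
    res = overlap_significance(3, 8, 7, 20)  # overlap near its expectation
    assert res.linear_p == pytest.approx(_brute_force_overlap(3, 8, 7, 20), rel=1e-12)
    assert 0.3 < res.linear_p < 1.0


def test_overlap_monotone_decreasing_in_k():
    values = [overlap_significance(k, 8, 7, 20).log10_p for k in range(0, 8)]
    assert all(a >= b for a, b in zip(values, values[1:]))


def test_overlap_invalid_counts_rejected():
    with pytest.raises(ValueError):
        overlap_significance(8, 5, 7, 20)
    with pytest.raises(ValueError):
        overlap_significance(1, 25, 7, 20)


# -- PPI pair proportions ---------------------------------------------------


def test_ppi_proportion_simple():
    assert ppi_pair_proportion({"a", "b", "c"}, [("a", "b")]) == pytest.approx(1 / 3)


def test_ppi_proportion_no_interactions():
    assert ppi_pair_proportion({"a", "b", "c"}, []) == 0.0


def test_ppi_proportion_complete_graph():
    genes = {"a", "b", "c", "d"}
    pairs = [(x, y) for x in genes for y in genes if x < y]
    assert ppi_pair_proportion(genes, pairs) == 1.0


def test_ppi_proportion_orientation_invariant():
    genes = {"a", "b", "c"}
    assert ppi_pair_proportion(genes, [("a", "b")]) == ppi_pair_proportion(
        genes, [("b", "a")]
    )


def test_ppi_proportion_ignores_self_pairs_and_small_sets():
    assert ppi_pair_proportion({"a"}, [("a", "a")]) == 0.0
    assert ppi_pair_proportion({"a", "b"}, [("a", "a")]) == 0.0


def test_ppi_mannwhitney_identical_samples():
    assert ppi_proportion_compare([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == pytest.approx(1.0)


def test_load_interactions_round_trip(tmp_path):
    from isoora.simulate import write_interactions_tsv

    pairs = [("g1", "g2"), ("g2", "g3")]
    path = tmp_path / "ppi.tsv"
    write_interactions_tsv(pairs, path)
    assert load_interactions(path) == pairs


# -- domain co-enrichment vs co-occurrence ----------------------------------


def _domains_from_index(index: dict[str, set[str]]) -> list[DomainAnnotation]:
    return [
        DomainAnnotation(iso, entry)
        for entry, isoforms in index.items()
        for iso in isoforms
    ]


def test_coenrichment_identical_rankings_give_rho_one():
    # three entry pairs ranked identically on both axes -> Spearman rho = 1
    datasets = [{"E1", "E2"}, {"E2", "E3"}, {"E2", "E3"}]
    domains = _domains_from_index(
        {"E1": {"T1"}, "E2": {"T1", "T2", "T3", "T4"}, "E3": {"T2", "T3"}}
    )
    res = coenrichment_cooccurrence(datasets, domains)
    # co-enrich: (E1,E2)=1/3, (E1,E3)=0, (E2,E3)=2/3
    # co-occur:  (E1,E2)=1/4, (E1,E3)=0, (E2,E3)=2/4
    assert res.coenrich_freq[frozenset(("E2", "E3"))] == pytest.approx(2 / 3)
    assert res.cooccur_freq[frozenset(("E1", "E2"))] == pytest.approx(1 / 4)
    assert res.n_pairs == 3
    assert res.correlation == pytest.approx(1.0)


def test_coenrichment_never_jointly_enriched_pair():
    datasets = [{"E1"}, {"E2"}]
    domains = _domains_from_index({"E1": {"T1"}, "E2": {"T1"}})
    res = coenrichment_cooccurrence(datasets, domains)
    assert res.coenrich_freq[frozenset(("E1", "E2"))] == 0.0


def test_coenrichment_hand_computed_five_datasets():
    datasets = [
        {"E1", "E2"}, {"E1", "E2"}, {"E1", "E3"}, {"E2", "E3"}, {"E1", "E2", "E3"},
    ]
    domains = _domains_from_index(
        {"E1": {"T1", "T2"}, "E2": {"T1", "T2", "T3"}, "E3": {"T3"}}
    )
    res = coenrichment_cooccurrence(datasets, domains)
    assert res.coenrich_freq[frozenset(("E1", "E2"))] == pytest.approx(3 / 5)
    assert res.coenrich_freq[frozenset(("E1", "E3"))] == pytest.approx(2 / 5)
    assert res.coenrich_freq[frozenset(("E2", "E3"))] == pytest.approx(2 / 5)
    assert res.cooccur_freq[frozenset(("E1", "E2"))] == pytest.approx(2 / 3)
    assert res.cooccur_freq[frozenset(("E2", "E3"))] == pytest.approx(1 / 3)
    assert res.cooccur_freq[frozenset(("E1", "E3"))] == 0.0
    assert not math.isnan(res.correlation)


def test_coenrichment_undefined_with_single_shared_pair():
    datasets = [{"E1", "E2"}, {"E1", "E2"}]
    domains = _domains_from_index({"E1": {"T1"}, "E2": {"T1"}})
    res = coenrichment_cooccurrence(datasets, domains)
    assert res.n_pairs == 1 and math.isnan(res.correlation)
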