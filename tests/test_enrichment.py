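"""Hypergeometric tails, ORA variants and multiple-testing corrections."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from isoora.annotations import AnnotationSet, DomainAnnotation
from isoora.enrichment import (
    CountsError,
    TwoByTwo,
    adjust_pvalues,
    domain_ora,
    hypergeometric_tail,
    log_hypergeom_sf,
    parent_child_ora,
    percent,
    term_for_term_ora,
)
from isoora.ontology import OntologyGraph, OntologyTerm
from isoora import simulate as sim

from conftest import A, B, C, ROOT


# -- 2×2 counts -------------------------------------------------------------


@pytest.mark.parametrize(
    "k,n,K,N",
    [(5, 4, 10, 20), (3, 5, 2, 20), (1, 5, 10, 8), (0, 5, 14, 18)],
)
def test_invalid_counts_rejected(k, n, K, N):
    with pytest.raises(CountsError):
        TwoByTwo(k=k, n=n, K=K, N=N)


def test_tail_at_zero_is_one():
    assert hypergeometric_tail(TwoByTwo(k=0, n=5, K=4, N=10)).linear == 1.0


def test_tail_exact_small_case():
    """N=10, K=4, n=5, k=3: [C(4,3)C(6,2)+C(4,4)C(6,1)]/C(10,5) = 66/252."""
    tail = hypergeometric_tail(TwoByTwo(k=3, n=5, K=4, N=10))
    assert tail.linear == pytest.approx(66 / 252, rel=1e-12)


def _exact_tail(k: int, N: int, K: int, n: int) -> Fraction:
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i))
    return total / math.comb(N, n)


def test_tail_matches_exact_fractions_on_random_tables():
    rng = np.random.default_rng(1)
    for _ in range(300):
        N = int(rng.integers(2, 80))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        lo, hi = max(0, n + K - N), min(n, K)
        k = int(rng.integers(lo, hi + 1))
        got = math.exp(log_hypergeom_sf(k, N, K, n))
        assert got == pytest.approx(
            float(_exact_tail(k, N, K, n)), rel=1e-12, abs=0.0
        )


def test_tail_matches_scipy_logsf_in_deep_tail():
    """Independent cross-check of the log-space sum against scipy."""
    for k, N, K, n in [(99, 15803, 724, 895), (251, 7696, 454, 1957),
                       (986, 7696, 1960, 1401)]:
        ours = log_hypergeom_sf(k, N, K, n)
        theirs = stats.hypergeom.logsf(k - 1, N, K, n)
        assert ours == pytest.approx(theirs, rel=1e-9)


def test_log_linear_consistency():
    rng = np.random.default_rng(2)
    for _ in range(100):
        N = int(rng.integers(10, 500))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, N))
        k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
        tail = hypergeometric_tail(TwoByTwo(k=k, n=n, K=K, N=N))
        if tail.linear >= 1e-300:
            assert tail.linear == pytest.approx(math.exp(tail.log), rel=1e-12, abs=0.0)


def test_printed_table_consistent_with_bonferroni():
    """The published hepatoblastoma enrichment tables print corrected
    p-values: printed / raw-tail ratios are constant within a dataset (the
    per-dataset number of tested terms) though the family size itself is
    not printed.  A column-constant ratio confirms the raw tails."""
    columns = {
        "hooks_das": [
            (99, 895, 724, 15803, 4.73e-13), (101, 895, 752, 15803, 7.72e-13),
            (100, 895, 745, 15803, 1.15e-12), (110, 895, 899, 15803, 2.47e-11),
            (65, 895, 435, 15803, 1.97e-9), (42, 895, 224, 15803, 1.88e-8),
            (50, 895, 303, 15803, 2.61e-8), (83, 895, 690, 15803, 1.66e-7),
        ],
        "hooks_dge": [
            (409, 1957, 848, 7696, 9.80e-49), (251, 1957, 454, 7696, 1.22e-40),
            (249, 1957, 450, 7696, 2.30e-40), (242, 1957, 439, 7696, 1.06e-38),
            (130, 1957, 199, 7696, 2.86e-29), (154, 1957, 263, 7696, 3.52e-27),
            (102, 1957, 144, 7696, 8.06e-27), (183, 1957, 356, 7696, 3.69e-23),
        ],
    }
    for rows in columns.values():
        ratios = [
            printed / hypergeometric_tail(TwoByTwo(k=k, n=n, K=K, N=N)).linear
            for k, n, K, N, printed in rows
        ]
        spread = (max(ratios) - min(ratios)) / np.mean(ratios)
        assert spread < 0.01  # constant up to 3-sig-fig rounding of printed p
        assert np.mean(ratios) > 1000  # a large multiple-testing family


# -- term-for-term ----------------------------------------------------------


def test_term_for_term_diamond_counts(diamond, diamond_annotations):
    rows = term_for_term_ora({"g1"}, {"g1", "g2", "g3"}, diamond_annotations)
    by_term = {r.term: r for r in rows}
    assert by_term[A].counts == TwoByTwo(k=1, n=1, K=1, N=3)
    assert by_term[ROOT].counts == TwoByTwo(k=1, n=1, K=3, N=3)
    assert by_term[ROOT].p_raw == 1.0
    assert by_term[A].p_raw == pytest.approx(1 / 3)


def test_term_for_term_study_equals_population(diamond, diamond_annotations):
    pop = {"g1", "g2", "g3"}
    rows = term_for_term_ora(pop, pop, diamond_annotations)
    assert all(r.p_raw == 1.0 for r in rows)


def test_term_for_term_requires_subset(diamond, diamond_annotations):
    with pytest.raises(ValueError, match="subset"):
        term_for_term_ora({"gX"}, {"g1"}, diamond_annotations)


def test_significance_closure_on_simulated_data(sim_cohort):
    """With closed annotations, parent counts dominate child counts."""
    _, graph, bundle, table, _ = sim_cohort
    population = sorted(bundle.isoform.items())
    study = set(population[: len(population) // 5])
    rows = {r.term: r for r in term_for_term_ora(study, population, bundle.isoform)}
    for term, row in rows.items():
        for parent in graph.parents(term):
            if parent in rows:
                assert rows[parent].counts.k >= row.counts.k
                assert rows[parent].counts.K >= row.counts.K


# -- parent–child -----------------------------------------------------------


def test_parent_child_single_parent_modes_agree(chain):
    annot = AnnotationSet.from_direct(
        {"g1": {A}, "g2": {B}, "g3": {B}, "g4": {ROOT}}, chain, "gene"
    )
    pop = {"g1", "g2", "g3", "g4"}
    union = parent_child_ora({"g1"}, pop, annot, chain, mode="union")
    inter = parent_child_ora({"g1"}, pop, annot, chain, mode="intersection")
    for u, i in zip(union, inter):
        assert (u.term, u.p_raw, u.counts) == (i.term, i.p_raw, i.counts)


def test_parent_child_reduces_to_term_for_term_under_root(diamond):
    """When a term's only parent is the root and the root annotates the whole
    population, conditioning changes nothing."""
    annot = AnnotationSet.from_direct(
        {"g1": {B}, "g2": {B}, "g3": {C}, "g4": {C}}, diamond, "gene"
    )
    pop = {"g1", "g2", "g3", "g4"}
    study = {"g1", "g3"}
    pc = {r.term: r for r in parent_child_ora(study, pop, annot, diamond)}
    tt = {r.term: r for r in term_for_term_ora(study, pop, annot)}
    for term in (B, C):
        assert pc[term].p_raw == pytest.approx(tt[term].p_raw)
        assert pc[term].conditioning_counts == (len(study), len(pop))


def test_parent_child_root_gets_p_one(diamond, diamond_annotations):
    rows = parent_child_ora({"g1"}, {"g1", "g2", "g3"}, diamond_annotations, diamond)
    root_row = next(r for r in rows if r.term == ROOT)
    assert root_row.p_raw == 1.0 and root_row.flag == "root"


def test_parent_child_union_vs_intersection_brute_force(diamond):
    """Two parents annotating different subsets: conditioning sets follow
    plain set arithmetic."""
    direct = {
        "g1": {A}, "g2": {B}, "g3": {B}, "g4": {C}, "g5": {C}, "g6": {ROOT},
    }
    annot = AnnotationSet.from_direct(direct, diamond, "gene")
    pop = frozenset(direct)
    study = frozenset({"g1", "g2"})
    union = {r.term: r for r in parent_child_ora(study, pop, annot, diamond, "union")}
    inter = {r.term: r for r in
             parent_child_ora(study, pop, annot, diamond, "intersection")}
    # brute force: items annotated to b: g1,g2,g3; to c: g1,g4,g5
    b_items, c_items = {"g1", "g2", "g3"}, {"g1", "g4", "g5"}
    assert union[A].conditioning_counts == (
        len((b_items | c_items) & study), len(b_items | c_items)
    )
    assert inter[A].conditioning_counts == (
        len((b_items & c_items) & study), len(b_items & c_items)
    )
    # union: k=1, n=2, K=1, N=5 -> P(X>=1) = 1 - C(4,2)/C(5,2) = 2/5
    assert union[A].p_raw == pytest.approx(2 / 5)
    # intersection: conditioning population is {g1} alone -> k=n=K=N=1 -> p=1
    assert inter[A].p_raw == 1.0


def test_parent_child_degenerate_equals_term_for_term():
    """Star ontology where the root annotates every item: parent–child and
    term-for-term coincide row by row (acceptance property)."""
    config = sim.SimulationConfig(seed=9, n_terms=30, dag_depth=1, n_genes=120)
    graph = sim.simulate_ontology(config)
    bundle = sim.simulate_annotations(graph, config)
    # population = items annotated to the root, so the root (every leaf's
    # only parent) covers the full population
    root = next(iter(graph.roots.values()))
    population = sorted(bundle.isoform.annotated_items(root))
    study = set(population[::4])
    tt = term_for_term_ora(study, population, bundle.isoform)
    for mode in ("union", "intersection"):
        pc = parent_child_ora(study, population, bundle.isoform, graph, mode=mode)
        tt_map = {r.term: r for r in tt}
        for row in pc:
            if row.flag == "root":
                continue
            ref = tt_map[row.term]
            assert row.counts == ref.counts
            assert row.p_raw == pytest.approx(ref.p_raw, rel=1e-12)


# -- domain ORA -------------------------------------------------------------


def test_domain_entry_covering_population_is_null():
    domains = [DomainAnnotation(f"T{i}", "IPR000001") for i in range(6)]
    rows = domain_ora({"T0", "T1"}, {f"T{i}" for i in range(6)}, domains)
    assert rows[0].p_raw == 1.0


def test_domain_fully_concentrated_annotation():
    """Entry annotating exactly the study set: p = 1/C(N, n) = 1/15."""
    domains = [DomainAnnotation("T0", "IPR000001"), DomainAnnotation("T1", "IPR000001")]
    rows = domain_ora({"T0", "T1"}, {f"T{i}" for i in range(6)}, domains)
    assert rows[0].p_raw == pytest.approx(1 / 15, rel=1e-12)
    assert rows[0].p_adj == pytest.approx(1 / 15, rel=1e-12)  # single entry


def test_domain_planted_enrichment_recovered():
    """A domain carried preferentially by the study set is significant after
    Bonferroni."""
    rng = np.random.default_rng(3)
    isoforms = [f"T{i:03d}" for i in range(400)]
    domains = sim.simulate_domains(isoforms, n_entries=20, rate=0.08, rng=rng)
    target = "IPR700000"
    carriers = sorted({d.isoform for d in domains if d.entry == target})
    others = [i for i in isoforms if i not in carriers]
    study = set(carriers[:20]) | set(others[:20])
    rows = domain_ora(study, isoforms, domains)
    row = next(r for r in rows if r.term == target)
    assert row.p_adj is not None and row.p_adj < 0.05
    assert rows[0].term == target


# -- corrections ------------------------------------------------------------


def _make_rows(pvals, ks=None):
    from isoora.enrichment import EnrichmentRow

    rows = []
    for i, p in enumerate(pvals):
        k = 1 if ks is None else ks[i]
        rows.append(
            EnrichmentRow(
                term=f"GO:{i:07d}", name="", counts=TwoByTwo(k=k, n=5, K=5, N=20),
                p_raw=p, log10_p=math.log10(p) if p > 0 else -math.inf,
                method="term_for_term",
            )
        )
    return rows


def test_bonferroni_multiplies_by_family_size():
    adjusted = adjust_pvalues(_make_rows([0.01, 0.02, 0.03]), method="bonferroni")
    assert [r.p_adj for r in adjusted] == pytest.approx([0.03, 0.06, 0.09])


def test_benjamini_hochberg_step_up_with_monotonicity():
    adjusted = adjust_pvalues(
        _make_rows([0.01, 0.04, 0.03]), method="benjamini_hochberg"
    )
    assert [r.p_adj for r in adjusted] == pytest.approx([0.03, 0.04, 0.04])


def test_single_row_unchanged_by_every_method():
    for method in ("bonferroni", "holm", "benjamini_hochberg"):
        adjusted = adjust_pvalues(_make_rows([0.2]), method=method)
        assert adjusted[0].p_adj == pytest.approx(0.2)


def test_adjusted_capped_at_one():
    adjusted = adjust_pvalues(_make_rows([0.5, 0.6, 0.9]), method="bonferroni")
    assert all(r.p_adj <= 1.0 for r in adjusted)


def test_study_family_restricts_to_hit_terms():
    rows = _make_rows([0.01, 0.02, 1.0], ks=[1, 1, 0])
    adjusted = adjust_pvalues(rows, method="bonferroni", family="study")
    assert [r.p_adj for r in adjusted] == pytest.approx([0.02, 0.04, 1.0])


def test_percent_one_decimal_convention():
    assert percent(157, 895) == 17.5
    assert percent(724, 15803) == 4.6
    assert percent(0, 0) == 0.0
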