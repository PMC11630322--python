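"""Overrepresentation statistics for GO terms and protein domains.

Every test here is a one-sided (overrepresentation-only) hypergeometric
tail — Fisher's exact test against the alternative of *more* study items
annotated to the term than chance expects.  The population includes the
study set, so the 2×2 table for a term is ``(k, n−k, K−k, N−n−K+k)`` with
``k`` study items annotated, ``n`` the study size, ``K`` population items
annotated and ``N`` the population size.

Three ORA variants are provided:

* term-for-term — each term tested independently;
* parent–child (union / intersection) — each term tested conditional on the
  items annotated to its direct parents, which discounts enrichment that a
  term merely inherits from an enriched parent;
* domain ORA — term-for-term over flat (DAG-free) InterPro/ProSite entries,
  Bonferroni-corrected by default.

Tail probabilities are computed in log space: strongly enriched terms in
large studies routinely fall below the smallest positive double
(~1e-308), where a linear-scale value underflows to 0 and the log value is
authoritative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .annotations import AnnotationSet, DomainAnnotation, domain_descriptions, domain_index
from .ontology import OntologyGraph

_LN10 = math.log(10.0)

CORRECTION_METHODS = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "benjamini_hochberg": "fdr_bh",
}


class CountsError(ValueError):
    """A 2×2 table violating the contingency invariants."""


@dataclass(frozen=True)
class TwoByTwo:
    """Counts for one term: study hits ``k`` of ``n``, population hits ``K`` of ``N``."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise CountsError(f"k={self.k} outside [0, min(n={self.n}, K={self.K})]")
        if not (self.n <= self.N and self.K <= self.N):
            raise CountsError(f"n={self.n} or K={self.K} exceeds N={self.N}")
        if self.N - self.n - self.K + self.k < 0:
            raise CountsError(
                f"impossible table: N-n-K+k = "
                f"{self.N - self.n - self.K + self.k} < 0"
            )


def log_hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Natural-log upper tail P(X ≥ k) for X ~ Hypergeometric(N, K, n).

    Summed in log space from the exact log-pmf (gammaln binomials), so
    values far below the double underflow threshold remain representable.
    Returns 0.0 (= log 1) for k ≤ max(0, n+K−N) and −inf for k > min(n, K).
    """
    support_max = min(n, K)
    if k <= max(0, n + K - N):
        return 0.0
    if k > support_max:
        return -math.inf
    i = np.arange(k, support_max + 1)
    logpmf = (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(logsumexp(logpmf))


@dataclass(frozen=True)
class TailProbability:
    """A tail probability with an exact log-space representation.

    ``linear`` may underflow to 0.0; ``log`` (natural) and ``log10`` are
    authoritative.
    """

    log: float

    @property
    def log10(self) -> float:
        return self.log / _LN10

    @property
    def linear(self) -> float:
        return math.exp(self.log)

    def __float__(self) -> float:
        return self.linear


def hypergeometric_tail(counts: TwoByTwo) -> TailProbability:
    """One-sided overrepresentation p-value P(X ≥ k) for a 2×2 table."""
    return TailProbability(log=log_hypergeom_sf(counts.k, counts.N, counts.K, counts.n))


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's ORA result.

    ``p_raw`` is the linear-scale tail (0.0 on underflow); ``log10_p`` is
    authoritative.  ``conditioning_counts`` = (study_pa, pop_pa) for the
    parent–child variants, None otherwise.  ``flag`` marks degenerate rows
    (roots, empty conditioning populations, k = 0).
    """

    term: str
    name: str
    counts: TwoByTwo
    p_raw: float
    log10_p: float
    method: str
    p_adj: float | None = None
    conditioning_counts: tuple[int, int] | None = None
    flag: str = ""

    @property
    def study_percent(self) -> float:
        return percent(self.counts.k, self.counts.n)

    @property
    def population_percent(self) -> float:
        return percent(self.counts.K, self.counts.N)


def percent(numerator: int, denominator: int, digits: int = 1) -> float:
    """Proportion as a percentage rounded to ``digits`` decimals (0 if 0/0)."""
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, digits)


def _sorted_rows(rows: list[EnrichmentRow]) -> list[EnrichmentRow]:
    return sorted(rows, key=lambda r: (r.log10_p, r.term))


def _check_study(study: frozenset[str], population: frozenset[str]) -> None:
    extra = study - population
    if extra:
        raise ValueError(
            f"study set is not a subset of the population "
            f"({len(extra)} extra items, e.g. {sorted(extra)[:3]})"
        )


def term_for_term_ora(
    study: Iterable[str],
    population: Iterable[str],
    annot: AnnotationSet,
    graph: OntologyGraph | None = None,
    drop_unhit: bool = False,
) -> list[EnrichmentRow]:
    """Independent one-sided hypergeometric test per term.

    One row per term annotating at least one population item (closed
    annotations).  Terms with k = 0 get p = 1 and are flagged; pass
    ``drop_unhit=True`` to suppress them.  Rows are ordered by
    (p, accession).
    """
    study = frozenset(study)
    population = frozenset(population)
    _check_study(study, population)
    N, n = len(population), len(study)
    rows: list[EnrichmentRow] = []
    for term in sorted(annot.term_index):
        pop_items = annot.annotated_items(term) & population
        K = len(pop_items)
        if K == 0:
            continue
        k = len(pop_items & study)
        if k == 0 and drop_unhit:
            continue
        counts = TwoByTwo(k=k, n=n, K=K, N=N)
        tail = hypergeometric_tail(counts)
        rows.append(
            EnrichmentRow(
                term=term,
                name=graph.name_of(term) if graph is not None else "",
                counts=counts,
                p_raw=tail.linear,
                log10_p=tail.log10,
                method="term_for_term",
                flag="no_study_hits" if k == 0 else "",
            )
        )
    return _sorted_rows(rows)


def parent_child_ora(
    study: Iterable[str],
    population: Iterable[str],
    annot: AnnotationSet,
    graph: OntologyGraph,
    mode: str = "union",
) -> list[EnrichmentRow]:
    """Parent–child conditional ORA (union or intersection variant).

    For term t with parents pa(t), the conditioning population is the set of
    population items annotated to ANY parent (union) or ALL parents
    (intersection); the study conditioning set is defined analogously.  The
    test is then P(X ≥ k) for X ~ Hypergeometric(|pop_pa|, K_t, |study_pa|)
    where K_t counts population items annotated to t (⊆ pop_pa under the
    true-path rule).  Namespace roots have no parents and receive p = 1.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    study = frozenset(study)
    population = frozenset(population)
    _check_study(study, population)
    rows: list[EnrichmentRow] = []
    for term in sorted(annot.term_index):
        pop_t = annot.annotated_items(term) & population
        if not pop_t:
            continue
        parents = graph.parents(term) if term in graph else frozenset()
        name = graph.name_of(term)
        if not parents:
            counts = TwoByTwo(
                k=len(pop_t & study), n=len(study), K=len(pop_t), N=len(population)
            )
            rows.append(
                EnrichmentRow(
                    term=term, name=name, counts=counts, p_raw=1.0, log10_p=0.0,
                    method=f"parent_child_{mode}",
                    conditioning_counts=(len(study), len(population)),
                    flag="root",
                )
            )
            continue
        parent_sets = [annot.annotated_items(p) & population for p in sorted(parents)]
        if mode == "union":
            pop_pa: frozenset[str] = frozenset().union(*parent_sets)
        else:
            pop_pa = parent_sets[0]
            for s in parent_sets[1:]:
                pop_pa = pop_pa & s
        study_pa = pop_pa & study
        K = len(pop_t & pop_pa)
        k = len(pop_t & study_pa)
        if len(pop_pa) == 0:
            rows.append(
                EnrichmentRow(
                    term=term, name=name,
                    counts=TwoByTwo(k=0, n=0, K=0, N=0),
                    p_raw=1.0, log10_p=0.0, method=f"parent_child_{mode}",
                    conditioning_counts=(0, 0), flag="empty_conditioning",
                )
            )
            continue
        counts = TwoByTwo(k=k, n=len(study_pa), K=K, N=len(pop_pa))
        tail = hypergeometric_tail(counts)
        rows.append(
            EnrichmentRow(
                term=term, name=name, counts=counts,
                p_raw=tail.linear, log10_p=tail.log10,
                method=f"parent_child_{mode}",
                conditioning_counts=(len(study_pa), len(pop_pa)),
                flag="no_study_hits" if k == 0 else "",
            )
        )
    return _sorted_rows(rows)


def domain_ora(
    das_isoforms: Iterable[str],
    population_isoforms: Iterable[str],
    domains: Sequence[DomainAnnotation],
    correction: str = "bonferroni",
) -> list[EnrichmentRow]:
    """Term-for-term ORA over flat InterPro/ProSite entries.

    An isoform carrying one or more annotations of an entry counts as
    annotated to that entry; there is no hierarchy and no closure.
    Bonferroni correction is applied by default.
    """
    study = frozenset(das_isoforms)
    population = frozenset(population_isoforms)
    _check_study(study, population)
    N, n = len(population), len(study)
    descriptions = domain_descriptions(domains)
    rows: list[EnrichmentRow] = []
    for entry, isoforms in sorted(domain_index(domains).items()):
        pop_items = isoforms & population
        K = len(pop_items)
        if K == 0:
            continue
        k = len(pop_items & study)
        counts = TwoByTwo(k=k, n=n, K=K, N=N)
        tail = hypergeometric_tail(counts)
        rows.append(
            EnrichmentRow(
                term=entry,
                name=descriptions.get(entry, ""),
                counts=counts,
                p_raw=tail.linear,
                log10_p=tail.log10,
                method="domain",
                flag="no_study_hits" if k == 0 else "",
            )
        )
    return adjust_pvalues(_sorted_rows(rows), method=correction)


def adjust_pvalues(
    rows: list[EnrichmentRow],
    method: str = "benjamini_hochberg",
    family: str = "population",
) -> list[EnrichmentRow]:
    """Fill ``p_adj`` by multiple-testing correction over the row family.

    ``family="population"`` (default, the Ontologizer convention) corrects
    over every row — all terms attached to the population.
    ``family="study"`` corrects only over rows with k ≥ 1; other rows get
    p_adj = 1.  Methods: bonferroni, holm, benjamini_hochberg (step-up with
    monotonicity enforcement).  Adjusted values are capped at 1.
    """
    if method not in CORRECTION_METHODS:
        raise ValueError(
            f"unknown correction {method!r}; choose from {sorted(CORRECTION_METHODS)}"
        )
    if family not in ("population", "study"):
        raise ValueError(f"unknown family {family!r}")
    if not rows:
        return []
    in_family = [
        family == "population" or r.counts.k >= 1 for r in rows
    ]
    pvals = [r.p_raw for r, keep in zip(rows, in_family) if keep]
    if pvals:
        adjusted = multipletests(pvals, method=CORRECTION_METHODS[method])[1]
    else:
        adjusted = []
    out: list[EnrichmentRow] = []
    it = iter(adjusted)
    for r, keep in zip(rows, in_family):
        p_adj = float(next(it)) if keep else 1.0
        out.append(replace(r, p_adj=min(1.0, p_adj)))
    return out


__all__ = [
    "CORRECTION_METHODS",
    "CountsError",
    "EnrichmentRow",
    "TailProbability",
    "TwoByTwo",
    "adjust_pvalues",
    "domain_ora",
    "hypergeometric_tail",
    "log_hypergeom_sf",
    "parent_child_ora",
    "percent",
    "term_for_term_ora",
]
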