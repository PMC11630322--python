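"""Comparing the functional profiles of differential expression and splicing.

A dataset's "functional profile" is the set of GO terms significantly
overrepresented in its differential genes (DGE) or differential isoforms
(DAS).  This module quantifies how much those two profiles — and profiles
across datasets — agree:

* Jaccard index between enriched-term sets, with a cohort summary of how
  many datasets fall below a cut-point;
* hypergeometric significance of the overlap between two called gene sets,
  reported in log10 space because real overlaps underflow linear doubles;
* the proportion of gene pairs in a called set that share a protein–protein
  interaction (PPI), compared between DGE and DAS cohorts with a
  Mann–Whitney U test;
* co-enrichment of protein-domain pairs across datasets versus their
  co-occurrence on the same isoforms (Spearman rank correlation).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .annotations import DomainAnnotation, domain_index
from .enrichment import log_hypergeom_sf

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class ProfilePair:
    """One dataset's DGE-enriched and DAS-enriched GO term sets."""

    dge_terms: frozenset[str]
    das_terms: frozenset[str]
    dataset_label: str = ""


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a∩b| / |a∪b|; 0.0 when both sets are empty."""
    a, b = frozenset(a), frozenset(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def jaccard_profile_summary(
    pairs: Sequence[ProfilePair], cutpoint: float = 0.1
) -> tuple[list[float], float]:
    """Per-dataset DGE-vs-DAS Jaccard indices and the fraction strictly below
    ``cutpoint``."""
    if not pairs:
        raise ValueError("need at least one profile pair")
    indices = [jaccard(p.dge_terms, p.das_terms) for p in pairs]
    fraction = sum(1 for j in indices if j < cutpoint) / len(indices)
    return indices, fraction


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap significance with authoritative log10 value.

    ``linear_p`` is 0.0 when the value underflows the double range.
    """

    k: int
    set1: int
    set2: int
    universe: int
    log10_p: float

    @property
    def linear_p(self) -> float:
        return 10.0 ** self.log10_p if self.log10_p > -307 else 0.0


def overlap_significance(k: int, set1: int, set2: int, N: int) -> OverlapResult:
    """P(X ≥ k) for X ~ Hypergeometric(N, set1, set2), in log10 space.

    The universe size N must be supplied explicitly — it is the count of
    items that could have appeared in either set.
    """
    if k > min(set1, set2):
        raise ValueError(f"overlap {k} exceeds min({set1}, {set2})")
    if max(set1, set2) > N:
        raise ValueError(f"set sizes ({set1}, {set2}) exceed universe {N}")
    log_p = log_hypergeom_sf(k, N, set1, set2)
    return OverlapResult(k=k, set1=set1, set2=set2, universe=N, log10_p=log_p / _LN10)


def _normalize_pairs(interactions: Iterable[tuple[str, str]]) -> frozenset[frozenset[str]]:
    pairs = set()
    for a, b in interactions:
        if a == b:
            continue  # self-pairs excluded
        pairs.add(frozenset((a, b)))
    return frozenset(pairs)


def ppi_pair_proportion(
    genes: Iterable[str], interactions: Iterable[tuple[str, str]]
) -> float:
    """Fraction of unordered gene pairs from ``genes`` that share a PPI.

    Orientation of the interaction list is irrelevant; self-pairs are
    ignored.  Returns 0.0 for fewer than two genes (no pairs to form).
    """
    genes = frozenset(genes)
    m = len(genes)
    if m < 2:
        return 0.0
    known = _normalize_pairs(interactions)
    hits = sum(1 for a, b in combinations(sorted(genes), 2) if frozenset((a, b)) in known)
    return hits / (m * (m - 1) / 2)


def ppi_proportion_compare(
    dge_proportions: Sequence[float], das_proportions: Sequence[float]
) -> float:
    """Two-sided Mann–Whitney U p-value comparing per-dataset PPI proportions.

    The sampling unit is the dataset (one proportion per dataset per
    modality).  Identical samples give p = 1.
    """
    res = stats.mannwhitneyu(
        dge_proportions, das_proportions, alternative="two-sided"
    )
    return float(res.pvalue)


@dataclass(frozen=True)
class CoenrichmentResult:
    coenrich_freq: dict[frozenset[str], float]
    cooccur_freq: dict[frozenset[str], float]
    correlation: float  # Spearman rho; NaN when < 2 co-observed pairs
    n_pairs: int


def coenrichment_cooccurrence(
    enriched_per_dataset: Sequence[Iterable[str]],
    domains: Sequence[DomainAnnotation],
) -> CoenrichmentResult:
    """Relate domain-pair co-enrichment across datasets to co-occurrence on
    isoforms.

    For each unordered entry pair: co-enrichment frequency = fraction of
    datasets where both entries are enriched; co-occurrence frequency =
    Jaccard of the two entries' isoform sets.  The Spearman rank correlation
    runs over pairs observed on both axes (co-enriched in ≥1 dataset and
    with ≥1 isoform carrying either entry).
    """
    if len(enriched_per_dataset) < 2:
        raise ValueError("need at least two datasets")
    datasets = [frozenset(s) for s in enriched_per_dataset]
    n_datasets = len(datasets)

    coenrich: dict[frozenset[str], float] = {}
    enriched_entries = sorted(frozenset().union(*datasets))
    for a, b in combinations(enriched_entries, 2):
        pair = frozenset((a, b))
        count = sum(1 for d in datasets if a in d and b in d)
        coenrich[pair] = count / n_datasets

    index = domain_index(domains)
    cooccur: dict[frozenset[str], float] = {}
    for a, b in combinations(sorted(index), 2):
        union = index[a] | index[b]
        if union:
            cooccur[frozenset((a, b))] = len(index[a] & index[b]) / len(union)

    shared = sorted(
        (tuple(sorted(p)) for p in coenrich.keys() & cooccur.keys())
    )
    if len(shared) < 2:
        return CoenrichmentResult(coenrich, cooccur, math.nan, len(shared))
    x = [coenrich[frozenset(p)] for p in shared]
    y = [cooccur[frozenset(p)] for p in shared]
    rho = stats.spearmanr(x, y).statistic
    return CoenrichmentResult(coenrich, cooccur, float(rho), len(shared))


def load_interactions(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column TSV of interacting gene pairs (BioGrid-style export)."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path, newline="") as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: interaction row with <2 columns: {row!r}")
            pairs.append((row[0].strip(), row[1].strip()))
    return pairs


__all__ = [
    "CoenrichmentResult",
    "OverlapResult",
    "ProfilePair",
    "coenrichment_cooccurrence",
    "jaccard",
    "jaccard_profile_summary",
    "load_interactions",
    "overlap_significance",
    "ppi_pair_proportion",
    "ppi_proportion_compare",
]
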