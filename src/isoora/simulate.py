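"""Synthetic ontologies, annotations and differential tables for testing.

Real inputs to this package are a GO release, per-gene and per-isoform GO
annotation tables, a domain table and a Bayesian differential-result table —
all products of heavy external pipelines.  The generators here emulate
those inputs at small scale so every stage of the package runs end to end
without downloads, with known ground truth:

* a random single-rooted DAG standing in for a GO namespace;
* per-isoform annotations drawn at a base rate, with gene annotations
  defined as the union of the gene's isoforms' annotations;
* a differential table whose truly differential items draw posterior error
  probabilities (PEPs) from a near-zero Beta component while null items
  draw from Uniform(0, 1) — so PEPs are calibrated and the mean-PEP
  thresholding rule can be audited against realized false discoveries;
* optional planted enrichment: truly differential isoforms are drawn
  preferentially (at a configurable fold) from isoforms annotated to chosen
  terms, so ORA power can be measured.

All generators are deterministic under ``SimulationConfig.seed``, and every
writer emits exactly the dialect the corresponding parser reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .annotations import AnnotationSet, DomainAnnotation
from .diffcall import DiffRecord, DiffTable, EXPRESSION_MARKER
from .ontology import OntologyGraph, OntologyTerm

#: Synthetic term accessions live in a high block so they can never collide
#: with a real GO release.
TERM_BASE = 7_000_000
NAMESPACE = "biological_process"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``mean_extra_isoforms`` parameterizes a shifted Poisson (1 + Poisson)
    for isoforms per gene, so single-isoform genes occur and exercise the
    multi-isoform restriction of the DAS population.  ``pep_alpha/beta``
    are the Beta parameters of the true-differential PEP component (mass
    near 0); null PEPs are Uniform(0, 1).
    """

    seed: int = 0
    n_genes: int = 200
    mean_extra_isoforms: float = 0.8
    n_terms: int = 50
    dag_depth: int = 4
    base_annotation_rate: float = 0.08
    planted_terms: tuple[tuple[str, float], ...] = ()
    pep_alpha: float = 0.5
    pep_beta: float = 9.0
    fraction_differential: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_annotation_rate <= 1.0:
            raise ValueError("base_annotation_rate must be in [0, 1]")
        if not 0.0 <= self.fraction_differential <= 1.0:
            raise ValueError("fraction_differential must be in [0, 1]")
        for term, fold in self.planted_terms:
            if fold < 1.0:
                raise ValueError(f"planted fold for {term} must be >= 1, got {fold}")


def term_id(index: int) -> str:
    return f"GO:{TERM_BASE + index:07d}"


def simulate_ontology(config: SimulationConfig, rng: np.random.Generator | None = None) -> OntologyGraph:
    """Random single-rooted DAG with ``n_terms`` terms and depth ≤ ``dag_depth``.

    Term 0 is the root; every other term gets 1–2 parents drawn from the
    previous depth level, so the graph is acyclic by construction.
    """
    if config.n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    terms = [OntologyTerm(id=term_id(0), name="synthetic root", namespace=NAMESPACE)]
    levels: dict[int, list[str]] = {0: [term_id(0)]}
    max_depth = max(1, config.dag_depth)
    for i in range(1, config.n_terms):
        attainable = min(max_depth, max(levels) + 1)
        depth = int(rng.integers(1, attainable + 1))
        pool = levels[depth - 1]
        n_parents = int(rng.integers(1, 3)) if len(pool) > 1 else 1
        parents = sorted(
            rng.choice(pool, size=min(n_parents, len(pool)), replace=False).tolist()
        )
        relations = tuple(
            (p, "is_a" if rng.random() < 0.8 else "part_of") for p in parents
        )
        tid = term_id(i)
        terms.append(
            OntologyTerm(id=tid, name=f"synthetic term {i}", namespace=NAMESPACE,
                         parents=relations)
        )
        levels.setdefault(depth, []).append(tid)
    return OntologyGraph(terms)


@dataclass(frozen=True)
class AnnotationBundle:
    """Isoform- and gene-level annotation sets plus the gene→isoform map."""

    isoform: AnnotationSet
    gene: AnnotationSet
    gene_to_isoforms: dict[str, tuple[str, ...]]

    @property
    def isoforms(self) -> frozenset[str]:
        return frozenset(i for iso in self.gene_to_isoforms.values() for i in iso)


def simulate_annotations(
    graph: OntologyGraph, config: SimulationConfig, rng: np.random.Generator | None = None
) -> AnnotationBundle:
    """Draw per-isoform annotations; gene annotation = union over its isoforms."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    candidate_terms = [t for t in graph.non_obsolete_ids() if t not in graph.roots.values()]
    gene_to_isoforms: dict[str, tuple[str, ...]] = {}
    iso_direct: dict[str, set[str]] = {}
    gene_direct: dict[str, set[str]] = {}
    for g in range(config.n_genes):
        gene = f"G{g:04d}"
        n_iso = 1 + int(rng.poisson(config.mean_extra_isoforms))
        isoforms = tuple(f"T{g:04d}x{j}" for j in range(1, n_iso + 1))
        gene_to_isoforms[gene] = isoforms
        union: set[str] = set()
        for iso in isoforms:
            mask = rng.random(len(candidate_terms)) < config.base_annotation_rate
            chosen = {t for t, hit in zip(candidate_terms, mask) if hit}
            iso_direct[iso] = chosen
            union |= chosen
        gene_direct[gene] = union
    return AnnotationBundle(
        isoform=AnnotationSet.from_direct(iso_direct, graph, "isoform"),
        gene=AnnotationSet.from_direct(gene_direct, graph, "gene"),
        gene_to_isoforms=gene_to_isoforms,
    )


@dataclass(frozen=True)
class GroundTruth:
    """Which simulated items are genuinely differential."""

    genes: frozenset[str]
    isoforms: frozenset[str]


def _draw_peps(
    rng: np.random.Generator, n: int, truth_mask: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    peps = rng.uniform(0.0, 1.0, size=n)
    n_true = int(truth_mask.sum())
    if n_true:
        peps[truth_mask] = rng.beta(config.pep_alpha, config.pep_beta, size=n_true)
    return peps


def simulate_difftable(
    graph: OntologyGraph,
    bundle: AnnotationBundle,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[DiffTable, GroundTruth]:
    """Generate a differential table with calibrated PEPs and planted signal.

    Truly differential isoforms are sampled without replacement with weight
    ``fold`` for isoforms annotated (closed) to a planted term and weight 1
    otherwise.  Gene-expression rows are drawn independently of splicing.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    genes = sorted(bundle.gene_to_isoforms)
    isoforms = sorted(i for iso in bundle.gene_to_isoforms.values() for i in iso)

    n_true_genes = round(config.fraction_differential * len(genes))
    true_genes = set(
        rng.choice(genes, size=n_true_genes, replace=False).tolist()
    ) if n_true_genes else set()

    weights = np.ones(len(isoforms))
    for term, fold in config.planted_terms:
        annotated = bundle.isoform.annotated_items(term)
        for idx, iso in enumerate(isoforms):
            if iso in annotated:
                weights[idx] *= fold
    n_true_iso = round(config.fraction_differential * len(isoforms))
    if n_true_iso:
        probs = weights / weights.sum()
        true_isoforms = set(
            rng.choice(isoforms, size=n_true_iso, replace=False, p=probs).tolist()
        )
    else:
        true_isoforms = set()

    gene_mask = np.array([g in true_genes for g in genes])
    gene_peps = _draw_peps(rng, len(genes), gene_mask, config)
    gene_fc = np.where(
        gene_mask, rng.normal(0.0, 2.0, len(genes)), rng.normal(0.0, 0.2, len(genes))
    )
    iso_mask = np.array([i in true_isoforms for i in isoforms])
    iso_peps = _draw_peps(rng, len(isoforms), iso_mask, config)
    iso_fc = np.where(
        iso_mask, rng.normal(0.0, 1.5, len(isoforms)), rng.normal(0.0, 0.15, len(isoforms))
    )

    gene_of = {
        iso: gene for gene, isos in bundle.gene_to_isoforms.items() for iso in isos
    }
    records: list[DiffRecord] = []
    row = 2  # header occupies line 1 in the serialized form
    for gene, pep, fc in zip(genes, gene_peps, gene_fc):
        records.append(DiffRecord(gene, None, float(fc), float(pep), row))
        row += 1
    for iso, pep, fc in zip(isoforms, iso_peps, iso_fc):
        records.append(DiffRecord(gene_of[iso], iso, float(fc), float(pep), row))
        row += 1
    table = DiffTable(records=tuple(records))
    return table, GroundTruth(genes=frozenset(true_genes), isoforms=frozenset(true_isoforms))


def simulate_calibrated_peps(
    n: int,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, float], frozenset[str]]:
    """PEPs that are *exactly* each item's probability of being null.

    Draw each item's PEP from the two-component marginal (Beta near 0 with
    probability ``fraction_differential``, else Uniform), then decide the
    item's true status as null with probability equal to its PEP.  By
    construction E[false-discovery proportion of any selection] equals the
    selection's mean PEP, which is what the mean-PEP thresholding rule
    reports as its achieved FDR.

    Returns (item → PEP, the set of truly null items).
    """
    rng = np.random.default_rng(config.seed + 5) if rng is None else rng
    from_signal = rng.random(n) < config.fraction_differential
    peps = np.where(
        from_signal,
        rng.beta(config.pep_alpha, config.pep_beta, size=n),
        rng.uniform(0.0, 1.0, size=n),
    )
    null_mask = rng.random(n) < peps
    items = [f"I{i:05d}" for i in range(n)]
    return (
        {item: float(p) for item, p in zip(items, peps)},
        frozenset(i for i, is_null in zip(items, null_mask) if is_null),
    )


def simulate_domains(
    isoforms: Iterable[str],
    n_entries: int = 25,
    rate: float = 0.08,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[DomainAnnotation]:
    """Random flat domain annotations (entry per isoform at ``rate``)."""
    rng = np.random.default_rng(seed) if rng is None else rng
    isoforms = sorted(isoforms)
    out: list[DomainAnnotation] = []
    for e in range(n_entries):
        entry = f"IPR{700000 + e:06d}"
        mask = rng.random(len(isoforms)) < rate
        for iso, hit in zip(isoforms, mask):
            if hit:
                out.append(DomainAnnotation(iso, entry, f"synthetic domain {e}"))
    return out


def simulate_interactions(
    genes: Iterable[str], density: float = 0.02, seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Random undirected gene-pair interaction list at the given density."""
    rng = np.random.default_rng(seed) if rng is None else rng
    genes = sorted(genes)
    pairs: list[tuple[str, str]] = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if rng.random() < density:
                pairs.append((genes[i], genes[j]))
    return pairs


# ---------------------------------------------------------------------------
# Writers — one per input dialect the parsers read.


def write_hbadeals(table: DiffTable, path: str | Path) -> None:
    """Serialize to the four-column differential dialect (full float precision,
    so a parse round-trip reproduces the table exactly)."""
    with open(path, "w") as handle:
        handle.write("Gene\tIsoform\tExplogFC\tP\n")
        for r in table.records:
            isoform = EXPRESSION_MARKER if r.isoform is None else r.isoform
            handle.write(f"{r.gene}\t{isoform}\t{r.log2fc!r}\t{r.pep!r}\n")


def write_annotation_tsv(annot: AnnotationSet, path: str | Path) -> None:
    """Write direct annotations as item<TAB>semicolon-joined term list."""
    with open(path, "w") as handle:
        for item in sorted(annot.direct):
            terms = sorted(annot.direct[item])
            if terms:
                handle.write(f"{item}\t{';'.join(terms)}\n")


def write_domain_tsv(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as handle:
        for d in sorted(domains, key=lambda d: (d.entry, d.isoform)):
            handle.write(f"{d.isoform}\t{d.entry}\t{d.description}\n")


def write_interactions_tsv(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for a, b in pairs:
            handle.write(f"{a}\t{b}\n")


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    """Write a minimal OBO 1.2 serialization of the graph."""
    with open(path, "w") as handle:
        handle.write("format-version: 1.2\nontology: isoora-synthetic\n")
        for tid in sorted(graph.terms):
            term = graph.terms[tid]
            handle.write(f"\n[Term]\nid: {term.id}\nname: {term.name}\n")
            if term.namespace:
                handle.write(f"namespace: {term.namespace}\n")
            for alt, primary in sorted(graph.alt_id_map.items()):
                if primary == term.id:
                    handle.write(f"alt_id: {alt}\n")
            if term.obsolete:
                handle.write("is_obsolete: true\n")
            for parent, relation in term.parents:
                if relation == "is_a":
                    handle.write(f"is_a: {parent}\n")
                else:
                    handle.write(f"relationship: {relation} {parent}\n")


def write_obographs_json(graph: OntologyGraph, path: str | Path) -> None:
    """Write the graph as obographs JSON (PURL ids, BFO part_of predicate)."""
    import json

    def purl(tid: str) -> str:
        return "http://purl.obolibrary.org/obo/" + tid.replace(":", "_", 1)

    nodes = []
    edges = []
    for tid in sorted(graph.terms):
        term = graph.terms[tid]
        meta: dict = {"basicPropertyValues": []}
        if term.namespace:
            meta["basicPropertyValues"].append(
                {
                    "pred": "http://www.geneontology.org/formats/oboInOwl#hasOBONamespace",
                    "val": term.namespace,
                }
            )
        for alt, primary in sorted(graph.alt_id_map.items()):
            if primary == tid:
                meta["basicPropertyValues"].append(
                    {
                        "pred": "http://www.geneontology.org/formats/oboInOwl#hasAlternativeId",
                        "val": alt,
                    }
                )
        if term.obsolete:
            meta["deprecated"] = True
        nodes.append({"id": purl(tid), "lbl": term.name, "type": "CLASS", "meta": meta})
        for parent, relation in term.parents:
            pred = (
                "is_a" if relation == "is_a"
                else "http://purl.obolibrary.org/obo/BFO_0000050"
            )
            edges.append({"sub": purl(tid), "pred": pred, "obj": purl(parent)})
    doc = {"graphs": [{"nodes": nodes, "edges": edges}]}
    with open(path, "w") as handle:
        json.dump(doc, handle, indent=1, sort_keys=True)


__all__ = [
    "AnnotationBundle",
    "GroundTruth",
    "NAMESPACE",
    "SimulationConfig",
    "simulate_annotations",
    "simulate_calibrated_peps",
    "simulate_difftable",
    "simulate_domains",
    "simulate_interactions",
    "simulate_ontology",
    "term_id",
    "write_annotation_tsv",
    "write_domain_tsv",
    "write_hbadeals",
    "write_interactions_tsv",
    "write_obo",
    "write_obographs_json",
]
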