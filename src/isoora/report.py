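"""End-to-end analysis runs and textual reports.

`run_analysis` mirrors the analysis tabs of an interactive enrichment
browser as files: a JSON summary (observed and differential counts,
achieved FDRs, numbers of significant terms), ranked GO-ORA tables for DGE
and DAS, a domain-ORA table, and called-set tables.  `gene_report` writes a
per-gene textual report: the gene's isoform fold changes and PEPs, an
isoform × GO incidence matrix flagging terms significant in the
dataset-wide DAS analysis, and an isoform × domain incidence matrix.

All output is deterministic for a fixed configuration: orderings are total
(p-value, then accession) and floats are formatted with repr-stable
conversions, so re-running a configuration is byte-identical.
"""

from __future__ import annotations

import difflib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

from . import annotations as anno
from . import compare as cmp
from .diffcall import DiffTable, DifferentialCalls, call_differential, parse_hbadeals
from .enrichment import (
    EnrichmentRow,
    adjust_pvalues,
    domain_ora,
    parent_child_ora,
    term_for_term_ora,
)
from .ontology import OntologyGraph, parse_ontology

logger = logging.getLogger(__name__)

ORA_METHODS = ("term_for_term", "parent_child_union", "parent_child_intersection")


@dataclass
class RunConfig:
    """Paths and parameters for one analysis run."""

    ontology: str
    gene_annotations: str
    isoform_annotations: str
    diff_table: str
    outdir: str
    domains: str | None = None
    interactions: str | None = None
    threshold: float = 0.05
    ora_method: str = "term_for_term"
    correction: str = "benjamini_hochberg"
    significance: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.ora_method not in ORA_METHODS:
            raise ValueError(f"ora_method must be one of {ORA_METHODS}")


ENRICHMENT_COLUMNS = [
    "term", "name", "study_count", "study_size", "pop_count", "pop_size",
    "study_pct", "pop_pct", "p_raw", "log10_p", "p_adj", "method",
]


def write_enrichment_tsv(rows: Sequence[EnrichmentRow], path: Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(ENRICHMENT_COLUMNS) + "\n")
        for r in rows:
            handle.write(
                "\t".join(
                    [
                        r.term,
                        r.name,
                        str(r.counts.k),
                        str(r.counts.n),
                        str(r.counts.K),
                        str(r.counts.N),
                        f"{r.study_percent:.1f}",
                        f"{r.population_percent:.1f}",
                        f"{r.p_raw:.6g}",
                        f"{r.log10_p:.4f}",
                        "" if r.p_adj is None else f"{r.p_adj:.6g}",
                        r.method,
                    ]
                )
                + "\n"
            )


def _write_calls_tsv(table: DiffTable, calls, kind: str, path: Path) -> None:
    called = calls.called_set
    with open(path, "w") as handle:
        handle.write("item\tlog2fc\tpep\tcalled\n" if kind == "gene"
                     else "item\tlog2fc\tpep\tcalled\tgene\n")
        if kind == "gene":
            records = sorted(table.expression_records().values(), key=lambda r: r.gene)
            for r in records:
                handle.write(f"{r.gene}\t{r.log2fc!r}\t{r.pep!r}\t{int(r.gene in called)}\n")
        else:
            for r in sorted(table.isoform_records(), key=lambda r: r.isoform):
                if r.isoform not in calls.population:
                    continue
                handle.write(
                    f"{r.isoform}\t{r.log2fc!r}\t{r.pep!r}\t{int(r.isoform in called)}"
                    f"\t{r.gene}\n"
                )


def _run_ora(
    study, population, annot, graph: OntologyGraph, method: str
) -> list[EnrichmentRow]:
    if method == "term_for_term":
        return term_for_term_ora(study, population, annot, graph=graph)
    mode = method.removeprefix("parent_child_")
    return parent_child_ora(study, population, annot, graph, mode=mode)


@dataclass
class RunResult:
    """In-memory products of one analysis run."""

    graph: OntologyGraph
    table: DiffTable
    calls: DifferentialCalls
    dge_rows: list[EnrichmentRow]
    das_rows: list[EnrichmentRow]
    domain_rows: list[EnrichmentRow]
    summary: dict
    iso_annot: anno.AnnotationSet
    gene_annot: anno.AnnotationSet
    domains: list[anno.DomainAnnotation]


def run_analysis(config: RunConfig) -> RunResult:
    """Execute a full DGE + DAS (+ domain) enrichment run and write outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    graph = parse_ontology(config.ontology)
    gene_annot = anno.load_annotations(config.gene_annotations, graph, "gene")
    iso_annot = anno.load_annotations(config.isoform_annotations, graph, "isoform")
    table = parse_hbadeals(config.diff_table)
    calls = call_differential(table, config.threshold)

    dge_rows = adjust_pvalues(
        _run_ora(calls.dge.called_set, calls.dge.population, gene_annot, graph,
                 config.ora_method),
        method=config.correction,
    )
    das_rows = adjust_pvalues(
        _run_ora(calls.das.called_set, calls.das.population, iso_annot, graph,
                 config.ora_method),
        method=config.correction,
    )

    domains: list[anno.DomainAnnotation] = []
    domain_rows: list[EnrichmentRow] = []
    if config.domains:
        domains = anno.load_domains(config.domains)
        domain_rows = domain_ora(
            calls.das.called_set, calls.das.population, domains
        )

    sig = config.significance
    summary = {
        "observed_genes": len(table.genes),
        "observed_isoforms": len(table.isoforms),
        "observed_multi_isoform_genes": len(table.multi_isoform_genes()),
        "das_population_isoforms": len(calls.das.population),
        "n_dge_genes": len(calls.dge),
        "n_das_isoforms": len(calls.das),
        "n_das_genes": len(calls.das_genes),
        "dge_achieved_fdr": calls.dge.achieved_fdr,
        "das_achieved_fdr": calls.das.achieved_fdr,
        "n_significant_go_dge": sum(
            1 for r in dge_rows if r.p_adj is not None and r.p_adj < sig
        ),
        "n_significant_go_das": sum(
            1 for r in das_rows if r.p_adj is not None and r.p_adj < sig
        ),
        "n_significant_domains": sum(
            1 for r in domain_rows if r.p_adj is not None and r.p_adj < sig
        ),
        "config": {
            "threshold": config.threshold,
            "ora_method": config.ora_method,
            "correction": config.correction,
            "significance": config.significance,
            "seed": config.seed,
        },
    }

    write_enrichment_tsv(dge_rows, outdir / "dge_go.tsv")
    write_enrichment_tsv(das_rows, outdir / "das_go.tsv")
    write_enrichment_tsv(domain_rows, outdir / "interpro.tsv")
    _write_calls_tsv(table, calls.dge, "gene", outdir / "dge_calls.tsv")
    _write_calls_tsv(table, calls.das, "isoform", outdir / "das_calls.tsv")
    with open(outdir / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    logger.info(
        "run complete: %d DGE genes, %d DAS isoforms (%d genes)",
        len(calls.dge), len(calls.das), len(calls.das_genes),
    )
    return RunResult(
        graph=graph, table=table, calls=calls,
        dge_rows=dge_rows, das_rows=das_rows, domain_rows=domain_rows,
        summary=summary, iso_annot=iso_annot, gene_annot=gene_annot,
        domains=domains,
    )


class UnknownGeneError(KeyError):
    """Requested gene absent from the differential table."""


def gene_report(result: RunResult, gene: str, path: str | Path,
                significance: float = 0.05) -> None:
    """Write a per-gene textual report (three TSV sections).

    Section 1: the gene-expression row and each isoform's proportion
    log2FC, PEP and called status.  Section 2: isoform × GO incidence with
    a flag for terms significant in the dataset-wide DAS ORA.  Section 3:
    isoform × domain incidence.
    """
    table = result.table
    if gene not in table.genes:
        near = difflib.get_close_matches(gene, sorted(table.genes), n=5)
        raise UnknownGeneError(
            f"gene {gene!r} not in the differential table"
            + (f"; close matches: {', '.join(near)}" if near else "")
        )
    iso_records = [r for r in table.isoform_records() if r.gene == gene]
    isoforms = [r.isoform for r in iso_records]
    expr = table.expression_records().get(gene)
    called = result.calls.das.called_set
    sig_terms = {
        r.term for r in result.das_rows
        if r.p_adj is not None and r.p_adj < significance
    }
    dom_index = anno.domain_index(result.domains)

    with open(path, "w") as handle:
        handle.write(f"## gene\t{gene}\n")
        handle.write("item\tkind\tlog2fc\tpep\tcalled_das\n")
        if expr is not None:
            handle.write(f"{gene}\texpression\t{expr.log2fc!r}\t{expr.pep!r}\t\n")
        for r in iso_records:
            handle.write(
                f"{r.isoform}\tisoform\t{r.log2fc!r}\t{r.pep!r}\t{int(r.isoform in called)}\n"
            )
        if len(iso_records) < 2:
            handle.write(
                "# note\tgene has fewer than two expressed isoforms; "
                "excluded from the DAS analysis\n"
            )

        handle.write("\n## go_annotations\n")
        handle.write("term\tname\tsignificant_das\t" + "\t".join(isoforms) + "\n")
        gene_terms = sorted(
            set().union(*(result.iso_annot.closed.get(i, frozenset()) for i in isoforms))
        ) if isoforms else []
        for term in gene_terms:
            cells = "\t".join(
                str(int(i in result.iso_annot.annotated_items(term))) for i in isoforms
            )
            handle.write(
                f"{term}\t{result.graph.name_of(term)}\t{int(term in sig_terms)}\t{cells}\n"
            )

        handle.write("\n## domains\n")
        handle.write("entry\t" + "\t".join(isoforms) + "\n")
        for entry in sorted(dom_index):
            members = dom_index[entry]
            if not members & set(isoforms):
                continue
            cells = "\t".join(str(int(i in members)) for i in isoforms)
            handle.write(f"{entry}\t{cells}\n")


def read_enrichment_tsv(path: str | Path) -> list[dict]:
    """Read back a ranked enrichment TSV as dict rows (strings preserved)."""
    import csv

    with open(path, newline="") as handle:
        return list(csv.DictReader(handle, delimiter="\t"))


def significant_terms(path: str | Path, significance: float = 0.05) -> frozenset[str]:
    """Terms with p_adj below the cut in a written enrichment table."""
    rows = read_enrichment_tsv(path)
    return frozenset(
        r["term"] for r in rows if r["p_adj"] and float(r["p_adj"]) < significance
    )


def compare_runs(
    run_dirs: Sequence[str | Path],
    labels: Sequence[str] | None = None,
    interactions: str | Path | None = None,
    universe: int | None = None,
    significance: float = 0.05,
) -> dict:
    """Cross-run comparison report from written `run_analysis` outputs.

    Per run: the Jaccard index between its DGE- and DAS-enriched GO term
    sets.  Across the first two runs (when a universe size is given): the
    hypergeometric overlap significance of their called DGE gene sets.
    With an interaction list: per-run PPI pair proportions for the called
    DGE genes and the DAS genes, compared with a Mann–Whitney U test.
    """
    run_dirs = [Path(d) for d in run_dirs]
    labels = list(labels) if labels else [d.name for d in run_dirs]
    pairs = [
        cmp.ProfilePair(
            dge_terms=significant_terms(d / "dge_go.tsv", significance),
            das_terms=significant_terms(d / "das_go.tsv", significance),
            dataset_label=label,
        )
        for d, label in zip(run_dirs, labels)
    ]
    indices, fraction = cmp.jaccard_profile_summary(pairs)
    report: dict = {
        "datasets": labels,
        "dge_das_jaccard": dict(zip(labels, indices)),
        "fraction_below_0.1": fraction,
    }

    def _called(path: Path) -> frozenset[str]:
        rows = read_enrichment_tsv(path)
        return frozenset(r["item"] for r in rows if r["called"] == "1")

    if len(run_dirs) >= 2 and universe is not None:
        a = _called(run_dirs[0] / "dge_calls.tsv")
        b = _called(run_dirs[1] / "dge_calls.tsv")
        overlap = cmp.overlap_significance(len(a & b), len(a), len(b), universe)
        report["dge_overlap"] = {
            "k": overlap.k, "set1": overlap.set1, "set2": overlap.set2,
            "universe": overlap.universe, "log10_p": overlap.log10_p,
            "linear_p": overlap.linear_p,
        }

    if interactions is not None:
        ints = cmp.load_interactions(interactions)
        dge_props, das_props = [], []
        for d in run_dirs:
            dge_props.append(
                cmp.ppi_pair_proportion(_called(d / "dge_calls.tsv"), ints)
            )
            das_rows = read_enrichment_tsv(d / "das_calls.tsv")
            das_genes = frozenset(r["gene"] for r in das_rows if r["called"] == "1")
            das_props.append(cmp.ppi_pair_proportion(das_genes, ints))
        report["ppi"] = {
            "dge_proportions": dict(zip(labels, dge_props)),
            "das_proportions": dict(zip(labels, das_props)),
            "mannwhitney_p": cmp.ppi_proportion_compare(dge_props, das_props),
        }
    return report


__all__ = [
    "ENRICHMENT_COLUMNS",
    "ORA_METHODS",
    "RunConfig",
    "RunResult",
    "UnknownGeneError",
    "compare_runs",
    "gene_report",
    "read_enrichment_tsv",
    "run_analysis",
    "significant_terms",
    "write_enrichment_tsv",
]
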