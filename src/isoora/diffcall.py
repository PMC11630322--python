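"""Differential calling from posterior error probabilities (PEPs).

Bayesian differential-expression/differential-splicing tools report, per
gene and per isoform, a posterior error probability: the posterior
probability that the item is *not* differential.  The mean PEP over a called
set estimates that set's false discovery rate, so a set can be called by
sorting items by PEP and taking the longest prefix whose mean PEP stays at
or below the target FDR; the achieved FDR is that mean.

The expected input is the four-column output dialect of HBA-DEALS (and of
the edgeR/DEXSeq conversion scripts that emit the same columns): ``Gene``,
``Isoform``, a fold-change column, and a PEP column, with gene-expression
rows flagged by a literal marker (default ``"Expression"``) in the isoform
column.  Isoform rows carry the log2 fold change of the isoform's
*proportion* of its gene's output; expression rows carry the gene-level
expression log2 fold change.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .annotations import strip_version

EXPRESSION_MARKER = "Expression"

_FC_COLUMNS = ("ExplogFC", "FoldChange", "log2FC", "logFC")
_PEP_COLUMNS = ("P", "PEP")


class DiffTableError(ValueError):
    """Malformed differential-result table."""


@dataclass(frozen=True)
class DiffRecord:
    """One row: a gene-expression result or an isoform-proportion result."""

    gene: str
    isoform: str | None  # None for gene-expression rows
    log2fc: float
    pep: float
    row: int = 0  # 1-based source line, for error messages

    @property
    def is_expression(self) -> bool:
        return self.isoform is None


@dataclass(frozen=True)
class DiffTable:
    records: tuple[DiffRecord, ...]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(r.gene for r in self.records)

    @property
    def isoforms(self) -> frozenset[str]:
        return frozenset(r.isoform for r in self.records if r.isoform is not None)

    def expression_records(self) -> dict[str, DiffRecord]:
        return {r.gene: r for r in self.records if r.is_expression}

    def isoform_records(self) -> list[DiffRecord]:
        return [r for r in self.records if not r.is_expression]

    def isoforms_of(self) -> dict[str, list[DiffRecord]]:
        """Gene → its isoform rows, in input order."""
        out: dict[str, list[DiffRecord]] = {}
        for r in self.records:
            if not r.is_expression:
                out.setdefault(r.gene, []).append(r)
        return out

    def multi_isoform_genes(self) -> frozenset[str]:
        """Genes with at least two expressed isoforms (isoform rows)."""
        return frozenset(g for g, rs in self.isoforms_of().items() if len(rs) >= 2)


@dataclass(frozen=True)
class StudySelection:
    """A called study set with the population it was drawn from.

    ``achieved_fdr`` is the mean PEP of the called items (NaN when nothing
    is called); ``called`` preserves the PEP-ascending selection order.
    """

    item_kind: str
    called: tuple[str, ...]
    threshold: float
    achieved_fdr: float
    population: frozenset[str]

    @property
    def called_set(self) -> frozenset[str]:
        return frozenset(self.called)

    def __len__(self) -> int:
        return len(self.called)


@dataclass(frozen=True)
class DifferentialCalls:
    """DGE over genes, DAS over isoforms, plus genes owning a called isoform."""

    dge: StudySelection
    das: StudySelection
    das_genes: frozenset[str]


def _to_log2(value: float, scale: str) -> float:
    if scale == "log2":
        return value
    if scale == "ln":
        return value / math.log(2.0)
    if scale == "ratio":
        if value <= 0:
            raise DiffTableError(f"fold-change ratio must be positive, got {value}")
        return math.log2(value)
    raise ValueError(f"unknown fold-change scale: {scale!r}")


def parse_hbadeals(
    path: str | Path,
    gene_col: str = "Gene",
    isoform_col: str = "Isoform",
    fc_col: str | None = None,
    pep_col: str | None = None,
    expression_marker: str = EXPRESSION_MARKER,
    sep: str = "\t",
    fc_scale: str = "log2",
) -> DiffTable:
    """Parse an HBA-DEALS-style differential result table.

    Column names default to ``Gene`` / ``Isoform`` / first match among
    ``ExplogFC``, ``FoldChange``, ``log2FC``, ``logFC`` / first match among
    ``P``, ``PEP``; output headers vary between versions so all are
    overridable.  Fold changes are converted to log2 according to
    ``fc_scale`` (``log2``, ``ln`` or ``ratio``).
    """
    path = Path(path)
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter=sep)
        if reader.fieldnames is None:
            raise DiffTableError(f"empty differential table: {path}")
        fields = reader.fieldnames
        for required in (gene_col, isoform_col):
            if required not in fields:
                raise DiffTableError(f"{path}: missing column {required!r}")
        if fc_col is None:
            fc_col = next((c for c in _FC_COLUMNS if c in fields), None)
        if pep_col is None:
            pep_col = next((c for c in _PEP_COLUMNS if c in fields), None)
        if fc_col is None or pep_col is None:
            raise DiffTableError(
                f"{path}: cannot locate fold-change/PEP columns in {fields}"
            )

        records: list[DiffRecord] = []
        seen_expression: set[str] = set()
        seen_isoforms: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            gene = row[gene_col].strip()
            isoform_raw = row[isoform_col].strip()
            try:
                pep = float(row[pep_col])
                fc = _to_log2(float(row[fc_col]), fc_scale)
            except (TypeError, ValueError) as exc:
                raise DiffTableError(f"{path}: row {lineno}: {exc}") from exc
            if not 0.0 <= pep <= 1.0:
                raise DiffTableError(
                    f"{path}: row {lineno}: PEP {pep} outside [0, 1]"
                )
            if isoform_raw == expression_marker:
                if gene in seen_expression:
                    raise DiffTableError(
                        f"{path}: row {lineno}: duplicate gene-expression row for {gene}"
                    )
                seen_expression.add(gene)
                records.append(DiffRecord(gene, None, fc, pep, lineno))
            else:
                isoform = strip_version(isoform_raw)
                if isoform in seen_isoforms:
                    raise DiffTableError(
                        f"{path}: row {lineno}: duplicate isoform row for {isoform}"
                    )
                seen_isoforms.add(isoform)
                records.append(DiffRecord(gene, isoform, fc, pep, lineno))
    if not records:
        raise DiffTableError(f"no data rows in {path}")
    return DiffTable(records=tuple(records))


def pep_threshold_select(
    peps: Mapping[str, float],
    threshold: float,
    item_kind: str = "item",
    population: Iterable[str] | None = None,
) -> StudySelection:
    """Call the largest PEP-ascending prefix whose mean PEP ≤ ``threshold``.

    Items are sorted by (PEP, id) — the id breaks ties deterministically.
    Because the items are sorted ascending, prefix means are non-decreasing,
    so the maximal qualifying prefix is the unique boundary set and its mean
    PEP is the achieved FDR.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    for item, pep in peps.items():
        if not 0.0 <= pep <= 1.0:
            raise ValueError(f"PEP for {item!r} outside [0, 1]: {pep}")
    pop = frozenset(population) if population is not None else frozenset(peps)
    ranked = sorted(peps.items(), key=lambda kv: (kv[1], kv[0]))
    called: list[str] = []
    cumulative = 0.0
    best = 0
    for i, (item, pep) in enumerate(ranked, start=1):
        cumulative += pep
        if cumulative / i <= threshold:
            best = i
        called.append(item)
    called = called[:best]
    achieved = (
        sum(peps[i] for i in called) / len(called) if called else math.nan
    )
    return StudySelection(
        item_kind=item_kind,
        called=tuple(called),
        threshold=threshold,
        achieved_fdr=achieved,
        population=pop,
    )


def call_differential(table: DiffTable, threshold: float = 0.05) -> DifferentialCalls:
    """Call DGE and DAS study sets from a parsed differential table.

    DGE: gene-expression PEPs over all genes in the table.  DAS: isoform
    PEPs over isoforms of genes with at least two expressed isoforms (a
    single-isoform gene cannot shift isoform proportions, so its isoform is
    excluded from the DAS population).  ``das_genes`` are the genes owning
    at least one called isoform — the "differentially spliced genes".
    """
    expr = table.expression_records()
    dge = pep_threshold_select(
        {g: r.pep for g, r in expr.items()},
        threshold,
        item_kind="gene",
        population=table.genes,
    )
    multi = table.multi_isoform_genes()
    iso_peps = {
        r.isoform: r.pep
        for r in table.isoform_records()
        if r.gene in multi and r.isoform is not None
    }
    das = pep_threshold_select(
        iso_peps,
        threshold,
        item_kind="isoform",
        population=iso_peps,
    )
    gene_of = {
        r.isoform: r.gene for r in table.isoform_records() if r.isoform is not None
    }
    das_genes = frozenset(gene_of[i] for i in das.called)
    return DifferentialCalls(dge=dge, das=das, das_genes=das_genes)


__all__ = [
    "DiffRecord",
    "DiffTable",
    "DiffTableError",
    "DifferentialCalls",
    "EXPRESSION_MARKER",
    "StudySelection",
    "call_differential",
    "parse_hbadeals",
    "pep_threshold_select",
]
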