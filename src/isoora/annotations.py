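"""Annotation loading and ancestor closure for genes, isoforms and domains.

Gene-level GO annotations, isoform-level predicted GO annotations
(machine-learning predictions of per-transcript function, supplied as an
accession → term-list table) and isoform-level InterPro/ProSite domain
annotations all flow through this module.  GO annotations are ancestor-closed
against an :class:`~isoora.ontology.OntologyGraph` so the true-path rule
holds everywhere downstream: for any term and any of its parents, the set of
items annotated to the term is contained in the set annotated to the parent.
Domain annotations are flat (no hierarchy) and stay unclosed.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .ontology import OntologyGraph, UnknownTermError

logger = logging.getLogger(__name__)

_VERSION_SUFFIX = re.compile(r"\.\d+$")


class AnnotationError(ValueError):
    """Unusable annotation input (empty file, wrong schema, wrong ontology)."""


def strip_version(accession: str) -> str:
    """Drop a trailing ``.N`` version from a transcript/gene accession.

    Ensembl accessions appear both versioned (``ENST00000335753.8``) and
    unversioned (``ENST00000256078``) across input files; stripping makes
    joins robust.
    """
    return _VERSION_SUFFIX.sub("", accession)


@dataclass(frozen=True)
class AnnotationSet:
    """Item → term annotations in direct and ancestor-closed form.

    ``term_index`` is the exact inverse of ``closed``: term → items.
    """

    item_kind: str  # "gene" or "isoform"
    direct: dict[str, frozenset[str]]
    closed: dict[str, frozenset[str]]
    term_index: dict[str, frozenset[str]]

    @classmethod
    def from_direct(
        cls,
        direct: Mapping[str, Iterable[str]],
        graph: OntologyGraph,
        item_kind: str,
    ) -> "AnnotationSet":
        """Build the closed form from direct annotations via the ontology."""
        direct_f = {
            item: frozenset(graph.resolve(t) for t in terms)
            for item, terms in direct.items()
        }
        closed: dict[str, frozenset[str]] = {}
        index: dict[str, set[str]] = {}
        for item, terms in direct_f.items():
            clo: set[str] = set()
            for term in terms:
                clo |= graph.ancestors(term)
            closed[item] = frozenset(clo)
            for term in clo:
                index.setdefault(term, set()).add(item)
        return cls(
            item_kind=item_kind,
            direct=direct_f,
            closed=closed,
            term_index={t: frozenset(v) for t, v in index.items()},
        )

    def items(self) -> frozenset[str]:
        return frozenset(self.closed)

    def annotated_items(self, term: str) -> frozenset[str]:
        return self.term_index.get(term, frozenset())

    def terms(self) -> frozenset[str]:
        return frozenset(self.term_index)


@dataclass(frozen=True)
class DomainAnnotation:
    """One isoform → InterPro/ProSite entry assignment."""

    isoform: str
    entry: str
    description: str = ""


def _read_tsv_rows(path: Path) -> list[list[str]]:
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        return [row for row in reader if row and not row[0].startswith("#")]


def load_annotations(
    path: str | Path,
    graph: OntologyGraph,
    item_kind: str,
    max_unknown_fraction: float = 0.5,
) -> AnnotationSet:
    """Load a two-column item → GO-term TSV and ancestor-close it.

    Column 2 may hold a single term or a semicolon-separated list.  Unknown
    or obsolete term ids are dropped with a logged count; if more than
    ``max_unknown_fraction`` of the term references are unknown the file is
    rejected as probably mismatched with the ontology.
    """
    path = Path(path)
    rows = _read_tsv_rows(path)
    if not rows:
        raise AnnotationError(f"empty annotation file: {path}")

    direct: dict[str, set[str]] = {}
    total = 0
    unknown = 0
    for row in rows:
        if len(row) < 2:
            raise AnnotationError(f"{path}: row with fewer than 2 columns: {row!r}")
        item = strip_version(row[0].strip()) if item_kind == "isoform" else row[0].strip()
        for raw_term in row[1].split(";"):
            term = raw_term.strip()
            if not term:
                continue
            total += 1
            try:
                primary = graph.resolve(term)
                if graph.terms[primary].obsolete:
                    raise UnknownTermError(term)
            except KeyError:
                unknown += 1
                continue
            direct.setdefault(item, set()).add(primary)
    if total == 0:
        raise AnnotationError(f"no term references found in {path}")
    if unknown / total > max_unknown_fraction:
        raise AnnotationError(
            f"{path}: {unknown}/{total} term ids unknown to the ontology; "
            "wrong ontology release or wrong file?"
        )
    if unknown:
        logger.warning("%s: dropped %d/%d unknown or obsolete term ids", path, unknown, total)
    return AnnotationSet.from_direct(direct, graph, item_kind)


def load_gaf(
    path: str | Path,
    graph: OntologyGraph,
    evidence_exclude: set[str] | None = None,
    max_unknown_fraction: float = 0.5,
) -> AnnotationSet:
    """Load gene-level annotations from a GAF 2.x file.

    Uses DB Object ID (column 2) and GO ID (column 5); rows whose qualifier
    contains ``NOT`` are skipped, as are evidence codes in
    ``evidence_exclude`` (all codes kept by default).
    """
    path = Path(path)
    direct: dict[str, set[str]] = {}
    total = 0
    unknown = 0
    with open(path, newline="") as handle:
        for line in handle:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                raise AnnotationError(f"{path}: GAF row with <7 columns")
            if "NOT" in cols[3].split("|"):
                continue
            if evidence_exclude and cols[6] in evidence_exclude:
                continue
            total += 1
            try:
                term = graph.resolve(cols[4])
                if graph.terms[term].obsolete:
                    raise UnknownTermError(term)
            except KeyError:
                unknown += 1
                continue
            direct.setdefault(cols[1], set()).add(term)
    if total == 0:
        raise AnnotationError(f"no annotation rows found in {path}")
    if unknown / total > max_unknown_fraction:
        raise AnnotationError(
            f"{path}: {unknown}/{total} GO ids unknown to the ontology"
        )
    if unknown:
        logger.warning("%s: dropped %d/%d unknown or obsolete GO ids", path, unknown, total)
    return AnnotationSet.from_direct(direct, graph, "gene")


def load_domains(path: str | Path) -> list[DomainAnnotation]:
    """Load an isoform → domain-entry TSV (optional third description column).

    Duplicate (isoform, entry) pairs are collapsed; isoform accessions are
    version-stripped.
    """
    path = Path(path)
    rows = _read_tsv_rows(path)
    if not rows:
        raise AnnotationError(f"empty domain file: {path}")
    seen: dict[tuple[str, str], DomainAnnotation] = {}
    for row in rows:
        if len(row) < 2:
            raise AnnotationError(f"{path}: domain row with fewer than 2 columns: {row!r}")
        isoform = strip_version(row[0].strip())
        entry = row[1].strip()
        description = row[2].strip() if len(row) > 2 else ""
        key = (isoform, entry)
        if key not in seen:
            seen[key] = DomainAnnotation(isoform, entry, description)
    return sorted(seen.values(), key=lambda d: (d.entry, d.isoform))


def domain_index(domains: Iterable[DomainAnnotation]) -> dict[str, frozenset[str]]:
    """Entry → set of isoforms carrying it."""
    index: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for dom in domains:
        index.setdefault(dom.entry, set()).add(dom.isoform)
        if dom.description:
            descriptions.setdefault(dom.entry, dom.description)
    return {entry: frozenset(items) for entry, items in index.items()}


def domain_descriptions(domains: Iterable[DomainAnnotation]) -> dict[str, str]:
    out: dict[str, str] = {}
    for dom in domains:
        if dom.description and dom.entry not in out:
            out[dom.entry] = dom.description
    return out


__all__ = [
    "AnnotationError",
    "AnnotationSet",
    "DomainAnnotation",
    "domain_descriptions",
    "domain_index",
    "load_annotations",
    "load_domains",
    "load_gaf",
    "strip_version",
]
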