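"""Gene Ontology DAG parsing and ancestor closure.

The Gene Ontology (GO) is a rooted directed acyclic graph with one root per
namespace (biological_process, molecular_function, cellular_component).
Annotation propagation follows the true-path rule: an item annotated to a
term is implicitly annotated to every ancestor of that term.  Propagation
here walks ``is_a`` and ``part_of`` edges by default, the GO-standard
relation set for closure; ``regulates``-family edges are excluded unless
explicitly requested.

Two serializations are supported: OBO 1.2/1.4 flat files (read through
:mod:`obonet`) and obographs JSON (the format GO distributes as ``go.json``).
Both dialects yield identical graphs for the same ontology content.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Edge relations retained for closure unless the caller overrides them.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

GO_ID_PATTERN = re.compile(r"^[A-Za-z_]+:\d{7}$")

#: obographs predicate URIs mapped to OBO relation names.
_OBOGRAPH_PREDICATES = {
    "is_a": "is_a",
    "part_of": "part_of",
    "http://purl.obolibrary.org/obo/BFO_0000050": "part_of",
    "BFO:0000050": "part_of",
}


class OntologyError(ValueError):
    """Malformed ontology file or structural violation (e.g. a cycle)."""


class UnknownTermError(KeyError):
    """A term id that is neither a primary nor an alternate id."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term.

    ``parents`` holds ``(parent_id, relation)`` pairs for *all* relations
    present in the source; filtering to the retained relation set happens in
    :class:`OntologyGraph`.  Obsolete terms carry no parents.
    """

    id: str
    name: str = ""
    namespace: str | None = None
    obsolete: bool = False
    parents: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not GO_ID_PATTERN.match(self.id):
            raise OntologyError(f"not a valid term accession: {self.id!r}")
        if self.obsolete and self.parents:
            raise OntologyError(f"obsolete term {self.id} must not retain parents")


class OntologyGraph:
    """A validated ontology DAG with memoized ancestor closure.

    Parameters
    ----------
    terms:
        Iterable of :class:`OntologyTerm`.
    alt_id_map:
        Map from alternate (merged) accessions to primary accessions.
    relations:
        Edge relations retained for ``parents``/``ancestors``.
    """

    def __init__(
        self,
        terms: Iterable[OntologyTerm],
        alt_id_map: Mapping[str, str] | None = None,
        relations: frozenset[str] = DEFAULT_RELATIONS,
    ) -> None:
        self.terms: dict[str, OntologyTerm] = {t.id: t for t in terms}
        self.alt_id_map: dict[str, str] = dict(alt_id_map or {})
        self.relations = frozenset(relations)
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._validate()

    # -- construction ------------------------------------------------------

    def _retained_parents(self, term: OntologyTerm) -> frozenset[str]:
        return frozenset(p for p, rel in term.parents if rel in self.relations)

    def _validate(self) -> None:
        dag = nx.DiGraph()
        for term in self.terms.values():
            if term.obsolete:
                continue
            dag.add_node(term.id)
            for parent in self._retained_parents(term):
                if parent not in self.terms:
                    raise OntologyError(
                        f"term {term.id} has unknown parent {parent}"
                    )
                dag.add_edge(term.id, parent)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise OntologyError(f"retained-edge graph is cyclic: {cycle}")
        self._dag = dag

        self.roots: dict[str | None, str] = {}
        for term in self.terms.values():
            if term.obsolete or self._retained_parents(term):
                continue
            ns = term.namespace
            if ns in self.roots:
                raise OntologyError(
                    f"namespace {ns!r} has multiple roots: "
                    f"{self.roots[ns]}, {term.id}"
                )
            self.roots[ns] = term.id
        root_ids = set(self.roots.values())
        for term in self.terms.values():
            if term.obsolete or term.id in root_ids:
                continue
            reached = self.ancestors(term.id) & root_ids
            if len(reached) != 1:
                raise OntologyError(
                    f"term {term.id} reaches {len(reached)} namespace roots"
                )

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_id_map

    def resolve(self, term_id: str) -> str:
        """Map an alternate or primary accession to the primary accession."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_id_map:
            return self.alt_id_map[term_id]
        raise UnknownTermError(term_id)

    def term(self, term_id: str) -> OntologyTerm:
        return self.terms[self.resolve(term_id)]

    def parents(self, term_id: str) -> frozenset[str]:
        """Direct parents over retained relations only."""
        return self._retained_parents(self.term(term_id))

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive transitive closure of ``parents`` (memoized).

        Obsolete terms are excluded from closure queries.
        """
        primary = self.resolve(term_id)
        term = self.terms[primary]
        if term.obsolete:
            raise UnknownTermError(f"term {primary} is obsolete")
        cached = self._ancestor_cache.get(primary)
        if cached is not None:
            return cached
        result = {primary}
        for parent in self._retained_parents(term):
            result |= self.ancestors(parent)
        out = frozenset(result)
        self._ancestor_cache[primary] = out
        return out

    def non_obsolete_ids(self) -> list[str]:
        return sorted(t.id for t in self.terms.values() if not t.obsolete)

    def name_of(self, term_id: str) -> str:
        try:
            return self.term(term_id).name
        except KeyError:
            return ""


# ---------------------------------------------------------------------------
# Parsing


def parse_ontology(
    path: str | Path,
    dialect: str | None = None,
    relations: frozenset[str] = DEFAULT_RELATIONS,
) -> OntologyGraph:
    """Parse an ontology release into an :class:`OntologyGraph`.

    Parameters
    ----------
    path:
        OBO flat file or obographs JSON file.
    dialect:
        ``"obo"`` or ``"obographs_json"``; inferred from the file suffix
        when omitted (``.json`` → obographs, anything else → OBO).
    relations:
        Relations retained for propagation; default ``{is_a, part_of}``.
    """
    path = Path(path)
    if dialect is None:
        dialect = "obographs_json" if path.suffix.lower() == ".json" else "obo"
    if dialect == "obo":
        terms, alt_ids = _read_obo(path)
    elif dialect == "obographs_json":
        terms, alt_ids = _read_obographs(path)
    else:
        raise ValueError(f"unknown ontology dialect: {dialect!r}")
    return OntologyGraph(terms, alt_ids, relations=relations)


def _read_obo(path: Path) -> tuple[list[OntologyTerm], dict[str, str]]:
    try:
        graph = obonet.read_obo(path, ignore_obsolete=False)
    except (ValueError, KeyError) as exc:
        raise OntologyError(f"cannot parse OBO file {path}: {exc}") from exc

    terms: list[OntologyTerm] = []
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        parents: list[tuple[str, str]] = []
        if not obsolete:
            parents = [
                (parent, relation)
                for _, parent, relation in graph.out_edges(node, keys=True)
            ]
        terms.append(
            OntologyTerm(
                id=node,
                name=data.get("name", ""),
                namespace=data.get("namespace"),
                obsolete=obsolete,
                parents=tuple(sorted(parents)),
            )
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    if not terms:
        raise OntologyError(f"no terms found in {path}")
    return terms, alt_ids


def _curie(uri: str) -> str:
    """Collapse an OBO PURL (``.../GO_0000001``) to a CURIE (``GO:0000001``)."""
    tail = uri.rsplit("/", 1)[-1]
    return tail.replace("_", ":", 1) if "_" in tail and ":" not in tail else tail


def _read_obographs(path: Path) -> tuple[list[OntologyTerm], dict[str, str]]:
    try:
        with open(path) as handle:
            doc = json.load(handle)
        graphs = doc["graphs"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise OntologyError(f"cannot parse obographs JSON {path}: {exc}") from exc
    if not graphs:
        raise OntologyError(f"no graphs in obographs document {path}")
    graph = graphs[0]

    parents_by_term: dict[str, list[tuple[str, str]]] = {}
    for edge in graph.get("edges", []):
        relation = _OBOGRAPH_PREDICATES.get(edge.get("pred"))
        if relation is None:
            relation = _curie(str(edge.get("pred")))
        child = _curie(edge["sub"])
        parent = _curie(edge["obj"])
        parents_by_term.setdefault(child, []).append((parent, relation))

    terms: list[OntologyTerm] = []
    alt_ids: dict[str, str] = {}
    for node in graph.get("nodes", []):
        if node.get("type") not in (None, "CLASS"):
            continue
        term_id = _curie(node["id"])
        if not GO_ID_PATTERN.match(term_id):
            continue
        meta = node.get("meta", {}) or {}
        obsolete = bool(meta.get("deprecated", False))
        namespace = None
        for bpv in meta.get("basicPropertyValues", []):
            pred = str(bpv.get("pred", ""))
            if pred.endswith("hasOBONamespace"):
                namespace = bpv.get("val")
            elif pred.endswith("hasAlternativeId"):
                alt_ids[_curie(str(bpv.get("val")))] = term_id
        parents = () if obsolete else tuple(sorted(parents_by_term.get(term_id, [])))
        terms.append(
            OntologyTerm(
                id=term_id,
                name=node.get("lbl", ""),
                namespace=namespace,
                obsolete=obsolete,
                parents=parents,
            )
        )
    if not terms:
        raise OntologyError(f"no term nodes found in {path}")
    return terms, alt_ids


__all__ = [
    "DEFAULT_RELATIONS",
    "OntologyError",
    "OntologyGraph",
    "OntologyTerm",
    "UnknownTermError",
    "parse_ontology",
]
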