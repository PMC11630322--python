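"""Shared fixtures: toy ontologies and a reusable simulated cohort."""

from __future__ import annotations

import pytest

from isoora.annotations import AnnotationSet
from isoora.ontology import OntologyGraph, OntologyTerm
from isoora import simulate as sim

ROOT = "GO:0000001"
B = "GO:0000002"
C = "GO:0000003"
A = "GO:0000004"


@pytest.fixture
def diamond() -> OntologyGraph:
    """root <- b, root <- c, b <- a, c <- a (a has two parents)."""
    return OntologyGraph(
        [
            OntologyTerm(ROOT, "root", "biological_process"),
            OntologyTerm(B, "b", "biological_process", parents=((ROOT, "is_a"),)),
            OntologyTerm(C, "c", "biological_process", parents=((ROOT, "is_a"),)),
            OntologyTerm(
                A, "a", "biological_process", parents=((B, "is_a"), (C, "is_a"))
            ),
        ]
    )


@pytest.fixture
def chain() -> OntologyGraph:
    """a -> b -> root."""
    return OntologyGraph(
        [
            OntologyTerm(ROOT, "root", "biological_process"),
            OntologyTerm(B, "b", "biological_process", parents=((ROOT, "is_a"),)),
            OntologyTerm(A, "a", "biological_process", parents=((B, "is_a"),)),
        ]
    )


@pytest.fixture
def diamond_annotations(diamond) -> AnnotationSet:
    """g1 -> leaf a; g2 -> leaf b; g3 -> leaf c."""
    return AnnotationSet.from_direct(
        {"g1": {A}, "g2": {B}, "g3": {C}}, diamond, "gene"
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """One simulated cohort shared across tests (read-only)."""
    config = sim.SimulationConfig(seed=42)
    graph = sim.simulate_ontology(config)
    bundle = sim.simulate_annotations(graph, config)
    table, truth = sim.simulate_difftable(graph, bundle, config)
    return config, graph, bundle, table, truth
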