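"""Shared fixtures: miniature ontologies, random-DAG builders, and an
independent brute-force reachability oracle."""

from __future__ import annotations

import numpy as np
import pytest

from phenomic.ontology import OntologyGraph, RelationKind, Term
from phenomic.simulate import generate_quality_ontology


def build_graph(terms, edges) -> OntologyGraph:
    """Construct a graph from (id, label[, flags]) tuples and edge triples.

    ``terms``: iterables of (id, label) or (id, label, dict-of-flags);
    ``edges``: (child, relation, parent) with relation a RelationKind or
    its string value.
    """
    g = OntologyGraph()
    for spec in terms:
        term_id, label, *rest = spec
        flags = rest[0] if rest else {}
        g.add_term(Term(id=term_id, label=label, **flags))
    for child, rel, parent in edges:
        if isinstance(rel, str):
            rel = RelationKind(rel)
        g.add_edge(child, rel, parent)
    g.validate()
    return g


def random_dag(rng: np.random.Generator, n_nodes: int, edge_prob: float = 0.15):
    """Random DAG over T0..T{n-1}: edges only from lower to higher index.

    Returns (graph, edge list) so oracles can work on the raw edges.
    """
    terms = [(f"T{i}", f"node {i}") for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                rel = (
                    RelationKind.PART_OF
                    if rng.random() < 0.5
                    else RelationKind.IS_A
                )
                edges.append((f"T{i}", rel, f"T{j}"))
    return build_graph(terms, edges), edges


def brute_force_closure(edges, start, relations, reverse=False):
    """Fixpoint reachability by repeated edge expansion (the oracle).

    Follows (child → parent) edges whose relation is in ``relations``;
    ``reverse=True`` follows parent → child instead.  Non-reflexive.
    """
    step = {}
    for child, rel, parent in edges:
        if rel in relations:
            if reverse:
                step.setdefault(parent, set()).add(child)
            else:
                step.setdefault(child, set()).add(parent)
    reached: set[str] = set()
    frontier = set(step.get(start, set()))
    while frontier:
        reached |= frontier
        frontier = {
            nxt for node in frontier for nxt in step.get(node, set())
        } - reached
    return reached


@pytest.fixture(scope="session")
def quality_graph() -> OntologyGraph:
    return generate_quality_ontology()


@pytest.fixture(scope="session")
def fin_limb_graph() -> OntologyGraph:
    """Miniature fin/limb + girdle anatomy with the terms of the worked
    EQ examples: opercle, scapulocoracoid with its dorsal surface and an
    anatomical projection (generalized), cleithrum, fibula and its
    postaxial process, scapular blade, and a pectoral fin ray with its
    proximal region."""
    P = RelationKind.PART_OF
    I = RelationKind.IS_A
    terms = [
        ("UBERON:0004708", "paired limb/fin"),
        ("UBERON:0010719", "girdle skeleton"),
        ("UBERON:0002268", "opercle"),  # skull bone: outside both regions
        ("UBERON:0004753", "scapulocoracoid"),
        ("UBERON:2000663", "cleithrum"),
        ("UBERON:4200022", "scapular blade"),
        ("UBERON:0001446", "fibula"),
        ("UBERON:4200132", "postaxial process of fibula"),
        ("UBERON:4000175", "pectoral fin lepidotrichium"),
        ("BSPO:0000077", "proximal region", {"generalized": True}),
        ("UBERON:0012180", "dorsal surface"),
        ("UBERON:0004529", "anatomical projection", {"generalized": True}),
        ("UBERON:0002102", "forelimb"),
        ("UBERON:0002398", "manus"),
        ("UBERON:0002389", "digit"),
    ]
    edges = [
        ("UBERON:0004753", P, "UBERON:0010719"),
        ("UBERON:2000663", P, "UBERON:0010719"),
        ("UBERON:4200022", P, "UBERON:0004753"),
        ("UBERON:0001446", P, "UBERON:0004708"),
        ("UBERON:4200132", P, "UBERON:0001446"),
        ("UBERON:4000175", P, "UBERON:0004708"),
        ("UBERON:0012180", P, "UBERON:0004753"),
        ("UBERON:0004529", P, "UBERON:0012180"),
        ("UBERON:0002102", I, "UBERON:0004708"),
        ("UBERON:0002398", P, "UBERON:0002102"),
        ("UBERON:0002389", P, "UBERON:0002398"),
    ]
    return build_graph(terms, edges)


FIN_LIMB_ROOTS = ("UBERON:0004708", "UBERON:0010719")


@pytest.fixture
def fin_limb_roots():
    return FIN_LIMB_ROOTS
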