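"""Presence/absence supermatrix synthesis and conflict detection.

From EQ corpora we infer taxon-level presence/absence assertions about
anatomical entities, propagate them over the ontology, assemble a
taxa × entities character grid, and report contradictions.

Inference rules
---------------
Direct assertions, per statement:

* quality subsumed by *absent*  → ABSENT for the E core term;
* quality subsumed by *present* → PRESENT for the E core term;
* any other quality → PRESENT (implied) for every named, non-generalized
  term in the E and RE trees that lies in the configured class space —
  describing the size of a process entails the process exists.

Missing data (no statement) yields nothing: an entity uncodable in a
source is never treated as absent.

Propagation: presence propagates *up* over both is_a and part_of (a part
existing entails some whole exists; an instance of a subclass is an
instance of the superclass); absence propagates *down* (no whole ⇒ no
parts, no class ⇒ no subclasses).  These are the sound directions for
existential part_of plus subclassing.

A cell supported both present and absent is POLYMORPHIC and yields one
:class:`Conflict` per (taxon, entity), with a severity tag recording
whether either side rests only on propagated support.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .annotations import (
    DEFAULT_ANCHORS,
    AnnotationCorpus,
    QualityAnchors,
)
from .ontology import (
    BOTH_RELATIONS,
    ClassSpaceMode,
    OntologyGraph,
    RelationKind,
)

__all__ = [
    "CellState",
    "AssertionOrigin",
    "PresenceAssertion",
    "Supermatrix",
    "Conflict",
    "ConflictSeverity",
    "direct_assertions",
    "propagate",
    "build_supermatrix",
    "find_conflicts",
    "write_nexus",
]


class CellState(enum.Enum):
    PRESENT = "1"
    ABSENT = "0"
    POLYMORPHIC = "{01}"
    UNKNOWN = "?"


class AssertionOrigin(enum.Enum):
    ASSERTED = "asserted"
    IMPLIED_BY_QUALITY = "implied_by_quality"
    PROPAGATED = "propagated"


class ConflictSeverity(enum.Enum):
    """How direct the contradicting support is.

    DIRECT: both sides include non-propagated support; MIXED: exactly one
    side is propagation-only; INFERRED: both sides are propagation-only.
    """

    DIRECT = "direct"
    MIXED = "mixed"
    INFERRED = "inferred"


@dataclass(frozen=True)
class PresenceAssertion:
    """One presence/absence claim about (taxon, entity) with provenance.

    ``chain`` is the ontology path from the originating entity to this
    one for PROPAGATED assertions (ending at ``entity``), empty otherwise.
    """

    taxon: str
    entity: str
    state: CellState  # PRESENT or ABSENT only
    origin: AssertionOrigin
    source_id: str
    statement_id: str
    chain: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.state not in (CellState.PRESENT, CellState.ABSENT):
            raise ValueError("assertions carry PRESENT or ABSENT only")
        if self.origin is AssertionOrigin.PROPAGATED:
            if not self.chain or self.chain[-1] != self.entity:
                raise ValueError(
                    "propagated assertions need a chain ending at the entity"
                )


@dataclass
class Conflict:
    taxon: str
    entity: str
    present_support: tuple[PresenceAssertion, ...]
    absent_support: tuple[PresenceAssertion, ...]
    severity: ConflictSeverity


@dataclass
class Supermatrix:
    """Taxa × entities presence/absence grid with per-cell provenance."""

    taxa: tuple[str, ...]
    entities: tuple[str, ...]
    cells: dict[tuple[str, str], CellState]
    provenance: dict[tuple[str, str], tuple[PresenceAssertion, ...]]

    def state(self, taxon: str, entity: str) -> CellState:
        return self.cells.get((taxon, entity), CellState.UNKNOWN)


# ---------------------------------------------------------------------------
# Direct assertion extraction
# ---------------------------------------------------------------------------

def _quality_reflexive_closure(g_quality: OntologyGraph, quality: str) -> set[str]:
    if quality not in g_quality:
        return {quality}
    return {quality} | g_quality.superclosure(quality, {RelationKind.IS_A})


def direct_assertions(
    corpus: AnnotationCorpus,
    g: OntologyGraph,
    g_quality: OntologyGraph,
    roots: Sequence[str],
    root_mode: ClassSpaceMode = ClassSpaceMode.ANY_OF,
    anchors: QualityAnchors = DEFAULT_ANCHORS,
    exclude_generalized: bool = True,
    space: Optional[set[str]] = None,
) -> list[PresenceAssertion]:
    """Presence/absence assertions read directly off a corpus's statements."""
    if space is None:
        space = g.class_space(roots, root_mode)

    def named_in_space(term_id: str) -> bool:
        if term_id not in space:
            return False
        return not (exclude_generalized and g.term(term_id).generalized)

    assertions: list[PresenceAssertion] = []
    closure_memo: dict[str, set[str]] = {}
    for s in corpus.statements:
        closure = closure_memo.get(s.quality)
        if closure is None:
            closure = _quality_reflexive_closure(g_quality, s.quality)
            closure_memo[s.quality] = closure
        if anchors.absent in closure:
            core = s.entity.core
            if core in g:
                assertions.append(
                    PresenceAssertion(
                        taxon=s.taxon, entity=core, state=CellState.ABSENT,
                        origin=AssertionOrigin.ASSERTED,
                        source_id=s.source_id, statement_id=s.statement_id,
                    )
                )
        elif anchors.present in closure:
            core = s.entity.core
            if core in g:
                assertions.append(
                    PresenceAssertion(
                        taxon=s.taxon, entity=core, state=CellState.PRESENT,
                        origin=AssertionOrigin.ASSERTED,
                        source_id=s.source_id, statement_id=s.statement_id,
                    )
                )
        else:
            trees = [s.entity] + ([s.related_entity] if s.related_entity else [])
            seen: set[str] = set()
            for tree in trees:
                for term_id in tree.iter_terms():
                    if term_id in seen or term_id not in g:
                        continue
                    seen.add(term_id)
                    if named_in_space(term_id):
                        assertions.append(
                            PresenceAssertion(
                                taxon=s.taxon, entity=term_id,
                                state=CellState.PRESENT,
                                origin=AssertionOrigin.IMPLIED_BY_QUALITY,
                                source_id=s.source_id,
                                statement_id=s.statement_id,
                            )
                        )
    return assertions


# ---------------------------------------------------------------------------
# Ontology-aware propagation
# ---------------------------------------------------------------------------

def propagate(
    g: OntologyGraph,
    assertions: Iterable[PresenceAssertion],
) -> list[PresenceAssertion]:
    """Close assertions under upward-presence / downward-absence rules.

    Input assertions are retained; each propagated assertion carries the
    shortest ontology path from its origin entity (inclusive) to the
    target entity as its chain.
    """
    up_graph = nx.DiGraph()
    down_graph = nx.DiGraph()
    up_graph.add_nodes_from(t for t in g.terms)
    down_graph.add_nodes_from(t for t in g.terms)
    for child, rel, parent in g.edges():
        if not g.term(child).obsolete and not g.term(parent).obsolete:
            up_graph.add_edge(child, parent)
            down_graph.add_edge(parent, child)

    closure_cache: dict[tuple[str, CellState], dict[str, tuple[str, ...]]] = {}

    def reach(entity: str, state: CellState) -> dict[str, tuple[str, ...]]:
        key = (entity, state)
        if key not in closure_cache:
            graph = up_graph if state is CellState.PRESENT else down_graph
            if entity in graph:
                paths = nx.single_source_shortest_path(graph, entity)
                paths.pop(entity, None)
            else:
                paths = {}
            closure_cache[key] = {t: tuple(p) for t, p in paths.items()}
        return closure_cache[key]

    out = list(assertions)
    for a in assertions:
        if a.entity not in g:
            continue
        for target, path in reach(a.entity, a.state).items():
            out.append(
                PresenceAssertion(
                    taxon=a.taxon, entity=target, state=a.state,
                    origin=AssertionOrigin.PROPAGATED,
                    source_id=a.source_id, statement_id=a.statement_id,
                    chain=path,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Matrix assembly and conflicts
# ---------------------------------------------------------------------------

def build_supermatrix(
    assertion_collections: Iterable[Iterable[PresenceAssertion]],
    taxa: Sequence[str],
    entities: Sequence[str],
) -> Supermatrix:
    """Assemble the grid from per-source assertion collections.

    Cell rule: PRESENT if only present support, ABSENT if only absent,
    POLYMORPHIC if both, UNKNOWN if none.  Assertions outside the given
    taxa/entities are ignored.
    """
    taxa = tuple(taxa)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels")
    entities = tuple(entities)
    taxon_set, entity_set = set(taxa), set(entities)

    provenance: dict[tuple[str, str], list[PresenceAssertion]] = {}
    for collection in assertion_collections:
        for a in collection:
            if a.taxon in taxon_set and a.entity in entity_set:
                provenance.setdefault((a.taxon, a.entity), []).append(a)

    cells: dict[tuple[str, str], CellState] = {}
    for key, support in provenance.items():
        has_present = any(a.state is CellState.PRESENT for a in support)
        has_absent = any(a.state is CellState.ABSENT for a in support)
        if has_present and has_absent:
            cells[key] = CellState.POLYMORPHIC
        elif has_present:
            cells[key] = CellState.PRESENT
        else:
            cells[key] = CellState.ABSENT

    return Supermatrix(
        taxa=taxa,
        entities=entities,
        cells=cells,
        provenance={k: tuple(v) for k, v in provenance.items()},
    )


def find_conflicts(m: Supermatrix) -> list[Conflict]:
    """One conflict per POLYMORPHIC cell, in deterministic order."""
    conflicts: list[Conflict] = []
    for taxon in sorted(m.taxa):
        for entity in sorted(m.entities):
            if m.state(taxon, entity) is not CellState.POLYMORPHIC:
                continue
            support = m.provenance[(taxon, entity)]
            present = tuple(a for a in support if a.state is CellState.PRESENT)
            absent = tuple(a for a in support if a.state is CellState.ABSENT)
            direct_present = any(
                a.origin is not AssertionOrigin.PROPAGATED for a in present
            )
            direct_absent = any(
                a.origin is not AssertionOrigin.PROPAGATED for a in absent
            )
            if direct_present and direct_absent:
                severity = ConflictSeverity.DIRECT
            elif direct_present or direct_absent:
                severity = ConflictSeverity.MIXED
            else:
                severity = ConflictSeverity.INFERRED
            conflicts.append(
                Conflict(
                    taxon=taxon, entity=entity,
                    present_support=present, absent_support=absent,
                    severity=severity,
                )
            )
    return conflicts


# ---------------------------------------------------------------------------
# NEXUS export
# ---------------------------------------------------------------------------

def _nexus_quote(label: str) -> str:
    if label and all(c.isalnum() or c in "._-" for c in label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_nexus(
    m: Supermatrix,
    path,
    g: Optional[OntologyGraph] = None,
) -> None:
    """Write the supermatrix as a NEXUS DATA block.

    Coding: 0 = absent, 1 = present, {01} = polymorphic, ? = unknown.
    Taxa and entities are sorted lexicographically so output is
    deterministic.  Character labels use ontology labels when a graph is
    supplied, with the term id in a comment.
    """
    if not m.taxa or not m.entities:
        raise ValueError("cannot write an empty supermatrix")
    taxa = sorted(m.taxa)
    entities = sorted(m.entities)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(
            f"    DIMENSIONS NTAX={len(taxa)} NCHAR={len(entities)};\n"
        )
        fh.write(
            '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n'
        )
        fh.write("    CHARSTATELABELS\n")
        label_lines = []
        for i, entity in enumerate(entities, start=1):
            label = entity
            if g is not None and entity in g and g.term(entity).label:
                label = g.term(entity).label
            label_lines.append(
                f"        {i} {_nexus_quote(label)} [{entity}]"
            )
        fh.write(",\n".join(label_lines))
        fh.write(";\n    MATRIX\n")
        width = max(len(_nexus_quote(t)) for t in taxa) + 2
        for taxon in taxa:
            row = "".join(m.state(taxon, e).value for e in entities)
            fh.write(f"    {_nexus_quote(taxon):<{width}}{row}\n")
        fh.write("    ;\nEND;\n")
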