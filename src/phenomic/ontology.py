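"""Anatomy/quality ontologies restricted to the two transitive relations
``is_a`` and ``part_of``.

The graph model is deliberately small: terms are nodes, each edge is a
(child, relation, parent) triple, and all reasoning is plain directed
reachability over a user-chosen subset of the two relations.  For this
two-relation fragment, union-reachability subsumes the usual chain rules
(is_a∘part_of and part_of∘is_a), so closures computed here agree with what
an EL reasoner infers for existential part_of plus subclassing.

Ontologies are read and written in a subset of the OBO 1.2 flat-file
format: ``[Term]`` stanzas with ``id``, ``name``, ``is_a``,
``relationship: part_of``, ``is_obsolete`` and ``subset`` tags.  Unknown
relationship types are dropped with a warning; other tags are ignored.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "RelationKind",
    "Term",
    "OntologyGraph",
    "OntologyError",
    "OboParseError",
    "ValidationError",
    "BOTH_RELATIONS",
    "load_obo",
    "write_obo",
    "load_id_list",
]


class OntologyError(Exception):
    """Base class for ontology loading/validation problems."""


class OboParseError(OntologyError):
    """Malformed OBO input; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(OntologyError):
    """Structurally invalid graph (cycle, dangling edge, duplicate)."""


class RelationKind(enum.Enum):
    IS_A = "is_a"
    PART_OF = "part_of"


#: Convenience constant: reason over both relations at once.
BOTH_RELATIONS = frozenset({RelationKind.IS_A, RelationKind.PART_OF})


class ClassSpaceMode(enum.Enum):
    """How multiple roots combine in a class-space query."""

    ALL_OF = "all_of"
    ANY_OF = "any_of"


@dataclass
class Term:
    """A single ontology class.

    ``generalized`` marks unnamed generic feature classes (e.g.
    'anatomical projection', 'bone fossa') that are excluded from
    named-entity extraction; ``obsolete`` terms are retained in the graph
    but excluded from closures and class-space queries by default.
    """

    id: str
    label: str = ""
    generalized: bool = False
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("term id must be non-empty")


class OntologyGraph:
    """DAG of terms connected by is_a / part_of edges.

    Edges run child → parent.  The union graph over both relations must be
    acyclic; :meth:`validate` enforces this together with referential
    integrity.
    """

    def __init__(self) -> None:
        self._terms: dict[str, Term] = {}
        self._g = nx.MultiDiGraph()
        self._label_index: dict[str, list[str]] | None = None

    # -- construction ------------------------------------------------------

    def add_term(self, term: Term) -> None:
        if term.id in self._terms:
            raise ValidationError(f"duplicate term id {term.id!r}")
        self._terms[term.id] = term
        self._g.add_node(term.id)
        self._label_index = None

    def add_edge(self, child: str, relation: RelationKind, parent: str) -> None:
        if self._g.has_edge(child, parent, key=relation):
            raise ValidationError(
                f"duplicate edge {child} {relation.value} {parent}"
            )
        self._g.add_edge(child, parent, key=relation)

    # -- basic access ------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def term(self, term_id: str) -> Term:
        try:
            return self._terms[term_id]
        except KeyError:
            raise KeyError(f"unknown term {term_id!r}") from None

    @property
    def terms(self) -> dict[str, Term]:
        return dict(self._terms)

    def edges(self) -> Iterator[tuple[str, RelationKind, str]]:
        for child, parent, rel in self._g.edges(keys=True):
            yield child, rel, parent

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def resolve_label(self, label: str) -> str:
        """Map a term label to its unique id.

        Raises ``KeyError`` if no term carries the label and
        ``ValueError`` listing candidates if the label is ambiguous.
        """
        if self._label_index is None:
            idx: dict[str, list[str]] = {}
            for t in self._terms.values():
                if t.label:
                    idx.setdefault(t.label, []).append(t.id)
            self._label_index = idx
        ids = self._label_index.get(label, [])
        if not ids:
            raise KeyError(f"no term labelled {label!r}")
        if len(ids) > 1:
            raise ValueError(
                f"ambiguous label {label!r}: candidates {sorted(ids)}"
            )
        return ids[0]

    def mark_generalized(self, ids: Iterable[str]) -> None:
        for term_id in ids:
            self.term(term_id).generalized = True

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        for child, parent in self._g.edges():
            for endpoint in (child, parent):
                if endpoint not in self._terms:
                    raise ValidationError(
                        f"edge references unknown term {endpoint!r}"
                    )
        if not nx.is_directed_acyclic_graph(self._g):
            cycle = nx.find_cycle(self._g)
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise ValidationError(f"cycle detected: {path}")

    # -- reasoning ---------------------------------------------------------

    def _filtered(
        self, relations: frozenset[RelationKind] | set[RelationKind],
        include_obsolete: bool,
    ) -> nx.DiGraph:
        view = nx.DiGraph()
        view.add_nodes_from(
            n for n in self._g.nodes
            if include_obsolete or not self._terms[n].obsolete
        )
        for child, parent, rel in self._g.edges(keys=True):
            if rel in relations and child in view and parent in view:
                view.add_edge(child, parent)
        return view

    def superclosure(
        self,
        term_id: str,
        relations: Iterable[RelationKind] = BOTH_RELATIONS,
        include_obsolete: bool = False,
    ) -> set[str]:
        """All ancestors of ``term_id`` reachable via ``relations``.

        Non-reflexive: the term itself is never a member.
        """
        self.term(term_id)
        view = self._filtered(frozenset(relations), include_obsolete)
        if term_id not in view:
            return set()
        return set(nx.descendants(view, term_id))

    def subclosure(
        self,
        term_id: str,
        relations: Iterable[RelationKind] = BOTH_RELATIONS,
        include_obsolete: bool = False,
    ) -> set[str]:
        """All descendants of ``term_id``; mirror of :meth:`superclosure`."""
        self.term(term_id)
        view = self._filtered(frozenset(relations), include_obsolete)
        if term_id not in view:
            return set()
        return set(nx.ancestors(view, term_id))

    def class_space(
        self,
        roots: Iterable[str],
        mode: ClassSpaceMode = ClassSpaceMode.ANY_OF,
        include_obsolete: bool = False,
    ) -> set[str]:
        """Terms below the given roots via is_a/part_of reachability.

        ``ALL_OF`` requires a path to every root, ``ANY_OF`` to at least
        one.  Roots themselves and (by default) obsolete terms are
        excluded.
        """
        roots = list(roots)
        if not roots:
            raise ValueError("class_space requires at least one root")
        for r in roots:
            self.term(r)
        memberships = [
            self.subclosure(r, BOTH_RELATIONS, include_obsolete)
            for r in roots
        ]
        if mode is ClassSpaceMode.ALL_OF:
            result = set.intersection(*memberships)
        else:
            result = set.union(*memberships)
        return result - set(roots)


# ---------------------------------------------------------------------------
# OBO 1.2 flat-file subset I/O
# ---------------------------------------------------------------------------

#: Name of the OBO subset used to flag generalized terms.
GENERALIZED_SUBSET = "generalized"


def load_obo(
    path,
    generalized_ids: Iterable[str] | None = None,
    validate: bool = True,
) -> OntologyGraph:
    """Read an ontology from an OBO 1.2 flat-file subset.

    Recognised term tags: ``id``, ``name``, ``is_a``,
    ``relationship: <type> <id>``, ``is_obsolete``, ``subset``.  A
    ``subset: generalized`` tag (or membership in ``generalized_ids``)
    flags a term as generalized.  Relationship types other than part_of
    are ignored with a logged warning.  Raises :class:`OboParseError`
    with a line number on malformed stanzas and :class:`ValidationError`
    on cycles or dangling edges.
    """
    g = OntologyGraph()
    pending_edges: list[tuple[str, RelationKind, str, int]] = []

    current: dict | None = None
    current_line = 0
    in_term_stanza = False

    def flush() -> None:
        nonlocal current
        if current is None:
            return
        if "id" not in current:
            raise OboParseError("[Term] stanza without id tag", current_line)
        g.add_term(
            Term(
                id=current["id"],
                label=current.get("name", ""),
                generalized=current.get("generalized", False),
                obsolete=current.get("obsolete", False),
            )
        )
        for rel, target, lineno in current.get("edges", []):
            pending_edges.append((current["id"], rel, target, lineno))
        current = None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip() if not raw.lstrip().startswith("!") else ""
            if not line:
                continue
            if line.startswith("["):
                flush()
                if line == "[Term]":
                    current = {"edges": []}
                    current_line = lineno
                    in_term_stanza = True
                elif line.endswith("]"):
                    in_term_stanza = False  # e.g. [Typedef]; skipped
                else:
                    raise OboParseError(f"malformed stanza header {line!r}", lineno)
                continue
            if ":" not in line:
                raise OboParseError(f"expected 'tag: value', got {line!r}", lineno)
            tag, _, value = line.partition(":")
            tag = tag.strip()
            value = value.strip()
            if current is None:
                continue  # header or skipped stanza
            if tag == "id":
                if not value:
                    raise OboParseError("empty id value", lineno)
                current["id"] = value
            elif tag == "name":
                current["name"] = value
            elif tag == "is_a":
                current["edges"].append((RelationKind.IS_A, value.split()[0], lineno))
            elif tag == "relationship":
                parts = value.split()
                if len(parts) < 2:
                    raise OboParseError(
                        f"malformed relationship value {value!r}", lineno
                    )
                rel_name, target = parts[0], parts[1]
                if rel_name == RelationKind.PART_OF.value:
                    current["edges"].append((RelationKind.PART_OF, target, lineno))
                else:
                    logger.warning(
                        "line %d: ignoring unsupported relationship type %r",
                        lineno, rel_name,
                    )
            elif tag == "is_obsolete":
                current["obsolete"] = value.lower() == "true"
            elif tag == "subset":
                if value == GENERALIZED_SUBSET:
                    current["generalized"] = True
            # other tags (def, comment, xref, ...) are ignored
        flush()

    for child, rel, parent, lineno in pending_edges:
        if parent not in g:
            raise ValidationError(
                f"line {lineno}: edge target {parent!r} not defined in file"
            )
        g.add_edge(child, rel, parent)

    if generalized_ids:
        g.mark_generalized(generalized_ids)
    if validate:
        g.validate()
    return g


def write_obo(g: OntologyGraph, path, ontology_name: str = "phenomic-export") -> None:
    """Serialise a graph back to the OBO subset, deterministically.

    Terms are emitted sorted by id; edges sorted by (relation, parent).
    ``load_obo(write_obo(g))`` reproduces ``g`` exactly.
    """
    out_edges: dict[str, list[tuple[RelationKind, str]]] = {}
    for child, rel, parent in g.edges():
        out_edges.setdefault(child, []).append((rel, parent))

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {ontology_name}\n")
        fh.write(f"subsetdef: {GENERALIZED_SUBSET} \"Unnamed generic feature classes\"\n")
        for term_id in sorted(g.terms):
            t = g.term(term_id)
            fh.write("\n[Term]\n")
            fh.write(f"id: {t.id}\n")
            if t.label:
                fh.write(f"name: {t.label}\n")
            if t.generalized:
                fh.write(f"subset: {GENERALIZED_SUBSET}\n")
            if t.obsolete:
                fh.write("is_obsolete: true\n")
            for rel, parent in sorted(
                out_edges.get(term_id, []), key=lambda e: (e[0].value, e[1])
            ):
                if rel is RelationKind.IS_A:
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")


def load_id_list(path) -> list[str]:
    """Read a plain-text id list (one CURIE per line, # comments allowed)."""
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return ids
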