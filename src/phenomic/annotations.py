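"""Entity–Quality (EQ) phenotype statements.

A phenotype is an anatomical *entity* (E) paired with a *quality* (Q), and
optionally a *related entity* (RE) when the quality is relational (e.g.
``attached_to``).  Entities may be *post-composed*: built on the fly from
ontology terms joined by part_of, e.g. ``'proximal region' part_of
('pectoral fin lepidotrichium')``.

EQ complexity — the number of ontology classes plus relation properties
used in one statement — is the granularity proxy computed throughout this
package: a bare ``E: opercle, Q: absent`` scores 2, while a deeply
post-composed entity with a related entity can score 7 or more.  Only
relations *inside* the E and RE expressions count; the implicit E–Q and
Q–RE attachments do not, which is the only counting rule consistent with
both of those reference scores.
"""

from __future__ import annotations

import csv
import enum
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .ontology import OntologyGraph, RelationKind

logger = logging.getLogger(__name__)

__all__ = [
    "SourceKind",
    "QualityClass",
    "QualityAnchors",
    "EntityExpression",
    "EQStatement",
    "AnnotationCorpus",
    "ExpressionParseError",
    "CorpusFormatError",
    "parse_entity_expression",
    "serialize_entity_expression",
    "eq_complexity",
    "classify_quality",
    "read_corpus_tsv",
    "write_corpus_tsv",
    "UNRESOLVED_PREFIX",
]


class SourceKind(enum.Enum):
    """Kind of publication an annotation was curated from."""

    MONOGRAPH = "monograph"
    MATRIX = "matrix"


class QualityClass(enum.Enum):
    """High-level character-quality classes.

    NEOMORPHIC covers presence/absence; MORPHOLOGY covers shape, size,
    texture, structure; POSITION covers position and orientation; NUMBER
    covers amount/count qualities not already presence/absence.
    """

    NEOMORPHIC = "Neomorphic"
    MORPHOLOGY = "Morphology"
    POSITION = "Position"
    NUMBER = "Number"
    OTHER = "Other"


@dataclass(frozen=True)
class QualityAnchors:
    """PATO anchor terms for the four quality classes.

    A quality belongs to the first class (in precedence order
    NEOMORPHIC → MORPHOLOGY → POSITION → NUMBER) whose anchor it equals
    or is_a-descends from.  present/absent are themselves subtypes of
    'amount', so NEOMORPHIC must precede NUMBER.
    """

    present: str = "PATO:0000467"
    absent: str = "PATO:0000462"
    morphology: str = "PATO:0000051"
    position: str = "PATO:0000140"
    amount: str = "PATO:0000070"


DEFAULT_ANCHORS = QualityAnchors()

#: Prefix given to placeholder ids for labels unresolvable in lenient mode.
UNRESOLVED_PREFIX = "UNRESOLVED"


class ExpressionParseError(ValueError):
    """Syntax or resolution error in an entity-expression string."""


class CorpusFormatError(ValueError):
    """Malformed corpus TSV; message carries the 1-based line number."""


@dataclass(frozen=True)
class EntityExpression:
    """Tree of ontology terms joined by relations (a post-composed entity).

    ``core`` is the genus term id; each differentia is a (relation,
    sub-expression) pair.
    """

    core: str
    differentia: tuple[tuple[RelationKind, "EntityExpression"], ...] = ()

    def __post_init__(self) -> None:
        if not self.core:
            raise ValueError("entity expression core must be non-empty")

    def iter_terms(self) -> Iterable[str]:
        yield self.core
        for _, sub in self.differentia:
            yield from sub.iter_terms()

    @property
    def n_terms(self) -> int:
        return 1 + sum(sub.n_terms for _, sub in self.differentia)

    @property
    def n_relations(self) -> int:
        return sum(1 + sub.n_relations for _, sub in self.differentia)

    @property
    def size(self) -> int:
        """Classes plus properties used by this expression."""
        return self.n_terms + self.n_relations

    def unresolved_terms(self) -> set[str]:
        return {t for t in self.iter_terms() if t.startswith(UNRESOLVED_PREFIX + ":")}


@dataclass(frozen=True)
class EQStatement:
    """One annotated phenotype: E, Q, optional RE, plus provenance.

    ``character_id`` groups EQ rows that derive from the same phenotypic
    statement (monograph) or character (matrix); ``comparative`` flags
    monograph statements that directly compare multiple taxa.
    """

    statement_id: str
    taxon: str
    entity: EntityExpression
    quality: str
    source_id: str
    source_kind: SourceKind
    related_entity: Optional[EntityExpression] = None
    character_id: Optional[str] = None
    comparative: bool = False

    def __post_init__(self) -> None:
        if not self.quality:
            raise ValueError("quality must be non-empty")
        if self.comparative and self.source_kind is not SourceKind.MONOGRAPH:
            raise ValueError("comparative statements occur only in monographs")


@dataclass
class AnnotationCorpus:
    """All EQ statements curated from one publication."""

    publication_id: str
    source_kind: SourceKind
    statements: list[EQStatement] = field(default_factory=list)
    declared_statement_count: Optional[int] = None
    declared_state_count: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for s in self.statements:
            if s.source_kind is not self.source_kind:
                raise ValueError(
                    f"statement {s.statement_id} has kind {s.source_kind}, "
                    f"corpus is {self.source_kind}"
                )
            if s.statement_id in seen:
                raise ValueError(f"duplicate statement id {s.statement_id!r}")
            seen.add(s.statement_id)

    @property
    def n_eqs(self) -> int:
        return len(self.statements)

    @property
    def n_statements(self) -> int:
        """Number of phenotypic statements / characters.

        Counts distinct ``character_id`` values when present, falling
        back to the declared count, then to the EQ count.
        """
        groups = {s.character_id for s in self.statements if s.character_id}
        if groups:
            return len(groups)
        if self.declared_statement_count is not None:
            return self.declared_statement_count
        return self.n_eqs

    @property
    def taxa(self) -> set[str]:
        return {s.taxon for s in self.statements}


# ---------------------------------------------------------------------------
# Entity-expression mini-grammar
# ---------------------------------------------------------------------------
#
#   EXPR := TERM { REL ["some"] "(" EXPR ")" }
#   TERM := CURIE | 'single-quoted label'
#   REL  := part_of | is_a
#
# The OWL-style keyword "some" is accepted and ignored; whitespace is
# insignificant outside quotes.

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<quoted>'[^']*')
      | (?P<lparen>\()
      | (?P<rparen>\))
      | (?P<word>[^\s()']+)
    )""",
    re.VERBOSE,
)

_RELATION_WORDS = {r.value: r for r in RelationKind}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip():
                raise ExpressionParseError(
                    f"unexpected character at position {pos}: {text[pos]!r}"
                )
            break
        pos = m.end()
        for kind in ("quoted", "lparen", "rparen", "word"):
            val = m.group(kind)
            if val is not None:
                tokens.append((kind, val, m.start()))
                break
    return tokens


class _Parser:
    def __init__(self, text: str, g: Optional[OntologyGraph], strict: bool):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0
        self.g = g
        self.strict = strict

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise ExpressionParseError(
                f"unexpected end of expression at position "
                f"{len(self.text)} in {self.text!r}"
            )
        self.i += 1
        return tok

    def resolve(self, token_kind: str, value: str) -> str:
        if token_kind == "word":
            return value  # CURIE used verbatim
        label = value[1:-1]
        if self.g is None:
            return f"{UNRESOLVED_PREFIX}:{label}"
        try:
            return self.g.resolve_label(label)
        except KeyError:
            if self.strict:
                raise ExpressionParseError(
                    f"label {label!r} not found in ontology"
                ) from None
            logger.warning("unresolved label %r (lenient mode)", label)
            return f"{UNRESOLVED_PREFIX}:{label}"
        except ValueError as exc:  # ambiguous
            raise ExpressionParseError(str(exc)) from None

    def parse_expr(self) -> EntityExpression:
        kind, value, pos = self.next()
        if kind in ("lparen", "rparen"):
            raise ExpressionParseError(
                f"expected a term at position {pos} in {self.text!r}"
            )
        core = self.resolve(kind, value)
        differentia: list[tuple[RelationKind, EntityExpression]] = []
        while True:
            tok = self.peek()
            if tok is None or tok[0] == "rparen":
                break
            kind, value, pos = tok
            if kind != "word" or value not in _RELATION_WORDS:
                raise ExpressionParseError(
                    f"expected a relation at position {pos}, got {value!r}"
                )
            rel = _RELATION_WORDS[value]
            self.i += 1
            tok = self.peek()
            if tok is not None and tok[0] == "word" and tok[1] == "some":
                self.i += 1
            tok = self.next()
            if tok[0] != "lparen":
                raise ExpressionParseError(
                    f"expected '(' after relation at position {tok[2]}"
                )
            sub = self.parse_expr()
            tok = self.next()
            if tok[0] != "rparen":
                raise ExpressionParseError(
                    f"expected ')' at position {tok[2]} in {self.text!r}"
                )
            differentia.append((rel, sub))
        return EntityExpression(core=core, differentia=tuple(differentia))


def parse_entity_expression(
    text: str,
    g: Optional[OntologyGraph] = None,
    strict: bool = True,
) -> EntityExpression:
    """Parse an entity-expression string into a tree of resolved term ids.

    Quoted labels are resolved against ``g``; bare CURIEs pass through
    verbatim.  In lenient mode (``strict=False``) unresolvable labels
    become placeholder ``UNRESOLVED:<label>`` terms instead of raising.
    """
    parser = _Parser(text, g, strict)
    if not parser.tokens:
        raise ExpressionParseError("empty entity expression")
    expr = parser.parse_expr()
    if parser.peek() is not None:
        kind, value, pos = parser.peek()
        raise ExpressionParseError(
            f"unbalanced or trailing input at position {pos}: {value!r}"
        )
    return expr


def serialize_entity_expression(expr: EntityExpression) -> str:
    """Inverse of :func:`parse_entity_expression` (ids, not labels)."""
    if expr.core.startswith(UNRESOLVED_PREFIX + ":"):
        # placeholder labels may contain spaces; re-emit as a quoted label
        core = "'" + expr.core.partition(":")[2] + "'"
    else:
        core = expr.core
    parts = [core]
    for rel, sub in expr.differentia:
        parts.append(f"{rel.value} ({serialize_entity_expression(sub)})")
    return " ".join(parts)


# ---------------------------------------------------------------------------
# Scoring and classification
# ---------------------------------------------------------------------------

def eq_complexity(eq: EQStatement) -> int:
    """Number of ontology classes plus relation properties in a statement.

    E-tree terms and relations + 1 for the quality + RE-tree terms and
    relations.  The implicit E–Q and Q–RE attachments are not counted.
    """
    total = eq.entity.size + 1
    if eq.related_entity is not None:
        total += eq.related_entity.size
    return total


def classify_quality(
    g_quality: OntologyGraph,
    quality: str,
    anchors: QualityAnchors = DEFAULT_ANCHORS,
    lenient: bool = False,
) -> QualityClass:
    """Assign a quality term to one of the five quality classes.

    Subsumption is is_a-only: a quality matches an anchor when it equals
    the anchor or the anchor is among its is_a ancestors.  First match in
    precedence order NEOMORPHIC → MORPHOLOGY → POSITION → NUMBER wins;
    anything else is OTHER.
    """
    if quality not in g_quality:
        if lenient:
            logger.warning("unknown quality %r classified OTHER", quality)
            return QualityClass.OTHER
        raise KeyError(f"unknown quality term {quality!r}")
    reflexive = {quality} | g_quality.superclosure(quality, {RelationKind.IS_A})
    if anchors.present in reflexive or anchors.absent in reflexive:
        return QualityClass.NEOMORPHIC
    if anchors.morphology in reflexive:
        return QualityClass.MORPHOLOGY
    if anchors.position in reflexive:
        return QualityClass.POSITION
    if anchors.amount in reflexive:
        return QualityClass.NUMBER
    return QualityClass.OTHER


# ---------------------------------------------------------------------------
# Corpus TSV I/O
# ---------------------------------------------------------------------------

CORPUS_COLUMNS = [
    "source_id",
    "source_kind",
    "statement_id",
    "character_id",
    "taxon",
    "entity",
    "quality",
    "related_entity",
    "comparative",
]


def read_corpus_tsv(
    path,
    g: Optional[OntologyGraph] = None,
    strict: bool = True,
) -> list[AnnotationCorpus]:
    """Read EQ corpora from the tabular annotation format.

    One corpus per distinct ``source_id``, rows kept in input order.
    Blank lines and ``#`` comments are skipped.  Raises
    :class:`CorpusFormatError` with a line number on bad rows.
    """
    by_source: dict[str, list[EQStatement]] = {}
    kinds: dict[str, SourceKind] = {}
    seen_ids: set[tuple[str, str]] = set()

    with open(path, encoding="utf-8", newline="") as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [h.strip() for h in fields]
                missing = [c for c in CORPUS_COLUMNS if c not in header]
                if missing:
                    raise CorpusFormatError(
                        f"line {lineno}: missing columns {missing}"
                    )
                continue
            row = dict(zip(header, fields))
            try:
                kind = SourceKind(row["source_kind"])
            except ValueError:
                raise CorpusFormatError(
                    f"line {lineno}: unknown source_kind "
                    f"{row.get('source_kind')!r}"
                ) from None
            source_id = row["source_id"]
            statement_id = row["statement_id"]
            key = (source_id, statement_id)
            if key in seen_ids:
                raise CorpusFormatError(
                    f"line {lineno}: duplicate statement id "
                    f"{statement_id!r} in source {source_id!r}"
                )
            seen_ids.add(key)
            comparative_raw = (row.get("comparative") or "").strip()
            if comparative_raw not in ("", "0", "1"):
                raise CorpusFormatError(
                    f"line {lineno}: comparative must be 0/1/empty, got "
                    f"{comparative_raw!r}"
                )
            try:
                entity = parse_entity_expression(row["entity"], g, strict)
                related_raw = (row.get("related_entity") or "").strip()
                related = (
                    parse_entity_expression(related_raw, g, strict)
                    if related_raw
                    else None
                )
                stmt = EQStatement(
                    statement_id=statement_id,
                    taxon=row["taxon"],
                    entity=entity,
                    quality=row["quality"],
                    related_entity=related,
                    source_id=source_id,
                    source_kind=kind,
                    character_id=(row.get("character_id") or "").strip() or None,
                    comparative=comparative_raw == "1",
                )
            except (ExpressionParseError, ValueError) as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from None
            by_source.setdefault(source_id, []).append(stmt)
            kinds[source_id] = kind

    return [
        AnnotationCorpus(
            publication_id=source_id,
            source_kind=kinds[source_id],
            statements=stmts,
        )
        for source_id, stmts in by_source.items()
    ]


def write_corpus_tsv(corpora: Iterable[AnnotationCorpus], path) -> None:
    """Write corpora to the tabular annotation format (ids, not labels)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CORPUS_COLUMNS)
        for corpus in corpora:
            for s in corpus.statements:
                writer.writerow(
                    [
                        s.source_id,
                        s.source_kind.value,
                        s.statement_id,
                        s.character_id or "",
                        s.taxon,
                        serialize_entity_expression(s.entity),
                        s.quality,
                        serialize_entity_expression(s.related_entity)
                        if s.related_entity
                        else "",
                        "1" if s.comparative else "0",
                    ]
                )
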