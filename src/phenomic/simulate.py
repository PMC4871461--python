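"""Synthetic ontologies and EQ corpora with known ground truth.

Real curated corpora of this kind live in non-machine-readable appendices,
so the generator emulates their statistical structure instead: two
anatomical root regions (paired-appendage and girdle analogues), random
is_a/part_of DAGs beneath them, and monograph-/matrix-style publications
whose per-publication statement counts, EQs per statement, taxa counts,
quality-class mixtures, and EQ-complexity distributions are calibrated to
the published summary statistics of curated fin-to-limb corpora
(statements 52.1/56.2, EQs-per-statement ratios 119.3/52.1 and 215.8/56.2,
taxa 8.7/32.2, mean complexity 3.4/2.9, and the quality-class mixtures
Morphology/Neomorphic/Position/Number = 54.3/12.4/30.5/2.8 for monographs
and 36.8/37.2/16.0/10.0 for matrices).

Two properties are guaranteed by construction, which is what makes the
generator usable as a test harness:

* every generated EQ realises its drawn target complexity *exactly*
  (differentia are added until the target is met), so the complexity
  scorer can be validated against known values;
* generated corpora are *closure-consistent* — after upward-presence /
  downward-absence propagation no taxon–entity pair is supported both
  present and absent — unless conflicts are explicitly injected, in which
  case the injected (taxon, entity) pairs are recorded as ground truth
  and are exactly the conflicts the pipeline should recover.

Determinism: one pseudo-random stream per artifact, derived from the
master seed by labelled sub-seeding, so identical (config, seed) yields
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .annotations import (
    AnnotationCorpus,
    DEFAULT_ANCHORS,
    EntityExpression,
    EQStatement,
    QualityClass,
    SourceKind,
    classify_quality,
)
from .ontology import (
    BOTH_RELATIONS,
    ClassSpaceMode,
    OntologyGraph,
    RelationKind,
    Term,
)
from . import supermatrix as _sm

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyConfig",
    "CorpusConfig",
    "ConflictConfig",
    "GeneratorConfig",
    "GroundTruth",
    "StudyData",
    "GenerationError",
    "generate_ontology",
    "generate_quality_ontology",
    "generate_corpus",
    "generate_quality_sample",
    "generate_study",
    "inject_conflicts",
    "truncated_geometric_complexity",
]


class GenerationError(RuntimeError):
    """Infeasible generator parameters."""


def _sub_rng(seed: int, label: str) -> np.random.Generator:
    """Labelled sub-stream of the master seed."""
    return np.random.default_rng([seed, zlib.crc32(label.encode()) & 0x7FFFFFFF])


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class OntologyConfig:
    """Shape of the synthetic anatomy ontology."""

    n_terms: int = 80
    max_depth: int = 6
    part_of_edge_fraction: float = 0.4
    n_roots: int = 2
    generalized_fraction: float = 0.08
    extra_parent_prob: float = 0.15  # second parent, makes a DAG not a tree

    def validate(self) -> None:
        if self.n_terms <= self.n_roots:
            raise GenerationError("need more terms than roots")
        if self.max_depth < 2:
            raise GenerationError("max_depth must be at least 2")
        if not 0 <= self.part_of_edge_fraction <= 1:
            raise GenerationError("part_of_edge_fraction outside [0,1]")


@dataclass
class CorpusConfig:
    """Per-source-kind corpus shape.

    ``statements_dispersion`` is the negative-binomial size parameter for
    per-publication statement counts (smaller = more spread); the quality
    mixture must sum to 1.
    """

    n_publications: int
    statements_mean: float
    statements_dispersion: float
    eqs_per_statement_mean: float
    taxa_mean: float
    quality_mixture: dict[QualityClass, float]
    absent_fraction: float = 0.5
    complexity_mean: float = 3.0
    complexity_max: int = 15
    comparative_fraction: float = 0.0

    def validate(self) -> None:
        total = sum(self.quality_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise GenerationError(f"quality mixture sums to {total}, not 1")
        if QualityClass.OTHER in self.quality_mixture:
            raise GenerationError("mixture is over the four named classes")
        if self.n_publications < 0 or self.statements_mean <= 0:
            raise GenerationError("counts must be positive")
        if not 2 <= self.complexity_mean <= self.complexity_max:
            raise GenerationError("complexity mean outside [2, max]")

    @classmethod
    def monograph_defaults(cls) -> "CorpusConfig":
        return cls(
            n_publications=7,
            statements_mean=52.1,
            statements_dispersion=1.3,
            eqs_per_statement_mean=119.3 / 52.1,
            taxa_mean=8.7,
            quality_mixture={
                QualityClass.MORPHOLOGY: 0.543,
                QualityClass.NEOMORPHIC: 0.124,
                QualityClass.POSITION: 0.305,
                QualityClass.NUMBER: 0.028,
            },
            absent_fraction=0.5,
            complexity_mean=3.4,
            comparative_fraction=9.6 / 52.1,
        )

    @classmethod
    def matrix_defaults(cls) -> "CorpusConfig":
        return cls(
            n_publications=6,
            statements_mean=56.2,
            statements_dispersion=1.3,
            eqs_per_statement_mean=215.8 / 56.2,
            taxa_mean=32.2,
            quality_mixture={
                QualityClass.MORPHOLOGY: 0.368,
                QualityClass.NEOMORPHIC: 0.372,
                QualityClass.POSITION: 0.160,
                QualityClass.NUMBER: 0.100,
            },
            absent_fraction=0.5,
            complexity_mean=2.9,
        )


@dataclass
class ConflictConfig:
    n_injected: int = 0
    mode: str = "asserted"  # "asserted" or "implied" present-side support

    def validate(self) -> None:
        if self.mode not in ("asserted", "implied"):
            raise GenerationError(f"unknown conflict mode {self.mode!r}")
        if self.n_injected < 0:
            raise GenerationError("n_injected must be non-negative")


@dataclass
class GeneratorConfig:
    """Full study configuration; the defaults are the study conditions."""

    seed: int
    ontology: OntologyConfig = field(default_factory=OntologyConfig)
    monograph: CorpusConfig = field(
        default_factory=CorpusConfig.monograph_defaults
    )
    matrix: CorpusConfig = field(default_factory=CorpusConfig.matrix_defaults)
    conflicts: ConflictConfig = field(default_factory=ConflictConfig)
    taxon_pool_size: int = 60
    n_focal_taxa: int = 4

    def validate(self) -> None:
        self.ontology.validate()
        self.monograph.validate()
        self.matrix.validate()
        self.conflicts.validate()
        if self.n_focal_taxa > self.taxon_pool_size:
            raise GenerationError("focal taxa exceed the taxon pool")


@dataclass
class GroundTruth:
    """What the generator actually did, for exact verification."""

    seed: int
    injected_conflicts: list[tuple[str, str]] = field(default_factory=list)
    complexity_targets: dict[tuple[str, str], int] = field(default_factory=dict)
    quality_mixtures: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "injected_conflicts": [list(p) for p in self.injected_conflicts],
            "complexity_targets": {
                f"{src}\t{sid}": c
                for (src, sid), c in sorted(self.complexity_targets.items())
            },
            "quality_mixtures": self.quality_mixtures,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Ontology generation
# ---------------------------------------------------------------------------

ROOT_IDS = ("ANAT:0000001", "ANAT:0000002")
ROOT_LABELS = ("paired appendage region", "girdle region")


def generate_ontology(
    config: OntologyConfig,
    seed: int,
) -> OntologyGraph:
    """Random anatomy DAG: every non-root term reaches at least one root.

    Non-root terms are assigned to depth levels 1..max_depth-1 and
    attached to a uniformly chosen parent one level up, via part_of with
    the configured probability (is_a otherwise); a fraction of terms get
    a second parent so the graph is a genuine DAG.  The configured
    fraction of non-root terms is flagged generalized.
    """
    config.validate()
    rng = _sub_rng(seed, "ontology")
    g = OntologyGraph()
    roots = list(ROOT_IDS[: config.n_roots])
    for rid, label in zip(roots, ROOT_LABELS):
        g.add_term(Term(id=rid, label=label))

    n_inner = config.n_terms - config.n_roots
    levels: dict[int, list[str]] = {0: roots}
    ids = [f"ANAT:{i + 1 + config.n_roots:07d}" for i in range(n_inner)]
    # spread terms over levels, guaranteeing each level is non-empty while
    # terms remain so deep chains exist up to max_depth
    depth_of: dict[str, int] = {}
    n_levels = config.max_depth - 1
    for i, term_id in enumerate(ids):
        if i < n_levels:
            depth = i + 1  # seed every level once
        else:
            depth = int(rng.integers(1, n_levels + 1))
        depth_of[term_id] = depth

    generalized = set(
        rng.choice(
            ids,
            size=int(round(config.generalized_fraction * n_inner)),
            replace=False,
        )
    ) if n_inner else set()

    for term_id in ids:
        depth = depth_of[term_id]
        label = f"anatomical structure {term_id.split(':')[1].lstrip('0')}"
        g.add_term(
            Term(id=term_id, label=label, generalized=term_id in generalized)
        )
        levels.setdefault(depth, []).append(term_id)

    def pick_relation() -> RelationKind:
        return (
            RelationKind.PART_OF
            if rng.random() < config.part_of_edge_fraction
            else RelationKind.IS_A
        )

    for term_id in ids:
        depth = depth_of[term_id]
        parents = levels.get(depth - 1) or levels[0]
        parent = str(rng.choice(parents))
        g.add_edge(term_id, pick_relation(), parent)
        if rng.random() < config.extra_parent_prob:
            shallower = [
                t for d in range(0, depth) for t in levels.get(d, [])
                if t != parent
            ]
            if shallower:
                second = str(rng.choice(sorted(shallower)))
                if not g._g.has_edge(term_id, second):
                    g.add_edge(term_id, pick_relation(), second)

    g.validate()
    return g


def generate_quality_ontology() -> OntologyGraph:
    """Fixed miniature quality ontology (synthetic PATO stand-in).

    Carries the five classification anchors plus a dozen descendant
    qualities so every quality class has concrete realisations.  The ids
    of the anchors are the real PATO ids; descendant ids are fixture
    values local to this package.
    """
    g = OntologyGraph()
    terms = [
        ("PATO:0000001", "quality", None),
        ("PATO:0000070", "amount", "PATO:0000001"),
        ("PATO:0000467", "present", "PATO:0000070"),
        ("PATO:0000462", "absent", "PATO:0000070"),
        ("PATO:0000470", "increased amount", "PATO:0000070"),
        ("PATO:0001997", "decreased amount", "PATO:0000070"),
        ("PATO:0000051", "morphology", "PATO:0000001"),
        ("PATO:0000052", "shape", "PATO:0000051"),
        ("PATO:0000117", "size", "PATO:0000051"),
        ("PATO:0000150", "texture", "PATO:0000051"),
        ("PATO:0000141", "structure", "PATO:0000051"),
        ("PATO:0000586", "increased size", "PATO:0000117"),
        ("PATO:0000587", "decreased size", "PATO:0000117"),
        ("PATO:0000411", "circular", "PATO:0000052"),
        ("PATO:0001154", "elongated", "PATO:0000052"),
        ("PATO:0001667", "attached to", "PATO:0000141"),
        ("PATO:0000140", "position", "PATO:0000001"),
        ("PATO:0000133", "orientation", "PATO:0000140"),
        ("PATO:0001236", "angle to", "PATO:0000140"),
        ("PATO:0002326", "anterior displacement", "PATO:0000140"),
    ]
    for term_id, label, parent in terms:
        g.add_term(Term(id=term_id, label=label))
    for term_id, _, parent in terms:
        if parent is not None:
            g.add_edge(term_id, RelationKind.IS_A, parent)
    g.validate()
    return g


def _quality_realizations(g_quality: OntologyGraph) -> dict[QualityClass, list[str]]:
    """Concrete quality terms per class, from the classifier itself."""
    by_class: dict[QualityClass, list[str]] = {cls: [] for cls in QualityClass}
    for term_id in sorted(g_quality.terms):
        by_class[classify_quality(g_quality, term_id)].append(term_id)
    return by_class


# ---------------------------------------------------------------------------
# Complexity distribution
# ---------------------------------------------------------------------------

def truncated_geometric_complexity(
    mean: float, lo: int = 2, hi: int = 15
) -> dict[int, float]:
    """Truncated geometric distribution on {lo..hi} with the given mean.

    p(c) ∝ r**(c-lo); the ratio r is solved numerically.  Degenerate
    means at the boundary collapse to a point mass.
    """
    values = np.arange(lo, hi + 1)
    if mean <= lo:
        return {lo: 1.0}
    if mean >= hi:
        return {hi: 1.0}

    def mean_for(r: float) -> float:
        w = r ** (values - lo)
        return float((values * w).sum() / w.sum())

    r = brentq(lambda r: mean_for(r) - mean, 1e-12, 1e6, xtol=1e-12)
    w = r ** (values - lo)
    w = w / w.sum()
    return {int(v): float(p) for v, p in zip(values, w)}


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

@dataclass
class _TaxonState:
    """Per-taxon closure bookkeeping that keeps corpora conflict-free.

    ``up`` holds the reflexive upward closure of every term asserted or
    implied present; ``down`` the reflexive downward closure of every
    term asserted absent.  A new absent core must avoid ``up``; terms of
    a new present-implying statement must avoid ``down``.
    """

    up: dict[str, set[str]] = field(default_factory=dict)
    down: dict[str, set[str]] = field(default_factory=dict)

    def up_for(self, taxon: str) -> set[str]:
        return self.up.setdefault(taxon, set())

    def down_for(self, taxon: str) -> set[str]:
        return self.down.setdefault(taxon, set())


class _ClosureCache:
    def __init__(self, g: OntologyGraph):
        self.g = g
        self._up: dict[str, frozenset[str]] = {}
        self._down: dict[str, frozenset[str]] = {}

    def up(self, term: str) -> frozenset[str]:
        if term not in self._up:
            self._up[term] = frozenset(
                {term} | self.g.superclosure(term, BOTH_RELATIONS)
            )
        return self._up[term]

    def down(self, term: str) -> frozenset[str]:
        if term not in self._down:
            self._down[term] = frozenset(
                {term} | self.g.subclosure(term, BOTH_RELATIONS)
            )
        return self._down[term]


def _taxon_pool(config: GeneratorConfig) -> tuple[list[str], list[str]]:
    pool = [f"TAX:{i + 1:04d}" for i in range(config.taxon_pool_size)]
    focal = pool[: config.n_focal_taxa]
    return pool, focal


def _build_expression(
    terms: Sequence[str],
) -> EntityExpression:
    """Chain terms into a part_of post-composition, outermost first."""
    expr = EntityExpression(core=terms[-1])
    for term in reversed(terms[:-1]):
        expr = EntityExpression(
            core=term, differentia=((RelationKind.PART_OF, expr),)
        )
    return expr


def _generate_kind(
    cfg: CorpusConfig,
    kind: SourceKind,
    g: OntologyGraph,
    g_quality: OntologyGraph,
    rng: np.random.Generator,
    pool: list[str],
    focal: list[str],
    state: _TaxonState,
    closures: _ClosureCache,
    truth: GroundTruth,
) -> list[AnnotationCorpus]:
    cfg.validate()
    space = sorted(g.class_space(ROOT_IDS[:2], ClassSpaceMode.ANY_OF))
    if not space:
        raise GenerationError("empty class space; enlarge the ontology")
    realizations = _quality_realizations(g_quality)
    for cls in cfg.quality_mixture:
        if not realizations[cls]:
            raise GenerationError(f"no quality terms realise {cls}")

    comp_dist = truncated_geometric_complexity(
        cfg.complexity_mean, 2, cfg.complexity_max
    )
    comp_values = np.array(list(comp_dist))
    comp_probs = np.array([comp_dist[int(v)] for v in comp_values])
    mix_classes = sorted(cfg.quality_mixture, key=lambda c: c.value)
    mix_probs = np.array([cfg.quality_mixture[c] for c in mix_classes])

    truth.quality_mixtures[kind.value] = {
        c.value: float(p) for c, p in zip(mix_classes, mix_probs)
    }

    prefix = "mono" if kind is SourceKind.MONOGRAPH else "matr"
    corpora: list[AnnotationCorpus] = []
    for p in range(cfg.n_publications):
        source_id = f"{prefix}{p + 1:02d}"
        n_stmts = _draw_count(
            rng, cfg.statements_mean, cfg.statements_dispersion
        )
        n_taxa = max(1, int(rng.poisson(cfg.taxa_mean)))
        n_taxa = min(n_taxa, len(pool))
        pub_taxa = list(focal[:n_taxa])
        if n_taxa > len(pub_taxa):
            extras = [t for t in pool if t not in focal]
            chosen = rng.choice(extras, size=n_taxa - len(pub_taxa), replace=False)
            pub_taxa += [str(t) for t in chosen]

        statements: list[EQStatement] = []
        for j in range(n_stmts):
            char_id = f"c{j + 1:03d}"
            n_eqs = 1 + int(rng.poisson(max(cfg.eqs_per_statement_mean - 1, 0)))
            comparative = (
                kind is SourceKind.MONOGRAPH
                and rng.random() < cfg.comparative_fraction
            )
            for e in range(n_eqs):
                stmt = _generate_statement(
                    rng=rng,
                    statement_id=f"{char_id}.{e + 1}",
                    character_id=char_id,
                    taxon=str(rng.choice(pub_taxa)),
                    source_id=source_id,
                    kind=kind,
                    comparative=comparative,
                    space=space,
                    realizations=realizations,
                    comp_values=comp_values,
                    comp_probs=comp_probs,
                    mix_classes=mix_classes,
                    mix_probs=mix_probs,
                    absent_fraction=cfg.absent_fraction,
                    g=g,
                    state=state,
                    closures=closures,
                    truth=truth,
                )
                statements.append(stmt)

        corpora.append(
            AnnotationCorpus(
                publication_id=source_id,
                source_kind=kind,
                statements=statements,
                declared_statement_count=n_stmts,
            )
        )
    return corpora


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative-binomial count with the given mean and size, clipped ≥ 1."""
    p = dispersion / (dispersion + mean)
    return max(1, int(rng.negative_binomial(dispersion, p)))


def _generate_statement(
    rng, statement_id, character_id, taxon, source_id, kind, comparative,
    space, realizations, comp_values, comp_probs, mix_classes, mix_probs,
    absent_fraction, g, state, closures, truth,
) -> EQStatement:
    target = int(rng.choice(comp_values, p=comp_probs))
    cls = mix_classes[int(rng.choice(len(mix_classes), p=mix_probs))]
    if cls is QualityClass.NEOMORPHIC:
        quality = (
            DEFAULT_ANCHORS.absent
            if rng.random() < absent_fraction
            else DEFAULT_ANCHORS.present
        )
    else:
        quality = str(rng.choice(realizations[cls]))

    is_absent = quality == DEFAULT_ANCHORS.absent
    is_present_anchor = quality == DEFAULT_ANCHORS.present

    # exact-complexity parity rule: even targets use no related entity,
    # odd targets attach a single-term related entity
    if target % 2 == 0:
        k_e, k_re = target // 2, 0
    else:
        k_e, k_re = (target - 1) // 2, 1

    up_t = state.up_for(taxon)
    down_t = state.down_for(taxon)

    if is_absent:
        core_pool = [t for t in space if t not in up_t]
        if not core_pool:
            # no absent-able entity left for this taxon; fall back to a
            # presence assertion (logged) rather than create a conflict
            logger.warning(
                "taxon %s: no conflict-free absent candidate; using 'present'",
                taxon,
            )
            quality = DEFAULT_ANCHORS.present
            is_absent, is_present_anchor = False, True

    if is_absent:
        core = str(rng.choice(core_pool))
        fillers = _sample_terms(rng, space, k_e - 1 + k_re, exclude={core})
        terms_e = [core] + fillers[: k_e - 1]
        terms_re = fillers[k_e - 1:]
        down_t |= closures.down(core)
    elif is_present_anchor:
        candidate = [t for t in space if t not in down_t]
        if not candidate:
            raise GenerationError(f"taxon {taxon}: class space exhausted")
        core = str(rng.choice(candidate))
        fillers = _sample_terms(rng, space, k_e - 1 + k_re, exclude={core})
        terms_e = [core] + fillers[: k_e - 1]
        terms_re = fillers[k_e - 1:]
        up_t |= closures.up(core)
    else:
        candidate = [t for t in space if t not in down_t]
        if len(candidate) < k_e + k_re:
            raise GenerationError(
                f"taxon {taxon}: not enough conflict-free entities for "
                f"complexity {target}"
            )
        chosen = [
            str(t)
            for t in rng.choice(candidate, size=k_e + k_re, replace=False)
        ]
        terms_e, terms_re = chosen[:k_e], chosen[k_e:]
        for t in chosen:
            if not g.term(t).generalized:
                up_t |= closures.up(t)

    entity = _build_expression(terms_e)
    related = _build_expression(terms_re) if terms_re else None
    truth.complexity_targets[(source_id, statement_id)] = target
    return EQStatement(
        statement_id=statement_id,
        taxon=taxon,
        entity=entity,
        quality=quality,
        related_entity=related,
        source_id=source_id,
        source_kind=kind,
        character_id=character_id,
        comparative=comparative,
    )


def _sample_terms(rng, space, k, exclude=frozenset()) -> list[str]:
    if k <= 0:
        return []
    candidates = [t for t in space if t not in exclude]
    if len(candidates) < k:
        raise GenerationError("ontology too small for requested complexity")
    return [str(t) for t in rng.choice(candidates, size=k, replace=False)]


def generate_corpus(
    config: GeneratorConfig,
    g: OntologyGraph,
    kind: SourceKind,
    g_quality: Optional[OntologyGraph] = None,
    state: Optional[_TaxonState] = None,
) -> tuple[list[AnnotationCorpus], GroundTruth]:
    """Generate all publications of one source kind.

    Pass the same ``state`` for both kinds to keep the joint corpus
    closure-consistent across sources (``generate_study`` does this).
    """
    config.validate()
    if g_quality is None:
        g_quality = generate_quality_ontology()
    if state is None:
        state = _TaxonState()
    truth = GroundTruth(seed=config.seed)
    rng = _sub_rng(config.seed, f"corpus-{kind.value}")
    pool, focal = _taxon_pool(config)
    cfg = config.monograph if kind is SourceKind.MONOGRAPH else config.matrix
    corpora = _generate_kind(
        cfg, kind, g, g_quality, rng, pool, focal, state,
        _ClosureCache(g), truth,
    )
    return corpora, truth


@dataclass
class StudyData:
    """Everything one simulated study produces."""

    ontology: OntologyGraph
    quality_ontology: OntologyGraph
    monograph_corpora: list[AnnotationCorpus]
    matrix_corpora: list[AnnotationCorpus]
    ground_truth: GroundTruth
    roots: tuple[str, ...] = ROOT_IDS


def generate_study(config: GeneratorConfig) -> StudyData:
    """Ontology + both corpora + optional injected conflicts, end to end."""
    config.validate()
    g = generate_ontology(config.ontology, config.seed)
    g_quality = generate_quality_ontology()
    state = _TaxonState()
    truth = GroundTruth(seed=config.seed)
    closures = _ClosureCache(g)
    pool, focal = _taxon_pool(config)

    mono = _generate_kind(
        config.monograph, SourceKind.MONOGRAPH, g, g_quality,
        _sub_rng(config.seed, "corpus-monograph"),
        pool, focal, state, closures, truth,
    )
    matr = _generate_kind(
        config.matrix, SourceKind.MATRIX, g, g_quality,
        _sub_rng(config.seed, "corpus-matrix"),
        pool, focal, state, closures, truth,
    )

    if config.conflicts.n_injected > 0:
        if not mono or not matr:
            raise GenerationError("conflict injection needs both source kinds")
        mono_mod, matr_mod, injected = _inject(
            mono, matr, config.conflicts.n_injected, config.conflicts.mode,
            _sub_rng(config.seed, "inject"), g, g_quality,
        )
        mono, matr = mono_mod, matr_mod
        truth.injected_conflicts = injected

    return StudyData(
        ontology=g,
        quality_ontology=g_quality,
        monograph_corpora=mono,
        matrix_corpora=matr,
        ground_truth=truth,
    )


def generate_quality_sample(
    n: int,
    mixture: dict[QualityClass, float],
    seed: int,
    g_quality: Optional[OntologyGraph] = None,
    absent_fraction: float = 0.5,
    kind: SourceKind = SourceKind.MATRIX,
) -> AnnotationCorpus:
    """``n`` minimal EQ statements whose quality classes follow ``mixture``.

    Each statement is a bare single-entity EQ; its quality class is drawn
    from the mixture and realised as a concrete quality term of that
    class (NEOMORPHIC splits present/absent by ``absent_fraction``).
    Used to validate the quality classifier against a known mixture.
    """
    if g_quality is None:
        g_quality = generate_quality_ontology()
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise GenerationError(f"mixture sums to {total}, not 1")
    realizations = _quality_realizations(g_quality)
    rng = _sub_rng(seed, "quality-sample")
    classes = sorted(mixture, key=lambda c: c.value)
    probs = np.array([mixture[c] for c in classes])
    draws = rng.choice(len(classes), size=n, p=probs)
    statements = []
    for i, d in enumerate(draws):
        cls = classes[int(d)]
        if cls is QualityClass.NEOMORPHIC:
            quality = (
                DEFAULT_ANCHORS.absent
                if rng.random() < absent_fraction
                else DEFAULT_ANCHORS.present
            )
        else:
            quality = str(rng.choice(realizations[cls]))
        statements.append(
            EQStatement(
                statement_id=f"s{i + 1:05d}",
                taxon="TAX:0001",
                entity=EntityExpression(core="ANAT:0000003"),
                quality=quality,
                source_id="sample01",
                source_kind=kind,
            )
        )
    return AnnotationCorpus(
        publication_id="sample01", source_kind=kind, statements=statements
    )


# ---------------------------------------------------------------------------
# Conflict injection
# ---------------------------------------------------------------------------

def _closure_state_from_corpora(
    corpora: Sequence[AnnotationCorpus],
    g: OntologyGraph,
    g_quality: OntologyGraph,
) -> _TaxonState:
    """Recover per-taxon closure state by running the real pipeline."""
    state = _TaxonState()
    space = g.class_space(ROOT_IDS[:2], ClassSpaceMode.ANY_OF)
    for corpus in corpora:
        asserted = _sm.direct_assertions(
            corpus, g, g_quality, ROOT_IDS[:2], ClassSpaceMode.ANY_OF,
            space=space,
        )
        for a in _sm.propagate(g, asserted):
            if a.state is _sm.CellState.PRESENT:
                state.up_for(a.taxon).add(a.entity)
            else:
                state.down_for(a.taxon).add(a.entity)
    return state


def _inject(
    corpora_a: list[AnnotationCorpus],
    corpora_b: list[AnnotationCorpus],
    n: int,
    mode: str,
    rng: np.random.Generator,
    g: OntologyGraph,
    g_quality: OntologyGraph,
) -> tuple[list[AnnotationCorpus], list[AnnotationCorpus], list[tuple[str, str]]]:
    space = g.class_space(ROOT_IDS[:2], ClassSpaceMode.ANY_OF)
    leaves = sorted(
        t for t in space
        if not g.subclosure(t, BOTH_RELATIONS) and not g.term(t).generalized
    )
    state = _closure_state_from_corpora(list(corpora_a) + list(corpora_b), g, g_quality)
    closures = _ClosureCache(g)

    taxa_a = set().union(*(c.taxa for c in corpora_a)) if corpora_a else set()
    taxa_b = set().union(*(c.taxa for c in corpora_b)) if corpora_b else set()
    # prefer taxa both kinds mention; fall back to any mentioned taxon
    # (a source may assert about a taxon the other never coded)
    shared = sorted(taxa_a & taxa_b) or sorted(taxa_a | taxa_b)

    candidates: list[tuple[str, str]] = []
    for taxon in shared:
        up_t = state.up_for(taxon)
        down_t = state.down_for(taxon)
        for leaf in leaves:
            if leaf in up_t or leaf in down_t:
                continue
            if closures.up(leaf) & down_t:
                continue
            candidates.append((taxon, leaf))

    if n > len(candidates):
        raise ValueError(
            f"cannot inject {n} conflicts; only {len(candidates)} "
            "conflict-free taxon-entity pairs available"
        )
    idx = rng.choice(len(candidates), size=n, replace=False)
    chosen = sorted(candidates[int(i)] for i in idx)

    morph_qualities = [
        t for t in sorted(g_quality.terms)
        if classify_quality(g_quality, t) is QualityClass.MORPHOLOGY
    ]

    new_a = [
        AnnotationCorpus(
            c.publication_id, c.source_kind, list(c.statements),
            c.declared_statement_count, c.declared_state_count,
        )
        for c in corpora_a
    ]
    new_b = [
        AnnotationCorpus(
            c.publication_id, c.source_kind, list(c.statements),
            c.declared_statement_count, c.declared_state_count,
        )
        for c in corpora_b
    ]

    for i, (taxon, entity) in enumerate(chosen):
        host_a = new_a[int(rng.integers(len(new_a)))]
        host_b = new_b[int(rng.integers(len(new_b)))]
        present_quality = (
            DEFAULT_ANCHORS.present
            if mode == "asserted"
            else str(rng.choice(morph_qualities))
        )
        host_a.statements.append(
            EQStatement(
                statement_id=f"inj{i + 1:03d}p",
                taxon=taxon,
                entity=EntityExpression(core=entity),
                quality=present_quality,
                source_id=host_a.publication_id,
                source_kind=host_a.source_kind,
                character_id=f"inj{i + 1:03d}",
            )
        )
        host_b.statements.append(
            EQStatement(
                statement_id=f"inj{i + 1:03d}a",
                taxon=taxon,
                entity=EntityExpression(core=entity),
                quality=DEFAULT_ANCHORS.absent,
                source_id=host_b.publication_id,
                source_kind=host_b.source_kind,
                character_id=f"inj{i + 1:03d}",
            )
        )
    return new_a, new_b, list(chosen)


def inject_conflicts(
    corpora_a: Sequence[AnnotationCorpus],
    corpora_b: Sequence[AnnotationCorpus],
    n: int,
    seed: int,
    g: OntologyGraph,
    g_quality: Optional[OntologyGraph] = None,
    mode: str = "asserted",
) -> tuple[list[AnnotationCorpus], list[AnnotationCorpus], GroundTruth]:
    """Plant exactly ``n`` present-vs-absent contradictions.

    Each injected pair gets a presence-implying statement in one corpus
    collection and an explicit absence in the other, at a leaf entity
    chosen so no incidental conflict arises elsewhere; the returned
    ground truth lists exactly the planted (taxon, entity) pairs.
    """
    if g_quality is None:
        g_quality = generate_quality_ontology()
    rng = _sub_rng(seed, "inject")
    new_a, new_b, chosen = _inject(
        list(corpora_a), list(corpora_b), n, mode, rng, g, g_quality
    )
    truth = GroundTruth(seed=seed, injected_conflicts=chosen)
    return new_a, new_b, truth
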