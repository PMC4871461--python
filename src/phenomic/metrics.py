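"""Phenomic-content measures over EQ corpora.

Four families of measures quantify how much anatomical knowledge a
publication's annotations carry and how two data-source kinds compare:

* **entity extraction / overlap** — the named anatomical entities a
  corpus uses, restricted to a reasoned class space, and unique/shared
  breakdowns between two entity sets;
* **class-space coverage** — the fraction of all relevant anatomical
  classes a corpus touches;
* **quality-class profiles** — percentage of EQs whose quality falls in
  each high-level class (Neomorphic, Morphology, Position, Number);
* **complexity summaries** — mean/median/max EQ complexity and the
  empirical distribution over integer scores.

Group comparisons use per-publication statistics as replicates (never
pooled EQs) and a two-sample t-test, Welch by default.
"""

from __future__ import annotations

import enum
import math
import statistics
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats as _scipy_stats

from .annotations import (
    DEFAULT_ANCHORS,
    AnnotationCorpus,
    QualityAnchors,
    QualityClass,
    SourceKind,
    classify_quality,
    eq_complexity,
)
from .ontology import BOTH_RELATIONS, ClassSpaceMode, OntologyGraph

__all__ = [
    "OverlapSummary",
    "PhenomicProfile",
    "GroupComparison",
    "TTestVariant",
    "round_half_up",
    "extract_entities",
    "overlap",
    "overlap_from_counts",
    "coverage",
    "quality_profile",
    "mean_quality_profile",
    "complexity_profile",
    "complexity_bins",
    "compare_groups",
]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used for reporting).

    Python's builtin ``round`` is banker's rounding; printed tables here
    use half-up (48.86 → 49, 18.75 → 18.8).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


class TTestVariant(enum.Enum):
    WELCH = "welch"
    STUDENT = "student"


# ---------------------------------------------------------------------------
# Entity extraction and set comparison
# ---------------------------------------------------------------------------

def extract_entities(
    corpus: AnnotationCorpus,
    g: OntologyGraph,
    roots: Sequence[str],
    root_mode: ClassSpaceMode = ClassSpaceMode.ANY_OF,
    exclude_generalized: bool = True,
    taxon: Optional[str] = None,
    space: Optional[set[str]] = None,
) -> set[str]:
    """Named anatomical entities a corpus uses within a class space.

    Walks every term in every E and RE tree (post-compositions included),
    keeps those inside ``class_space(g, roots, root_mode)``, and drops
    generalized (unnamed generic) terms when ``exclude_generalized``.
    ``taxon`` filters statements by exact taxon-identifier match.  A
    precomputed ``space`` may be passed to avoid recomputing the query.
    """
    if space is None:
        space = g.class_space(roots, root_mode)
    found: set[str] = set()
    for s in corpus.statements:
        if taxon is not None and s.taxon != taxon:
            continue
        trees = [s.entity] + ([s.related_entity] if s.related_entity else [])
        for tree in trees:
            for term_id in tree.iter_terms():
                if term_id not in space:
                    continue
                if exclude_generalized and g.term(term_id).generalized:
                    continue
                found.add(term_id)
    return found


@dataclass(frozen=True)
class OverlapSummary:
    """Unique/shared breakdown of two entity sets.

    Percentages are unrounded; ``rounded()`` applies the half-up
    reporting convention (whole percents by default).  A percentage with
    an empty denominator is ``None``.
    """

    size_a: int
    size_b: int
    shared: int
    unique_a: int
    unique_b: int
    union_size: int
    pct_unique_a: Optional[float]
    pct_unique_b: Optional[float]
    pct_shared_of_union: Optional[float]

    def rounded(self, ndigits: int = 0) -> "OverlapSummary":
        def r(x):
            return None if x is None else round_half_up(x, ndigits)

        return OverlapSummary(
            self.size_a, self.size_b, self.shared,
            self.unique_a, self.unique_b, self.union_size,
            r(self.pct_unique_a), r(self.pct_unique_b),
            r(self.pct_shared_of_union),
        )


def overlap(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapSummary:
    """Pairwise unique/shared entity comparison."""
    a, b = set(set_a), set(set_b)
    shared = len(a & b)
    union = len(a | b)
    return OverlapSummary(
        size_a=len(a),
        size_b=len(b),
        shared=shared,
        unique_a=len(a) - shared,
        unique_b=len(b) - shared,
        union_size=union,
        pct_unique_a=100.0 * (len(a) - shared) / len(a) if a else None,
        pct_unique_b=100.0 * (len(b) - shared) / len(b) if b else None,
        pct_shared_of_union=100.0 * shared / union if union else None,
    )


def overlap_from_counts(size_a: int, size_b: int, shared: int) -> OverlapSummary:
    """Overlap summary from printed (|A|, |B|, |A∩B|) counts alone."""
    if shared > min(size_a, size_b) or min(size_a, size_b, shared) < 0:
        raise ValueError("inconsistent counts")
    union = size_a + size_b - shared
    return OverlapSummary(
        size_a=size_a,
        size_b=size_b,
        shared=shared,
        unique_a=size_a - shared,
        unique_b=size_b - shared,
        union_size=union,
        pct_unique_a=100.0 * (size_a - shared) / size_a if size_a else None,
        pct_unique_b=100.0 * (size_b - shared) / size_b if size_b else None,
        pct_shared_of_union=100.0 * shared / union if union else None,
    )


def coverage(used: Iterable[str], space: Iterable[str], ndigits: Optional[int] = 1) -> float:
    """Percent of a class space touched by a set of used terms.

    Elements of ``used`` outside ``space`` are ignored.  Rounded half-up
    to ``ndigits`` (default one decimal); pass ``ndigits=None`` for the
    raw value.
    """
    space = set(space)
    if not space:
        raise ValueError("coverage is undefined for an empty class space")
    pct = 100.0 * len(set(used) & space) / len(space)
    return pct if ndigits is None else round_half_up(pct, ndigits)


# ---------------------------------------------------------------------------
# Quality-class and complexity profiles
# ---------------------------------------------------------------------------

def quality_profile(
    corpus: AnnotationCorpus,
    g_quality: OntologyGraph,
    anchors: QualityAnchors = DEFAULT_ANCHORS,
    lenient: bool = False,
) -> dict[QualityClass, float]:
    """Percent of EQs per quality class; NaN-valued for an empty corpus."""
    if not corpus.statements:
        return {cls: math.nan for cls in QualityClass}
    counts = {cls: 0 for cls in QualityClass}
    memo: dict[str, QualityClass] = {}  # classification per distinct quality
    for s in corpus.statements:
        cls = memo.get(s.quality)
        if cls is None:
            cls = classify_quality(g_quality, s.quality, anchors, lenient)
            memo[s.quality] = cls
        counts[cls] += 1
    n = corpus.n_eqs
    return {cls: 100.0 * c / n for cls, c in counts.items()}


def mean_quality_profile(
    corpora: Sequence[AnnotationCorpus],
    g_quality: OntologyGraph,
    anchors: QualityAnchors = DEFAULT_ANCHORS,
) -> dict[QualityClass, float]:
    """Group profile: mean of per-publication percentages (not pooled EQs)."""
    if not corpora:
        return {cls: math.nan for cls in QualityClass}
    profiles = [quality_profile(c, g_quality, anchors) for c in corpora]
    return {
        cls: sum(p[cls] for p in profiles) / len(profiles)
        for cls in QualityClass
    }


@dataclass
class PhenomicProfile:
    """Per-publication summary statistics.

    ``entity_terms_*`` is the entity-side size per EQ (classes plus
    relations in E and RE together); ``quality_terms_*`` the
    quality-side size.  All statistics are unrounded; reports apply the
    single half-up rounding rule.
    """

    publication_id: str
    source_kind: SourceKind
    n_statements: int
    n_eqs: int
    n_taxa: int
    complexity_mean: float
    complexity_median: float
    complexity_max: int
    entity_terms_mean: float
    entity_terms_max: int
    quality_terms_mean: float
    quality_terms_max: int
    quality_class_pct: Optional[dict[QualityClass, float]] = None

    def to_dict(self) -> dict:
        d = {
            "publication_id": self.publication_id,
            "source_kind": self.source_kind.value,
            "n_statements": self.n_statements,
            "n_eqs": self.n_eqs,
            "n_taxa": self.n_taxa,
            "complexity_mean": self.complexity_mean,
            "complexity_median": self.complexity_median,
            "complexity_max": self.complexity_max,
            "entity_terms_mean": self.entity_terms_mean,
            "entity_terms_max": self.entity_terms_max,
            "quality_terms_mean": self.quality_terms_mean,
            "quality_terms_max": self.quality_terms_max,
        }
        if self.quality_class_pct is not None:
            d["quality_class_pct"] = {
                cls.value: pct for cls, pct in self.quality_class_pct.items()
            }
        return d


def complexity_profile(
    corpus: AnnotationCorpus,
    g_quality: Optional[OntologyGraph] = None,
    anchors: QualityAnchors = DEFAULT_ANCHORS,
) -> PhenomicProfile:
    """Complexity and size statistics for one publication.

    The quality-class breakdown is filled in when a quality ontology is
    supplied.  Raises ``ValueError`` on an empty corpus.
    """
    if not corpus.statements:
        raise ValueError(f"corpus {corpus.publication_id!r} is empty")
    complexities = [eq_complexity(s) for s in corpus.statements]
    e_sizes = [
        s.entity.size + (s.related_entity.size if s.related_entity else 0)
        for s in corpus.statements
    ]
    q_sizes = [1 for _ in corpus.statements]  # single quality term per EQ
    return PhenomicProfile(
        publication_id=corpus.publication_id,
        source_kind=corpus.source_kind,
        n_statements=corpus.n_statements,
        n_eqs=corpus.n_eqs,
        n_taxa=len(corpus.taxa),
        complexity_mean=statistics.fmean(complexities),
        complexity_median=statistics.median(complexities),
        complexity_max=max(complexities),
        entity_terms_mean=statistics.fmean(e_sizes),
        entity_terms_max=max(e_sizes),
        quality_terms_mean=statistics.fmean(q_sizes),
        quality_terms_max=max(q_sizes),
        quality_class_pct=(
            quality_profile(corpus, g_quality, anchors) if g_quality else None
        ),
    )


def complexity_bins(corpus: AnnotationCorpus) -> dict[int, float]:
    """Empirical distribution over integer EQ-complexity scores."""
    if not corpus.statements:
        return {}
    counts: dict[int, int] = {}
    for s in corpus.statements:
        c = eq_complexity(s)
        counts[c] = counts.get(c, 0) + 1
    n = corpus.n_eqs
    return {c: k / n for c, k in sorted(counts.items())}


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Two-sample t-test between per-publication statistics."""

    group_a_values: tuple[float, ...]
    group_b_values: tuple[float, ...]
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    variant: TTestVariant
    significant_at: dict[float, bool] = field(default_factory=dict)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variant: TTestVariant = TTestVariant.WELCH,
    thresholds: Sequence[float] = (0.05, 0.001),
) -> GroupComparison:
    """Two-sided two-sample t-test (Welch by default).

    Requires at least two values per group.  The degenerate case of zero
    variance in both groups with equal means reports t=0, p=1.
    """
    a = [float(v) for v in values_a]
    b = [float(v) for v in values_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    import warnings

    with warnings.catch_warnings():
        # near-constant groups trigger a precision warning; the nan they
        # produce is handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _scipy_stats.ttest_ind(
            a, b, equal_var=(variant is TTestVariant.STUDENT)
        )
    t, p = float(res.statistic), float(res.pvalue)
    if math.isnan(t) and statistics.fmean(a) == statistics.fmean(b):
        t, p = 0.0, 1.0
    return GroupComparison(
        group_a_values=tuple(a),
        group_b_values=tuple(b),
        mean_a=statistics.fmean(a),
        mean_b=statistics.fmean(b),
        t_statistic=t,
        p_value=p,
        variant=variant,
        significant_at={thr: p < thr for thr in thresholds},
    )
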