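"""Report writers: per-publication profile tables, overlap/coverage
tables, quality-class group comparisons, and conflict listings.

TSV outputs apply the single reporting rounding rule (half-up; whole
percents for overlap tables, one decimal for coverage and means); the
JSON bundle always carries the unrounded values.
"""

from __future__ import annotations

import csv
import json
from typing import Mapping, Optional, Sequence

from .annotations import QualityClass
from .metrics import (
    GroupComparison,
    OverlapSummary,
    PhenomicProfile,
    round_half_up,
)
from .supermatrix import Conflict

__all__ = [
    "write_profiles_tsv",
    "write_profiles_json",
    "write_overlap_tsv",
    "write_quality_groups_tsv",
    "write_coverage_tsv",
    "write_conflicts_tsv",
]

_QUALITY_ORDER = [
    QualityClass.MORPHOLOGY,
    QualityClass.NEOMORPHIC,
    QualityClass.POSITION,
    QualityClass.NUMBER,
    QualityClass.OTHER,
]


def _writer(fh):
    return csv.writer(fh, delimiter="\t", lineterminator="\n")


def write_profiles_tsv(profiles: Sequence[PhenomicProfile], path) -> None:
    """Per-publication breakdown of counts, complexity, and sizes."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = _writer(fh)
        header = [
            "publication", "source_kind", "statements", "eqs", "taxa",
            "complexity_mean", "complexity_median", "complexity_max",
            "entity_size_mean", "entity_size_max",
            "quality_size_mean", "quality_size_max",
        ] + [f"pct_{cls.value.lower()}" for cls in _QUALITY_ORDER]
        w.writerow(header)
        for p in profiles:
            row = [
                p.publication_id, p.source_kind.value,
                p.n_statements, p.n_eqs, p.n_taxa,
                round_half_up(p.complexity_mean, 1),
                round_half_up(p.complexity_median, 1),
                p.complexity_max,
                round_half_up(p.entity_terms_mean, 1),
                p.entity_terms_max,
                round_half_up(p.quality_terms_mean, 1),
                p.quality_terms_max,
            ]
            for cls in _QUALITY_ORDER:
                if p.quality_class_pct is None:
                    row.append("")
                else:
                    row.append(round_half_up(p.quality_class_pct[cls], 1))
            w.writerow(row)


def write_profiles_json(profiles: Sequence[PhenomicProfile], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([p.to_dict() for p in profiles], fh, indent=1, sort_keys=True)


def write_overlap_tsv(
    overlaps: Mapping[str, OverlapSummary], path, ndigits: int = 0
) -> None:
    """One row per key (typically per taxon), whole-percent rounding."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = _writer(fh)
        w.writerow([
            "key", "total_a", "total_b", "unique_a", "pct_unique_a",
            "unique_b", "pct_unique_b", "shared", "union", "pct_shared_of_union",
        ])
        for key in sorted(overlaps):
            o = overlaps[key]
            r = o.rounded(ndigits)
            w.writerow([
                key, o.size_a, o.size_b,
                o.unique_a, _fmt(r.pct_unique_a),
                o.unique_b, _fmt(r.pct_unique_b),
                o.shared, o.union_size, _fmt(r.pct_shared_of_union),
            ])


def _fmt(value) -> str:
    return "NA" if value is None else f"{value:g}"


def write_quality_groups_tsv(
    group_a_label: str,
    group_b_label: str,
    means_a: Mapping[QualityClass, float],
    means_b: Mapping[QualityClass, float],
    tests: Mapping[QualityClass, GroupComparison],
    path,
) -> None:
    """Group-mean quality-class percentages with t-test results."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = _writer(fh)
        w.writerow([
            "quality_class", f"mean_pct_{group_a_label}",
            f"mean_pct_{group_b_label}", "t_statistic", "p_value",
            "significance",
        ])
        for cls in _QUALITY_ORDER:
            if cls not in tests:
                continue
            t = tests[cls]
            stars = (
                "**" if t.p_value < 0.001
                else "*" if t.p_value < 0.05
                else ""
            )
            w.writerow([
                cls.value,
                round_half_up(means_a[cls], 1),
                round_half_up(means_b[cls], 1),
                round_half_up(t.t_statistic, 3),
                f"{t.p_value:.4g}",
                stars,
            ])


def write_coverage_tsv(coverages: Mapping[str, tuple[int, int, float]], path) -> None:
    """Rows of (label, used, space size, percent covered)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = _writer(fh)
        w.writerow(["dataset", "entities_used", "class_space", "coverage_pct"])
        for label in sorted(coverages):
            used, space, pct = coverages[label]
            w.writerow([label, used, space, round_half_up(pct, 1)])


def write_conflicts_tsv(conflicts: Sequence[Conflict], path) -> None:
    """Conflict report: one row per contradicted (taxon, entity)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = _writer(fh)
        w.writerow([
            "taxon", "entity", "severity",
            "n_present_support", "n_absent_support",
            "present_sources", "absent_sources",
        ])
        for c in conflicts:
            w.writerow([
                c.taxon, c.entity, c.severity.value,
                len(c.present_support), len(c.absent_support),
                ";".join(sorted({a.source_id for a in c.present_support})),
                ";".join(sorted({a.source_id for a in c.absent_support})),
            ])
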