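"""Precision / recall / F1 accounting over a callset comparison.

Neither sequencing modality is designated a gold standard: metrics are
computed from both perspectives. In the baseline accounting, records
labeled ``exact`` or ``context_equivalent`` are true positives from
either perspective, while modality-unique records are false positives
for their own callset and false negatives for the other.

The *modified* metrics credit high-quality modality-unique variants
that the other modality had no realistic chance to call: a unique
record that passes a quality rule in its own modality and sits where
the other modality is under-covered is reclassified from FP to TP (and
removed from the other perspective's FN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .context_match import CallsetComparison
from .genomic import DepthProfile, HaplotkError, VariantRecord

VARIANT_CLASSES = ("all", "snv", "indel")


class MetricsError(HaplotkError, ValueError):
    pass


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not (0.0 <= v <= 1.0):
            raise MetricsError(f"{name} must be in [0, 1], got {v}")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class ConcordanceMetrics:
    """TP/FP/FN counts and derived rates for one variant class and
    perspective. Undefined ratios (zero denominators) are ``None``."""

    tp: int
    fp: int
    fn: int
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    variant_class: str = "all"
    perspective: str = "a_as_query"


def metrics_from_counts(
    tp: int,
    fp: int,
    fn: int,
    variant_class: str = "all",
    perspective: str = "a_as_query",
) -> ConcordanceMetrics:
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise MetricsError(f"{name} must be non-negative, got {v}")
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    f1 = (
        f1_from_pr(precision, recall)
        if precision is not None and recall is not None
        else None
    )
    return ConcordanceMetrics(tp, fp, fn, precision, recall, f1, variant_class, perspective)


@dataclass(frozen=True)
class QualityRule:
    """Thresholds deciding whether a modality-unique record is credible
    enough to credit in the modified metrics.

    The record must have call quality >= ``min_qual`` and depth >=
    ``min_own_depth`` in its own modality, while the *other* modality's
    depth at its position is below ``other_depth_below`` — below the
    allele-depth pass threshold, the other caller could not have emitted
    a passing record there.
    """

    min_qual: float = 20.0
    min_own_depth: int = 15
    other_depth_below: int = 15


@dataclass
class ModifiedMetricsResult:
    baseline: Dict[str, ConcordanceMetrics]
    modified: Dict[str, ConcordanceMetrics]
    reclassified_a: List[VariantRecord] = field(default_factory=list)
    reclassified_b: List[VariantRecord] = field(default_factory=list)
    excluded: List[Tuple[VariantRecord, str]] = field(default_factory=list)


def _record_qualifies(
    record: VariantRecord,
    rule: QualityRule,
    other_profile: Optional[DepthProfile],
    exclusions: List[Tuple[VariantRecord, str]],
) -> bool:
    if record.qual is None or record.depth is None:
        exclusions.append((record, "missing qual/depth annotation"))
        return False
    if record.qual < rule.min_qual or record.depth < rule.min_own_depth:
        return False
    if other_profile is None:
        exclusions.append((record, "no depth profile for the other modality"))
        return False
    try:
        other_depth = other_profile.depth_at(record.chrom, record.pos - 1)
    except KeyError:
        exclusions.append((record, "position outside the other modality's profile"))
        return False
    return other_depth < rule.other_depth_below


def modified_metrics(
    comparison: CallsetComparison,
    quality_rule: QualityRule = QualityRule(),
    depth_a: Optional[DepthProfile] = None,
    depth_b: Optional[DepthProfile] = None,
    variant_class: str = "all",
) -> ModifiedMetricsResult:
    """Baseline and modified metrics for both perspectives.

    ``depth_a``/``depth_b`` are the per-base depth tracks of callsets A
    and B; a unique-to-A record is judged against ``depth_b`` and vice
    versa. Records that cannot be judged (missing annotations, no
    profile) fail the rule and are listed in the exclusion report.
    """
    if variant_class not in VARIANT_CLASSES:
        raise MetricsError(f"variant_class must be one of {VARIANT_CLASSES}")

    def _count(side: str, label: str) -> int:
        return comparison.count(side, label, variant_class)

    def _select(records: List[VariantRecord]) -> List[VariantRecord]:
        if variant_class == "all":
            return records
        return [r for r in records if r.variant_class == variant_class]

    exclusions: List[Tuple[VariantRecord, str]] = []
    qualified_a = [
        r
        for r in _select(comparison.unique_records("a"))
        if _record_qualifies(r, quality_rule, depth_b, exclusions)
    ]
    qualified_b = [
        r
        for r in _select(comparison.unique_records("b"))
        if _record_qualifies(r, quality_rule, depth_a, exclusions)
    ]

    tp_a = _count("a", "exact") + _count("a", "context_equivalent")
    tp_b = _count("b", "exact") + _count("b", "context_equivalent")
    fp_a = _count("a", "unique_a")
    fp_b = _count("b", "unique_b")

    baseline = {
        "a_as_query": metrics_from_counts(tp_a, fp_a, fp_b, variant_class, "a_as_query"),
        "b_as_query": metrics_from_counts(tp_b, fp_b, fp_a, variant_class, "b_as_query"),
    }
    modified = {
        "a_as_query": metrics_from_counts(
            tp_a + len(qualified_a),
            fp_a - len(qualified_a),
            fp_b - len(qualified_b),
            variant_class,
            "a_as_query",
        ),
        "b_as_query": metrics_from_counts(
            tp_b + len(qualified_b),
            fp_b - len(qualified_b),
            fp_a - len(qualified_a),
            variant_class,
            "b_as_query",
        ),
    }
    return ModifiedMetricsResult(baseline, modified, qualified_a, qualified_b, exclusions)


def round4(value: Optional[float]) -> Optional[float]:
    """Report rounding: 4 decimal places, round-half-even."""
    return None if value is None else round(value, 4)


def metrics_table(
    comparison: CallsetComparison,
    quality_rule: QualityRule = QualityRule(),
    depth_a: Optional[DepthProfile] = None,
    depth_b: Optional[DepthProfile] = None,
) -> pd.DataFrame:
    """A report table shaped like a published concordance summary:
    one row per variant class x perspective x baseline/modified."""
    rows = []
    for vc in VARIANT_CLASSES:
        res = modified_metrics(comparison, quality_rule, depth_a, depth_b, vc)
        for which, metrics in (("baseline", res.baseline), ("modified", res.modified)):
            for persp, m in metrics.items():
                rows.append(
                    {
                        "variant_class": vc,
                        "perspective": persp,
                        "accounting": which,
                        "tp": m.tp,
                        "fp": m.fp,
                        "fn": m.fn,
                        "precision": round4(m.precision),
                        "recall": round4(m.recall),
                        "f1": round4(m.f1),
                    }
                )
    return pd.DataFrame(rows)
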