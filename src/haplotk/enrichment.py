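"""Adaptive-sampling enrichment statistics, per-base depth, and the
paired-depth kernel-density quantile analysis.

In a channel-split run, half of the flow-cell channels perform adaptive
sampling (ejecting off-target strands after a few hundred basecalled
bases) while the other half sequence everything. Fold enrichment is the
per-channel on-target signal of the adaptive arm divided by that of the
control arm — by default in bases of on-target coverage (``base`` mode),
optionally in overlapping read counts (``read`` mode).

The paired-depth analysis fits a 2-D Gaussian kernel density over
(depth in modality A, depth in modality B) at variant sites and assigns
each point to the innermost density level set containing it, where the
level sets are chosen to enclose stated fractions of the fitted
probability mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .context_match import CallsetComparison
from .genomic import DepthProfile, HaplotkError, ReadSummary, Region


class EnrichmentError(HaplotkError, ValueError):
    pass


def n50(lengths: Sequence[int]) -> int:
    """The largest length L such that reads of length >= L sum to at
    least half the total bases."""
    if len(lengths) == 0:
        raise EnrichmentError("n50 of an empty length list is undefined")
    arr = np.asarray(lengths, dtype=np.int64)
    if (arr <= 0).any():
        raise EnrichmentError("read lengths must be positive")
    arr = np.sort(arr)[::-1]
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[min(idx, len(arr) - 1)])


@dataclass(frozen=True)
class EnrichmentResult:
    fold: float
    on_target_adaptive: int
    on_target_control: int
    channels_adaptive: int
    channels_control: int
    mode: str

    @property
    def per_channel_adaptive(self) -> float:
        return self.on_target_adaptive / self.channels_adaptive

    @property
    def per_channel_control(self) -> float:
        return self.on_target_control / self.channels_control


def _overlap_bases(read: ReadSummary, target: Region) -> int:
    r = read.mapped_region
    if r is None or r.chrom != target.chrom:
        return 0
    return max(0, min(r.end, target.end) - max(r.start, target.start))


def fold_enrichment(
    reads: Sequence[ReadSummary],
    target: Region,
    mode: str = "base",
    channels: Optional[Mapping[str, int]] = None,
) -> EnrichmentResult:
    """Per-channel-normalized fold enrichment of the adaptive arm over
    the control arm. ``channels`` may supply the channel counts per arm;
    by default the distinct channels observed per arm are used."""
    if mode not in ("base", "read"):
        raise EnrichmentError(f"mode must be base or read, got {mode!r}")
    arms: Dict[str, List[ReadSummary]] = {"adaptive": [], "control": []}
    for r in reads:
        if r.arm is None:
            raise EnrichmentError(f"read {r.read_id} has no arm label")
        arms[r.arm].append(r)
    if not arms["adaptive"] or not arms["control"]:
        raise EnrichmentError(
            "both arms must be non-empty; an all-adaptive run has no internal "
            "control — compare in read mode against a separate reference run"
        )
    signal = {}
    n_channels = {}
    for arm, arm_reads in arms.items():
        if mode == "base":
            signal[arm] = int(sum(_overlap_bases(r, target) for r in arm_reads))
        else:
            signal[arm] = int(sum(1 for r in arm_reads if _overlap_bases(r, target) > 0))
        if channels is not None and arm in channels:
            n_channels[arm] = int(channels[arm])
        else:
            n_channels[arm] = len({r.channel for r in arm_reads})
    per_adaptive = signal["adaptive"] / n_channels["adaptive"]
    per_control = signal["control"] / n_channels["control"]
    if per_control == 0:
        warnings.warn("control arm has zero on-target signal; fold is infinite")
        fold = float("inf")
    else:
        fold = per_adaptive / per_control
    return EnrichmentResult(
        fold,
        signal["adaptive"],
        signal["control"],
        n_channels["adaptive"],
        n_channels["control"],
        mode,
    )


def depth_profile(reads: Sequence[ReadSummary], region: Region) -> DepthProfile:
    """Per-base count of reads overlapping each base of ``region``."""
    delta = np.zeros(len(region) + 1, dtype=np.int64)
    for r in reads:
        mr = r.mapped_region
        if mr is None or mr.chrom != region.chrom:
            continue
        s = max(mr.start, region.start) - region.start
        e = min(mr.end, region.end) - region.start
        if s < e:
            delta[s] += 1
            delta[e] -= 1
    return DepthProfile(region, np.cumsum(delta[:-1]))


# ---------------------------------------------------------------------------
# Paired-depth KDE quantiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedDepthPoint:
    """Depth of the same position in both modalities, with the variant
    status it carries and (after analysis) its density quantile."""

    position: int
    depth_a: int
    depth_b: int
    carries_variant: str = "none"  # none | unique_a | unique_b | concordant
    quantile: Optional[float] = None

    def __post_init__(self) -> None:
        if self.depth_a < 0 or self.depth_b < 0:
            raise ValueError("depths must be non-negative")


DEFAULT_LEVELS = (0.25, 0.5, 0.75, 0.95)


def paired_depth_quantiles(
    points: Sequence[PairedDepthPoint],
    levels: Sequence[float] = DEFAULT_LEVELS,
    seed: int = 0,
    n_mc: int = 4000,
) -> List[PairedDepthPoint]:
    """Assign each point the innermost KDE level set containing it.

    A Gaussian product kernel with Scott's-rule bandwidth is fitted over
    (depth_a, depth_b). For each probability level p the density
    threshold enclosing mass p is estimated by Monte Carlo sampling from
    the fitted density (``n_mc`` draws, seeded); a point whose density
    exceeds the level-p threshold lies inside that contour. The
    assigned ``quantile`` is the smallest such p (None outside the
    largest level).
    """
    if len(points) < 10:
        raise EnrichmentError("paired-depth analysis needs at least 10 points")
    levels = list(levels)
    if not levels or any(not (0 < l < 1) for l in levels) or levels != sorted(levels):
        raise EnrichmentError("levels must be strictly increasing probabilities in (0,1)")
    xy = np.array([(p.depth_a, p.depth_b) for p in points], dtype=float).T
    try:
        kde = stats.gaussian_kde(xy)
    except np.linalg.LinAlgError:
        warnings.warn(
            "degenerate paired-depth cloud (singular covariance); all points "
            "assigned the innermost quantile"
        )
        return [replace(p, quantile=levels[0]) for p in points]
    rng = np.random.default_rng(seed)
    samples = kde.resample(n_mc, seed=rng)
    sample_density = kde(samples)
    thresholds = {p: float(np.quantile(sample_density, 1.0 - p)) for p in levels}
    point_density = kde(xy)
    out = []
    for p, dens in zip(points, point_density):
        label = None
        for level in levels:  # ascending: innermost first
            if dens >= thresholds[level]:
                label = level
                break
        out.append(replace(p, quantile=label))
    return out


# ---------------------------------------------------------------------------
# Attribution of modality-unique variants to coverage
# ---------------------------------------------------------------------------


def attribute_unique_variants(
    comparison: CallsetComparison,
    depth_a: DepthProfile,
    depth_b: DepthProfile,
    low_cov_threshold: int = 15,
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], int]]:
    """Annotate every modality-unique record with whether the *other*
    modality was under-covered at its position.

    Returns a per-record table and summary counts keyed by
    (variant class, attribution), where attribution is
    ``low_coverage_other`` (other-modality depth < threshold) or
    ``covered_other``.
    """
    rows = []
    counts: Dict[Tuple[str, str], int] = {}
    for side, other_profile in (("a", depth_b), ("b", depth_a)):
        for rec in comparison.unique_records(side):
            try:
                other_depth = other_profile.depth_at(rec.chrom, rec.pos - 1)
            except KeyError as exc:
                raise EnrichmentError(
                    f"unique variant at {rec.chrom}:{rec.pos} lies outside the "
                    f"other modality's depth profile"
                ) from exc
            attribution = (
                "low_coverage_other"
                if other_depth < low_cov_threshold
                else "covered_other"
            )
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref_allele,
                    "alt": rec.alt_allele,
                    "variant_class": rec.variant_class,
                    "unique_to": side,
                    "other_depth": other_depth,
                    "attribution": attribution,
                }
            )
            key = (rec.variant_class, attribution)
            counts[key] = counts.get(key, 0) + 1
    return pd.DataFrame(rows), counts
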