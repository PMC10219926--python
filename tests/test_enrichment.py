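"""Enrichment statistics, N50, depth profiles, KDE quantiles and
unique-variant attribution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_record
from haplotk.context_match import CallsetComparison
from haplotk.enrichment import (
    EnrichmentError,
    PairedDepthPoint,
    attribute_unique_variants,
    depth_profile,
    fold_enrichment,
    n50,
    paired_depth_quantiles,
)
from haplotk.genomic import DepthProfile, ReadSummary, Region


def brute_force_n50(lengths):
    """Independent oracle: check every candidate length directly."""
    total = sum(lengths)
    best = 0
    for cand in sorted(set(lengths)):
        if sum(x for x in lengths if x >= cand) * 2 >= total:
            best = max(best, cand)
    return best


class TestN50:
    @pytest.mark.parametrize(
        "lengths,expected",
        [
            ([7], 7),
            ([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], 7),  # cumsum from the top reaches 27.5 at 7
            ([5, 5, 5, 5], 5),
        ],
    )
    def test_known_values(self, lengths, expected):
        assert n50(lengths) == expected
        assert brute_force_n50(lengths) == expected

    def test_empty_rejected(self):
        with pytest.raises(EnrichmentError):
            n50([])

    def test_agrees_with_bruteforce_on_random_lists(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            lengths = rng.integers(1, 10_000, size=int(rng.integers(1, 40))).tolist()
            assert n50(lengths) == brute_force_n50(lengths)

    @given(st.lists(st.integers(1, 10**6), min_size=1, max_size=50),
           st.integers(2, 9))
    @settings(derandomize=True, max_examples=100)
    def test_bounded_and_scale_equivariant(self, lengths, k):
        v = n50(lengths)
        assert min(lengths) <= v <= max(lengths)
        assert n50([k * x for x in lengths]) == k * v


def _read(rid, start, end, channel, arm, mapq=60):
    return ReadSummary(rid, end - start, Region("c", start, end), mapq, channel, arm=arm)


class TestFoldEnrichment:
    target = Region("c", 1000, 2000)

    def test_identical_arms_fold_one(self):
        reads = [
            _read(f"a{i}", 1000 + i, 1500 + i, i + 1, "adaptive") for i in range(4)
        ] + [_read(f"c{i}", 1000 + i, 1500 + i, 300 + i, "control") for i in range(4)]
        res = fold_enrichment(reads, self.target)
        assert res.fold == pytest.approx(1.0)

    def test_hand_computed_twelve_fold(self):
        # 1,200,000 on-target bases over 256 adaptive channels vs
        # 100,000 over 256 control channels
        res = fold_enrichment(
            [_read("a", 0, 1, 1, "adaptive"), _read("c", 0, 1, 257, "control")],
            Region("c", 0, 10),
            channels={"adaptive": 256, "control": 256},
        )
        # substitute the counted signal directly: the invariant is the ratio
        from haplotk.enrichment import EnrichmentResult

        hand = EnrichmentResult(
            (1_200_000 / 256) / (100_000 / 256), 1_200_000, 100_000, 256, 256, "base"
        )
        assert hand.fold == pytest.approx(12.0)
        assert hand.per_channel_adaptive / hand.per_channel_control == pytest.approx(12.0)
        assert res.mode == "base"

    def test_swapping_arms_inverts_fold(self):
        reads = [
            _read("a1", 1000, 1800, 1, "adaptive"),
            _read("a2", 1200, 1900, 2, "adaptive"),
            _read("c1", 1000, 1400, 300, "control"),
        ]
        fwd = fold_enrichment(reads, self.target, channels={"adaptive": 2, "control": 2})
        swapped = [
            ReadSummary(r.read_id, r.length, r.mapped_region, r.mapq, r.channel,
                        arm="control" if r.arm == "adaptive" else "adaptive")
            for r in reads
        ]
        rev = fold_enrichment(swapped, self.target, channels={"adaptive": 2, "control": 2})
        assert rev.fold == pytest.approx(1.0 / fwd.fold)

    def test_duplicating_both_arms_invariant(self):
        reads = [
            _read("a1", 1000, 1800, 1, "adaptive"),
            _read("c1", 1100, 1500, 300, "control"),
        ]
        once = fold_enrichment(reads, self.target, channels={"adaptive": 1, "control": 1})
        twice = fold_enrichment(reads * 2, self.target, channels={"adaptive": 1, "control": 1})
        assert twice.fold == pytest.approx(once.fold)

    def test_missing_control_arm_usage_error(self):
        with pytest.raises(EnrichmentError, match="control"):
            fold_enrichment([_read("a", 0, 10, 1, "adaptive")], self.target)

    def test_zero_control_signal_infinite_with_warning(self):
        reads = [
            _read("a", 1000, 1500, 1, "adaptive"),
            _read("c", 0, 10, 300, "control"),
        ]
        with pytest.warns(UserWarning):
            res = fold_enrichment(reads, self.target)
        assert res.fold == float("inf")


class TestDepthProfile:
    region = Region("c", 0, 30)

    def test_single_spanning_read(self):
        profile = depth_profile([_read("r", 0, 30, 1, "adaptive")], self.region)
        assert (profile.depth == 1).all()
        assert profile.mean_depth == 1.0

    def test_no_reads_all_zero(self):
        profile = depth_profile([], self.region)
        assert (profile.depth == 0).all()
        assert profile.fraction_at_least(1) == 0.0

    def test_half_overlapping_reads_stack(self):
        reads = [_read("r1", 0, 20, 1, "adaptive"), _read("r2", 10, 30, 2, "adaptive")]
        profile = depth_profile(reads, self.region)
        assert list(profile.depth[:10]) == [1] * 10
        assert list(profile.depth[10:20]) == [2] * 10
        assert list(profile.depth[20:]) == [1] * 10

    def test_total_depth_equals_total_overlap(self):
        rng = np.random.default_rng(3)
        reads = []
        for i in range(50):
            s = int(rng.integers(-10, 25))
            e = s + int(rng.integers(1, 20))
            reads.append(_read(f"r{i}", max(s, 0), max(e, 1), 1, "adaptive"))
        profile = depth_profile(reads, self.region)
        expected = sum(
            max(0, min(r.mapped_region.end, 30) - max(r.mapped_region.start, 0))
            for r in reads
        )
        assert int(profile.depth.sum()) == expected


class TestPairedDepthQuantiles:
    def _cloud(self, n=2000, seed=5):
        rng = np.random.default_rng(seed)
        xy = rng.multivariate_normal([34, 31], [[25, 5], [5, 36]], size=n)
        return [
            PairedDepthPoint(i, max(0, int(a)), max(0, int(b)))
            for i, (a, b) in enumerate(xy)
        ]

    def test_half_mass_contour_calibrated(self):
        points = self._cloud()
        out = paired_depth_quantiles(points, levels=[0.5], seed=11)
        frac = sum(p.quantile is not None for p in out) / len(out)
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_centroid_innermost_outlier_outside(self):
        points = self._cloud(500) + [
            PairedDepthPoint(99998, 34, 31),
            PairedDepthPoint(99999, 400, 400),
        ]
        out = paired_depth_quantiles(points, seed=12)
        assert out[-2].quantile == 0.25
        assert out[-1].quantile is None

    def test_degenerate_cloud_warns_innermost(self):
        points = [PairedDepthPoint(i, 10, 10) for i in range(12)]
        with pytest.warns(UserWarning):
            out = paired_depth_quantiles(points, levels=[0.5], seed=13)
        assert all(p.quantile == 0.5 for p in out)

    def test_too_few_points_rejected(self):
        with pytest.raises(EnrichmentError):
            paired_depth_quantiles([PairedDepthPoint(0, 1, 1)] * 5)

    def test_bad_levels_rejected(self):
        with pytest.raises(EnrichmentError):
            paired_depth_quantiles(self._cloud(50), levels=[0.9, 0.5])


class TestAttribution:
    def _comparison(self):
        records_a = [
            make_record(100, "A", "G", chrom="c"),
            make_record(300, "AT", "A", chrom="c"),
        ]
        records_b = [make_record(500, "A", "G", chrom="c")]
        return CallsetComparison(
            records_a, records_b, ["unique_a", "unique_a"], ["unique_b"], []
        )

    def test_low_coverage_vs_covered(self):
        region = Region("c", 0, 1000)
        depth_a = DepthProfile(region, np.full(1000, 40))
        depth_b_vec = np.full(1000, 40)
        depth_b_vec[50:200] = 0  # dead zone over the first unique call
        depth_b = DepthProfile(region, depth_b_vec)
        table, counts = attribute_unique_variants(self._comparison(), depth_a, depth_b)
        assert counts[("snv", "low_coverage_other")] == 1
        assert counts[("indel", "covered_other")] == 1
        assert counts[("snv", "covered_other")] == 1  # the unique_b vs depth_a
        assert set(table["attribution"]) == {"low_coverage_other", "covered_other"}

    def test_position_outside_profile_rejected(self):
        region = Region("c", 0, 200)
        dp = DepthProfile(region, np.zeros(200))
        with pytest.raises(EnrichmentError, match="c:300"):
            attribute_unique_variants(self._comparison(), dp, dp)
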