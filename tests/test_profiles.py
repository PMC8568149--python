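"""Probability transforms, relative scaling, binning, smoothing, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from methtrace import MethylationRecord, build_store
from methtrace.features import Feature, FeatureSet
from methtrace.profiles import (
    aggregate_features,
    binned_means,
    per_site_means,
    region_summary,
    relative_position,
    sigmoid,
    smooth_curve,
)
from methtrace.synth import MethylationLandscape, RegionEffect, simulate_records


def rec(sample="s1", chrom="chr1", pos=100, stat=1.0, read="r1"):
    return MethylationRecord(sample, chrom, pos, stat, read)


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert sigmoid(0.0) == 0.5

    def test_known_value(self):
        assert sigmoid(2.0) == pytest.approx(0.8807970779778823, abs=1e-12)

    @given(st.floats(-30, 30, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, s):
        assert sigmoid(s) + sigmoid(-s) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(1e-6, 1 - 1e-6))
    @settings(max_examples=100, deadline=None)
    def test_inverts_logit(self, p):
        assert sigmoid(logit(p)) == pytest.approx(p, abs=1e-12)


class TestPerSiteMeans:
    def test_opposite_confident_calls_average_to_half(self):
        # two reads at one site called 0.99 and 0.01 -> smoothed value 0.5
        records = [
            rec(stat=float(logit(0.99)), read="r1"),
            rec(stat=float(logit(0.01)), read="r2"),
        ]
        out = per_site_means(records)
        assert out["mean_probability"].iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_single_read_mean_is_its_probability(self):
        out = per_site_means([rec(stat=1.7)])
        assert out["mean_probability"].iloc[0] == pytest.approx(sigmoid(1.7))

    def test_identical_probabilities_are_reproduced(self):
        records = [rec(stat=0.8, read=f"r{i}") for i in range(7)]
        out = per_site_means(records)
        assert out["mean_probability"].iloc[0] == pytest.approx(sigmoid(0.8))
        assert out["n_reads"].iloc[0] == 7

    def test_group_mapping_pools_samples(self):
        records = [rec(sample="s1", stat=4.0), rec(sample="s2", stat=-4.0, read="r2")]
        out = per_site_means(records, group_by="group", groups={"s1": "g", "s2": "g"})
        assert len(out) == 1
        assert out["mean_probability"].iloc[0] == pytest.approx(0.5, abs=1e-12)


class TestRelativePosition:
    feature = Feature("chr1", 1001, 3000, "+", "F")

    def test_endpoints(self):
        assert relative_position(self.feature, 1001, flank=2000) == 0.0
        assert relative_position(self.feature, 3000, flank=2000) == 1.0

    def test_body_midpoint_is_half_regardless_of_length(self):
        for length in (10, 999, 123456):
            f = Feature("chr1", 1000, 1000 + length, "+", "F")
            mid = 1000 + length / 2
            assert relative_position(f, mid, flank=500) == pytest.approx(0.5)

    def test_upstream_flank_scaling(self):
        # 500 bp upstream with a 2000 bp flank: -f * 500/2000
        f = 1.0 / 3.0
        got = relative_position(self.feature, 1001 - 500, flank=2000, flank_fraction=f)
        assert got == pytest.approx(-f * 500 / 2000)

    def test_downstream_flank_scaling(self):
        f = 1.0 / 3.0
        got = relative_position(self.feature, 3000 + 1000, flank=2000, flank_fraction=f)
        assert got == pytest.approx(1 + f * 1000 / 2000)

    def test_minus_strand_is_mirrored(self):
        minus = Feature("chr1", 1001, 3000, "-", "F")
        assert relative_position(minus, 3000, flank=100) == 0.0  # 5' end
        assert relative_position(minus, 1001, flank=100) == 1.0

    def test_outside_window_raises(self):
        with pytest.raises(ValueError, match="outside"):
            relative_position(self.feature, 100, flank=100)

    def test_strictly_monotone_plus_and_reversed_minus(self):
        positions = np.arange(1001 - 2000, 3000 + 2001, 97)
        plus = relative_position(self.feature, positions, flank=2000)
        assert np.all(np.diff(plus) > 0)
        minus_f = Feature("chr1", 1001, 3000, "-", "F")
        minus = relative_position(minus_f, positions, flank=2000)
        assert np.all(np.diff(minus) < 0)


class TestBinnedMeans:
    def test_hand_tally_two_bins(self):
        out = binned_means([0.1, 0.2, 0.9], [0.2, 0.4, 0.8], 2, domain=(0, 1))
        assert list(out["mean"]) == [pytest.approx(0.3), pytest.approx(0.8)]

    def test_constant_input_gives_constant_bins(self, rng):
        x = rng.uniform(-0.3, 1.3, 200)
        out = binned_means(x, np.full(200, 0.42), 25, domain=(-1 / 3, 4 / 3))
        assert np.allclose(out["mean"], 0.42)

    def test_single_bin_is_global_mean(self):
        y = [0.1, 0.5, 0.9]
        out = binned_means([0.0, 0.5, 1.0], y, 1, domain=(0, 1))
        assert len(out) == 1
        assert out["mean"].iloc[0] == pytest.approx(np.mean(y))

    def test_empty_bins_emit_no_row(self):
        out = binned_means([0.05, 0.95], [0.2, 0.8], 10, domain=(0, 1))
        assert list(out["bin"]) == [0, 9]

    def test_domain_endpoint_falls_in_last_bin(self):
        out = binned_means([1.0], [0.7], 4, domain=(0, 1))
        assert list(out["bin"]) == [3]

    def test_binned_then_global_mean_matches_when_bins_equally_populated(self):
        # 3 bins x 2 points each: mean of bin means == global mean
        x = [0.1, 0.2, 0.4, 0.5, 0.7, 0.8]
        y = [0.1, 0.3, 0.2, 0.6, 0.9, 0.5]
        out = binned_means(x, y, 3, domain=(0, 0.9))
        assert out["mean"].mean() == pytest.approx(np.mean(y))
        # and differs when bins are unevenly populated (2, 1, 2, 1 points)
        out2 = binned_means(x, y, 4, domain=(0, 1))
        assert abs(out2["mean"].mean() - np.mean(y)) > 1e-3


class TestSmoothCurve:
    def test_constant_input_reproduced_exactly(self):
        x = np.arange(20.0)
        curve = smooth_curve(x, np.full(20, 0.37), span=0.5)
        assert curve.smoothed
        assert np.allclose(curve.y, 0.37, atol=1e-12)

    def test_full_span_on_linear_data_matches_least_squares(self):
        x = np.linspace(0, 1, 40)
        y = 0.2 + 0.6 * x
        curve = smooth_curve(x, y, span=1.0)
        slope, intercept = np.polyfit(x, y, 1)
        assert np.max(np.abs(curve.y - (intercept + slope * curve.x))) < 1e-6

    def test_fewer_than_five_points_pass_through_flagged(self):
        curve = smooth_curve([1, 2, 3], [0.1, 0.9, 0.2], span=0.5)
        assert not curve.smoothed
        assert np.allclose(curve.y, [0.1, 0.9, 0.2])

    def test_output_clamped_to_unit_interval(self, rng):
        x = np.linspace(0, 1, 50)
        y = np.clip(1.2 * x, 0, 1)  # near-1 plateau invites overshoot
        curve = smooth_curve(x, y, span=0.3)
        assert curve.y.min() >= 0.0 and curve.y.max() <= 1.0


class TestAggregateFeatures:
    @staticmethod
    def build(tmp_path, rows, name="agg.tsv.bgz", samples=None):
        recs = [
            MethylationRecord(s, c, p, stat, r) for (s, c, p, stat, r) in rows
        ]
        return build_store(recs, tmp_path / name, samples=samples)

    def test_single_feature_equals_its_binned_means(self, tmp_path):
        rows = [("s1", "chr1", p, 2.0, f"r{p}") for p in range(1000, 2001, 100)]
        store = self.build(tmp_path, rows)
        feats = FeatureSet([Feature("chr1", 1000, 2000, "+", "F1")])
        curves = aggregate_features(store, feats, flank=500, n_bins=10)
        assert len(curves) == 1
        means = per_site_means(store.query_region("chr1", 500, 2500))
        rel = relative_position(feats[0], means["position"].to_numpy(), 500)
        expected = binned_means(
            rel, means["mean_probability"], 10, domain=(-1 / 3, 4 / 3)
        )
        assert np.allclose(curves[0].y, expected["mean"])

    def test_duplicating_reads_of_one_feature_leaves_aggregate_unchanged(self, tmp_path):
        # two features, identical profiles, wildly different coverage
        base = [("s1", "chr1", p, 3.0, f"a{p}") for p in range(1000, 2001, 50)]
        other = [("s1", "chr1", p + 10_000, 3.0, f"b{p}{i}")
                 for p in range(1000, 2001, 50) for i in range(20)]
        feats = FeatureSet(
            [
                Feature("chr1", 1000, 2000, "+", "F1"),
                Feature("chr1", 11_000, 12_000, "+", "F2"),
            ]
        )
        s1 = self.build(tmp_path, base + other, "agg1.tsv.bgz")
        s2 = self.build(tmp_path, base + other + other_dup(other), "agg2.tsv.bgz")
        c1 = aggregate_features(s1, feats, flank=500, n_bins=20, group_by="sample")
        c2 = aggregate_features(s2, feats, flank=500, n_bins=20, group_by="sample")
        assert np.max(np.abs(c1[0].y - c2[0].y)) < 1e-12

    def test_equal_weight_differs_from_read_weighted_mean(self, tmp_path):
        # F1 low methylation / low coverage, F2 high methylation / high coverage
        low = [("s1", "chr1", p, -3.0, f"a{p}") for p in range(1000, 2001, 100)]
        high = [("s1", "chr1", p + 10_000, 3.0, f"b{p}{i}")
                for p in range(1000, 2001, 100) for i in range(30)]
        store = self.build(tmp_path, low + high)
        feats = FeatureSet(
            [
                Feature("chr1", 1000, 2000, "+", "F1"),
                Feature("chr1", 11_000, 12_000, "+", "F2"),
            ]
        )
        curves = aggregate_features(store, feats, flank=0 + 100, n_bins=1, group_by="sample")
        equal_weight = curves[0].y[0]
        p_low, p_high = sigmoid(-3.0), sigmoid(3.0)
        assert equal_weight == pytest.approx((p_low + p_high) / 2, abs=1e-9)
        read_weighted = (11 * p_low + 11 * 30 * p_high) / (11 + 11 * 30)
        assert abs(equal_weight - read_weighted) > 0.1

    def test_feature_missing_a_bin_does_not_contribute_there(self, tmp_path):
        rows = [("s1", "chr1", 1500, 4.0, "a1"),            # F1: body only
                ("s1", "chr1", 11_000, -4.0, "b1"),          # F2: body start
                ("s1", "chr1", 12_000, -4.0, "b2")]          # F2: body end
        store = self.build(tmp_path, rows)
        feats = FeatureSet(
            [
                Feature("chr1", 1000, 2000, "+", "F1"),
                Feature("chr1", 11_000, 12_000, "+", "F2"),
            ]
        )
        curves = aggregate_features(store, feats, flank=100, n_bins=3, group_by="sample")
        # middle bin: mean of F1's ~1 and nothing from F2's edge bins
        y = dict(zip(np.round(curves[0].x, 3), curves[0].y))
        assert curves[0].y.max() > 0.9  # F1-only bin stays near 1

    def test_no_overlapping_data_raises(self, tmp_path):
        store = self.build(tmp_path, [("s1", "chr1", 100, 1.0, "r")])
        feats = FeatureSet([Feature("chr2", 1000, 2000, "+", "F")])
        with pytest.raises(ValueError, match="overlap"):
            aggregate_features(store, feats)


def other_dup(rows):
    return [(s, c, p, stat, r + "_dup") for (s, c, p, stat, r) in rows]


class TestRegionSummary:
    def test_universal_class_covers_all_sites(self, small_store):
        regions = FeatureSet(
            [
                Feature("chr1", 1, 20_000, "+", "all1", "everything"),
                Feature("chr2", 1, 12_000, "+", "all2", "everything"),
            ]
        )
        out = region_summary(small_store, regions, group_by="sample")
        all_means = per_site_means(small_store.to_frame(), group_by="sample")
        assert len(out) == len(all_means)

    def test_uncovered_sites_only_in_complement_class(self, tmp_path):
        rows = [("s1", "chr1", 100, 2.0, "r1"), ("s1", "chr1", 900, 2.0, "r2")]
        store = TestAggregateFeatures.build(tmp_path, rows, "rs.tsv.bgz")
        regions = FeatureSet([Feature("chr1", 50, 150, "+", "prom1", "promoter")])
        out = region_summary(
            store, regions, group_by="sample", complement_label="non-promoter"
        )
        by_class = out.groupby("region_class")["position"].apply(list).to_dict()
        assert by_class == {"promoter": [100], "non-promoter": [900]}

    def test_two_class_synthetic_medians_recover_simulated_levels(self, tmp_path):
        landscape = MethylationLandscape(
            chrom_lengths={"chr1": 30_000},
            background_mu=0.85,
            regions=[RegionEffect("chr1", 10_001, 20_000, 0.15)],
            coverage=60,
            read_length_median=1500,
            site_seed=3,
            grouped_fraction=0.0,
        )
        recs = list(simulate_records(landscape, "s1", "A", 77))
        store = build_store(recs, tmp_path / "twoclass.tsv.bgz")
        regions = FeatureSet(
            [
                Feature("chr1", 1, 10_000, "+", "hi1", "high"),
                Feature("chr1", 20_001, 30_000, "+", "hi2", "high"),
                Feature("chr1", 10_001, 20_000, "+", "lo", "low"),
            ]
        )
        out = region_summary(store, regions, group_by="sample")
        medians = out.groupby("region_class")["mean_probability"].median()
        # expected per-site mean under the LLR mixture: mu*E[s(+)]+(1-mu)*E[s(-)]
        from scipy.stats import norm

        z = np.linspace(-8, 8, 4001)
        m, s = landscape.llr_mean, landscape.llr_sd
        e_pos = np.trapezoid(sigmoid(m + s * z) * norm.pdf(z), z)
        for cls, mu in (("high", 0.85), ("low", 0.15)):
            expected = mu * e_pos + (1 - mu) * (1 - e_pos)
            assert medians[cls] == pytest.approx(expected, abs=0.05)
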