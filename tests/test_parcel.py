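"""Extreme-voxel extraction, representation splitting, extremeness, smoothing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conngrad.parcel import (
    DEFAULT_SWEEP_PCTS,
    RepresentationMap,
    VoxelGrid,
    extract_extremes,
    extremeness,
    gradient_parcellation,
    less_extreme_test,
    overlap_table,
    position_summary,
    smooth_map,
    split_by_representation,
    sweep_extremes,
)
from conngrad.exceptions import EmptyRegionError, InvalidParameterError


class TestExtractExtremes:
    def test_exact_top_five_of_hundred(self):
        values = np.arange(1, 101, dtype=float)
        mask = extract_extremes(values, np.ones(100, bool), 5, "high")
        assert set(values[mask]) == {96, 97, 98, 99, 100}

    def test_ceil_rounding_on_small_region(self):
        values = np.arange(7, dtype=float)
        mask = extract_extremes(values, np.ones(7, bool), 5, "high")
        assert mask.sum() == 1  # ceil(0.35)

    def test_ties_broken_by_lower_voxel_id(self):
        # ties straddle the cutoff: brute-force sort with the stated tie rule
        values = np.array([3.0, 5.0, 5.0, 5.0, 1.0, 5.0, 0.0, 2.0])
        region = np.ones(8, bool)
        mask = extract_extremes(values, region, 25, "high")  # ceil(2)
        order = sorted(range(8), key=lambda i: (-values[i], i))
        expected = set(order[:2])
        assert set(np.flatnonzero(mask)) == expected == {1, 2}

    def test_low_direction(self):
        values = np.array([5.0, -2.0, 7.0, -2.0, 0.0])
        mask = extract_extremes(values, np.ones(5, bool), 40, "low")
        assert set(np.flatnonzero(mask)) == {1, 3}

    def test_empty_region_rejected(self):
        with pytest.raises(EmptyRegionError):
            extract_extremes(np.arange(5.0), np.zeros(5, bool), 5, "high")

    @given(st.integers(0, 2**31 - 1), st.floats(0.5, 100.0))
    @settings(max_examples=40, deadline=None)
    def test_count_law(self, seed, pct):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60)
        values = rng.standard_normal(n)
        region = rng.random(n) < 0.7
        if not region.any():
            region[0] = True
        mask = extract_extremes(values, region, pct, "high")
        assert mask.sum() == math.ceil(pct / 100 * region.sum())
        assert not (mask & ~region).any()


class TestSweepExtremes:
    def test_nesting_and_saturation(self):
        rng = np.random.default_rng(0)
        values = rng.standard_normal(200)
        masks = {"r": np.ones(200, bool)}
        out = sweep_extremes(values, masks, [5, 10, 100], "high")
        assert not (out[5.0]["r"] & ~out[10.0]["r"]).any()  # 5% subset of 10%
        assert out[100.0]["r"].all()

    def test_default_grid_counts_match_ceil_formula(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal(500)
        masks = {"a": rng.random(500) < 0.4, "b": rng.random(500) < 0.3}
        out = sweep_extremes(values, masks, DEFAULT_SWEEP_PCTS, "low")
        for pct, per_region in out.items():
            for name, mask in per_region.items():
                assert mask.sum() == math.ceil(pct / 100 * masks[name].sum())


class TestSplitByRepresentation:
    def _rep(self):
        labels = np.array(["M1"] * 3 + ["M2"] * 2 + ["N1"] * 4 + ["N2"] * 3 + ["N3"] * 2 + ["none"])
        return RepresentationMap(labels, np.arange(len(labels)))

    def test_full_cover_returns_representation_sizes(self):
        rep = self._rep()
        out = split_by_representation(np.ones(15, bool), rep, "triple")
        assert {k: int(v.sum()) for k, v in out.items()} == {"N1": 4, "N2": 3, "N3": 2}

    def test_merged_grouping_reports_empty_intersection(self):
        rep = self._rep()
        mask = rep.mask("N3")
        out = split_by_representation(mask, rep, "merged-N1N2")
        assert out["N1N2"].sum() == 0  # reported, not dropped
        np.testing.assert_array_equal(out["N3"], mask)

    def test_map_absent_from_third_representation(self):
        # a working-memory-like map confined to N1/N2 leaves N3 empty
        rep = self._rep()
        mask = rep.mask("N1") | rep.mask("N2")
        out = split_by_representation(mask, rep, "triple")
        assert out["N3"].sum() == 0
        assert out["N1"].sum() == 4

    def test_motor_pair(self):
        rep = self._rep()
        out = split_by_representation(np.ones(15, bool), rep, "motor-pair")
        assert {k: int(v.sum()) for k, v in out.items()} == {"M1": 3, "M2": 2}

    def test_unknown_grouping_rejected(self):
        with pytest.raises(InvalidParameterError):
            split_by_representation(np.ones(15, bool), self._rep(), "quadruple")


class TestExtremeness:
    def test_values_at_center_score_zero(self):
        v = np.full(10, 2.5)
        assert extremeness(v, np.ones(10, bool), center=2.5) == 0.0

    def test_symmetric_pair(self):
        v = np.array([-2.0, 2.0])
        assert extremeness(v, np.ones(2, bool), center=0.0) == 2.0

    def test_matches_brute_force_median_of_deviations(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(300)
        mask = rng.random(300) < 0.4
        c = float(np.median(v))
        expected = float(np.median(sorted(abs(x - c) for x in v[mask])))
        assert extremeness(v, mask) == pytest.approx(expected, abs=1e-15)


class TestLessExtremeTest:
    def test_identical_distributions_not_distinguished(self):
        v = np.concatenate([np.linspace(-1, 1, 50)] * 2)
        mask_a = np.zeros(100, bool)
        mask_a[:50] = True
        res = less_extreme_test(v, mask_a, ~mask_a, n_boot=500, seed=0)
        assert res.verdict == "not distinguished"
        assert res.difference == 0.0

    def test_inner_group_declared_less_extreme(self):
        rng = np.random.default_rng(3)
        v = np.concatenate([rng.uniform(-0.2, 0.2, 80), rng.uniform(0.8, 1.2, 80)])
        mask_a = np.zeros(160, bool)
        mask_a[:80] = True
        res = less_extreme_test(v, mask_a, ~mask_a, center=0.0, n_boot=500, seed=1)
        assert res.verdict == "A less extreme than B"
        assert res.ci_low <= res.difference <= res.ci_high

    def test_swap_negates_difference_exactly(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(120)
        a = np.zeros(120, bool)
        a[:40] = True
        b = np.zeros(120, bool)
        b[60:] = True
        r1 = less_extreme_test(v, a, b, n_boot=200, seed=2)
        r2 = less_extreme_test(v, b, a, n_boot=200, seed=2)
        assert r1.difference == -r2.difference

    def test_verdict_invariant_to_increasing_affine_rescale(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([rng.uniform(-0.1, 0.1, 60), rng.uniform(0.9, 1.1, 60)])
        a = np.zeros(120, bool)
        a[:60] = True
        r1 = less_extreme_test(v, a, ~a, n_boot=400, seed=3)
        r2 = less_extreme_test(3.7 * v - 11.0, a, ~a, n_boot=400, seed=3)
        assert r1.verdict == r2.verdict

    def test_single_voxel_flagged_unreliable(self):
        v = np.arange(10, dtype=float)
        a = np.zeros(10, bool)
        a[4] = True
        res = less_extreme_test(v, a, ~a, n_boot=200, seed=0)
        assert res.unreliable


class TestOverlapAndSummary:
    def _gradients(self, scene):
        from tests.conftest import latent_reference

        return latent_reference(scene)

    def test_no_labels_empty_table(self, default_scene):
        g = self._gradients(default_scene)
        table = overlap_table(g, {})
        assert len(table) == 0

    def test_full_cover_row_count(self, default_scene):
        g = self._gradients(default_scene)
        table = overlap_table(g, {"all": np.ones(g.n_voxels, bool)})
        assert len(table) == g.n_voxels

    def test_zone_ordering_along_gradient_one(self, default_scene):
        scene = default_scene
        g = self._gradients(scene)
        table = overlap_table(g, scene.latent.zone_label)
        means = table.groupby("label")["gradient_1"].mean()
        assert (
            means["motor"]
            < means["task-focused-nonmotor"]
            < means["task-unfocused-nonmotor"]
        )

    def test_position_summary_intervals_contain_estimates(self, default_scene):
        scene = default_scene
        g = self._gradients(scene)
        rep = scene.representation_map
        out = position_summary(
            g, {m: rep.mask(m) for m in ("M1", "M2", "N3")}, n_boot=300, seed=0
        )
        assert (out["n"] > 0).all()
        for comp in (1, 2):
            assert (out[f"g{comp}_ci_low"] <= out[f"g{comp}_extremeness"]).all()
            assert (out[f"g{comp}_ci_high"] >= out[f"g{comp}_extremeness"]).all()


class TestGradientParcellation:
    def test_mask_sizes_follow_ceil_law_per_representation(self, default_scene, scene_gradients):
        rep = default_scene.representation_map
        parc = gradient_parcellation(scene_gradients, rep, 5.0)
        for name, labels in (("high_g1", ("N1", "N2", "N3")), ("low_g1", ("M1", "M2"))):
            for label in labels:
                sub = parc.per_representation[name][label]
                assert sub.sum() == math.ceil(0.05 * rep.mask(label).sum())

    def test_masks_exclude_unlabeled_voxels(self, default_scene, scene_gradients):
        rep = default_scene.representation_map
        parc = gradient_parcellation(scene_gradients, rep, 5.0)
        none_mask = rep.mask("none")
        for name in ("high_g1", "high_g2", "low_g1"):
            assert not (getattr(parc, name) & none_mask).any()


class TestSmoothMap:
    def test_constant_map_unchanged(self):
        mask = np.zeros((8, 9), bool)
        mask[1:7, 2:8] = True
        grid = VoxelGrid(mask)
        v = np.full(grid.n_voxels, 3.3)
        np.testing.assert_allclose(smooth_map(v, grid, sigma=1.5), v, atol=1e-12)

    def test_delta_matches_direct_kernel_evaluation(self):
        mask = np.ones((21, 21), bool)
        grid = VoxelGrid(mask)
        v = np.zeros(grid.n_voxels)
        center = 10 * 21 + 10
        v[center] = 1.0
        sigma = 2.0
        out = smooth_map(v, grid, sigma)
        # direct truncated-Gaussian oracle with the same discrete kernel
        radius = int(4.0 * sigma + 0.5)
        yy, xx = np.mgrid[0:21, 0:21]
        d2 = (yy - 10) ** 2 + (xx - 10) ** 2
        cheb = np.maximum(np.abs(yy - 10), np.abs(xx - 10))
        k = np.where(cheb <= radius, np.exp(-d2 / (2 * sigma**2)), 0.0)
        # the mask renormalizer cancels in ratios wherever the truncated kernel
        # support lies fully inside the grid (positions >= radius from borders)
        ratio = out.reshape(21, 21) / out.reshape(21, 21)[10, 10]
        expected = k / k[10, 10]
        inner = cheb <= 10 - radius
        assert inner.sum() >= 9
        np.testing.assert_allclose(ratio[inner], expected[inner], atol=1e-10)

    def test_boundary_stays_convex_combination_of_in_mask_values(self):
        mask = np.zeros((10, 10), bool)
        mask[:, :5] = True
        grid = VoxelGrid(mask)
        rng = np.random.default_rng(6)
        v = rng.uniform(5.0, 9.0, grid.n_voxels)
        out = smooth_map(v, grid, sigma=2.0)
        assert out.min() >= v.min() - 1e-12
        assert out.max() <= v.max() + 1e-12

    def test_missing_geometry_rejected(self):
        with pytest.raises(InvalidParameterError):
            smooth_map(np.ones(4), None, 1.0)

    def test_nonpositive_sigma_rejected(self):
        grid = VoxelGrid(np.ones((3, 3), bool))
        with pytest.raises(InvalidParameterError):
            smooth_map(np.ones(9), grid, 0.0)
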