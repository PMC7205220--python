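"""Distance maps, nodal projection, depth profiles and box statistics."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from nodalmorph import (
    FlatSurface,
    SectionPhantomSpec,
    SineSurface,
    SurfaceCurve,
    align_series,
    compute_distance_map,
    depth_profile,
    make_heart_series,
    make_section,
    measure_section_depth,
    nodal_projection,
    section_depth_stats,
)
from conftest import brute_force_edt


def _flat_curve(n_samples, spacing_um, y_um=0.0):
    x = np.arange(n_samples) * spacing_um
    return SurfaceCurve(
        sample_points_um=np.stack([x, np.full_like(x, y_um)], 1),
        arc_length_um=x.copy(),
        smoothing_param=0.0,
        residual_rms_um=0.0,
    )


class TestDistanceMap:
    def test_single_source_345(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 0] = True
        dmap = compute_distance_map(mask, 4.0)
        assert dmap.values_um[3, 4] == pytest.approx(20.0)  # 3-4-5 triangle
        assert dmap.values_um[0, 0] == 0.0

    def test_full_source_is_zero(self):
        dmap = compute_distance_map(np.ones((5, 7), dtype=bool), 2.0)
        assert np.all(dmap.values_um == 0.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_distance_map(np.zeros((4, 4), dtype=bool), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((64, 64)) < 0.03
        mask.flat[0] = True  # guarantee nonempty
        dmap = compute_distance_map(mask, 3.5)
        oracle = brute_force_edt(mask, 3.5)
        np.testing.assert_allclose(dmap.values_um, oracle, rtol=1e-9, atol=1e-9)

    def test_lipschitz_between_neighbors(self):
        rng = np.random.default_rng(9)
        mask = rng.random((48, 48)) < 0.02
        mask.flat[-1] = True
        v = compute_distance_map(mask, 4.0).values_um
        assert np.max(np.abs(np.diff(v, axis=0))) <= 4.0 + 1e-9
        assert np.max(np.abs(np.diff(v, axis=1))) <= 4.0 + 1e-9


class TestNodalProjection:
    def test_disc_under_flat_surface_symmetric_interval(self):
        px = 4.0
        node = np.zeros((100, 100), dtype=bool)
        yy, xx = np.indices(node.shape)
        node[(yy - 60) ** 2 + (xx - 50) ** 2 <= 10**2] = True
        curve = _flat_curve(100, px)
        i0, i1 = nodal_projection(node, curve, px)
        assert 39 <= i0 and i1 <= 61
        assert i0 < 50 < i1

    def test_single_pixel_node_width_zero(self):
        node = np.zeros((20, 50), dtype=bool)
        node[10, 25] = True
        i0, i1 = nodal_projection(node, _flat_curve(50, 4.0), 4.0)
        assert i0 == i1 == 25

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_assignment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        node = ndimage.binary_dilation(rng.random((60, 80)) < 0.005, iterations=3)
        node[40:, :] = False
        node[:20, :] = False
        if not node.any():
            node[30, 40] = True
        x = np.arange(80) * 4.0
        curve = SurfaceCurve(
            sample_points_um=np.stack([x, 8.0 * np.sin(x / 50)], 1),
            arc_length_um=np.concatenate(
                [[0], np.cumsum(np.hypot(np.diff(x), np.diff(8.0 * np.sin(x / 50))))]
            ),
            smoothing_param=0.0,
            residual_rms_um=0.0,
        )
        i0, i1 = nodal_projection(node, curve, 4.0)
        rows, cols = np.nonzero(node)
        pts = np.stack([cols * 4.0, rows * 4.0], 1)
        d = np.hypot(
            pts[:, None, 0] - curve.sample_points_um[None, :, 0],
            pts[:, None, 1] - curve.sample_points_um[None, :, 1],
        )
        hits = d.argmin(axis=1)
        assert (i0, i1) == (hits.min(), hits.max())


class TestDepthProfile:
    def test_phantom_min_depth_within_rasterization_bound(self, flat_disc_section):
        _, masks, gt = flat_disc_section
        profile, _ = measure_section_depth(masks, 4.0)
        assert abs(profile.min_depth_um - gt.true_min_depth_um) <= 4.0 * math.sqrt(2)

    def test_tangent_node_min_depth_within_one_pixel(self, flat_disc_spec):
        spec = replace(flat_disc_spec, node_center_depth_um=flat_disc_spec.node_radius_um)
        _, masks, _ = make_section(spec)
        profile, _ = measure_section_depth(masks, 4.0)
        assert profile.min_depth_um <= 4.0

    def test_v_shaped_series_recovers_depth_curve(self):
        base = SectionPhantomSpec(
            image_height_px=220, image_width_px=160, pixel_size_um=4.0,
            surface_shape=FlatSurface(row_um=16.0),
            node_center_depth_um=40.0, node_radius_um=40.0, seed=13,
        )
        depth = lambda i: 150.0 + 50.0 * abs(i - 4)
        series = make_heart_series(9, 100.0, depth, ["none"] * 9, base)
        for i, (_, masks, _) in enumerate(series):
            profile, _ = measure_section_depth(masks, 4.0)
            assert abs(profile.min_depth_um - depth(i)) <= 4.0 * math.sqrt(2)

    def test_translation_invariance(self, flat_disc_spec):
        _, masks, _ = make_section(flat_disc_spec)
        p0, _ = measure_section_depth(masks, 4.0)
        shifted = replace(
            flat_disc_spec,
            surface_shape=FlatSurface(row_um=40.0),
            node_center_x_um=(flat_disc_spec.image_width_px - 1) / 2 * 4.0 + 20.0,
        )
        _, masks_s, _ = make_section(shifted)
        p1, _ = measure_section_depth(masks_s, 4.0)
        assert abs(p1.min_depth_um - p0.min_depth_um) <= 4.0 * math.sqrt(2)

    def test_min_depth_non_increasing_under_dilation(self, flat_disc_section):
        _, masks, _ = flat_disc_section
        p0, curve = measure_section_depth(masks, 4.0)
        dilated = ndimage.binary_dilation(masks.node_mask, iterations=3)
        dmap = compute_distance_map(dilated, 4.0)
        interval = nodal_projection(dilated, curve, 4.0)
        p1 = depth_profile(dmap, curve, interval)
        assert p1.min_depth_um <= p0.min_depth_um + 1e-9

    def test_out_of_bounds_sample_rejected(self, flat_disc_section):
        _, masks, _ = flat_disc_section
        dmap = compute_distance_map(masks.node_mask, 4.0)
        bad = _flat_curve(400, 4.0, y_um=-40.0)  # 10 px above the image
        with pytest.raises(ValueError, match="outside image bounds"):
            depth_profile(dmap, bad, (0, 10))


class TestAlignSeries:
    def test_origin_at_first_section(self):
        table = align_series({"H1": [100, 200, 300]}, {"H1": 0}, 100.0)
        assert list(table.aligned_offset_um) == [0.0, 100.0, 200.0]

    def test_translation_invariance_of_alignment(self):
        canon = [500, 400, 300, 200, 300, 400]
        a = align_series({"A": [0] * 3 + canon}, {"A": 3 + 2}, 100.0)
        b = align_series({"B": canon}, {"B": 2}, 100.0)
        merged = a.merge(b, on="aligned_offset_um", suffixes=("_a", "_b"))
        assert len(merged) == len(canon)
        np.testing.assert_allclose(merged.min_depth_um_a, merged.min_depth_um_b)

    def test_missing_origin_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            table = align_series({"H1": [1, 2], "H2": [3, 4]}, {"H1": 0}, 100.0)
        assert set(table.heart_id) == {"H1"}
        assert "H2" in caplog.text

    def test_offset_zero_exists_for_every_heart(self):
        table = align_series(
            {"A": [1, 2, 3, 4], "B": [5, 6, 7]}, {"A": 2, "B": 1}, 100.0
        )
        for _, g in table.groupby("heart_id"):
            assert 0.0 in set(g.aligned_offset_um)


class TestBoxStats:
    def test_constant_profile(self):
        s = section_depth_stats([42.0] * 9)
        assert s.mean == s.median == s.q1 == s.q3 == 42.0
        assert s.outliers.size == 0

    def test_documented_quartile_convention(self):
        s = section_depth_stats([100.0, 200.0, 300.0, 400.0, 1000.0])
        assert s.median == 300.0
        assert s.q1 == 150.0
        assert s.q3 == 700.0

    def test_symmetric_profile_mean_equals_median(self):
        s = section_depth_stats([10.0, 20.0, 30.0, 40.0, 50.0])
        assert s.mean == s.median == 30.0

    def test_outliers_beyond_whiskers(self):
        data = [10.0] * 5 + [11.0] * 5 + [500.0]
        s = section_depth_stats(data)
        assert 500.0 in s.outliers
        assert s.whisker_high <= 11.0
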