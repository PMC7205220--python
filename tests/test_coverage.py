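"""Stain classification, ROI placement, superficial restriction and the
cephalic/nodal/caudal partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodalmorph import (
    CLASS_CODES,
    FlatSurface,
    ROI_DEFAULTS_UM,
    RoiSeries,
    SectionPhantomSpec,
    classify_red_dual,
    classify_white,
    compute_distance_map,
    make_section,
    measure_section_depth,
    partition_surface_regions,
    place_rois,
    roi_class_percentages,
    superficial_mask,
)
from nodalmorph.surface import SurfaceCurve, fit_smoothing_spline


def _rgb(*colors):
    return np.array([[list(c) for c in colors]], dtype=np.uint8)


def _line_curve(length_um, n=200):
    x = np.linspace(0, length_um, n)
    return fit_smoothing_spline(np.stack([x, np.zeros_like(x)], 1), 0.0)


class TestClassifiers:
    def test_red_dual_rule_on_pure_colors(self):
        img = _rgb((255, 0, 0), (0, 0, 255), (255, 255, 255), (40, 0, 0))
        mask = classify_red_dual(img).class_mask[0]
        # pure red passes; blue and white fail dominance; dark red fails intensity
        assert list(mask) == [True, False, False, False]

    def test_white_rule_on_pure_colors(self):
        img = _rgb((250, 250, 250), (250, 120, 120), (100, 100, 100))
        mask = classify_white(img).class_mask[0]
        assert list(mask) == [True, False, False]

    def test_thresholds_validated(self):
        img = _rgb((0, 0, 0))
        with pytest.raises(ValueError):
            classify_red_dual(img, t_dominance=300)
        with pytest.raises(ValueError):
            classify_white(img, t_bright=-1)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        t_low=st.integers(0, 200),
        delta=st.integers(1, 55),
        seed=st.integers(0, 100),
    )
    def test_red_mask_monotone_in_dominance_threshold(self, t_low, delta, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        loose = classify_red_dual(img, t_dominance=t_low).class_mask
        tight = classify_red_dual(img, t_dominance=t_low + delta).class_mask
        assert not np.any(tight & ~loose)

    def test_phantom_red_fraction_recovered(self, flat_disc_spec):
        from dataclasses import replace

        spec = replace(flat_disc_spec, class_fractions={"all": (0.7, 0.2, 0.1)})
        img, masks, gt = make_section(spec)
        tissue = masks.tissue_mask & (gt.class_labels != CLASS_CODES["node"])
        measured = classify_red_dual(img.pixels).class_mask[tissue].mean()
        assert abs(measured - 0.7) <= 0.02

    def test_phantom_white_fraction_recovered(self, flat_disc_spec):
        from dataclasses import replace

        spec = replace(flat_disc_spec, class_fractions={"all": (0.45, 0.12, 0.43)})
        img, masks, gt = make_section(spec)
        tissue = masks.tissue_mask & (gt.class_labels != CLASS_CODES["node"])
        measured = classify_white(img.pixels).class_mask[tissue].mean()
        assert abs(measured - 0.43) <= 0.02


class TestPlaceRois:
    def test_default_geometries(self):
        assert ROI_DEFAULTS_UM["SAN"] == (150.0, 75.0)
        assert ROI_DEFAULTS_UM["AVN"] == (500.0, 250.0)

    def test_straight_surface_center_count(self):
        rois = place_rois(_line_curve(1000.0), radius_um=100.0, spacing_um=250.0)
        assert len(rois) == 5
        np.testing.assert_allclose(rois.arc_positions_um, [0, 250, 500, 750, 1000])

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            place_rois(_line_curve(1000.0), radius_um=0.0, spacing_um=75.0)


class TestRoiPercentages:
    def _uniform_section(self, color, shape=(60, 120), px=4.0):
        img = np.zeros(shape + (3,), dtype=np.uint8)
        img[...] = color
        surface = np.zeros(shape, dtype=bool)
        surface[0, :] = True
        tissue = np.ones(shape, dtype=bool)
        return img, surface, tissue, px

    def test_uniform_red_no_node_is_100(self):
        img, surface, tissue, px = self._uniform_section((200, 40, 40))
        surf_dmap = compute_distance_map(surface, px, source="surface")
        rois = place_rois(_line_curve(119 * px), radius_um=60.0, spacing_um=60.0)
        out = roi_class_percentages(
            classify_red_dual(img), rois, np.zeros_like(tissue), tissue, surf_dmap, px
        )
        assert np.all(out.valid)
        np.testing.assert_allclose(out.percent, 100.0)

    def test_class_negative_superficial_tissue_is_0(self):
        img, surface, tissue, px = self._uniform_section((70, 90, 180))  # all blue
        node = np.zeros_like(tissue)
        node[40:50, :] = True
        surf_dmap = compute_distance_map(surface, px, source="surface")
        rois = place_rois(_line_curve(119 * px), radius_um=60.0, spacing_um=120.0)
        out = roi_class_percentages(
            classify_red_dual(img), rois, node, tissue, surf_dmap, px
        )
        assert np.all(out.percent[out.valid] == 0.0)

    def test_red_plus_complement_is_100(self, flat_disc_section):
        img, masks, _ = flat_disc_section
        px = img.pixel_size_um
        _, curve = measure_section_depth(masks, px)
        surf_dmap = compute_distance_map(masks.surface_mask, px, source="surface")
        rois = place_rois(curve, radius_um=100.0, spacing_um=100.0)
        red = classify_red_dual(img.pixels)
        nonred = type(red)(
            class_mask=~red.class_mask, class_kind="red", thresholds=red.thresholds
        )
        a = roi_class_percentages(red, rois, masks.node_mask, masks.tissue_mask, surf_dmap, px)
        b = roi_class_percentages(nonred, rois, masks.node_mask, masks.tissue_mask, surf_dmap, px)
        valid = a.valid & b.valid
        np.testing.assert_allclose(a.percent[valid] + b.percent[valid], 100.0)

    def test_percent_matches_ground_truth_count_over_node(self):
        spec = SectionPhantomSpec(
            image_height_px=180, image_width_px=220, pixel_size_um=4.0,
            surface_shape=FlatSurface(row_um=8.0),
            node_center_depth_um=200.0, node_radius_um=80.0,
            class_fractions={"all": (0.5, 0.35, 0.15)}, seed=17,
        )
        img, masks, gt = make_section(spec)
        px = img.pixel_size_um
        _, curve = measure_section_depth(masks, px)
        surf_dmap = compute_distance_map(masks.surface_mask, px, source="surface")
        rois = place_rois(curve, radius_um=150.0, spacing_um=75.0)
        out = roi_class_percentages(
            classify_red_dual(img.pixels), rois, masks.node_mask, masks.tissue_mask,
            surf_dmap, px,
        )
        # oracle: count ground-truth red labels over the same denominator
        from skimage.draw import disk

        eligible = masks.tissue_mask & superficial_mask(masks.node_mask, surf_dmap)
        for k in np.nonzero(out.valid)[0]:
            cx, cy = out.centers_um[k]
            rr, cc = disk((cy / px, cx / px), 150.0 / px, shape=masks.node_mask.shape)
            sel = eligible[rr, cc]
            truth = 100.0 * (gt.class_labels[rr, cc][sel] == CLASS_CODES["red"]).sum() / sel.sum()
            assert abs(out.percent[k] - truth) <= 2.0

    def test_empty_denominator_flagged_not_zero(self):
        img, surface, tissue, px = self._uniform_section((200, 40, 40))
        tissue[:] = False  # nothing eligible anywhere
        surf_dmap = compute_distance_map(surface, px, source="surface")
        rois = place_rois(_line_curve(119 * px), radius_um=40.0, spacing_um=120.0)
        out = roi_class_percentages(
            classify_red_dual(img), rois, np.zeros_like(tissue), tissue, surf_dmap, px
        )
        assert not out.valid.any()
        assert np.isnan(out.percent).all()

    def test_percent_invariant_to_pixels_outside_discs(self):
        img, surface, tissue, px = self._uniform_section((200, 40, 40), shape=(80, 120))
        surf_dmap = compute_distance_map(surface, px, source="surface")
        rois = place_rois(_line_curve(119 * px), radius_um=30.0, spacing_um=240.0)
        red = classify_red_dual(img)
        base = roi_class_percentages(red, rois, np.zeros_like(tissue), tissue, surf_dmap, px)
        img2 = img.copy()
        img2[60:, :] = (70, 90, 180)  # far below every disc (radius 30 um = 7.5 px)
        out2 = roi_class_percentages(
            classify_red_dual(img2), rois, np.zeros_like(tissue), tissue, surf_dmap, px
        )
        np.testing.assert_allclose(base.percent, out2.percent)


class TestSuperficialRules:
    def test_node_pixels_never_superficial(self, flat_disc_section):
        _, masks, _ = flat_disc_section
        surf_dmap = compute_distance_map(masks.surface_mask, 4.0, source="surface")
        for rule in ("surface_distance", "min_depth"):
            sup = superficial_mask(masks.node_mask, surf_dmap, rule=rule)
            assert not (sup & masks.node_mask).any()

    def test_no_node_everything_superficial(self):
        surface = np.zeros((20, 30), dtype=bool)
        surface[0] = True
        surf_dmap = compute_distance_map(surface, 4.0, source="surface")
        sup = superficial_mask(np.zeros((20, 30), dtype=bool), surf_dmap)
        assert sup.all()

    def test_surface_distance_rule_keeps_pixels_above_node(self, flat_disc_section):
        _, masks, _ = flat_disc_section
        surf_dmap = compute_distance_map(masks.surface_mask, 4.0, source="surface")
        sup = superficial_mask(masks.node_mask, surf_dmap)
        rows, cols = np.nonzero(masks.node_mask)
        top, cx = rows.min(), int(np.median(cols))
        assert sup[1 : top - 1, cx].all()  # column above the node, below surface
        assert not sup[rows.max() + 2 :, cx].any()  # deeper than the node


class TestPartition:
    def _rois(self, arcs):
        arcs = np.asarray(arcs, dtype=float)
        return RoiSeries(
            arc_positions_um=arcs,
            centers_um=np.stack([arcs, np.zeros_like(arcs)], 1),
            radius_um=10.0,
            spacing_um=arcs[1] - arcs[0] if len(arcs) > 1 else 1.0,
        )

    def test_example_partition(self):
        rois = self._rois(np.arange(40) * 10.0)
        labels = partition_surface_regions(rois, (100.0, 200.0))
        assert list(labels[:10]) == ["cephalic"] * 10
        assert list(labels[10:21]) == ["nodal"] * 11
        assert list(labels[21:]) == ["caudal"] * 19

    def test_no_node_section_all_none(self):
        labels = partition_surface_regions(self._rois([0.0, 10.0, 20.0]), None)
        assert list(labels) == ["none"] * 3

    @pytest.mark.parametrize("seed", range(10))
    def test_randomized_against_direct_comparison(self, seed):
        rng = np.random.default_rng(seed)
        arcs = np.sort(rng.uniform(0, 1000, 30))
        lo, hi = np.sort(rng.uniform(0, 1000, 2))
        labels = partition_surface_regions(self._rois(arcs), (lo, hi))
        for arc, lab in zip(arcs, labels):
            expected = "cephalic" if arc < lo else ("caudal" if arc > hi else "nodal")
            assert lab == expected
        assert set(labels) <= {"cephalic", "nodal", "caudal"}
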