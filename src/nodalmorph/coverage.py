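"""Stain-class coverage in circular ROIs on the tissue surface.

Trichrome-red percentage (myocardium) and trichrome-white percentage
(adipose / empty space) are quantified in circular ROIs centered on the
fitted surface curve, restricted to tissue *superficial* to the node,
and the surface is partitioned into cephalic / nodal / caudal regions
around the nodal projection.

"Superficial to the node" is formalized as: a pixel p belongs to the
superficial set iff its surface distance is strictly smaller than the
surface distance of the node pixel nearest to p (rule
``"surface_distance"``, the default). An alternative rule
(``"min_depth"``) keeps every non-node pixel whose surface distance is
below the node's minimal surface distance. Sections without a node use
all pixels.

Default ROI geometry follows the node type: radius 150 um with 75 um
spacing for the SAN, radius 500 um with 250 um spacing for the AVN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import disk

from .depth import DistanceMap
from .surface import SurfaceCurve, resample_uniform

__all__ = [
    "ROI_DEFAULTS_UM",
    "StainClassMap",
    "RoiSeries",
    "classify_red_dual",
    "classify_red_hue",
    "classify_white",
    "place_rois",
    "superficial_mask",
    "roi_class_percentages",
    "partition_surface_regions",
]

# (radius_um, spacing_um) per node type
ROI_DEFAULTS_UM = {"SAN": (150.0, 75.0), "AVN": (500.0, 250.0)}


@dataclass
class StainClassMap:
    class_mask: np.ndarray  # bool H x W
    class_kind: str  # "red" | "white"
    thresholds: dict[str, float]


@dataclass
class RoiSeries:
    """Circular ROIs along the surface with per-ROI class percentage."""

    arc_positions_um: np.ndarray
    centers_um: np.ndarray  # (N, 2) of (x, y)
    radius_um: float
    spacing_um: float
    class_kind: str | None = None
    percent: np.ndarray | None = None  # NaN where the denominator was empty
    valid: np.ndarray | None = None
    region: np.ndarray | None = None  # "cephalic" | "nodal" | "caudal" | "none"
    denominator_px: np.ndarray | None = None

    def __len__(self) -> int:
        return self.arc_positions_um.shape[0]


def _check_threshold(name: str, value: float) -> None:
    if not 0 <= value <= 255:
        raise ValueError(f"{name} must be in [0, 255], got {value}")


def classify_red_dual(
    image: np.ndarray, t_dominance: float = 50.0, t_intensity: float = 120.0
) -> StainClassMap:
    """Dual red threshold: red iff (R - B) >= t_dominance and R >= t_intensity.

    The dominance condition rejects white (R == B) and blue pixels; the
    intensity condition rejects dark pixels whose weak channels happen to
    differ. Lowering ``t_dominance`` monotonically grows the mask.
    """
    _check_threshold("t_dominance", t_dominance)
    _check_threshold("t_intensity", t_intensity)
    img = np.asarray(image)
    r = img[..., 0].astype(np.int16)
    b = img[..., 2].astype(np.int16)
    mask = (r - b >= t_dominance) & (r >= t_intensity)
    return StainClassMap(
        class_mask=mask,
        class_kind="red",
        thresholds={"t_dominance": t_dominance, "t_intensity": t_intensity},
    )


def classify_red_hue(
    image: np.ndarray,
    hue_low: float = 0.90,
    hue_high: float = 0.08,
    s_min: float = 0.25,
    v_min: float = 0.35,
) -> StainClassMap:
    """Alternative hue-window red classifier (for real-stain robustness).

    Hue is on [0, 1); the red window wraps around 0, so a pixel is red
    iff hue >= hue_low or hue <= hue_high, with minimum saturation and
    value. Kept behind an explicit call; the dual threshold is default.
    """
    from skimage.color import rgb2hsv

    hsv = rgb2hsv(np.asarray(image))
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    mask = ((h >= hue_low) | (h <= hue_high)) & (s >= s_min) & (v >= v_min)
    return StainClassMap(
        class_mask=mask,
        class_kind="red",
        thresholds={"hue_low": hue_low, "hue_high": hue_high, "s_min": s_min, "v_min": v_min},
    )


def classify_white(
    image: np.ndarray, t_bright: float = 200.0, t_spread: float = 30.0
) -> StainClassMap:
    """White iff min(R,G,B) >= t_bright and max-min <= t_spread (near-achromatic)."""
    _check_threshold("t_bright", t_bright)
    _check_threshold("t_spread", t_spread)
    img = np.asarray(image).astype(np.int16)
    cmin = img.min(axis=-1)
    cmax = img.max(axis=-1)
    mask = (cmin >= t_bright) & (cmax - cmin <= t_spread)
    return StainClassMap(
        class_mask=mask,
        class_kind="white",
        thresholds={"t_bright": t_bright, "t_spread": t_spread},
    )


def place_rois(curve: SurfaceCurve, radius_um: float, spacing_um: float) -> RoiSeries:
    """Centers at uniform arc-length positions on the fitted curve."""
    if not radius_um > 0 or not spacing_um > 0:
        raise ValueError("radius_um and spacing_um must be positive")
    sampled = resample_uniform(curve, spacing_um)
    return RoiSeries(
        arc_positions_um=sampled.arc_length_um,
        centers_um=sampled.sample_points_um,
        radius_um=radius_um,
        spacing_um=spacing_um,
    )


def superficial_mask(
    node_mask: np.ndarray,
    surface_distance_map: DistanceMap,
    rule: str = "surface_distance",
) -> np.ndarray:
    """Pixels superficial to the node under the configured rule.

    With no node in the section, every pixel is superficial.
    """
    node_mask = np.asarray(node_mask, dtype=bool)
    surf_d = surface_distance_map.values_um
    if not node_mask.any():
        return np.ones_like(node_mask)
    if rule == "surface_distance":
        # nearest node pixel to every pixel, via EDT feature transform
        inds = ndimage.distance_transform_edt(~node_mask, return_distances=False, return_indices=True)
        nearest_node_surf_d = surf_d[inds[0], inds[1]]
        return surf_d < nearest_node_surf_d
    if rule == "min_depth":
        node_min = surf_d[node_mask].min()
        return (surf_d < node_min) & ~node_mask
    raise ValueError(f"unknown superficial rule {rule!r}")


def roi_class_percentages(
    class_map: StainClassMap,
    rois: RoiSeries,
    node_mask: np.ndarray,
    tissue_mask: np.ndarray,
    surface_distance_map: DistanceMap,
    pixel_size_um: float,
    rule: str = "surface_distance",
) -> RoiSeries:
    """Per-ROI class percentage over tissue superficial to the node.

    Denominator: pixels in the ROI disc (clipped at image borders) that
    are tissue and superficial to the node; numerator: those that are
    class-positive. ROIs with an empty denominator are flagged invalid
    and carry NaN, never 0.
    """
    shape = class_map.class_mask.shape
    eligible = np.asarray(tissue_mask, dtype=bool) & superficial_mask(
        node_mask, surface_distance_map, rule=rule
    )
    positive = eligible & class_map.class_mask
    r_px = rois.radius_um / pixel_size_um
    percents = np.full(len(rois), np.nan)
    valid = np.zeros(len(rois), dtype=bool)
    denom = np.zeros(len(rois), dtype=int)
    for i, (cx_um, cy_um) in enumerate(rois.centers_um):
        rr, cc = disk((cy_um / pixel_size_um, cx_um / pixel_size_um), r_px, shape=shape)
        den = int(eligible[rr, cc].sum())
        denom[i] = den
        if den == 0:
            continue
        percents[i] = 100.0 * positive[rr, cc].sum() / den
        valid[i] = True
    return RoiSeries(
        arc_positions_um=rois.arc_positions_um,
        centers_um=rois.centers_um,
        radius_um=rois.radius_um,
        spacing_um=rois.spacing_um,
        class_kind=class_map.class_kind,
        percent=percents,
        valid=valid,
        denominator_px=denom,
    )


def partition_surface_regions(
    rois: RoiSeries, projection_interval_um: tuple[float, float] | None
) -> np.ndarray:
    """Label each ROI cephalic / nodal / caudal by its center's arc position.

    The curve is oriented cephalic-to-caudal, so an ROI is *nodal* iff
    its arc position lies inside the nodal projection interval,
    *cephalic* before it and *caudal* after. With no node in the section
    the cephalic/caudal split is undefined and every ROI is labeled
    ``"none"``. The partition is exhaustive and disjoint.
    """
    arc = rois.arc_positions_um
    if projection_interval_um is None:
        labels = np.full(arc.shape, "none", dtype=object)
    else:
        lo, hi = projection_interval_um
        if lo > hi:
            raise ValueError("projection interval must have lo <= hi")
        labels = np.where(arc < lo, "cephalic", np.where(arc > hi, "caudal", "nodal")).astype(object)
    rois.region = labels
    return labels
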