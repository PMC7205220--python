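"""Depth morphometry: distance maps, nodal projection, depth profiles,
per-section minimal depth, and cross-heart aligned depth topology.

Depth of the node beneath the epi/endocardial surface is measured by
evaluating the exact Euclidean distance transform of the node mask at
sub-pixel positions along the fitted surface curve (bilinear sampling by
default). The per-section *minimal depth* is the minimum of that profile
over the nodal projection interval — the stretch of surface nearest to
the node — not over the whole surface (a whole-surface variant is
computed alongside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .section_io import SectionMasks
from .surface import SurfaceCurve, surface_curve_from_mask

__all__ = [
    "DistanceMap",
    "DepthProfile",
    "BoxStats",
    "compute_distance_map",
    "nodal_projection",
    "depth_profile",
    "measure_section_depth",
    "align_series",
    "section_depth_stats",
]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMap:
    """Exact Euclidean distance (um, pixel-center metric) to a source mask."""

    values_um: np.ndarray
    source: str  # "node" | "surface"
    pixel_size_um: float


@dataclass
class DepthProfile:
    """Depth (um) at each surface sample, with the per-section minimum.

    ``projection_interval`` indexes the surface samples hit by the
    nearest-point projection of the node; ``min_depth_um`` is the
    minimum of ``depth_um`` over that interval.
    """

    section_index: int
    arc_positions_um: np.ndarray
    depth_um: np.ndarray
    projection_interval: tuple[int, int]
    min_depth_um: float
    min_depth_whole_surface_um: float

    def __post_init__(self) -> None:
        i0, i1 = self.projection_interval
        if not 0 <= i0 <= i1 < len(self.depth_um):
            raise ValueError("projection_interval out of range")

    @property
    def projection_arc_um(self) -> tuple[float, float]:
        i0, i1 = self.projection_interval
        return float(self.arc_positions_um[i0]), float(self.arc_positions_um[i1])


def compute_distance_map(
    mask: np.ndarray, pixel_size_um: float, source: str = "node"
) -> DistanceMap:
    """Exact Euclidean distance transform of a source mask, scaled to um."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"cannot compute a distance map from an empty {source} mask")
    values = ndimage.distance_transform_edt(~mask) * pixel_size_um
    return DistanceMap(values_um=values, source=source, pixel_size_um=pixel_size_um)


def nodal_projection(
    node_mask: np.ndarray, curve: SurfaceCurve, pixel_size_um: float
) -> tuple[int, int]:
    """Project the node onto the surface: [min, max] of nearest-sample hits.

    Each node pixel (at its center position) is assigned its nearest
    surface sample; ties resolve to the lower sample index (first
    minimum). Returns the index interval into ``curve`` samples.
    """
    node_mask = np.asarray(node_mask, dtype=bool)
    if not node_mask.any():
        raise ValueError("node mask is empty")
    rows, cols = np.nonzero(node_mask)
    px_x = cols * pixel_size_um
    px_y = rows * pixel_size_um
    sx = curve.sample_points_um[:, 0]
    sy = curve.sample_points_um[:, 1]
    lo, hi = np.inf, -np.inf
    for start in range(0, px_x.size, 1024):
        dx = sx[None, :] - px_x[start : start + 1024, None]
        dy = sy[None, :] - px_y[start : start + 1024, None]
        idx = np.argmin(dx * dx + dy * dy, axis=1)  # first minimum = lower index
        lo = min(lo, idx.min())
        hi = max(hi, idx.max())
    return int(lo), int(hi)


def depth_profile(
    node_distance_map: DistanceMap,
    curve: SurfaceCurve,
    projection_interval: tuple[int, int],
    section_index: int = 0,
    interpolation: str = "bilinear",
) -> DepthProfile:
    """Sample the node distance map along the surface curve.

    The fitted surface samples are sub-pixel, so the map is sampled with
    bilinear interpolation by default (``interpolation="nearest"`` for
    the nearest-pixel alternative). Samples outside the image raise.
    """
    px = node_distance_map.pixel_size_um
    H, W = node_distance_map.values_um.shape
    cols = curve.sample_points_um[:, 0] / px
    rows = curve.sample_points_um[:, 1] / px
    # the smoothing spline may overshoot the pixel grid by a fraction of a
    # pixel at the curve endpoints; clip that, error on anything larger
    eps = 1.0
    if (
        rows.min() < -eps
        or cols.min() < -eps
        or rows.max() > H - 1 + eps
        or cols.max() > W - 1 + eps
    ):
        raise ValueError(
            f"surface sample outside image bounds: rows [{rows.min():.2f}, {rows.max():.2f}], "
            f"cols [{cols.min():.2f}, {cols.max():.2f}] vs image {H}x{W}"
        )
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    depth = ndimage.map_coordinates(
        node_distance_map.values_um,
        np.stack([np.clip(rows, 0, H - 1), np.clip(cols, 0, W - 1)]),
        order=order,
        mode="nearest",
    )
    i0, i1 = projection_interval
    return DepthProfile(
        section_index=section_index,
        arc_positions_um=curve.arc_length_um.copy(),
        depth_um=depth,
        projection_interval=(i0, i1),
        min_depth_um=float(depth[i0 : i1 + 1].min()),
        min_depth_whole_surface_um=float(depth.min()),
    )


def measure_section_depth(
    masks: SectionMasks,
    pixel_size_um: float,
    section_index: int = 0,
    smoothing_param: float | None = None,
    sample_spacing_um: float | None = None,
    interpolation: str = "bilinear",
) -> tuple[DepthProfile, SurfaceCurve]:
    """Full per-section chain: surface fit, distance map, projection, profile."""
    curve = surface_curve_from_mask(
        masks.surface_mask,
        pixel_size_um,
        smoothing_param=smoothing_param,
        resample_spacing_um=sample_spacing_um,
    )
    dmap = compute_distance_map(masks.node_mask, pixel_size_um, source="node")
    interval = nodal_projection(masks.node_mask, curve, pixel_size_um)
    profile = depth_profile(dmap, curve, interval, section_index, interpolation)
    return profile, curve


def align_series(
    min_depths: Mapping[str, Sequence[float]],
    origin_indices: Mapping[str, int],
    section_interval_um: float,
) -> pd.DataFrame:
    """Align per-section minimal depths across hearts at a common origin.

    ``min_depths`` maps heart_id to the per-section minimal depths (in
    section order); ``origin_indices`` gives each heart's alignment
    origin (for the AVN, its first transition-to-His section). Aligned
    offset = (section_index - origin_index) * section_interval_um, so
    offset 0 exists for every aligned heart. Hearts without an origin
    are excluded with a logged warning.
    """
    rows = []
    for heart_id, depths in min_depths.items():
        if heart_id not in origin_indices or origin_indices[heart_id] is None:
            logger.warning("heart %s has no alignment origin; excluded from topology", heart_id)
            continue
        origin = origin_indices[heart_id]
        if not 0 <= origin < len(depths):
            logger.warning("heart %s origin %d out of range; excluded", heart_id, origin)
            continue
        for i, d in enumerate(depths):
            rows.append(
                {
                    "heart_id": heart_id,
                    "aligned_offset_um": (i - origin) * section_interval_um,
                    "min_depth_um": float(d),
                }
            )
    return pd.DataFrame(rows, columns=["heart_id", "aligned_offset_um", "min_depth_um"])


@dataclass
class BoxStats:
    """Box-plot statistics under the exclusive-median-halves quartile rule."""

    n: int
    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def _median(sorted_values: np.ndarray) -> float:
    n = sorted_values.size
    mid = n // 2
    if n % 2:
        return float(sorted_values[mid])
    return float(0.5 * (sorted_values[mid - 1] + sorted_values[mid]))


def section_depth_stats(values: Sequence[float]) -> BoxStats:
    """Mean, median, quartiles, 1.5*IQR whiskers and outliers.

    Quartiles use the exclusive-median-halves convention: split the
    sorted data at the median (dropping the median element when n is
    odd) and take the median of each half. For {100,200,300,400,1000}
    this gives Q1=150, Q3=700.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("values must be nonempty")
    n = v.size
    med = _median(v)
    if n == 1:
        q1 = q3 = med
    else:
        q1 = _median(v[: n // 2])
        q3 = _median(v[(n + 1) // 2 :])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxStats(
        n=n,
        mean=float(v.mean()),
        median=med,
        q1=q1,
        q3=q3,
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=v[(v < lo_fence) | (v > hi_fence)],
    )
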