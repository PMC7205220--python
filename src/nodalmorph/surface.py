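"""Surface-trace geometry: polyline extraction, smoothing-spline fit,
arc-length parameterization and uniform resampling.

The segmented epi/endocardial surface arrives as a one-pixel-wide
8-connected trace. It is ordered into a polyline, fitted with a cubic
smoothing spline on a chord-length parameter, and resampled at uniform
arc length. All depth and ROI analyses anchor on the resulting
:class:`SurfaceCurve`. By package convention the curve is oriented so
that arc length increases in the cephalic-to-caudal direction, which in
phantoms and loaded images means increasing x (column) position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline

__all__ = [
    "SurfaceCurve",
    "TopologyError",
    "extract_surface_polyline",
    "fit_smoothing_spline",
    "resample_uniform",
    "surface_curve_from_mask",
    "default_smoothing_param",
]

_AXIAL = ((-1, 0), (1, 0), (0, -1), (0, 1))
_DIAG = ((-1, -1), (-1, 1), (1, -1), (1, 1))


class TopologyError(ValueError):
    """Surface mask is not a single non-branching 8-connected curve."""


@dataclass
class SurfaceCurve:
    """A smooth surface curve sampled along its length.

    ``sample_points_um`` is an (N, 2) array of (x, y) positions in um;
    ``arc_length_um`` the cumulative arc length per sample. After
    :func:`resample_uniform` the arc values are exactly uniformly spaced.
    """

    sample_points_um: np.ndarray
    arc_length_um: np.ndarray
    smoothing_param: float
    residual_rms_um: float

    def __post_init__(self) -> None:
        self.sample_points_um = np.asarray(self.sample_points_um, dtype=float)
        self.arc_length_um = np.asarray(self.arc_length_um, dtype=float)
        if self.sample_points_um.shape[0] != self.arc_length_um.shape[0]:
            raise ValueError("points and arc lengths must have equal length")
        if np.any(np.diff(self.arc_length_um) <= 0):
            raise ValueError("arc_length_um must be strictly increasing")

    @property
    def length_um(self) -> float:
        return float(self.arc_length_um[-1])

    def __len__(self) -> int:
        return self.sample_points_um.shape[0]


def default_smoothing_param(pixel_size_um: float) -> float:
    """Default per-point mean-squared residual allowance (um^2).

    One pixel of allowed RMS misfit: rasterization quantizes the trace to
    the pixel grid, so demanding a closer fit only chases grid noise.
    """
    return float(pixel_size_um) ** 2


def extract_surface_polyline(surface_mask: np.ndarray) -> np.ndarray:
    """Order the pixels of a one-pixel-wide trace from end to end.

    Returns an (N, 2) integer array of (row, col) positions in which
    every mask pixel appears exactly once, ordered by 8-connectivity
    from one endpoint to the other (the endpoint with the smaller
    (col, row) comes first). Raises :class:`TopologyError` for branch
    pixels, multiple components, or closed loops.

    Right-angle corners form an 8-connected 3-clique, so branchpoints
    cannot be detected by a naive degree count; instead the traversal
    prefers axial steps over diagonal ones and treats any remaining
    ambiguity or unvisited pixels as a topology violation.
    """
    mask = np.asarray(surface_mask, dtype=bool)
    pixels = set(map(tuple, np.argwhere(mask)))
    if not pixels:
        raise TopologyError("surface mask is empty")
    if len(pixels) == 1:
        return np.array(sorted(pixels))

    def nbrs(p, offsets):
        r, c = p
        return [(r + dr, c + dc) for dr, dc in offsets if (r + dr, c + dc) in pixels]

    degree = {p: len(nbrs(p, _AXIAL + _DIAG)) for p in pixels}
    endpoints = [p for p, d in degree.items() if d == 1]
    for p, d in degree.items():
        if d == 0 and len(pixels) > 1:
            raise TopologyError(f"multiple components: isolated pixel at {p}")
    if len(endpoints) > 2:
        raise TopologyError(f"branching curve: more than two endpoints, e.g. {sorted(endpoints)[2]}")
    if len(endpoints) < 2:
        raise TopologyError("closed or degenerate curve: fewer than two endpoints")

    start = min(endpoints, key=lambda p: (p[1], p[0]))
    order = [start]
    visited = {start}
    current = start
    while len(order) < len(pixels):
        ax = [p for p in nbrs(current, _AXIAL) if p not in visited]
        dg = [p for p in nbrs(current, _DIAG) if p not in visited]
        # prefer the axial neighbor: at a corner the diagonal shortcut would
        # skip the corner pixel
        candidates = ax if ax else dg
        if not candidates:
            raise TopologyError(f"multiple components: traversal stalled at {current}")
        if len(candidates) > 1:
            raise TopologyError(f"branch pixel at {current}: ambiguous continuation {candidates}")
        current = candidates[0]
        order.append(current)
        visited.add(current)
    return np.array(order)


def polyline_length_um(polyline_px: np.ndarray, pixel_size_um: float) -> float:
    """Length of an ordered pixel polyline (axial step 1 px, diagonal sqrt(2))."""
    steps = np.diff(np.asarray(polyline_px, dtype=float), axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum() * pixel_size_um)


def fit_smoothing_spline(
    points_um: np.ndarray,
    smoothing_param: float,
    dense_per_point: int = 10,
) -> SurfaceCurve:
    """Fit a cubic smoothing spline to an ordered point sequence.

    Each coordinate is fitted as a function of the chord-length parameter
    with ``scipy.interpolate.UnivariateSpline``; ``smoothing_param`` is
    the allowed mean squared residual per point in um^2 (0 interpolates).
    The returned curve is densely sampled (``dense_per_point`` samples
    per input point) with cumulative chordal arc length.
    """
    pts = np.asarray(points_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points_um must be an (N, 2) array")
    if smoothing_param < 0:
        raise ValueError("smoothing_param must be nonnegative")
    keep = np.ones(pts.shape[0], dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    pts = pts[keep]
    n = pts.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 distinct points for a cubic spline, got {n}")

    t = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))])
    s_total = smoothing_param * n
    sx = UnivariateSpline(t, pts[:, 0], k=3, s=s_total)
    sy = UnivariateSpline(t, pts[:, 1], k=3, s=s_total)

    t_dense = np.linspace(t[0], t[-1], max(2, dense_per_point * n))
    dense = np.stack([sx(t_dense), sy(t_dense)], axis=1)
    # residual = point-to-curve distance (not distance at equal parameter,
    # which would charge the fit for chord-parameter distortion); seed with
    # the equal-parameter distance so exact interpolation reports zero
    fitted = np.stack([sx(t), sy(t)], axis=1)
    res2 = np.sum((fitted - pts) ** 2, axis=1)
    for start in range(0, t_dense.size, 1024):
        blk = dense[start : start + 1024]
        d2 = (pts[:, None, 0] - blk[None, :, 0]) ** 2 + (pts[:, None, 1] - blk[None, :, 1]) ** 2
        res2 = np.minimum(res2, d2.min(axis=1))
    residual_rms = float(np.sqrt(np.mean(res2)))
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(dense, axis=0).T))])
    # collapse numerically duplicate samples (can occur under heavy smoothing)
    keep = np.ones(arc.size, dtype=bool)
    keep[1:] = np.diff(arc) > 1e-12
    return SurfaceCurve(
        sample_points_um=dense[keep],
        arc_length_um=arc[keep],
        smoothing_param=smoothing_param,
        residual_rms_um=residual_rms,
    )


def resample_uniform(curve: SurfaceCurve, spacing_um: float) -> SurfaceCurve:
    """Resample a curve at arc lengths 0, s, 2s, ... (floor(L/s)+1 samples)."""
    if not spacing_um > 0:
        raise ValueError("spacing_um must be positive")
    L = curve.length_um
    if spacing_um >= L:
        raise ValueError(f"spacing {spacing_um} um must be smaller than curve length {L:.3g} um")
    n = int(np.floor(L / spacing_um)) + 1
    targets = np.arange(n) * spacing_um
    x = np.interp(targets, curve.arc_length_um, curve.sample_points_um[:, 0])
    y = np.interp(targets, curve.arc_length_um, curve.sample_points_um[:, 1])
    return SurfaceCurve(
        sample_points_um=np.stack([x, y], axis=1),
        arc_length_um=targets,
        smoothing_param=curve.smoothing_param,
        residual_rms_um=curve.residual_rms_um,
    )


def surface_curve_from_mask(
    surface_mask: np.ndarray,
    pixel_size_um: float,
    smoothing_param: float | None = None,
    resample_spacing_um: float | None = None,
) -> SurfaceCurve:
    """Full chain: trace -> ordered polyline -> smoothing spline -> resample.

    ``smoothing_param`` defaults to :func:`default_smoothing_param` (one
    pixel RMS); ``resample_spacing_um`` defaults to one pixel.
    """
    if smoothing_param is None:
        smoothing_param = default_smoothing_param(pixel_size_um)
    if resample_spacing_um is None:
        resample_spacing_um = pixel_size_um
    poly = extract_surface_polyline(surface_mask)
    pts_um = np.stack([poly[:, 1] * pixel_size_um, poly[:, 0] * pixel_size_um], axis=1)
    curve = fit_smoothing_spline(pts_um, smoothing_param)
    return resample_uniform(curve, resample_spacing_um)
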