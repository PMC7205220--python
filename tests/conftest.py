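"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
exhaustive pairwise distances instead of the EDT, direct pixel counting
instead of the ROI machinery, and graph search instead of the polyline
traversal.
"""

import numpy as np
import pytest

from nodalmorph import FlatSurface, SectionPhantomSpec, make_section


def brute_force_edt(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Exhaustive min-over-source-pixels Euclidean distance map."""
    src = np.argwhere(mask).astype(float)
    H, W = mask.shape
    rr, cc = np.indices((H, W))
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    d2 = ((pts[:, None, :] - src[None, :, :]) ** 2).sum(axis=-1)
    return np.sqrt(d2.min(axis=1)).reshape(H, W) * pixel_size_um


def brute_min_pair_distance(mask_a: np.ndarray, mask_b: np.ndarray, pixel_size_um: float) -> float:
    """Minimum pixel-center distance over all (a, b) pixel pairs."""
    a = np.argwhere(mask_a).astype(float)
    b = np.argwhere(mask_b).astype(float)
    best = np.inf
    for start in range(0, a.shape[0], 1024):
        blk = a[start : start + 1024]
        d2 = ((blk[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1)
        best = min(best, d2.min())
    return float(np.sqrt(best) * pixel_size_um)


@pytest.fixture
def flat_disc_spec():
    """Disc node 50 px deep (radius 10 px) under a flat surface at row 0,
    4 um pixels: analytic minimal depth (50-10)*4 = 160 um."""
    return SectionPhantomSpec(
        image_height_px=200,
        image_width_px=200,
        pixel_size_um=4.0,
        surface_shape=FlatSurface(row_um=0.0),
        node_center_depth_um=200.0,
        node_radius_um=40.0,
        seed=11,
    )


@pytest.fixture
def flat_disc_section(flat_disc_spec):
    return make_section(flat_disc_spec)
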