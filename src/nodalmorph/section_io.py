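"""Reading and writing serial-section studies.

A *heart dataset* is one serial stack of stained sections from a single
node region (SAN or AVN) of one heart: per-section RGB images, binary
masks for the nodal tissue, the epi/endocardial surface trace and the
tissue as a whole, plus a JSON sidecar with the physical metadata
(pixel size, section interval, postmenstrual age in months).

Conventions (fixed across the package):

* pixel indices are row-major and 0-based; physical positions are
  ``index * pixel_size_um`` at pixel centers;
* all persisted lengths are in micrometers, ages in months and
  percentages on a 0-100 scale;
* images are stored as TIFF, masks as 0/255 PNG, metadata as JSON and
  result tables as CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "SectionImage",
    "SectionMasks",
    "HeartDataset",
    "SectionIOError",
    "REGION_LABELS",
    "NODE_TYPES",
    "load_heart",
    "write_heart",
    "write_results",
    "read_table",
]

REGION_LABELS = ("extension", "compact", "transition", "his", "san_nodal", "none")
NODE_TYPES = ("SAN", "AVN")

_SIDECAR = "heart.json"


class SectionIOError(ValueError):
    """Raised when a dataset on disk violates the section/metadata contract."""


@dataclass
class SectionImage:
    """One RGB section with its physical calibration and axial position."""

    pixels: np.ndarray  # H x W x 3, uint8
    pixel_size_um: float
    section_index: int
    axial_position_um: float
    node_type: str = "AVN"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise SectionIOError(f"pixels must be HxWx3, got {self.pixels.shape}")
        if min(self.pixels.shape[:2]) < 1:
            raise SectionIOError("image must have at least one pixel")
        if not self.pixel_size_um > 0:
            raise SectionIOError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if self.section_index < 0 or self.axial_position_um < 0:
            raise SectionIOError("section_index and axial_position_um must be nonnegative")
        if self.node_type not in NODE_TYPES:
            raise SectionIOError(f"node_type must be one of {NODE_TYPES}, got {self.node_type!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class SectionMasks:
    """Binary masks for one section: node, surface trace, and all tissue."""

    node_mask: np.ndarray
    surface_mask: np.ndarray
    tissue_mask: np.ndarray
    region_label: str = "none"

    def __post_init__(self) -> None:
        self.node_mask = np.asarray(self.node_mask, dtype=bool)
        self.surface_mask = np.asarray(self.surface_mask, dtype=bool)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        shapes = {self.node_mask.shape, self.surface_mask.shape, self.tissue_mask.shape}
        if len(shapes) != 1:
            raise SectionIOError(f"mask shapes differ: {sorted(shapes)}")
        if self.region_label not in REGION_LABELS:
            raise SectionIOError(
                f"region_label must be one of {REGION_LABELS}, got {self.region_label!r}"
            )
        if np.any(self.node_mask & ~self.tissue_mask):
            raise SectionIOError("node_mask must be a subset of tissue_mask")

    @property
    def node_absent(self) -> bool:
        return not self.node_mask.any()


@dataclass
class HeartDataset:
    """An ordered serial stack from one node region of one heart."""

    heart_id: str
    age_months: float
    node_type: str
    section_interval_um: float
    sections: list[tuple[SectionImage, SectionMasks]] = field(default_factory=list)
    alignment_origin_index: int | None = None

    def __post_init__(self) -> None:
        if not self.age_months > 0:
            raise SectionIOError(f"age_months must be positive, got {self.age_months}")
        if self.node_type not in NODE_TYPES:
            raise SectionIOError(f"node_type must be one of {NODE_TYPES}")
        if not self.section_interval_um > 0:
            raise SectionIOError("section_interval_um must be positive")
        indices = [img.section_index for img, _ in self.sections]
        if indices != sorted(indices) or len(set(indices)) != len(indices):
            raise SectionIOError(f"section indices must be strictly increasing, got {indices}")
        for img, masks in self.sections:
            if masks.node_mask.shape != img.shape:
                raise SectionIOError(
                    f"mask shape {masks.node_mask.shape} does not match image {img.shape} "
                    f"(section {img.section_index})"
                )
            expected = img.section_index * self.section_interval_um
            if abs(img.axial_position_um - expected) > 1e-6 * max(1.0, expected):
                raise SectionIOError(
                    f"axial_position_um {img.axial_position_um} != "
                    f"section_index*interval {expected} (section {img.section_index})"
                )
        if self.alignment_origin_index is not None:
            if self.alignment_origin_index not in indices:
                raise SectionIOError(
                    f"alignment_origin_index {self.alignment_origin_index} not among "
                    f"section indices {indices}"
                )

    def __len__(self) -> int:
        return len(self.sections)


def _mask_to_png(mask: np.ndarray, path: Path) -> None:
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)


def _png_to_mask(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path)) >= 128


def write_heart(dataset: HeartDataset, directory: str | Path, force: bool = False) -> Path:
    """Persist a heart dataset (TIFF images, PNG masks, JSON sidecar)."""
    directory = Path(directory)
    sidecar = directory / _SIDECAR
    if sidecar.exists() and not force:
        raise FileExistsError(f"{sidecar} exists; pass force=True to overwrite")
    directory.mkdir(parents=True, exist_ok=True)

    meta_sections = []
    for img, masks in dataset.sections:
        stem = f"section_{img.section_index:03d}"
        tifffile.imwrite(directory / f"{stem}_image.tif", img.pixels)
        _mask_to_png(masks.surface_mask, directory / f"{stem}_surface.png")
        _mask_to_png(masks.tissue_mask, directory / f"{stem}_tissue.png")
        if not masks.node_absent:
            _mask_to_png(masks.node_mask, directory / f"{stem}_node.png")
        meta_sections.append(
            {
                "section_index": img.section_index,
                "axial_position_um": img.axial_position_um,
                "pixel_size_um": img.pixel_size_um,
                "region_label": masks.region_label,
                "node_absent": masks.node_absent,
            }
        )
    meta = {
        "heart_id": dataset.heart_id,
        "age_months": dataset.age_months,
        "node_type": dataset.node_type,
        "section_interval_um": dataset.section_interval_um,
        "alignment_origin_index": dataset.alignment_origin_index,
        "sections": meta_sections,
    }
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return directory


def load_heart(directory: str | Path) -> HeartDataset:
    """Load and validate a heart dataset written by :func:`write_heart`.

    Sections with a missing node mask are permitted only when the sidecar
    flags them ``node_absent``; every other inconsistency raises
    :class:`SectionIOError` naming the offending section.
    """
    directory = Path(directory)
    sidecar = directory / _SIDECAR
    if not sidecar.exists():
        raise SectionIOError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("heart_id", "age_months", "node_type", "section_interval_um", "sections"):
        if key not in meta:
            raise SectionIOError(f"sidecar missing required key {key!r}")

    sections: list[tuple[SectionImage, SectionMasks]] = []
    for sec in meta["sections"]:
        idx = int(sec["section_index"])
        stem = f"section_{idx:03d}"
        if "pixel_size_um" not in sec:
            raise SectionIOError(f"section {idx}: missing pixel_size_um")
        img_path = directory / f"{stem}_image.tif"
        if not img_path.exists():
            raise SectionIOError(f"section {idx}: missing image {img_path.name}")
        pixels = tifffile.imread(img_path)
        img = SectionImage(
            pixels=pixels,
            pixel_size_um=float(sec["pixel_size_um"]),
            section_index=idx,
            axial_position_um=float(sec["axial_position_um"]),
            node_type=meta["node_type"],
        )
        surface = _png_to_mask(directory / f"{stem}_surface.png")
        tissue = _png_to_mask(directory / f"{stem}_tissue.png")
        node_path = directory / f"{stem}_node.png"
        if node_path.exists():
            node = _png_to_mask(node_path)
        elif sec.get("node_absent", False):
            node = np.zeros_like(tissue)
        else:
            raise SectionIOError(
                f"section {idx}: node mask missing and not flagged node_absent"
            )
        masks = SectionMasks(
            node_mask=node,
            surface_mask=surface,
            tissue_mask=tissue,
            region_label=sec.get("region_label", "none"),
        )
        sections.append((img, masks))

    return HeartDataset(
        heart_id=str(meta["heart_id"]),
        age_months=float(meta["age_months"]),
        node_type=str(meta["node_type"]),
        section_interval_um=float(meta["section_interval_um"]),
        sections=sections,
        alignment_origin_index=(
            None
            if meta.get("alignment_origin_index") is None
            else int(meta["alignment_origin_index"])
        ),
    )


def write_results(tables: Mapping[str, pd.DataFrame], directory: str | Path) -> dict[str, Path]:
    """Write result tables as CSV with unit-suffixed column names.

    ``tables`` maps a table name (e.g. ``"depth"``) to a DataFrame; each is
    written to ``<directory>/<name>.csv``. Floats are written with 10
    significant digits so a round-trip preserves at least 6.
    """
    if not tables:
        raise ValueError("tables must be nonempty")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        paths[name] = path
    return paths


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
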