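"""Well-plate image handling: layout geometry, ROI location, channel statistics.

A plate image is an 8-bit sRGB raster of a standard 96-well (8x12) microplate
captured on a flatbed-scanner imaging fixture.  Because the fixture holds the
plate in a fixed position, wells are located from the layout's template grid
rather than by blob detection; an optional brightness-centroid refinement
(a few pixels) is available for slightly misregistered scans.

Each well is reduced to the mean R, G and B intensity over a central disk ROI
(default 60 % of the well radius, avoiding meniscus and edge shading).  The
mean red intensity is the primary response variable of the Cr(VI) assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk

ROW_LABELS = "ABCDEFGH"
N_ROWS = 8
N_COLS = 12

__all__ = [
    "PlateImage",
    "PlateGeometry",
    "WellAssignment",
    "PlateLayout",
    "WellROI",
    "WellFeature",
    "locate_wells",
    "extract_well_features",
    "features_to_frame",
    "well_labels",
]


def well_labels() -> list[str]:
    """All 96 well labels, row-major: A1..A12, B1..B12, ..., H12."""
    return [f"{r}{c}" for r in ROW_LABELS for c in range(1, N_COLS + 1)]


@dataclass
class PlateImage:
    """An 8-bit RGB raster with resolution metadata.

    pixels has shape (height, width, 3), dtype uint8; dpi is the scan
    resolution in dots per inch.
    """

    pixels: np.ndarray
    dpi: float = 600.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must have shape (height, width, 3)")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @classmethod
    def from_file(cls, path: str | Path, dpi: float = 600.0) -> "PlateImage":
        """Read a PNG or TIFF plate scan (8-bit RGB; alpha dropped if present)."""
        arr = iio.imread(path)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[-1] == 4:
            arr = arr[..., :3]
        return cls(pixels=arr, dpi=dpi)

    def to_file(self, path: str | Path) -> None:
        iio.imwrite(path, self.pixels)


@dataclass(frozen=True)
class PlateGeometry:
    """Template grid of well centers, in pixel coordinates (origin top-left).

    x0, y0: center of well A1; dx, dy: center-to-center spacing; well_radius:
    physical well radius in pixels.
    """

    x0: float
    y0: float
    dx: float
    dy: float
    well_radius: float

    def center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) center of the well at 0-based (row, col)."""
        return (self.x0 + col * self.dx, self.y0 + row * self.dy)


@dataclass(frozen=True)
class WellAssignment:
    """Role of one well: blank, standard (known ppb) or unknown sample."""

    role: str  # "blank" | "standard" | "unknown"
    conc_ppb: float | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("blank", "standard", "unknown"):
            raise ValueError(f"unknown well role: {self.role!r}")
        if self.role == "standard":
            if self.conc_ppb is None or self.conc_ppb < 0:
                raise ValueError("standard wells need a concentration >= 0 ppb")
        if self.role == "unknown" and not self.sample_id:
            raise ValueError("unknown wells need a sample_id")


@dataclass
class PlateLayout:
    """A 96-well plate layout: geometry plus per-well assignments."""

    geometry: PlateGeometry
    wells: Mapping[str, WellAssignment] = field(default_factory=dict)
    n_rows: int = N_ROWS
    n_cols: int = N_COLS

    def __post_init__(self) -> None:
        valid = set(well_labels())
        for label in self.wells:
            if label not in valid:
                raise ValueError(f"invalid well label: {label!r}")

    @staticmethod
    def parse_label(label: str) -> tuple[int, int]:
        """'C7' -> (2, 6), 0-based (row, col)."""
        row = ROW_LABELS.index(label[0])
        col = int(label[1:]) - 1
        if not 0 <= col < N_COLS:
            raise ValueError(f"invalid well label: {label!r}")
        return row, col

    def center(self, label: str) -> tuple[float, float]:
        row, col = self.parse_label(label)
        return self.geometry.center(row, col)

    def labels(self) -> list[str]:
        """Assigned well labels in row-major plate order."""
        order = {lab: i for i, lab in enumerate(well_labels())}
        return sorted(self.wells, key=order.__getitem__)


@dataclass(frozen=True)
class WellROI:
    """A disk region of interest for one well, pixel coordinates."""

    well: str
    cx: float
    cy: float
    radius: float

    def pixel_indices(self, shape: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) index arrays of the disk, clipped to the image shape."""
        return disk((self.cy, self.cx), self.radius, shape=shape[:2])


@dataclass(frozen=True)
class WellFeature:
    """Per-well color statistics over the ROI pixels (0-255 scale, fractional)."""

    well: str
    mean_r: float
    mean_g: float
    mean_b: float
    composite_rgb: float
    n_pixels: int


def locate_wells(
    image: PlateImage,
    layout: PlateLayout,
    roi_fraction: float = 0.6,
    refine: bool = False,
    refine_radius_px: int = 3,
) -> list[WellROI]:
    """Place one disk ROI per well of the full 8x12 grid.

    ROIs are disks of radius ``roi_fraction * well_radius`` centered on the
    layout's template grid.  With ``refine=True`` each center is nudged (at
    most ``refine_radius_px`` pixels) to the brightness-weighted centroid of
    its neighbourhood, for scans that are slightly off the template.

    Raises ValueError if any ROI would be degenerate or fall outside the
    image bounds (the offending well is named).
    """
    if roi_fraction <= 0:
        raise ValueError("roi_fraction must be positive (got a degenerate ROI)")
    r = roi_fraction * layout.geometry.well_radius
    if r < 0.5:
        raise ValueError("ROI radius below half a pixel; nothing to average")
    h, w = image.height_px, image.width_px
    rois: list[WellROI] = []
    for label in well_labels():
        cx, cy = layout.center(label)
        if refine:
            cx, cy = _refine_center(image.pixels, cx, cy, r, refine_radius_px)
        if cx - r < 0 or cy - r < 0 or cx + r > w or cy + r > h:
            raise ValueError(
                f"well {label}: ROI (center=({cx:.1f},{cy:.1f}), r={r:.1f}) "
                f"falls outside the {w}x{h} image"
            )
        rois.append(WellROI(well=label, cx=cx, cy=cy, radius=r))
    return rois


def _refine_center(
    pixels: np.ndarray, cx: float, cy: float, r: float, max_shift: int
) -> tuple[float, float]:
    """Brightness-centroid refinement within +/- max_shift pixels."""
    h, w = pixels.shape[:2]
    y0 = max(int(cy - r - max_shift), 0)
    y1 = min(int(cy + r + max_shift) + 1, h)
    x0 = max(int(cx - r - max_shift), 0)
    x1 = min(int(cx + r + max_shift) + 1, w)
    patch = pixels[y0:y1, x0:x1].astype(float).sum(axis=2)
    total = patch.sum()
    if total == 0:
        return cx, cy
    ys, xs = np.mgrid[y0:y1, x0:x1]
    ncy = float((ys * patch).sum() / total)
    ncx = float((xs * patch).sum() / total)
    ncy = min(max(ncy, cy - max_shift), cy + max_shift)
    ncx = min(max(ncx, cx - max_shift), cx + max_shift)
    return ncx, ncy


def extract_well_features(
    image: PlateImage,
    rois: Sequence[WellROI],
    statistic: str = "mean",
) -> list[WellFeature]:
    """Reduce each ROI to per-channel statistics.

    statistic: "mean" (default, the assay's response definition) or "median"
    for robustness to specks.  composite_rgb is always the sum of the three
    per-channel statistics.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic: {statistic!r}")
    reduce = np.mean if statistic == "mean" else np.median
    pixels = image.pixels
    out: list[WellFeature] = []
    for roi in rois:
        rr, cc = roi.pixel_indices(pixels.shape)
        if rr.size == 0:
            raise ValueError(f"well {roi.well}: empty ROI")
        vals = pixels[rr, cc, :].astype(float)
        mr = float(reduce(vals[:, 0]))
        mg = float(reduce(vals[:, 1]))
        mb = float(reduce(vals[:, 2]))
        out.append(
            WellFeature(
                well=roi.well,
                mean_r=mr,
                mean_g=mg,
                mean_b=mb,
                composite_rgb=mr + mg + mb,
                n_pixels=int(rr.size),
            )
        )
    return out


def features_to_frame(features: Iterable[WellFeature]) -> pd.DataFrame:
    """Tabulate WellFeatures (columns well, mean_r, mean_g, mean_b, composite_rgb, n_pixels)."""
    return pd.DataFrame(
        [
            {
                "well": f.well,
                "mean_r": f.mean_r,
                "mean_g": f.mean_g,
                "mean_b": f.mean_b,
                "composite_rgb": f.composite_rgb,
                "n_pixels": f.n_pixels,
            }
            for f in features
        ]
    )
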