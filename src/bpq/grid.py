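"""Shared raster containers: metric image grids and region label maps.

Conventions used throughout the package:

* arrays are row-major, 0-based, with the origin at the *center* of pixel
  ``(0, 0)``;
* physical coordinates are in micrometres with x increasing along columns
  and y *decreasing* along rows (image row 0 is the top of the frame);
* areas are ``pixel count * pixel_size**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Integer codes of the region label map.
BACKGROUND = 0
TRUNK = 1
TIP_STEM = 2
TIP_LEFT = 3
TIP_RIGHT = 4

LABEL_NAMES = {
    BACKGROUND: "background",
    TRUNK: "trunk",
    TIP_STEM: "tip_stem",
    TIP_LEFT: "tip_left",
    TIP_RIGHT: "tip_right",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

TIP_LABELS = (TIP_STEM, TIP_LEFT, TIP_RIGHT)

#: Region groups used by the per-region reports.
GROUPS = {"tips": TIP_LABELS, "trunk": (TRUNK,)}


@dataclass
class ImageGrid:
    """A 2D scalar (or boolean) image with metric pixel size.

    Parameters
    ----------
    pixels
        2D array; dtype is preserved (bool for masks, float for channels).
    pixel_size
        Edge length of one pixel in micrometres.
    origin
        ``(x, y)`` micrometre coordinates of the center of pixel ``(0, 0)``.
        y decreases as the row index increases.
    """

    pixels: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def like(self, pixels: np.ndarray) -> "ImageGrid":
        """A new grid on the same frame with different pixel values."""
        if np.shape(pixels) != self.pixels.shape:
            raise ValueError("pixel array shape mismatch")
        return ImageGrid(np.asarray(pixels), self.pixel_size, self.origin)

    def pixel_coords_um(self, rows: np.ndarray, cols: np.ndarray):
        """Micrometre ``(x, y)`` coordinates of pixel centers."""
        x0, y0 = self.origin
        return (x0 + np.asarray(cols) * self.pixel_size,
                y0 - np.asarray(rows) * self.pixel_size)

    def extent_um(self) -> tuple[float, float, float, float]:
        """Frame extent ``(xmin, xmax, ymin, ymax)`` of pixel centers."""
        nr, nc = self.pixels.shape
        x0, y0 = self.origin
        return (x0, x0 + (nc - 1) * self.pixel_size,
                y0 - (nr - 1) * self.pixel_size, y0)

    def foreground_area_um2(self) -> float:
        return float(np.count_nonzero(self.pixels)) * self.pixel_size**2


@dataclass
class LabeledPartition:
    """Per-pixel sub-region labels over an :class:`ImageGrid` frame.

    Labels are mutually exclusive integers from :data:`LABEL_NAMES`; the
    non-background labels tile the foreground of the mask the partition was
    derived from, exactly.
    """

    labels: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 2D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        unknown = set(np.unique(self.labels)) - set(LABEL_NAMES)
        if unknown:
            raise ValueError(f"unknown label codes: {sorted(unknown)}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def foreground(self) -> np.ndarray:
        return self.labels != BACKGROUND

    def label_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean mask of a region group (``"tips"`` or ``"trunk"``)."""
        if group not in GROUPS:
            raise ValueError(f"unknown region group {group!r}")
        return np.isin(self.labels, GROUPS[group])

    def area_um2(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.pixel_size**2

    def areas_by_name(self) -> dict[str, float]:
        return {LABEL_NAMES[c]: self.area_um2(c)
                for c in (TRUNK, TIP_STEM, TIP_LEFT, TIP_RIGHT)}
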