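"""Image quantification readouts.

Implements the analysis procedures applied to the culture images: growth
expansion between two culture days, invasion extraction by morphological
opening with outline-length normalization, Ki67/DAPI proliferation ratio,
nucleus-level viability, and confluence normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .geometry import outline_length
from .grid import (GROUPS, LABEL_NAMES, TIP_LABELS, TRUNK, ImageGrid,
                   LabeledPartition)

logger = logging.getLogger(__name__)

__all__ = ["GrowthReport", "InvasionReport", "ProliferationReport",
           "ViabilityReport", "ConfluenceSeries",
           "segment_culture", "growth_expansion", "extract_invasion",
           "invasion_per_region", "ki67_ratio", "viability",
           "confluence_series"]

REGION_KEYS = ("tips", "trunk", "tip_stem", "tip_left", "tip_right")


def _region_masks(partition: LabeledPartition) -> dict[str, np.ndarray]:
    out = {name: partition.group_mask(name) for name in GROUPS}
    for lab in TIP_LABELS:
        out[LABEL_NAMES[lab]] = partition.label_mask(lab)
    return out


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _fill_small_holes(fg: np.ndarray, max_px: int) -> np.ndarray:
    """Fill background components fully enclosed by foreground and smaller
    than ``max_px`` pixels."""
    holes, n = ndi.label(~fg)
    if n == 0:
        return fg
    border = np.unique(np.concatenate([
        holes[0], holes[-1], holes[:, 0], holes[:, -1]]))
    sizes = ndi.sum_labels(np.ones_like(holes), holes,
                           index=np.arange(1, n + 1))
    fill = np.flatnonzero(sizes < max_px) + 1
    fill = np.setdiff1d(fill, border)
    return fg | np.isin(holes, fill)

def segment_culture(image: ImageGrid, method: str = "otsu",
                    threshold: float | None = None, invert: bool = False,
                    fill_holes_px: int = 100) -> ImageGrid:
    """Segment a culture image into a binary foreground mask.

    ``method`` is ``"otsu"`` or ``"fixed"`` (requires ``threshold``).
    ``invert`` flips contrast polarity for dark-foreground images. Holes
    smaller than ``fill_holes_px`` pixels are filled. Deterministic.
    """
    img = np.asarray(image.pixels, dtype=float)
    if invert:
        img = -img
    if method == "otsu":
        if np.ptp(img) == 0:
            raise ValueError("constant image: Otsu threshold is undefined")
        thr = threshold_otsu(img)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = -threshold if invert else threshold
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    fg = img > thr
    if fill_holes_px > 0 and fg.any():
        fg = _fill_small_holes(fg, fill_holes_px)
    logger.info("segment_culture: method=%s threshold=%.6g invert=%s",
                method, thr, invert)
    return image.like(fg)


# ---------------------------------------------------------------------------
# growth expansion
# ---------------------------------------------------------------------------

@dataclass
class GrowthReport:
    """Per-region areas at two culture days and their expansion ratios."""

    area_day3_um2: dict[str, float]
    area_day14_um2: dict[str, float]
    expansion_ratio: dict[str, float]
    percent_change: dict[str, float]
    undefined: set = field(default_factory=set)

    def to_rows(self) -> list[dict]:
        return [{"region": k,
                 "area_day3_um2": self.area_day3_um2[k],
                 "area_day14_um2": self.area_day14_um2[k],
                 "expansion_ratio": self.expansion_ratio[k],
                 "percent_change": self.percent_change[k]}
                for k in REGION_KEYS]


def growth_expansion(mask_d3: ImageGrid, mask_d14: ImageGrid,
                     partition: LabeledPartition) -> GrowthReport:
    """Relative area change per sub-region between two registered masks.

    The expansion ratio of a region is area(day14 ∩ region) /
    area(day3 ∩ region); regions with zero day-3 area are flagged
    ``undefined`` (NaN ratio) instead of raising.
    """
    if mask_d3.shape != mask_d14.shape or mask_d3.shape != partition.shape:
        raise ValueError("masks and partition must share one grid")
    f3 = np.asarray(mask_d3.pixels).astype(bool)
    f14 = np.asarray(mask_d14.pixels).astype(bool)
    px2 = partition.pixel_size**2
    a3, a14, ratio, pct = {}, {}, {}, {}
    undefined = set()
    for name, region in _region_masks(partition).items():
        a3[name] = float(np.count_nonzero(f3 & region)) * px2
        a14[name] = float(np.count_nonzero(f14 & region)) * px2
        if a3[name] == 0:
            undefined.add(name)
            ratio[name] = float("nan")
            pct[name] = float("nan")
            logger.warning("growth_expansion: zero day-3 area in %s; "
                           "ratio undefined", name)
        else:
            ratio[name] = a14[name] / a3[name]
            pct[name] = 100.0 * (ratio[name] - 1.0)
    return GrowthReport(a3, a14, ratio, pct, undefined)


# ---------------------------------------------------------------------------
# invasion
# ---------------------------------------------------------------------------

def _binary_opening(fg: np.ndarray, radius_px: int) -> np.ndarray:
    """Opening with a disk, zero-padded borders."""
    footprint = disk(radius_px)
    eroded = ndi.binary_erosion(fg, structure=footprint, border_value=0)
    return ndi.binary_dilation(eroded, structure=footprint, border_value=0)


def extract_invasion(mask: ImageGrid, opening_radius: int,
                     min_component: int = 0) -> tuple[ImageGrid, ImageGrid]:
    """Split a segmented culture into its main structure and invasions.

    The main structure is the largest connected component of the
    morphological opening of the mask with a disk of ``opening_radius``
    pixels (the largest-component step is a reproducible surrogate for the
    manual erasing of residual invasions). The invasion mask is the
    remainder, with connected components smaller than ``min_component``
    pixels discarded as noise.
    """
    if opening_radius < 1:
        raise ValueError("opening_radius must be >= 1 pixel")
    fg = np.asarray(mask.pixels).astype(bool)
    opened = _binary_opening(fg, int(opening_radius))
    if not opened.any():
        raise ValueError(
            f"opening with radius {opening_radius} px removed the entire "
            "structure; the radius exceeds the structure half-width")
    labels, n = ndi.label(opened)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    main = labels == (1 + int(np.argmax(sizes)))
    invasion = fg & ~main
    if min_component > 0 and invasion.any():
        ilab, ni = ndi.label(invasion)
        isz = ndi.sum_labels(np.ones_like(ilab), ilab, index=np.arange(1, ni + 1))
        keep = np.flatnonzero(isz >= min_component) + 1
        invasion = np.isin(ilab, keep)
    return mask.like(main), mask.like(invasion)


@dataclass
class InvasionReport:
    """Invasion area per region group, normalized by outline length."""

    main_area_um2: float
    invasion_area_um2: dict[str, float]      # per group {tips, trunk}
    outline_length_um: dict[str, float]
    normalized_invasion: dict[str, float]    # µm²/µm
    opening_radius_px: int | None = None

    def to_rows(self) -> list[dict]:
        return [{"region": g,
                 "invasion_area_um2": self.invasion_area_um2[g],
                 "outline_length_um": self.outline_length_um[g],
                 "normalized_invasion_um": self.normalized_invasion[g]}
                for g in ("tips", "trunk")]


def invasion_per_region(invasion_mask: ImageGrid, main_mask: ImageGrid,
                        partition: LabeledPartition,
                        opening_radius_px: int | None = None) -> InvasionReport:
    """Assign invasion pixels to region groups and normalize by outline.

    Each invasion pixel takes the group (tips/trunk) of the nearest outline
    pixel of the main structure; the group's invasion area is divided by
    its outline length (mean tip outline for the tips group).
    """
    if invasion_mask.shape != main_mask.shape or main_mask.shape != partition.shape:
        raise ValueError("masks and partition must share one grid")
    main = np.asarray(main_mask.pixels).astype(bool)
    inv = np.asarray(invasion_mask.pixels).astype(bool)
    if not main.any():
        raise ValueError("main mask is empty: no outline to normalize against")
    boundary = main & ~ndi.binary_erosion(main, border_value=0)
    bcoords = np.argwhere(boundary)
    blabels = partition.labels[boundary]
    px2 = partition.pixel_size**2

    areas = {"tips": 0.0, "trunk": 0.0}
    if inv.any():
        icoords = np.argwhere(inv)
        _, idx = cKDTree(bcoords).query(icoords)
        nearest = blabels[idx]
        areas["tips"] = float(np.count_nonzero(np.isin(nearest, TIP_LABELS))) * px2
        areas["trunk"] = float(np.count_nonzero(nearest == TRUNK)) * px2

    lengths = {g: outline_length(partition, main_mask, g) for g in ("tips", "trunk")}
    normalized = {g: (areas[g] / lengths[g] if lengths[g] > 0 else float("nan"))
                  for g in ("tips", "trunk")}
    return InvasionReport(
        main_area_um2=float(np.count_nonzero(main)) * px2,
        invasion_area_um2=areas, outline_length_um=lengths,
        normalized_invasion=normalized, opening_radius_px=opening_radius_px)


# ---------------------------------------------------------------------------
# proliferation
# ---------------------------------------------------------------------------

@dataclass
class ProliferationReport:
    """Ki67/DAPI signal-area ratio per sub-region and per group."""

    dapi_area_um2: dict[str, float]
    ki67_area_um2: dict[str, float]
    ratio: dict[str, float]
    undefined: set = field(default_factory=set)

    def to_rows(self) -> list[dict]:
        return [{"region": k, "dapi_area_um2": self.dapi_area_um2[k],
                 "ki67_area_um2": self.ki67_area_um2[k],
                 "ki67_ratio": self.ratio[k]} for k in REGION_KEYS]


def _channel_mask(image: ImageGrid, method: str, threshold: float) -> np.ndarray:
    img = np.asarray(image.pixels, dtype=float)
    if method == "otsu":
        if np.ptp(img) == 0:
            return np.zeros(img.shape, dtype=bool)  # blank channel: no signal
        return img > threshold_otsu(img)
    if method == "fixed":
        return img > threshold
    raise ValueError(f"unknown channel segmentation method {method!r}")


def ki67_ratio(dapi: ImageGrid, ki67: ImageGrid, partition: LabeledPartition,
               method: str = "fixed", threshold: float = 0.25
               ) -> ProliferationReport:
    """Ki67-positive fraction of the nuclear signal area, per region.

    Both channels are thresholded; the Ki67 mask is intersected with the
    DAPI mask so the ratio stays in [0, 1]. Group values pool the areas of
    their sub-regions. Regions with zero DAPI area are flagged undefined.
    """
    if dapi.shape != ki67.shape or dapi.shape != partition.shape:
        raise ValueError("channels and partition must share one grid")
    dmask = _channel_mask(dapi, method, threshold)
    kmask = _channel_mask(ki67, method, threshold) & dmask
    px2 = partition.pixel_size**2
    dareas, kareas, ratio = {}, {}, {}
    undefined = set()
    for name, region in _region_masks(partition).items():
        dareas[name] = float(np.count_nonzero(dmask & region)) * px2
        kareas[name] = float(np.count_nonzero(kmask & region)) * px2
        if dareas[name] == 0:
            undefined.add(name)
            ratio[name] = float("nan")
            logger.warning("ki67_ratio: zero DAPI area in %s; ratio undefined",
                           name)
        else:
            ratio[name] = kareas[name] / dareas[name]
    return ProliferationReport(dareas, kareas, ratio, undefined)


# ---------------------------------------------------------------------------
# viability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViabilityReport:
    n_nuclei: int
    n_pi_positive: int
    viability_percent: float


def viability(dapi: ImageGrid, pi: ImageGrid, dapi_threshold: float = 0.3,
              pi_threshold: float = 0.3, min_distance_px: int = 1
              ) -> ViabilityReport:
    """Fraction of live nuclei from the DAPI and propidium-iodide channels.

    Nuclei are DAPI local maxima above ``dapi_threshold``; a nucleus is
    dead when the PI signal at its position exceeds ``pi_threshold``.
    """
    if dapi.shape != pi.shape:
        raise ValueError("channels must share one grid")
    peaks = peak_local_max(np.asarray(dapi.pixels, dtype=float),
                           min_distance=min_distance_px,
                           threshold_abs=dapi_threshold)
    if len(peaks) == 0:
        raise ValueError("no nuclei detected in the DAPI channel")
    pi_vals = np.asarray(pi.pixels, dtype=float)[peaks[:, 0], peaks[:, 1]]
    n_dead = int(np.count_nonzero(pi_vals > pi_threshold))
    return ViabilityReport(
        n_nuclei=len(peaks), n_pi_positive=n_dead,
        viability_percent=100.0 * (1.0 - n_dead / len(peaks)))


# ---------------------------------------------------------------------------
# confluence
# ---------------------------------------------------------------------------

@dataclass
class ConfluenceSeries:
    """Foreground fraction over time, normalized to the 0-h frame."""

    times_h: np.ndarray
    confluence: np.ndarray
    normalized: np.ndarray


def confluence_series(frames, times_h) -> ConfluenceSeries:
    """Per-frame confluence (foreground fraction) normalized to t = 0.

    ``frames`` are binary masks on one grid; ``times_h`` must be strictly
    increasing and start at 0.
    """
    times = np.asarray(times_h, dtype=float)
    if len(frames) == 0 or len(frames) != len(times):
        raise ValueError("need one timepoint per frame")
    if times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and start at 0")
    conf = np.array([np.count_nonzero(f.pixels) / f.pixels.size
                     for f in frames])
    if conf[0] == 0:
        raise ValueError("zero confluence at the 0-h frame; "
                         "normalization undefined")
    return ConfluenceSeries(times, conf, conf / conf[0])
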