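"""Printable Y-structure geometry.

Defines the parametric Y design, rasterizes it to binary masks, partitions
mask foregrounds into tip/trunk sub-regions by nearest skeleton point, and
emits/parses the extrusion toolpath as RepRap-dialect G-code.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import find_contours
from skimage.morphology import skeletonize

from .grid import (BACKGROUND, GROUPS, LABEL_NAMES, TIP_LABELS, TIP_LEFT,
                   TIP_RIGHT, TIP_STEM, TRUNK, ImageGrid, LabeledPartition)

logger = logging.getLogger(__name__)

__all__ = [
    "StructureDesign", "WellLayout", "RigidTransform",
    "build_y_design", "default_design", "default_well_layout",
    "rasterize_design", "partition_regions", "register_mask",
    "outline_length", "outline_lengths_by_label",
    "emit_gcode", "parse_gcode",
    "measure_stroke_width", "measure_branch_angle",
]

#: Segment order follows the print sequence: stem, then left, then right branch.
SEGMENT_NAMES = ("stem", "left", "right")
SEGMENT_TIP_LABEL = {"stem": TIP_STEM, "left": TIP_LEFT, "right": TIP_RIGHT}


@dataclass(frozen=True)
class StructureDesign:
    """Parametric Y-shape: a stem and two mirror-symmetric branches.

    The stem points along +y from the branch point; the branches point
    downward, each at ``branch_angle / 2`` from the (extended) stem axis, so
    ``branch_angle`` is the full angle between the two branch segments.
    All lengths are micrometres, ``branch_angle`` is degrees.
    """

    stem_length: float
    branch_length: float
    branch_angle: float
    stroke_width: float
    branch_point: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("stem_length", "branch_length", "stroke_width"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.branch_angle < 180:
            raise ValueError("branch_angle must lie strictly between 0 and 180 degrees")

    def skeleton(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """The three skeleton segments as ``(name, branch_point, free_end)``.

        All three share the branch point as their common endpoint.
        """
        bx, by = self.branch_point
        bp = np.array([bx, by], dtype=float)
        half = math.radians(self.branch_angle) / 2.0
        stem_end = bp + [0.0, self.stem_length]
        left_end = bp + [-self.branch_length * math.sin(half),
                         -self.branch_length * math.cos(half)]
        right_end = bp + [self.branch_length * math.sin(half),
                          -self.branch_length * math.cos(half)]
        return [("stem", bp, stem_end), ("left", bp, left_end), ("right", bp, right_end)]

    def skeleton_path(self) -> np.ndarray:
        """Print-order polyline (µm): stem tip -> branch point -> left tip ->
        branch point -> right tip."""
        segs = {name: end for name, _, end in self.skeleton()}
        bp = np.array(self.branch_point, dtype=float)
        return np.array([segs["stem"], bp, segs["left"], bp, segs["right"]])

    def segment_length(self, name: str) -> float:
        return self.stem_length if name == "stem" else self.branch_length


def build_y_design(stem_length: float, branch_length: float,
                   branch_angle: float, stroke_width: float,
                   branch_point: tuple[float, float] = (0.0, 0.0)) -> StructureDesign:
    """Validated constructor for :class:`StructureDesign`."""
    return StructureDesign(stem_length, branch_length, branch_angle,
                           stroke_width, branch_point)


def default_design() -> StructureDesign:
    """100 µm stroke, 60° branch angle; 1 mm stem and branches (assumed)."""
    return build_y_design(1000.0, 1000.0, 60.0, 100.0)


@dataclass(frozen=True)
class WellLayout:
    """Placement of printed structures in one well plus print settings.

    ``designs`` pairs each design with a planar offset (µm) added to its
    coordinates. Speed is mm/s, pressure mbar, cell density cells/ml.
    """

    designs: tuple
    print_speed: float = 1.0
    pressure: float = 5.0
    cell_density: float = 3e6

    def __post_init__(self) -> None:
        if len(self.designs) == 0:
            raise ValueError("layout must contain at least one design")
        if not self.print_speed > 0:
            raise ValueError("print_speed must be > 0")
        boxes = []
        for design, offset in self.designs:
            boxes.append(_footprint_box(design, offset))
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                if _boxes_overlap(boxes[i], boxes[j]):
                    raise ValueError(
                        f"footprints of designs {i} and {j} overlap")


def _footprint_box(design: StructureDesign, offset) -> tuple[float, float, float, float]:
    pts = [design.branch_point] + [end for _, _, end in design.skeleton()]
    pts = np.asarray(pts, dtype=float) + np.asarray(offset, dtype=float)
    r = design.stroke_width / 2.0
    return (pts[:, 0].min() - r, pts[:, 0].max() + r,
            pts[:, 1].min() - r, pts[:, 1].max() + r)


def _boxes_overlap(a, b) -> bool:
    return not (a[1] <= b[0] or b[1] <= a[0] or a[3] <= b[2] or b[3] <= a[2])


def default_well_layout() -> WellLayout:
    """Four Y-structures per well in a 2x2 arrangement, 1 mm/s, 5 mbar."""
    d = default_design()
    spacing = 4000.0
    offsets = [(0.0, 0.0), (spacing, 0.0), (0.0, spacing), (spacing, spacing)]
    return WellLayout(tuple((d, o) for o in offsets))


# ---------------------------------------------------------------------------
# rasterization and partitioning
# ---------------------------------------------------------------------------

def _point_segment_distance(px, py, a, b):
    """Distance from points to segment ``a->b`` and the clipped projection
    parameter t in [0, 1] (t = 1 at the free end ``b``)."""
    ab = b - a
    denom = float(ab @ ab)
    t = ((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    dx = px - (a[0] + t * ab[0])
    dy = py - (a[1] + t * ab[1])
    return np.hypot(dx, dy), t


def rasterize_design(design: StructureDesign, pixel_size: float,
                     pad: float | None = None) -> ImageGrid:
    """Rasterize a design to a binary mask with round-capped strokes.

    Foreground pixels are exactly those whose center lies within
    ``stroke_width / 2`` of the skeleton polyline. The frame is chosen
    symmetric in x about the stem axis so mirroring is a pixel-exact
    ``fliplr``. Deterministic.
    """
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    if pixel_size > design.stroke_width / 4.0:
        raise ValueError(
            f"pixel_size {pixel_size} too coarse for stroke width "
            f"{design.stroke_width} (need pixel_size <= stroke_width/4)")
    if pad is None:
        pad = design.stroke_width / 2.0 + 2.0 * pixel_size
    bx, by = design.branch_point
    segs = design.skeleton()
    pts = np.asarray([design.branch_point] + [end for _, _, end in segs])
    xext = float(np.abs(pts[:, 0] - bx).max())
    nxh = int(math.ceil((xext + pad) / pixel_size))       # half-width in px
    ylo = float(pts[:, 1].min()) - pad
    yhi = float(pts[:, 1].max()) + pad
    nrows = int(math.ceil((yhi - ylo) / pixel_size)) + 1
    ncols = 2 * nxh + 1
    origin = (bx - nxh * pixel_size, yhi)

    xs = origin[0] + np.arange(ncols) * pixel_size
    ys = origin[1] - np.arange(nrows) * pixel_size
    px, py = np.meshgrid(xs, ys)
    dmin = np.full(px.shape, np.inf)
    for _, a, b in segs:
        d, _ = _point_segment_distance(px, py, a, b)
        np.minimum(dmin, d, out=dmin)
    fg = dmin <= design.stroke_width / 2.0
    return ImageGrid(fg, pixel_size, origin)


def partition_regions(mask: ImageGrid, design: StructureDesign,
                      tip_fraction: float = 0.30) -> LabeledPartition:
    """Assign every foreground pixel to a tip or trunk sub-region.

    Each pixel is routed by its nearest skeleton point: if that point lies
    within ``tip_fraction * segment_length`` (arc length) of the segment's
    free endpoint the pixel takes that segment's tip label, otherwise it is
    trunk. Pixels equidistant (within numerical tolerance) to two or more
    segments — the branch-point neighbourhood — are labelled trunk.
    """
    fg = np.asarray(mask.pixels).astype(bool)
    if not fg.any():
        raise ValueError("mask has no foreground pixels")
    if not 0 < tip_fraction < 1:
        raise ValueError("tip_fraction must lie strictly between 0 and 1")
    _check_frames_overlap(mask, design)

    rows, cols = np.nonzero(fg)
    px, py = mask.pixel_coords_um(rows, cols)
    segs = design.skeleton()
    dists = np.empty((3, rows.size))
    tip_dist = np.empty((3, rows.size))  # arc distance from free endpoint
    for i, (name, a, b) in enumerate(segs):
        d, t = _point_segment_distance(px, py, a, b)
        dists[i] = d
        tip_dist[i] = (1.0 - t) * design.segment_length(name)

    order = np.argsort(dists, axis=0)
    best = order[0]
    d_sorted = np.take_along_axis(dists, order, axis=0)
    tol = 1e-9 * max(1.0, design.stem_length + design.branch_length)
    tie = (d_sorted[1] - d_sorted[0]) < tol

    labels_flat = np.full(rows.size, TRUNK, dtype=np.uint8)
    for i, (name, _, _) in enumerate(segs):
        cutoff = tip_fraction * design.segment_length(name)
        in_tip = (best == i) & ~tie & (tip_dist[i] <= cutoff)
        labels_flat[in_tip] = SEGMENT_TIP_LABEL[name]

    labels = np.zeros(fg.shape, dtype=np.uint8)
    labels[rows, cols] = labels_flat
    return LabeledPartition(labels, mask.pixel_size, mask.origin)


def _check_frames_overlap(mask: ImageGrid, design: StructureDesign) -> None:
    xmin, xmax, ymin, ymax = mask.extent_um()
    bx0, bx1, by0, by1 = _footprint_box(design, (0.0, 0.0))
    if bx1 < xmin or bx0 > xmax or by1 < ymin or by0 > ymax:
        raise ValueError(
            "design footprint does not intersect the mask frame; register "
            "the mask to the design frame first (see register_mask)")


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Rigid map ``p' = R(rotation) @ p + translation`` in µm coordinates."""

    rotation_deg: float
    translation_um: tuple[float, float]

    def matrix(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        return np.array([[math.cos(th), -math.sin(th)],
                         [math.sin(th), math.cos(th)]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.matrix().T + np.asarray(self.translation_um)


def _mask_moments(grid: ImageGrid):
    rows, cols = np.nonzero(np.asarray(grid.pixels).astype(bool))
    x, y = grid.pixel_coords_um(rows, cols)
    c = np.array([x.mean(), y.mean()])
    dx, dy = x - c[0], y - c[1]
    cov = np.array([[np.mean(dx * dx), np.mean(dx * dy)],
                    [np.mean(dx * dy), np.mean(dy * dy)]])
    return np.column_stack([x, y]), c, cov


def register_mask(mask: ImageGrid, design: StructureDesign,
                  anisotropy_min: float = 1.05) -> RigidTransform:
    """Rigid transform aligning a mask to the design frame.

    Centroids are matched and the mask's principal axis is rotated onto the
    design's stem axis; the 180° ambiguity of the principal axis is resolved
    by minimizing the symmetric-difference area against the rasterized
    design. No scaling (pixel size is metadata).
    """
    fg = np.asarray(mask.pixels).astype(bool)
    if not fg.any():
        raise ValueError("mask has no foreground pixels")
    ref = rasterize_design(design, mask.pixel_size)
    pts, c_mask, cov = _mask_moments(mask)
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 0 or evals[1] / evals[0] < anisotropy_min:
        raise ValueError(
            "mask is nearly isotropic; principal axis is ill-defined — "
            "supply a manual transform")
    _, c_ref, cov_ref = _mask_moments(ref)
    ang_mask = 0.5 * math.degrees(math.atan2(2 * cov[0, 1], cov[0, 0] - cov[1, 1]))
    ang_ref = 0.5 * math.degrees(math.atan2(2 * cov_ref[0, 1],
                                            cov_ref[0, 0] - cov_ref[1, 1]))
    base = ang_ref - ang_mask

    best = None
    for theta in (base, base + 180.0):
        theta = ((theta + 180.0) % 360.0) - 180.0
        tr = RigidTransform(theta, tuple(c_ref - _rot(theta) @ c_mask))
        mis = _symmetric_difference(tr, pts, ref)
        if best is None or mis < best[0]:
            best = (mis, tr)
    return best[1]


def _rot(theta_deg: float) -> np.ndarray:
    th = math.radians(theta_deg)
    return np.array([[math.cos(th), -math.sin(th)],
                     [math.sin(th), math.cos(th)]])


def _symmetric_difference(tr: RigidTransform, pts: np.ndarray,
                          ref: ImageGrid) -> int:
    moved = tr.apply(pts)
    x0, y0 = ref.origin
    cols = np.round((moved[:, 0] - x0) / ref.pixel_size).astype(int)
    rows = np.round((y0 - moved[:, 1]) / ref.pixel_size).astype(int)
    img = np.zeros(ref.shape, dtype=bool)
    ok = (rows >= 0) & (rows < ref.shape[0]) & (cols >= 0) & (cols < ref.shape[1])
    img[rows[ok], cols[ok]] = True
    out_of_frame = int(np.count_nonzero(~ok))
    return int(np.count_nonzero(img ^ np.asarray(ref.pixels).astype(bool))) + out_of_frame


# ---------------------------------------------------------------------------
# outlines
# ---------------------------------------------------------------------------

def outline_lengths_by_label(partition: LabeledPartition,
                             main_mask: ImageGrid,
                             smooth_sigma_px: float = 1.5) -> dict[int, float]:
    """Marching-squares outline length (µm) of ``main_mask`` apportioned to
    the partition label nearest each contour segment.

    The contour is taken at the 0.5 level of a lightly smoothed copy of the
    mask: on a raw binary image marching squares overestimates the length
    of oblique and curved outlines by several percent (staircase bias).
    """
    fg = np.asarray(main_mask.pixels).astype(bool)
    if not fg.any():
        raise ValueError("main_mask has no foreground pixels")
    if fg.shape != partition.shape:
        raise ValueError("main_mask and partition are on different grids")
    # nearest foreground pixel of the main mask, for label lookup
    _, (ir, ic) = ndi.distance_transform_edt(~fg, return_indices=True)
    lengths: dict[int, float] = {lab: 0.0 for lab in
                                 (TRUNK, TIP_STEM, TIP_LEFT, TIP_RIGHT)}
    surface = fg.astype(float)
    if smooth_sigma_px > 0:
        surface = ndi.gaussian_filter(surface, smooth_sigma_px)
    for contour in find_contours(surface, 0.5):
        steps = np.diff(contour, axis=0)
        seg_len = np.hypot(steps[:, 0], steps[:, 1])
        mids = 0.5 * (contour[:-1] + contour[1:])
        mr = np.clip(np.round(mids[:, 0]).astype(int), 0, fg.shape[0] - 1)
        mc = np.clip(np.round(mids[:, 1]).astype(int), 0, fg.shape[1] - 1)
        labs = partition.labels[ir[mr, mc], ic[mr, mc]]
        for lab in lengths:
            lengths[lab] += float(seg_len[labs == lab].sum())
    return {lab: L * main_mask.pixel_size for lab, L in lengths.items()}


def outline_length(partition: LabeledPartition, main_mask: ImageGrid,
                   region_group: str, smooth_sigma_px: float = 1.5) -> float:
    """Outline length (µm) for a region group.

    For ``"tips"`` this is the *mean* over the three tip sub-regions; for
    ``"trunk"`` it is the trunk outline length.
    """
    if region_group not in GROUPS:
        raise ValueError(f"unknown region group {region_group!r}")
    by_label = outline_lengths_by_label(partition, main_mask, smooth_sigma_px)
    if region_group == "tips":
        return float(np.mean([by_label[lab] for lab in TIP_LABELS]))
    return by_label[TRUNK]


# ---------------------------------------------------------------------------
# G-code
# ---------------------------------------------------------------------------

def emit_gcode(layout: WellLayout, z_height: float = 0.0) -> str:
    """Serialize a well layout as RepRap-dialect G-code text.

    One ``G0`` travel then chained ``G1`` moves per structure, tracing stem
    then left then right branch (the print sequence). Coordinates are mm,
    the feed word is ``print_speed * 60`` (mm/min) on every G1 line, and the
    pneumatic pressure is recorded as a comment.
    """
    feed = layout.print_speed * 60.0
    lines = [
        "; bpq toolpath",
        f"; pressure_mbar: {layout.pressure:g}",
        f"; cell_density_per_ml: {layout.cell_density:g}",
        "G21 ; units mm",
        "G90 ; absolute positioning",
    ]
    for i, (design, offset) in enumerate(layout.designs):
        path_mm = (design.skeleton_path() + np.asarray(offset, dtype=float)) / 1000.0
        lines.append(f"; structure {i}")
        x, y = path_mm[0]
        lines.append(f"G0 X{x:.4f} Y{y:.4f} Z{z_height:.4f}")
        for x, y in path_mm[1:]:
            lines.append(f"G1 X{x:.4f} Y{y:.4f} F{feed:g}")
    return "\n".join(lines) + "\n"


_WORD_RE = re.compile(r"([A-Za-z])([-+]?[0-9]*\.?[0-9]+)")


def parse_gcode(text: str) -> tuple[list[np.ndarray], float | None]:
    """Parse G0/G1 motion into polylines (mm) split at G0 travels.

    Returns ``(polylines, feed_mm_per_min)`` where the feed is the common F
    word of the G1 moves (None if absent). Unknown words are ignored with a
    logged warning; text with no motion commands raises ``ValueError``.
    """
    polylines: list[list[tuple[float, float]]] = []
    current: list[tuple[float, float]] = []
    pos = [0.0, 0.0]
    feeds: set[float] = set()
    n_moves = 0
    for raw in text.splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        words = _WORD_RE.findall(line)
        if not words:
            continue
        cmd = (words[0][0].upper(), words[0][1])
        if cmd[0] != "G" or float(cmd[1]) not in (0.0, 1.0):
            # modal/setup commands (units, positioning, M codes) are expected
            if cmd[0] == "G" and float(cmd[1]) in (20.0, 21.0, 90.0, 91.0) \
                    or cmd[0] in ("M", "T"):
                logger.debug("skipping modal command: %s", line)
            else:
                logger.warning("ignoring unsupported command: %s", line)
            continue
        for letter, value in words[1:]:
            letter = letter.upper()
            if letter == "X":
                pos[0] = float(value)
            elif letter == "Y":
                pos[1] = float(value)
            elif letter == "F":
                feeds.add(float(value))
            elif letter in ("Z", "E"):
                pass
            else:
                logger.warning("ignoring unknown word %s%s", letter, value)
        n_moves += 1
        if float(cmd[1]) == 0.0:  # travel: start a new polyline
            if len(current) > 1:
                polylines.append(current)
            current = [tuple(pos)]
        else:
            current.append(tuple(pos))
    if len(current) > 1:
        polylines.append(current)
    if n_moves == 0:
        raise ValueError("no G0/G1 motion commands found")
    feed = feeds.pop() if len(feeds) == 1 else (None if not feeds else max(feeds))
    return [np.asarray(p) for p in polylines], feed


# ---------------------------------------------------------------------------
# skeleton-based measurements (used by acceptance round-trips)
# ---------------------------------------------------------------------------

def measure_stroke_width(mask: ImageGrid) -> float:
    """Stroke width (µm) as twice the median distance-transform value along
    the morphological skeleton of the mask."""
    fg = np.asarray(mask.pixels).astype(bool)
    if not fg.any():
        raise ValueError("mask has no foreground pixels")
    skel = skeletonize(fg)
    edt = ndi.distance_transform_edt(fg)
    return float(2.0 * np.median(edt[skel]) * mask.pixel_size)


def measure_branch_angle(mask: ImageGrid, exclusion_radius_px: int = 6) -> float:
    """Angle (degrees) between the two branch arms of a Y-shaped mask.

    Skeletonizes the mask, locates the branch point (skeleton pixel with
    three or more skeleton neighbours), and fits a principal direction to
    each of the two downward arms, excluding pixels near the branch point
    where the skeleton is distorted.
    """
    fg = np.asarray(mask.pixels).astype(bool)
    skel = skeletonize(fg)
    nbrs = ndi.convolve(skel.astype(int), np.ones((3, 3), int), mode="constant")
    branch_pts = np.argwhere(skel & (nbrs >= 4))  # self + >=3 neighbours
    if branch_pts.size == 0:
        raise ValueError("no skeleton branch point found")
    bp = branch_pts.mean(axis=0)
    pts = np.argwhere(skel).astype(float)
    rel = pts - bp
    dist = np.hypot(rel[:, 0], rel[:, 1])
    below = rel[:, 0] > 0  # larger row index = below branch point
    dirs = []
    for side in (rel[:, 1] < 0, rel[:, 1] > 0):
        arm = rel[below & side & (dist > exclusion_radius_px)]
        if len(arm) < 2:
            raise ValueError("branch arm too short to fit a direction")
        arm = arm - arm.mean(axis=0)
        _, _, vt = np.linalg.svd(arm, full_matrices=False)
        v = vt[0]
        if v[0] < 0:  # orient away from the branch point (downward)
            v = -v
        dirs.append(v)
    cosang = float(np.clip(dirs[0] @ dirs[1], -1.0, 1.0))
    return math.degrees(math.acos(cosang))
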