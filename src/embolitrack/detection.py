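"""Per-frame bubble-candidate segmentation and rule-based filtering.

The detector works inside a user-seeded region of interest (ROI) bounding the
vessel lumen.  Each frame is thresholded, connected bright components are
extracted, and each component is screened with shape rules (area band, aspect
ratio of the second-moment ellipse, boundary circularity, absence of holes) to
separate bubble highlights from wall/tissue signal.  The ROI is periodically
re-estimated by a wall-gradient method: radial rays from the ROI centroid
search a band around the previous boundary for the strongest intensity edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Polygon
from skimage import measure
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError
from .io_core import Calibration, Frame, px_to_mm

# 8-connectivity: bright blobs with anti-aliased edges fragment under 4-connectivity.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)

#: number of radial rays in the wall-gradient ROI update
N_RAYS = 72
#: half-width of the radial search band, as a fraction of the previous radius
RADIUS_BAND = 0.20
#: circular moving-average window applied to the updated ROI vertices
SMOOTH_WINDOW = 5
#: inward offset (px) from the wall-gradient peak: the ROI bounds the lumen
#: interior, and the peak of a blurred step edge sits mid-edge, so without an
#: inset bright wall pixels leak inside the polygon
WALL_INSET_PX = 1.0


@dataclass
class RegionOfInterest:
    """Closed simple polygon bounding the vessel lumen, in pixel coordinates.

    ``vertices`` is an (N, 2) array of (x, y) points; the polygon is closed
    implicitly (last vertex connects to the first).
    """

    vertices: np.ndarray
    frame_index_updated: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("ROI needs at least 3 (x, y) vertices")
        object.__setattr__(self, "vertices", v)
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("ROI polygon must be simple with positive area")

    # -- geometry ----------------------------------------------------------
    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_px(self) -> float:
        return float(self.polygon.area)

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean raster of the polygon interior on an image of ``shape``."""
        rr, cc = draw_polygon(self.vertices[:, 1], self.vertices[:, 0], shape=shape)
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        return m

    def contains(self, x: float, y: float, tol: float = 0.0) -> bool:
        if tol > 0:
            return bool(self.polygon.buffer(tol).contains(shapely.Point(x, y)))
        return bool(shapely.contains_xy(self.polygon, x, y))

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_rect(cls, x0: float, y0: float, x1: float, y1: float) -> "RegionOfInterest":
        return cls(np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float))

    @classmethod
    def circle(cls, center: Sequence[float], radius: float, n: int = 48) -> "RegionOfInterest":
        theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        cx, cy = center
        verts = np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])
        return cls(verts)


@dataclass(frozen=True)
class DetectionParams:
    """Rule parameters for candidate screening.

    The aspect ratio is minor/major axis length of the region's second-moment
    ellipse, in (0, 1]; the min/max bounds bracket it.  Circularity is
    4*pi*area/perimeter**2, ~1 for a disc.  Defaults are configuration
    defaults, tunable per machine and probe.
    """

    grey_threshold: float | str = "auto"
    aspect_ratio_min: float = 0.33
    aspect_ratio_max: float = 1.0
    area_min_px: float = 2.0
    area_max_px: float = 2000.0
    circularity_min: float = 0.5
    roi_update_period: int = 25

    def __post_init__(self) -> None:
        if isinstance(self.grey_threshold, str):
            if self.grey_threshold != "auto":
                raise ValueError("grey_threshold must be a number or 'auto'")
        elif not 0 <= self.grey_threshold <= 255:
            raise ValueError("grey_threshold must lie in [0, 255]")
        if not 0 < self.aspect_ratio_min <= 1 <= self.aspect_ratio_max:
            raise ValueError("need 0 < aspect_ratio_min <= 1 <= aspect_ratio_max")
        if not 0 < self.area_min_px < self.area_max_px:
            raise ValueError("need 0 < area_min_px < area_max_px")
        if not 0 < self.circularity_min <= 1:
            raise ValueError("circularity_min must lie in (0, 1]")
        if self.roi_update_period < 1:
            raise ValueError("roi_update_period must be >= 1")


@dataclass(frozen=True)
class BubbleSlice:
    """A single-frame filtered detection in physical units."""

    centroid: np.ndarray  # (x, y) in mm
    equivalent_radius: float  # mm, radius of the circle with the region's area
    area: float  # mm^2
    mean_intensity: float
    frame_index: int
    time: float


@dataclass
class CandidateRegion:
    """A connected bright component inside the ROI, prior to rule screening."""

    mask: np.ndarray  # boolean crop
    offset: tuple[int, int]  # (row, col) of the crop in the frame
    centroid_px: np.ndarray  # (x, y)
    area_px: float
    mean_intensity: float
    major_axis: float
    minor_axis: float
    frame_index: int
    time: float


# ---------------------------------------------------------------------------
# Threshold estimation
# ---------------------------------------------------------------------------

#: if more than this fraction of ROI pixels sit at/above the Otsu split, the
#: scene holds no sparse highlights and the threshold is raised above the data.
_SPARSE_FOREGROUND_FRACTION = 0.25


def estimate_threshold(frames: Sequence[Frame], roi: RegionOfInterest) -> float:
    """Estimate an intensity threshold separating speckle from bubble highlights.

    Otsu's criterion restricted to ROI pixels, pooled over the first
    ``min(30, n)`` frames, refined by intermeans iterations (Ridler-Calvard):
    with very few bright pixels the raw Otsu split can settle on the edge of
    the background tail, while the intermeans fixed point sits midway between
    the class means.  Bubbles are sparse: if the split would label more than
    25% of ROI pixels as foreground the scene is treated as background-only
    and the threshold is placed above the brightest pooled pixel with a
    spread-scaled margin (later frames sample deeper into the noise tail).
    Adding a uniform offset ``c`` to all pixels (below clipping) shifts the
    returned threshold by ``c`` up to histogram-binning slack.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("estimate_threshold needs at least one frame")
    m = roi.mask(frames[0].shape)
    if not m.any():
        raise DegenerateInputError("ROI rasterizes to an empty mask")
    pooled = np.concatenate([f.pixels[m].ravel() for f in frames[: min(30, len(frames))]])
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi == 255.0:
        raise DegenerateInputError("ROI fully saturated (all pixels at 255)")
    if lo == hi:
        return min(hi + 0.5, 255.0)
    t = float(threshold_otsu(pooled, nbins=256))
    for _ in range(50):  # intermeans fixed point
        fg, bg = pooled[pooled >= t], pooled[pooled < t]
        if fg.size == 0 or bg.size == 0:
            break
        t_new = 0.5 * (float(fg.mean()) + float(bg.mean()))
        done = abs(t_new - t) < 0.5
        t = t_new
        if done:
            break
    if np.mean(pooled >= t) > _SPARSE_FOREGROUND_FRACTION:
        return min(hi + 0.5 + 3.0 * float(pooled.std()), 255.0)
    return t


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_frame(
    frame: Frame,
    roi: RegionOfInterest,
    params: DetectionParams,
    roi_mask: np.ndarray | None = None,
) -> list[CandidateRegion]:
    """Extract connected bright components inside the ROI.

    Candidates are maximal 8-connected components of
    ``{pixels in ROI with intensity >= grey_threshold}``.  The threshold must
    be numeric here; resolve "auto" via :func:`estimate_threshold` first.
    """
    if isinstance(params.grey_threshold, str):
        raise ValueError("grey_threshold is 'auto'; resolve it with estimate_threshold first")
    if roi_mask is None:
        roi_mask = roi.mask(frame.shape)
    fg = (frame.pixels >= params.grey_threshold) & roi_mask
    labels, n = ndimage.label(fg, structure=_STRUCTURE_8)
    if n == 0:
        return []
    out: list[CandidateRegion] = []
    for rp in measure.regionprops(labels, intensity_image=frame.pixels):
        r0, c0, r1, c1 = rp.bbox
        out.append(
            CandidateRegion(
                mask=rp.image.copy(),
                offset=(r0, c0),
                centroid_px=np.array([rp.centroid[1], rp.centroid[0]]),
                area_px=float(rp.area),
                mean_intensity=float(rp.intensity_mean),
                major_axis=float(rp.axis_major_length),
                minor_axis=float(rp.axis_minor_length),
                frame_index=frame.index,
                time=frame.time,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Boundary-chain perimeter and rule filtering
# ---------------------------------------------------------------------------

# Moore neighbourhood in clockwise order starting west (row, col offsets).
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Outer boundary chain of a connected mask (Moore-neighbour tracing).

    Returns the ordered (row, col) boundary pixels; the chain closes back to
    its start.  A single-pixel mask yields a one-point chain.
    """
    padded = np.pad(mask.astype(bool), 1)
    rows, cols = np.nonzero(padded)
    if rows.size == 0:
        return np.empty((0, 2), dtype=int)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    chain = [start]
    backtrack = (start[0], start[1] - 1)
    current = start
    first_move: tuple[tuple[int, int], tuple[int, int]] | None = None
    while True:
        d = (backtrack[0] - current[0], backtrack[1] - current[1])
        i = _MOORE.index(d)
        nxt = None
        last_bg = backtrack
        for k in range(1, 9):
            dr, dc = _MOORE[(i + k) % 8]
            cand = (current[0] + dr, current[1] + dc)
            if padded[cand]:
                nxt = cand
                break
            last_bg = cand
        if nxt is None:  # isolated pixel
            break
        move = (current, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            chain.pop()  # the re-entry duplicate of start
            break
        chain.append(nxt)
        backtrack = last_bg
        current = nxt
        if len(chain) > 4 * padded.size:  # pragma: no cover - safety net
            raise RuntimeError("boundary trace failed to terminate")
    return np.array(chain, dtype=int)


def boundary_perimeter(mask: np.ndarray) -> float:
    """Perimeter by weighted boundary-step counting (diagonal steps sqrt(2))."""
    chain = trace_boundary(mask)
    if len(chain) < 2:
        return 0.0
    closed = np.vstack([chain, chain[:1]])
    steps = np.diff(closed, axis=0)
    return float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))


def circularity(mask: np.ndarray) -> float:
    """4*pi*A/P^2 with the chain perimeter; degenerate 1-2 px regions count as round."""
    p = boundary_perimeter(mask)
    if p == 0.0:
        return float("inf")
    return 4.0 * math.pi * float(mask.sum()) / p**2


def _has_holes(mask: np.ndarray) -> bool:
    return bool(np.any(ndimage.binary_fill_holes(mask) != mask))


def region_aspect_ratio(region: CandidateRegion) -> float:
    """Minor/major axis length of the second-moment ellipse, in (0, 1]."""
    if region.major_axis == 0.0:
        return 1.0  # point-like region: no orientation, treat as round
    return region.minor_axis / region.major_axis


def filter_candidates(
    regions: Iterable[CandidateRegion],
    params: DetectionParams,
    calibration: Calibration,
) -> list[BubbleSlice]:
    """Apply the embolus screening rules and convert survivors to mm units.

    A region survives iff its pixel area lies in ``[area_min_px, area_max_px]``,
    its aspect ratio in ``[aspect_ratio_min, aspect_ratio_max]``, its
    circularity is at least ``circularity_min``, and its boundary is a single
    closed contour (no interior holes).
    """
    px_area_mm2 = calibration.mm_per_px_x * calibration.mm_per_px_y
    out: list[BubbleSlice] = []
    for reg in regions:
        if not params.area_min_px <= reg.area_px <= params.area_max_px:
            continue
        ar = region_aspect_ratio(reg)
        if not params.aspect_ratio_min <= ar <= params.aspect_ratio_max:
            continue
        if circularity(reg.mask) < params.circularity_min:
            continue
        if _has_holes(reg.mask):
            continue
        area_mm2 = reg.area_px * px_area_mm2
        out.append(
            BubbleSlice(
                centroid=px_to_mm(reg.centroid_px, calibration),
                equivalent_radius=math.sqrt(area_mm2 / math.pi),
                area=area_mm2,
                mean_intensity=reg.mean_intensity,
                frame_index=reg.frame_index,
                time=reg.time,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Wall-gradient ROI update
# ---------------------------------------------------------------------------

def _boundary_radius(poly: Polygon, centroid: np.ndarray, direction: np.ndarray) -> float:
    """Distance from centroid to the polygon boundary along a ray."""
    reach = 4.0 * max(poly.bounds[2] - poly.bounds[0], poly.bounds[3] - poly.bounds[1])
    ray = LineString([centroid, centroid + reach * direction])
    inter = poly.exterior.intersection(ray)
    if inter.is_empty:
        return 0.0
    pts = shapely.get_coordinates(inter)
    dists = np.hypot(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
    return float(dists.max())


def update_roi(
    frame: Frame,
    previous: RegionOfInterest,
    params: DetectionParams,
) -> RegionOfInterest:
    """Re-estimate the ROI boundary by the wall-gradient method.

    For each of ``N_RAYS`` equally spaced rays from the previous ROI centroid,
    the new boundary point is the radius of maximum positive (dark lumen to
    bright wall) outward intensity gradient within +/-20% of the previous
    boundary radius, stepped inward by ``WALL_INSET_PX``; vertices are then
    smoothed with a circular 5-point moving average.  If fewer than half the
    rays find a gradient peak above the noise floor, or smoothing breaks
    polygon simplicity, the previous ROI is returned unchanged.
    """
    if previous.area_px <= 0:  # pragma: no cover - constructor forbids this
        raise ValueError("previous ROI is degenerate")
    poly = previous.polygon
    centroid = previous.centroid
    h, w = frame.shape

    thetas = np.linspace(0.0, 2 * np.pi, N_RAYS, endpoint=False)
    prev_radii = np.empty(N_RAYS)
    profiles = []
    radii_grids = []
    for k, th in enumerate(thetas):
        u = np.array([math.cos(th), math.sin(th)])
        r_prev = _boundary_radius(poly, centroid, u)
        prev_radii[k] = r_prev
        r_lo, r_hi = (1 - RADIUS_BAND) * r_prev, (1 + RADIUS_BAND) * r_prev
        n_samples = max(int(math.ceil((r_hi - r_lo) / 0.5)) + 1, 5)
        rs = np.linspace(r_lo, r_hi, n_samples)
        xs = centroid[0] + rs * u[0]
        ys = centroid[1] + rs * u[1]
        vals = ndimage.map_coordinates(
            frame.pixels, np.vstack([ys, xs]), order=1, mode="nearest"
        )
        profiles.append(np.gradient(vals, rs))
        radii_grids.append(rs)

    all_grad = np.abs(np.concatenate(profiles))
    noise_floor = max(2.0, 3.0 * float(np.median(all_grad)))

    new_radii = prev_radii.copy()
    n_found = 0
    for k in range(N_RAYS):
        # the lumen interior is dark and the wall bright: the boundary is the
        # rising (positive outward) gradient edge, not the wall's far side
        g = profiles[k]
        peak = int(np.argmax(g))
        if g[peak] > noise_floor:
            r_peak = radii_grids[k][peak]
            if 0 < peak < len(g) - 1:  # sub-sample parabolic refinement
                denom = g[peak - 1] - 2 * g[peak] + g[peak + 1]
                if denom < 0:
                    step = radii_grids[k][1] - radii_grids[k][0]
                    r_peak += 0.5 * step * (g[peak - 1] - g[peak + 1]) / denom
            new_radii[k] = max(r_peak - WALL_INSET_PX, 1.0)
            n_found += 1
    if n_found < N_RAYS // 2:
        return previous

    verts = np.column_stack(
        [centroid[0] + new_radii * np.cos(thetas), centroid[1] + new_radii * np.sin(thetas)]
    )
    # circular moving average over vertices; averaging points on an arc pulls
    # them toward the centroid, so rescale by the polygon chord factor
    kernel = np.ones(SMOOTH_WINDOW) / SMOOTH_WINDOW
    pad = SMOOTH_WINDOW // 2
    ext = np.vstack([verts[-pad:], verts, verts[:pad]])
    smoothed = np.column_stack(
        [np.convolve(ext[:, 0], kernel, mode="valid"), np.convolve(ext[:, 1], kernel, mode="valid")]
    )
    shrink = np.mean(np.cos(2 * np.pi * np.arange(-pad, pad + 1) / N_RAYS))
    smoothed = centroid + (smoothed - centroid) / shrink
    smoothed[:, 0] = np.clip(smoothed[:, 0], 0, w - 1)
    smoothed[:, 1] = np.clip(smoothed[:, 1], 0, h - 1)
    if not Polygon(smoothed).is_valid:
        return previous
    return RegionOfInterest(smoothed, frame_index_updated=frame.index)


# ---------------------------------------------------------------------------
# Sequence driver
# ---------------------------------------------------------------------------

def detect_sequence(
    frames: Iterable[Frame],
    roi_seed: RegionOfInterest,
    params: DetectionParams,
    calibration: Calibration,
    return_rois: bool = False,
):
    """Detect bubble slices over a whole frame sequence.

    Equivalent to concatenating ``filter_candidates(segment_frame(...))`` over
    frames, with :func:`update_roi` applied every ``roi_update_period`` frames
    and an "auto" threshold resolved once from the first frames.  Accepts any
    iterable of frames (a generator is consumed lazily after a small buffer
    used for threshold estimation).
    """
    frames = iter(frames)
    buffer: list[Frame] = []
    roi = roi_seed

    if isinstance(params.grey_threshold, str):
        for f in frames:
            buffer.append(f)
            if len(buffer) >= 30:
                break
        if not buffer:
            return ([], []) if return_rois else []
        params = replace(params, grey_threshold=estimate_threshold(buffer, roi))

    slices: list[BubbleSlice] = []
    roi_series: list[tuple[int, RegionOfInterest]] = []
    roi_mask: np.ndarray | None = None

    def process(frame: Frame) -> None:
        nonlocal roi, roi_mask
        if frame.index - roi.frame_index_updated >= params.roi_update_period:
            new_roi = update_roi(frame, roi, params)
            if new_roi is not roi:
                roi = new_roi
                roi_mask = None
            else:
                roi = replace(roi, frame_index_updated=frame.index)
        if roi_mask is None:
            roi_mask = roi.mask(frame.shape)
        roi_series.append((frame.index, roi))
        regions = segment_frame(frame, roi, params, roi_mask=roi_mask)
        slices.extend(filter_candidates(regions, params, calibration))

    for f in buffer:
        process(f)
    for f in frames:
        process(f)
    if return_rois:
        return slices, roi_series
    return slices
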