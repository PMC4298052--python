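"""Synthetic rise-chamber rig: seeded ground truth, ultrasound-like rendering,
and a clean optical reference stream.

The emulated experiment: air bubbles of radius 0.1-1.5 mm rise at constant
speed through a horizontal imaging plane inside a cylindrical lumen.  While a
bubble's sphere intersects the plane it appears as a bright blob whose radius
follows the chord law r(t) = sqrt(R^2 - d(t)^2), at a laterally wobbling
position.  The highlight is a Gaussian blob of size-independent peak whose
half-peak radius equals the chord radius.  Frames carry multiplicative
speckle (exponential intensity, low-pass filtered by the point-spread
function), a bright wall ring around the lumen, optional phantom-echo
duplicates displaced axially (+y) with decaying peak, and a uniform gain
offset.  Rendering is appearance-level: it exercises the image-analysis
chain, not acoustics.

The "optical" reference is synthesised directly from ground truth (with
optional small jitter), standing in for the rig's high-speed camera stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .detection import BubbleSlice, DetectionParams, RegionOfInterest, detect_sequence
from .io_core import Calibration, Frame, PipelineResult, RunConfig, run_pipeline
from .reconstruction import BubbleTrack, LinkingParams, sphere_volume
from .reporting import Report
from .validation import MatchResult, MatchWeights, match_streams


@dataclass(frozen=True)
class SceneParams:
    """Conditions of one simulated rig run.

    Geometry is isotropic: ``mm_per_px`` applies to both axes, the lumen is a
    circle centred in the frame.  ``seed`` fixes all randomness.
    """

    n_bubbles: int = 100
    radius_range: tuple[float, float] = (0.1, 1.5)  # mm
    rise_speed: float = 5.0  # mm/s through the imaging plane
    wobble_amplitude_mm: float = 1.0
    wobble_period_s: float = 1.0
    frame_rate: float = 25.0  # Hz
    frame_shape: tuple[int, int] = (256, 256)  # (rows, cols)
    mm_per_px: float = 0.1
    duration_s: float = 400.0
    speckle_scale: float = 30.0  # mean speckle intensity (exponential scale)
    blob_peak: float = 220.0
    psf_sigma_mm: float = 0.15
    phantom_prob: float = 0.0
    phantom_offsets_mm: tuple[float, ...] = (3.0, 6.0)  # axial (+y), per echo
    phantom_decay: float = 0.7  # peak multiplier per successive echo
    gain_offset: float = 0.0
    wall_intensity: float = 200.0
    lumen_radius_mm: float | None = None  # default: 0.35 * min frame extent
    bubble_margin: float = 0.7  # bubbles sampled within this fraction of the lumen radius
    crossing_spacing_s: float | None = None  # if set, crossing times are spaced, not uniform
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.radius_range
        if not 0 < lo < hi:
            raise ValueError("radius_range must satisfy 0 < lo < hi")
        if not 0 <= self.phantom_prob <= 1:
            raise ValueError("phantom_prob must lie in [0, 1]")
        if self.n_bubbles < 0 or self.duration_s <= 0 or self.frame_rate <= 0:
            raise ValueError("n_bubbles >= 0, duration_s > 0, frame_rate > 0 required")

    # -- derived geometry --------------------------------------------------
    @property
    def center_px(self) -> np.ndarray:
        h, w = self.frame_shape
        return np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    @property
    def center_mm(self) -> np.ndarray:
        return self.center_px * self.mm_per_px

    @property
    def lumen_radius(self) -> float:
        if self.lumen_radius_mm is not None:
            return self.lumen_radius_mm
        return 0.35 * min(self.frame_shape) * self.mm_per_px

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))

    @property
    def calibration(self) -> Calibration:
        return Calibration.isotropic(self.mm_per_px, self.frame_rate)

    def roi_seed(self) -> RegionOfInterest:
        """Detection ROI: a circle just inside the lumen wall."""
        r_px = (self.lumen_radius - 0.5) / self.mm_per_px
        return RegionOfInterest.circle(self.center_px, r_px)

    # -- presets -----------------------------------------------------------
    @classmethod
    def paper_regime(cls, seed: int = 0) -> "SceneParams":
        """The full validation regime: 1030 bubbles, phantom echoes on,
        moderate speckle, 1 mm wobble."""
        return cls(
            n_bubbles=1030,
            phantom_prob=1.0,
            wobble_amplitude_mm=1.0,
            speckle_scale=30.0,
            duration_s=400.0,
            seed=seed,
        )

    @classmethod
    def clean_regime(cls, n_bubbles: int = 200, seed: int = 0) -> "SceneParams":
        """Low-noise, phantom-free, temporally disjoint bubbles, for
        parameter-recovery checks.

        The crossing spacing (1.8 s) exceeds the longest visibility window
        (2 * 1.5 mm / 2 mm/s = 1.5 s), so tracks cannot interact, and the
        slow rise guarantees every bubble — including the 0.1 mm floor —
        subtends a resolvable chord in at least one frame.
        """
        return cls(
            n_bubbles=n_bubbles,
            phantom_prob=0.0,
            wobble_amplitude_mm=0.3,
            speckle_scale=10.0,
            rise_speed=2.0,
            frame_shape=(128, 128),
            crossing_spacing_s=1.8,
            duration_s=max(1.8 * n_bubbles, 2.0),
            seed=seed,
        )


@dataclass(frozen=True)
class GroundTruthBubble:
    """One simulated bubble and its lateral trajectory."""

    bubble_id: int
    radius: float  # mm
    crossing_time: float  # s, when the sphere centre crosses the plane
    lateral_position: np.ndarray  # (x, y) mm, wobble midpoint
    wobble_amplitude: float  # mm per axis
    wobble_period: float  # s
    phase: np.ndarray  # (phi_x, phi_y)
    has_phantom: bool = False

    def position_at(self, t: float) -> np.ndarray:
        """In-plane position at time t, including wobble."""
        if self.wobble_period <= 0 or self.wobble_amplitude == 0:
            return self.lateral_position.copy()
        ang = 2 * math.pi * t / self.wobble_period + self.phase
        return self.lateral_position + self.wobble_amplitude * np.sin(ang)


def sample_bubbles(params: SceneParams) -> list[GroundTruthBubble]:
    """Draw the ground-truth bubble population for one run.

    Radii are i.i.d. uniform on ``radius_range``; crossing times uniform over
    the run (or evenly spaced with jitter when ``crossing_spacing_s`` is set);
    lateral positions uniform in a disc of ``bubble_margin`` times the lumen
    radius.  Identical seed gives identical output.
    """
    rng = np.random.default_rng([params.seed, 0])
    n = params.n_bubbles
    lo, hi = params.radius_range
    radii = rng.uniform(lo, hi, n)
    if params.crossing_spacing_s is None:
        times = np.sort(rng.uniform(0.0, params.duration_s, n))
    else:
        spacing = params.crossing_spacing_s
        base = (np.arange(n) + 0.5) * min(spacing, params.duration_s / max(n, 1))
        times = base + rng.uniform(-0.05, 0.05, n)
        times = np.clip(times, 0.0, params.duration_s)
    r_max = params.bubble_margin * params.lumen_radius
    rr = r_max * np.sqrt(rng.uniform(0.0, 1.0, n))
    theta = rng.uniform(0.0, 2 * math.pi, n)
    cx, cy = params.center_mm
    phases = rng.uniform(0.0, 2 * math.pi, (n, 2))
    phantom = rng.uniform(0.0, 1.0, n) < params.phantom_prob
    return [
        GroundTruthBubble(
            bubble_id=i,
            radius=float(radii[i]),
            crossing_time=float(times[i]),
            lateral_position=np.array([cx + rr[i] * math.cos(theta[i]), cy + rr[i] * math.sin(theta[i])]),
            wobble_amplitude=params.wobble_amplitude_mm,
            wobble_period=params.wobble_period_s,
            phase=phases[i],
            has_phantom=bool(phantom[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Ultrasound rendering
# ---------------------------------------------------------------------------

def _wall_ring(params: SceneParams) -> np.ndarray:
    """Static bright wall ring enclosing the lumen (pre-blur intensity)."""
    h, w = params.frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = params.center_px
    d_mm = np.hypot(xx - cx, yy - cy) * params.mm_per_px
    r_in = params.lumen_radius + 0.6
    r_out = params.lumen_radius + 1.1
    ring = np.zeros((h, w))
    ring[(d_mm >= r_in) & (d_mm <= r_out)] = params.wall_intensity
    return ring


def _add_blob(img: np.ndarray, cx_px: float, cy_px: float, r_px: float, peak: float) -> None:
    """Add a bubble highlight: a disc of size-independent peak intensity with
    a 1 px anti-aliased edge (in place).

    Bubbles are strong acoustic scatterers, so a small bubble is weak in
    extent, not in amplitude; the sharp edge keeps the thresholded extent
    equal to the chord radius independent of the threshold level.
    """
    h, w = img.shape
    reach = int(math.ceil(r_px + 2))
    x0, x1 = max(int(cx_px) - reach, 0), min(int(cx_px) + reach + 1, w)
    y0, y1 = max(int(cy_px) - reach, 0), min(int(cy_px) + reach + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx_px, yy - cy_px)
    img[y0:y1, x0:x1] += peak * np.clip(r_px - d + 0.5, 0.0, 1.0)


def _visible_chord(bubble: GroundTruthBubble, t: float, rise_speed: float) -> float | None:
    """Chord radius (mm) of the sphere-plane intersection at time t, or None."""
    d = rise_speed * (t - bubble.crossing_time)
    if abs(d) >= bubble.radius:
        return None
    return math.sqrt(bubble.radius**2 - d**2)


def iter_ultrasound_frames(
    bubbles: Sequence[GroundTruthBubble], params: SceneParams
) -> Iterator[Frame]:
    """Lazily render the ultrasound frame stream (seed-deterministic)."""
    ring = _wall_ring(params)
    psf_px = params.psf_sigma_mm / params.mm_per_px
    dt_vis = max(b.radius for b in bubbles) / params.rise_speed if bubbles else 0.0
    times = np.array([b.crossing_time for b in bubbles])
    order = np.argsort(times)
    sorted_times = times[order]

    if psf_px > 0:
        ring = gaussian_filter(ring, psf_px)
    for i in range(params.n_frames):
        t = i / params.frame_rate
        rng = np.random.default_rng([params.seed, 1, i])
        if params.speckle_scale > 0:
            img = rng.exponential(params.speckle_scale, params.frame_shape)
            if psf_px > 0:
                img = gaussian_filter(img, psf_px)
        else:
            img = np.zeros(params.frame_shape)
        img += ring
        lo = int(np.searchsorted(sorted_times, t - dt_vis))
        hi = int(np.searchsorted(sorted_times, t + dt_vis))
        for k in order[lo:hi]:
            b = bubbles[k]
            chord = _visible_chord(b, t, params.rise_speed)
            if chord is None:
                continue
            pos_px = b.position_at(t) / params.mm_per_px
            r_px = chord / params.mm_per_px
            _add_blob(img, pos_px[0], pos_px[1], r_px, params.blob_peak)
            if b.has_phantom:
                peak = params.blob_peak
                for off in params.phantom_offsets_mm:
                    peak *= params.phantom_decay
                    _add_blob(
                        img, pos_px[0], pos_px[1] + off / params.mm_per_px, r_px, peak
                    )
        img = np.clip(np.rint(img) + params.gain_offset, 0.0, 255.0)
        yield Frame(img.astype(np.float32), index=i, time=t)


def render_ultrasound(
    bubbles: Sequence[GroundTruthBubble], params: SceneParams
) -> tuple[list[Frame], RegionOfInterest]:
    """Materialised frame list plus the ROI seed (use the iterator for long runs)."""
    return list(iter_ultrasound_frames(bubbles, params)), params.roi_seed()


# ---------------------------------------------------------------------------
# Optical reference stream
# ---------------------------------------------------------------------------

def render_optical(
    bubbles: Sequence[GroundTruthBubble],
    params: SceneParams,
    jitter_pos_mm: float = 0.0,
    jitter_time_s: float = 0.0,
    jitter_radius_mm: float = 0.0,
) -> list[BubbleTrack]:
    """Ground truth as an "optical" track stream with optional Gaussian jitter.

    With all jitters at zero the stream equals the exact truth: one track per
    bubble, positioned where the (wobbling) bubble crossed the plane.
    """
    rng = np.random.default_rng([params.seed, 2])
    tracks = []
    for b in bubbles:
        pos = b.position_at(b.crossing_time) + rng.normal(0.0, 1.0, 2) * jitter_pos_mm
        t = b.crossing_time + float(rng.normal(0.0, 1.0)) * jitter_time_s
        r = max(b.radius + float(rng.normal(0.0, 1.0)) * jitter_radius_mm, 1e-6)
        sl = BubbleSlice(
            centroid=pos,
            equivalent_radius=r,
            area=math.pi * r**2,
            mean_intensity=255.0,
            frame_index=int(round(t * params.frame_rate)),
            time=t,
        )
        tracks.append(
            BubbleTrack(
                track_id=b.bubble_id,
                slices=[sl],
                position=pos,
                time=t,
                radius=r,
                volume=sphere_volume(r),
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# Full rig emulation
# ---------------------------------------------------------------------------

@dataclass
class RigResult:
    """Everything one emulated validation run produces."""

    match: MatchResult
    report: Report
    pipeline: PipelineResult
    optical: list[BubbleTrack]
    bubbles: list[GroundTruthBubble]


def rig_emulation(
    params: SceneParams,
    detection_params: DetectionParams | None = None,
    linking_params: LinkingParams | None = None,
    weights: MatchWeights | None = None,
) -> RigResult:
    """Run the full in-silico validation experiment.

    Renders the ultrasound stream, runs the complete detection pipeline, and
    matches the detected tracks against the zero-jitter optical reference.
    Fully seeded: identical params give identical results.
    """
    config = RunConfig(
        calibration=params.calibration,
        detection_params=detection_params or DetectionParams(),
        linking_params=linking_params or LinkingParams(),
        seed=params.seed,
    )
    bubbles = sample_bubbles(params)
    frames = iter_ultrasound_frames(bubbles, params)
    result = run_pipeline(config, frames, params.roi_seed())
    optical = render_optical(bubbles, params)
    match = match_streams(result.tracks, optical, weights)
    return RigResult(
        match=match,
        report=result.report,
        pipeline=result,
        optical=optical,
        bubbles=bubbles,
    )
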