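"""Linking per-frame slices into bubble tracks over (x, y, time).

One bubble crossing the imaging plane appears as a short run of slices in
consecutive frames.  Linking solves an optimal per-frame assignment between
open tracks and new slices (cost = squared centroid distance, gated by a
maximum link distance); phantom-echo duplicates — axially displaced copies of
a bubble produced by low acoustic impedance in the water rig — are merged
afterwards; finally each track is reduced to a single bubble estimate:
position is the mean of its slice centroids, the radius is the largest slice
equivalent radius (the widest chord of a sphere crossing a plane is its
diameter), and the volume follows the sphere model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import BubbleSlice

_FORBIDDEN = 1e9  # cost sentinel dominating any sum of feasible squared distances


@dataclass(frozen=True)
class LinkingParams:
    """Gates for frame-to-frame linking and phantom merging (mm / frames).

    A phantom echo is an axially displaced, *attenuated copy* of its bubble:
    it shares the bubble's frame support, lateral trajectory and chord-radius
    profile, at a reduced reflection intensity.  ``phantom_min_frame_overlap``
    (fraction of the shorter track's frames that must be common),
    ``phantom_max_radius_reldiff`` (mean per-frame relative radius
    difference) and ``phantom_max_intensity_ratio`` (the dimmer member must
    be at most this fraction of the brighter one's mean intensity) encode
    the copy test that separates echoes from coincidentally nearby real
    bubbles, which are equally bright.
    """

    max_link_distance: float = 3.0
    max_frame_gap: int = 1
    phantom_axial_window: float = 4.0
    phantom_lateral_window: float = 1.0
    phantom_min_frame_overlap: float = 0.5
    phantom_max_radius_reldiff: float = 0.5
    phantom_max_intensity_ratio: float = 0.9
    phantom_min_axial_offset: float = 0.5
    phantom_max_traj_dev: float = 0.3
    pinch_split_ratio: float = 0.4
    merge_phantoms_enabled: bool = True

    def __post_init__(self) -> None:
        if self.max_link_distance <= 0:
            raise ValueError("max_link_distance must be > 0")
        if self.max_frame_gap < 0:
            raise ValueError("max_frame_gap must be >= 0")
        if self.phantom_axial_window <= 0 or self.phantom_lateral_window <= 0:
            raise ValueError("phantom windows must be > 0")


@dataclass
class BubbleTrack:
    """Slices linked across frames: one potential embolus.

    ``slices`` are the detections attributed to the bubble itself and define
    the track estimate; ``echo_slices`` holds detections absorbed from merged
    phantom-echo duplicates — retained (nothing is deleted by merging) but
    excluded from the position/radius estimate so artifact copies do not bias
    the bubble.
    """

    track_id: int
    slices: list[BubbleSlice]
    position: np.ndarray = field(default_factory=lambda: np.zeros(2))  # (x, y) mm
    time: float = 0.0  # s, mean of slice times
    radius: float = 0.0  # mm
    volume: float = 0.0  # mm^3
    echo_slices: list[BubbleSlice] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("a track needs at least one slice")

    @property
    def mean_intensity(self) -> float:
        return float(np.mean([s.mean_intensity for s in self.slices]))

    @property
    def t_start(self) -> float:
        return min(s.time for s in self.slices)

    @property
    def t_end(self) -> float:
        return max(s.time for s in self.slices)


def sphere_volume(radius: float) -> float:
    """Volume of a sphere of the given radius, mm^3."""
    return 4.0 / 3.0 * math.pi * float(radius) ** 3


def _robust_max_radius(radii: Sequence[float]) -> float:
    """Largest slice radius, guarding against a single fused-blob outlier.

    Near the diameter the chord profile is flat, so in a well-sampled track
    (>= 4 slices) the largest and second-largest slice radii are close; a
    jump of more than 40% means the top slice merged with a neighbouring
    bright object and the runner-up is used instead.
    """
    r = sorted(radii, reverse=True)
    if len(r) >= 4 and r[0] > 1.4 * r[1]:
        return r[1]
    return r[0]


def estimate_bubble(track: BubbleTrack) -> BubbleTrack:
    """Fill in the track-level bubble estimate from its slices.

    position = arithmetic mean of slice centroids; time = mean slice time;
    radius = largest slice equivalent radius (the widest chord of the sphere,
    with a fused-slice outlier guard); volume = (4/3) pi r^3.
    """
    centroids = np.array([s.centroid for s in track.slices], dtype=float)
    radius = _robust_max_radius([s.equivalent_radius for s in track.slices])
    return BubbleTrack(
        track_id=track.track_id,
        slices=track.slices,
        position=centroids.mean(axis=0),
        time=float(np.mean([s.time for s in track.slices])),
        radius=radius,
        volume=sphere_volume(radius),
        echo_slices=track.echo_slices,
    )


def link_slices(slices: Sequence[BubbleSlice], params: LinkingParams) -> list[BubbleTrack]:
    """Group frame-stamped slices into tracks by optimal per-frame assignment.

    Frames are visited in order; the slices of each frame are assigned to open
    tracks whose last slice lies within ``max_link_distance`` (Euclidean, mm)
    and within ``max_frame_gap`` missed frames, minimising the total squared
    distance of the frame's assignment (Hungarian algorithm).  Unmatched
    slices open new tracks; tracks silent for more than ``max_frame_gap``
    frames close.  Every input slice ends up in exactly one track.
    """
    by_frame: dict[int, list[BubbleSlice]] = {}
    for s in slices:
        by_frame.setdefault(s.frame_index, []).append(s)

    open_tracks: list[dict] = []  # {"id", "slices", "last"}
    closed: list[dict] = []
    next_id = 0

    for f in sorted(by_frame):
        still_open = []
        for tr in open_tracks:
            if f - tr["slices"][-1].frame_index - 1 > params.max_frame_gap:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        frame_slices = by_frame[f]

        assigned = [False] * len(frame_slices)
        if open_tracks and frame_slices:
            cost = np.full((len(frame_slices), len(open_tracks)), _FORBIDDEN)
            for i, s in enumerate(frame_slices):
                for j, tr in enumerate(open_tracks):
                    d2 = float(np.sum((s.centroid - tr["slices"][-1].centroid) ** 2))
                    if d2 <= params.max_link_distance**2:
                        cost[i, j] = d2
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < _FORBIDDEN:
                    open_tracks[j]["slices"].append(frame_slices[i])
                    assigned[i] = True
        for i, s in enumerate(frame_slices):
            if not assigned[i]:
                open_tracks.append({"id": next_id, "slices": [s]})
                next_id += 1

    all_tracks = sorted(closed + open_tracks, key=lambda tr: tr["id"])
    chains = [tr["slices"] for tr in all_tracks]
    split: list[list[BubbleSlice]] = []
    for chain in chains:
        split.extend(_split_at_pinch(chain, params.pinch_split_ratio))
    return [
        estimate_bubble(BubbleTrack(track_id=i, slices=sl)) for i, sl in enumerate(split)
    ]


def _split_at_pinch(slices: list[BubbleSlice], ratio: float) -> list[list[BubbleSlice]]:
    """Split a slice chain where its radius profile pinches to near zero.

    A single bubble's chord radius rises to the diameter and falls once; a
    deep interior minimum (below ``ratio`` of the maxima on both sides) means
    two successive crossings at the same spot were chained together.
    Requires at least two slices on each side of the pinch.
    """
    n = len(slices)
    if n < 5 or ratio <= 0:
        return [slices]
    r = np.array([s.equivalent_radius for s in slices])
    for m in range(2, n - 2):
        if r[m] < ratio * r[:m].max() and r[m] < ratio * r[m + 1 :].max():
            left = slices[: m + 1]
            right = slices[m + 1 :]
            return _split_at_pinch(left, ratio) + _split_at_pinch(right, ratio)
    return [slices]


def _temporal_overlap(a: BubbleTrack, b: BubbleTrack) -> bool:
    return a.t_start <= b.t_end and b.t_start <= a.t_end


def _is_phantom_pair(a: BubbleTrack, b: BubbleTrack, params: LinkingParams) -> bool:
    """True when track b looks like an axially displaced copy of track a (or
    vice versa): shared frames, small per-frame lateral separation, axial
    separation within the echo window, and a similar radius profile."""
    fa = {s.frame_index: s for s in a.slices}
    fb = {s.frame_index: s for s in b.slices}
    common = sorted(fa.keys() & fb.keys())
    if not common:
        return False
    if len(common) < params.phantom_min_frame_overlap * min(len(fa), len(fb)):
        return False
    dx = np.mean([abs(fa[f].centroid[0] - fb[f].centroid[0]) for f in common])
    if dx > params.phantom_lateral_window:
        return False
    dy = np.mean([abs(fa[f].centroid[1] - fb[f].centroid[1]) for f in common])
    if dy > params.phantom_axial_window:
        return False
    ra = np.array([fa[f].equivalent_radius for f in common])
    rb = np.array([fb[f].equivalent_radius for f in common])
    scale = max(float(ra.mean()), float(rb.mean()))
    if scale > 0 and float(np.mean(np.abs(ra - rb))) / scale > params.phantom_max_radius_reldiff:
        return False
    ia = float(np.mean([fa[f].mean_intensity for f in common]))
    ib = float(np.mean([fb[f].mean_intensity for f in common]))
    if max(ia, ib) > 0 and min(ia, ib) / max(ia, ib) > params.phantom_max_intensity_ratio:
        return False  # equally bright: two real bubbles, not an echo
    if len(common) >= 4:
        # an echo rides its bubble's wobble: the per-frame separation vector
        # is constant, while independent bubbles drift apart
        dxs = np.array([fa[f].centroid[0] - fb[f].centroid[0] for f in common])
        dys = np.array([fa[f].centroid[1] - fb[f].centroid[1] for f in common])
        if float(dxs.std()) > params.phantom_max_traj_dev or float(dys.std()) > params.phantom_max_traj_dev:
            return False
    return True


def merge_phantoms(tracks: Sequence[BubbleTrack], params: LinkingParams) -> list[BubbleTrack]:
    """Merge phantom-echo duplicate tracks into their true bubble.

    Two temporally overlapping tracks are merged when they pass the
    displaced-copy test of :func:`_is_phantom_pair` — mean per-frame lateral
    separation at most ``phantom_lateral_window``, mean axial separation at
    most ``phantom_axial_window``, sufficient shared frame support and a
    similar per-frame radius profile; merging is transitive.  The surviving
    track is the member with the highest mean intensity (echo intensity
    decays, so the brightest copy is the true bubble); its own slices define
    the bubble estimate while the duplicates' slices are kept on
    ``echo_slices``, so no slice is ever dropped.
    """
    if not params.merge_phantoms_enabled or len(tracks) < 2:
        return [estimate_bubble(t) for t in tracks]

    n = len(tracks)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # coarse vectorised prefilter before the per-frame copy test
    t0 = np.array([t.t_start for t in tracks])
    t1 = np.array([t.t_end for t in tracks])
    xs = np.array([t.position[0] for t in tracks])
    ys = np.array([t.position[1] for t in tracks])
    for i in range(n):
        near = (
            (t0[i] <= t1)
            & (t0 <= t1[i])
            & (np.abs(xs - xs[i]) <= 2 * params.phantom_lateral_window)
            & (np.abs(ys - ys[i]) <= params.phantom_axial_window)
        )
        for j in np.nonzero(near[i + 1 :])[0] + i + 1:
            j = int(j)
            if _is_phantom_pair(tracks[i], tracks[j], params):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    merged: list[BubbleTrack] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(estimate_bubble(tracks[members[0]]))
            continue
        survivor = max(
            (tracks[i] for i in members),
            key=lambda t: (t.mean_intensity, -t.track_id),
        )
        # A member may only be absorbed as an echo of the survivor if it is
        # physically consistent with one: attenuated AND axially below.
        # Equally bright or not-below members were chained in transitively
        # (e.g. a real bubble crossing near another bubble's echo) and are
        # restored as independent tracks.
        absorbed: list[BubbleTrack] = []
        for i in members:
            t = tracks[i]
            if t is survivor:
                continue
            is_echo = (
                t.mean_intensity
                <= params.phantom_max_intensity_ratio * survivor.mean_intensity
                and t.position[1] - survivor.position[1] >= params.phantom_min_axial_offset
            )
            if is_echo:
                absorbed.append(t)
            else:
                merged.append(estimate_bubble(t))
        echoes = sorted(
            (s for t in absorbed for s in t.slices + t.echo_slices),
            key=lambda s: (s.frame_index, s.centroid[1], s.centroid[0]),
        )
        merged.append(
            estimate_bubble(
                BubbleTrack(
                    track_id=survivor.track_id,
                    slices=survivor.slices,
                    echo_slices=survivor.echo_slices + echoes,
                )
            )
        )
    merged.sort(key=lambda t: t.track_id)
    return merged
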