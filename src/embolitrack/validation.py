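"""Dual-modality validation: least-squares matching of two detection streams.

Each detected bubble carries a planar position (mm), a crossing time (s) and a
radius (mm).  Two streams (e.g. ultrasound detections vs an optical reference)
are matched one-to-one by minimising the total weighted squared error of the
position, time and radius differences, with a gate on the per-pair cost; the
match is then summarised by the Pearson correlation of matched radii and the
sample standard deviations of the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .errors import UndefinedStatisticError
from .reconstruction import BubbleTrack

_FORBIDDEN = 1e12  # dominates any sum of gated pair costs


@dataclass(frozen=True)
class MatchWeights:
    """Weights of the three error terms and the per-pair cost gate.

    Defaults normalise each term by a typical spread (position 1.4 mm, time
    0.4 s, radius 0.2 mm) so the three terms are commensurate; the gate of 9
    corresponds to a ~3-sigma joint residual.
    """

    w_pos: float = 1.0 / 1.4**2  # 1/mm^2
    w_time: float = 1.0 / 0.4**2  # 1/s^2
    w_radius: float = 1.0 / 0.2**2  # 1/mm^2
    gate_cost: float = 9.0

    def __post_init__(self) -> None:
        if min(self.w_pos, self.w_time, self.w_radius) <= 0:
            raise ValueError("all weights must be > 0")
        if self.gate_cost <= 0:
            raise ValueError("gate_cost must be > 0")


@dataclass
class MatchResult:
    """One-to-one correspondence between two streams plus residual statistics."""

    pairs: list[tuple[int, int]]  # (track_a_id, track_b_id)
    unmatched_a: list[int]
    unmatched_b: list[int]
    r_radius: float  # Pearson correlation of matched radii (nan if < 2 pairs)
    std_position: float  # mm, sample SD of planar distances (nan if < 2 pairs)
    std_time: float  # s, sample SD of signed time differences
    std_radius: float  # mm, sample SD of signed radius differences


def pair_cost(a: BubbleTrack, b: BubbleTrack, weights: MatchWeights) -> float:
    """Weighted squared error of one candidate pairing."""
    dp2 = float(np.sum((a.position - b.position) ** 2))
    return (
        weights.w_pos * dp2
        + weights.w_time * (a.time - b.time) ** 2
        + weights.w_radius * (a.radius - b.radius) ** 2
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise UndefinedStatisticError("pearson_r needs two equal-length samples of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def match_streams(
    tracks_a: Sequence[BubbleTrack],
    tracks_b: Sequence[BubbleTrack],
    weights: MatchWeights | None = None,
) -> MatchResult:
    """Optimal one-to-one matching of two detection streams.

    Pair cost = w_pos*||dpos||^2 + w_time*dt^2 + w_radius*dr^2; pairs costing
    more than ``gate_cost`` are forbidden.  Among all one-to-one matchings of
    maximal allowed size the returned one minimises total cost (Hungarian
    algorithm with a dominating sentinel on forbidden pairs).
    """
    weights = weights or MatchWeights()
    na, nb = len(tracks_a), len(tracks_b)
    pairs: list[tuple[int, int]] = []
    matched_a: set[int] = set()
    matched_b: set[int] = set()
    residual_idx: list[tuple[int, int]] = []

    if na and nb:
        pa = np.array([t.position for t in tracks_a])
        pb = np.array([t.position for t in tracks_b])
        ta = np.array([t.time for t in tracks_a])[:, None]
        tb = np.array([t.time for t in tracks_b])[None, :]
        ra = np.array([t.radius for t in tracks_a])[:, None]
        rb = np.array([t.radius for t in tracks_b])[None, :]
        dp2 = np.sum((pa[:, None, :] - pb[None, :, :]) ** 2, axis=-1)
        cost = weights.w_pos * dp2 + weights.w_time * (ta - tb) ** 2 + weights.w_radius * (ra - rb) ** 2
        cost[cost > weights.gate_cost] = _FORBIDDEN
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] < _FORBIDDEN:
                pairs.append((tracks_a[i].track_id, tracks_b[j].track_id))
                residual_idx.append((i, j))
                matched_a.add(i)
                matched_b.add(j)

    unmatched_a = [t.track_id for i, t in enumerate(tracks_a) if i not in matched_a]
    unmatched_b = [t.track_id for j, t in enumerate(tracks_b) if j not in matched_b]

    r = s_pos = s_time = s_rad = float("nan")
    if len(residual_idx) >= 2:
        ra = [tracks_a[i].radius for i, _ in residual_idx]
        rb = [tracks_b[j].radius for _, j in residual_idx]
        if np.ptp(ra) > 0 and np.ptp(rb) > 0:
            r = pearson_r(ra, rb)
        s_pos, s_time, s_rad = _residuals(
            [tracks_a[i] for i, _ in residual_idx], [tracks_b[j] for _, j in residual_idx]
        )

    return MatchResult(
        pairs=pairs,
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
        r_radius=r,
        std_position=s_pos,
        std_time=s_time,
        std_radius=s_rad,
    )


def _residuals(sel_a: list[BubbleTrack], sel_b: list[BubbleTrack]) -> tuple[float, float, float]:
    dpos = [float(np.hypot(*(a.position - b.position))) for a, b in zip(sel_a, sel_b)]
    dt = [a.time - b.time for a, b in zip(sel_a, sel_b)]
    dr = [a.radius - b.radius for a, b in zip(sel_a, sel_b)]
    return (
        float(np.std(dpos, ddof=1)),
        float(np.std(dt, ddof=1)),
        float(np.std(dr, ddof=1)),
    )


def residual_stats(
    result: MatchResult,
    tracks_a: Sequence[BubbleTrack],
    tracks_b: Sequence[BubbleTrack],
) -> tuple[float, float, float]:
    """(std_position mm, std_time s, std_radius mm) over the matched pairs.

    Position residual is the planar Euclidean distance; time and radius
    residuals are signed differences (a minus b).  Sample SDs (ddof = 1).
    """
    if len(result.pairs) < 2:
        raise UndefinedStatisticError("residual statistics need at least 2 matched pairs")
    by_id_a = {t.track_id: t for t in tracks_a}
    by_id_b = {t.track_id: t for t in tracks_b}
    sel_a = [by_id_a[i] for i, _ in result.pairs]
    sel_b = [by_id_b[j] for _, j in result.pairs]
    return _residuals(sel_a, sel_b)


def match_to_dict(result: MatchResult) -> dict:
    """JSON-serialisable form of a MatchResult (``match.json`` schema)."""
    return {
        "pairs": [[int(a), int(b)] for a, b in result.pairs],
        "unmatched_a": [int(i) for i in result.unmatched_a],
        "unmatched_b": [int(i) for i in result.unmatched_b],
        "n_matched": len(result.pairs),
        "r_radius": float(result.r_radius),
        "std_position_mm": float(result.std_position),
        "std_time_s": float(result.std_time),
        "std_radius_mm": float(result.std_radius),
    }
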