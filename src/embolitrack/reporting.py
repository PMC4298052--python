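"""Report panel as data: counts, rates, cumulative air volume, size histogram.

The "air volume" is the cumulative sphere volume of all detected bubbles; the
per-frame air fraction — detected bubble area over ROI area in that frame —
is emitted alongside as a 2-D proxy for the volume percentage of the lumen,
since a single imaging plane carries no per-frame 3-D volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, InputError
from .io_core import RunConfig, dump_json
from .reconstruction import BubbleTrack

#: default histogram edges: 0-2 mm in 0.1 mm bins, covering the 0.1-1.5 mm rig range
DEFAULT_BIN_EDGES = tuple(round(0.1 * i, 10) for i in range(21))


@dataclass
class SizeHistogram:
    """Counts of track radii per radius bin (mm)."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("need len(counts) == len(bin_edges) - 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly ascending")


@dataclass
class Report:
    """Output panel of one run."""

    total_count: int
    count_rate: float  # emboli / second over the trailing report window
    cumulative_volume: float  # mm^3
    per_frame_air_fraction: list[tuple[int, float]]  # (frame_index, fraction in [0, 1])
    histogram: SizeHistogram
    report_window: float = 10.0


def build_histogram(radii: Sequence[float], bin_edges: Sequence[float] = DEFAULT_BIN_EDGES) -> SizeHistogram:
    """Histogram of radii; values outside the edges are clipped into the end bins
    so that the counts always sum to the number of tracks."""
    edges = np.asarray(bin_edges, dtype=float)
    if len(radii) == 0:
        return SizeHistogram(edges, np.zeros(len(edges) - 1, dtype=int))
    r = np.clip(np.asarray(radii, dtype=float), edges[0], np.nextafter(edges[-1], 0.0))
    counts, _ = np.histogram(r, bins=edges)
    return SizeHistogram(edges, counts)


def compute_report(
    tracks: Sequence[BubbleTrack],
    slices: Sequence,
    roi_series: Sequence[tuple[int, object]],
    config: RunConfig,
) -> Report:
    """Assemble the report from finalized tracks.

    count_rate counts tracks whose mean time falls in the trailing
    ``report_window`` seconds of the run (window end = last covered frame
    time, or the last track time if no ROI series is given).
    """
    total = len(tracks)
    volume = float(sum(t.volume for t in tracks))

    if roi_series:
        t_end = max(fi for fi, _ in roi_series) / config.calibration.frame_rate
    elif tracks:
        t_end = max(t.time for t in tracks)
    else:
        t_end = 0.0
    w = config.report_window
    in_window = sum(1 for t in tracks if t_end - w < t.time <= t_end)
    rate = in_window / w

    px_area_mm2 = config.calibration.mm_per_px_x * config.calibration.mm_per_px_y
    area_by_frame: dict[int, float] = {}
    for s in slices:
        area_by_frame[s.frame_index] = area_by_frame.get(s.frame_index, 0.0) + s.area
    fractions = []
    for fi, roi in roi_series:
        roi_mm2 = roi.area_px * px_area_mm2
        frac = min(area_by_frame.get(fi, 0.0) / roi_mm2, 1.0) if roi_mm2 > 0 else 0.0
        fractions.append((fi, frac))

    return Report(
        total_count=total,
        count_rate=rate,
        cumulative_volume=volume,
        per_frame_air_fraction=fractions,
        histogram=build_histogram([t.radius for t in tracks]),
        report_window=w,
    )


def export_report(report: Report, out_dir: str | Path) -> None:
    """Write ``report.json`` and ``histogram.csv`` with a stable schema."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise InputError(f"cannot create output directory {out}: {e}") from e
    payload = {
        "total_count": report.total_count,
        "count_rate_per_s": report.count_rate,
        "report_window_s": report.report_window,
        "cumulative_volume_mm3": report.cumulative_volume,
        "per_frame_air_fraction": [[int(fi), float(fr)] for fi, fr in report.per_frame_air_fraction],
        "histogram": {
            "bin_edges_mm": [float(e) for e in report.histogram.bin_edges],
            "counts": [int(c) for c in report.histogram.counts],
        },
    }
    dump_json(payload, out / "report.json")
    import pandas as pd

    edges = report.histogram.bin_edges
    pd.DataFrame(
        {
            "bin_lo_mm": edges[:-1],
            "bin_hi_mm": edges[1:],
            "count": report.histogram.counts,
        }
    ).to_csv(out / "histogram.csv", index=False)


def import_report(path: str | Path) -> Report:
    """Read back a ``report.json`` written by :func:`export_report`."""
    path = Path(path)
    if path.is_dir():
        path = path / "report.json"
    if not path.exists():
        raise InputError(f"no such report: {path}")
    with open(path) as fh:
        data = json.load(fh)
    try:
        return Report(
            total_count=int(data["total_count"]),
            count_rate=float(data["count_rate_per_s"]),
            cumulative_volume=float(data["cumulative_volume_mm3"]),
            per_frame_air_fraction=[(int(a), float(b)) for a, b in data["per_frame_air_fraction"]],
            histogram=SizeHistogram(
                np.asarray(data["histogram"]["bin_edges_mm"]),
                np.asarray(data["histogram"]["counts"]),
            ),
            report_window=float(data.get("report_window_s", 10.0)),
        )
    except KeyError as e:
        raise FormatError(f"report.json missing field {e}") from e
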