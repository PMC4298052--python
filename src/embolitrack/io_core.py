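"""Image-sequence and configuration I/O, pixel/physical calibration, pipeline driver.

Coordinate convention used throughout the package: image origin at the top-left
corner, ``x`` is the column index increasing rightward, ``y`` is the row index
increasing downward (the axial/depth direction, away from the transducer), both
0-based.  Physical coordinates use the same axes scaled to millimetres; time is
``frame_index / frame_rate`` in seconds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import yaml

from .errors import FormatError, InputError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .detection import DetectionParams, RegionOfInterest
    from .reconstruction import BubbleTrack, LinkingParams
    from .reporting import Report

#: ITU-R 601 luminance weights for colour -> grey conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-physical mapping of one ultrasound stream.

    Parameters
    ----------
    mm_per_px_x, mm_per_px_y : float
        Physical extent of one pixel along the lateral (x) and axial (y)
        image axes, in millimetres.
    frame_rate : float
        Acquisition rate in frames per second.
    """

    mm_per_px_x: float
    mm_per_px_y: float
    frame_rate: float

    def __post_init__(self) -> None:
        for name in ("mm_per_px_x", "mm_per_px_y", "frame_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"Calibration.{name} must be finite and > 0, got {v!r}")

    @classmethod
    def isotropic(cls, mm_per_px: float, frame_rate: float) -> "Calibration":
        return cls(mm_per_px, mm_per_px, frame_rate)


@dataclass(frozen=True)
class Frame:
    """One calibrated greyscale image: the unit of detection input."""

    pixels: np.ndarray  # 2-D float array, intensities in [0, 255]
    index: int
    time: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise FormatError(f"Frame.pixels must be 2-D, got shape {self.pixels.shape}")
        if self.index < 0:
            raise ValueError("Frame.index must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def px_to_mm(point: Sequence[float], calibration: Calibration) -> np.ndarray:
    """Map pixel coordinates ``(x, y)`` to physical millimetres."""
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError(f"non-finite pixel coordinates: {point!r}")
    return p * np.array([calibration.mm_per_px_x, calibration.mm_per_px_y])


def mm_to_px(point: Sequence[float], calibration: Calibration) -> np.ndarray:
    """Exact inverse of :func:`px_to_mm`."""
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError(f"non-finite physical coordinates: {point!r}")
    return p / np.array([calibration.mm_per_px_x, calibration.mm_per_px_y])


def _to_grey(img: np.ndarray) -> np.ndarray:
    """Collapse a colour image to luminance; pass greyscale through."""
    if img.ndim == 2:
        return np.asarray(img, dtype=float)
    if img.ndim == 3 and img.shape[-1] in (3, 4):
        return np.asarray(img[..., :3], dtype=float) @ _LUMA
    raise FormatError(f"unsupported image shape {img.shape}")


def _rescale_to_255(img: np.ndarray, dtype: np.dtype) -> np.ndarray:
    """Rescale integer bit depths other than 8-bit so that dtype max maps to 255."""
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        if info.max != 255:
            return img * (255.0 / info.max)
    return np.clip(img, 0.0, 255.0)


def load_sequence(path: str | Path, calibration: Calibration) -> list[Frame]:
    """Load an ordered greyscale frame sequence.

    ``path`` may be a directory of lexicographically ordered PNG/TIFF files or
    a single multi-page TIFF.  Colour images are converted to luminance and
    non-8-bit sources rescaled so that the dtype maximum maps to 255.
    """
    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file or directory: {path}")

    raw: list[tuple[np.ndarray, np.dtype]] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise FormatError(f"no PNG/TIFF frames found in {path}")
        for f in files:
            img = iio.imread(f)
            raw.append((_to_grey(img), img.dtype))
    else:
        if path.suffix.lower() in (".tif", ".tiff"):
            with tifffile.TiffFile(path) as tif:
                stack = np.stack([page.asarray() for page in tif.pages])
        else:
            stack = iio.imread(path)
        stack = np.asarray(stack)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim == 4:  # pages of colour images
            raw = [(_to_grey(page), stack.dtype) for page in stack]
        elif stack.ndim == 3 and stack.shape[-1] in (3, 4) and stack.shape[0] not in (3, 4):
            raw = [(_to_grey(stack), stack.dtype)]
        else:
            raw = [(np.asarray(page, dtype=float), stack.dtype) for page in stack]

    if not raw:
        raise FormatError(f"zero frames in {path}")
    shape = raw[0][0].shape
    for i, (img, _) in enumerate(raw):
        if img.shape != shape:
            raise FormatError(f"frame {i} has shape {img.shape}, expected {shape}")

    return [
        Frame(_rescale_to_255(img, dtype), index=i, time=i / calibration.frame_rate)
        for i, (img, dtype) in enumerate(raw)
    ]


@dataclass
class RunConfig:
    """Complete, reproducible configuration of one detection run."""

    calibration: Calibration
    detection_params: "DetectionParams" = field(default_factory=lambda: _default_detection())
    linking_params: "LinkingParams" = field(default_factory=lambda: _default_linking())
    report_window: float = 10.0  # seconds; trailing window for the "current" count rate
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.report_window <= 0:
            raise ValueError("report_window must be > 0")


def _default_detection():
    from .detection import DetectionParams

    return DetectionParams()


def _default_linking():
    from .reconstruction import LinkingParams

    return LinkingParams()


def load_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML (or JSON) file mirroring its field names."""
    from .detection import DetectionParams
    from .reconstruction import LinkingParams

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such config file: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        cal = Calibration(**data["calibration"])
    except KeyError as e:
        raise FormatError(f"config missing required section: {e}") from e
    det = DetectionParams(**data.get("detection_params", {}))
    link = LinkingParams(**data.get("linking_params", {}))
    return RunConfig(
        calibration=cal,
        detection_params=det,
        linking_params=link,
        report_window=float(data.get("report_window", 10.0)),
        seed=data.get("seed"),
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    data = {
        "calibration": dataclasses.asdict(config.calibration),
        "detection_params": dataclasses.asdict(config.detection_params),
        "linking_params": dataclasses.asdict(config.linking_params),
        "report_window": config.report_window,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class PipelineResult:
    """Everything one run produces: the report plus all intermediate products."""

    report: "Report"
    tracks: list["BubbleTrack"]
    slices: list  # list[BubbleSlice]
    roi_series: list  # list[(frame_index, RegionOfInterest)]


def run_pipeline(
    config: RunConfig,
    frames: Iterable[Frame],
    roi_seed: "RegionOfInterest",
) -> PipelineResult:
    """Run the full detection chain on a frame sequence.

    Deterministic composition detect_sequence -> link_slices -> merge_phantoms
    -> estimate_bubble -> compute_report; identical inputs and config give
    identical outputs.  An empty detection result is not an error: the report
    simply carries zero counts.
    """
    from .detection import detect_sequence
    from .reconstruction import estimate_bubble, link_slices, merge_phantoms
    from .reporting import compute_report

    slices, roi_series = detect_sequence(
        frames,
        roi_seed,
        config.detection_params,
        config.calibration,
        return_rois=True,
    )
    tracks = link_slices(slices, config.linking_params)
    tracks = merge_phantoms(tracks, config.linking_params)
    tracks = [estimate_bubble(t) for t in tracks]
    report = compute_report(tracks, slices, roi_series, config)
    return PipelineResult(report=report, tracks=tracks, slices=slices, roi_series=roi_series)


# ---------------------------------------------------------------------------
# Tabular exports shared by the CLI and the validation tools
# ---------------------------------------------------------------------------

def tracks_to_frame(tracks: Sequence["BubbleTrack"]):
    """Tracks as a pandas DataFrame matching the ``tracks.csv`` schema."""
    import pandas as pd

    rows = [
        {
            "track_id": t.track_id,
            "x_mm": t.position[0],
            "y_mm": t.position[1],
            "t_s": t.time,
            "radius_mm": t.radius,
            "volume_mm3": t.volume,
            "n_slices": len(t.slices),
        }
        for t in tracks
    ]
    return pd.DataFrame(
        rows, columns=["track_id", "x_mm", "y_mm", "t_s", "radius_mm", "volume_mm3", "n_slices"]
    )


def slices_to_frame(slices: Sequence):
    """Per-frame detections as a DataFrame matching the ``slices.csv`` schema."""
    import pandas as pd

    rows = [
        {
            "frame_index": s.frame_index,
            "time_s": s.time,
            "x_mm": s.centroid[0],
            "y_mm": s.centroid[1],
            "radius_mm": s.equivalent_radius,
            "area_mm2": s.area,
            "mean_intensity": s.mean_intensity,
        }
        for s in slices
    ]
    return pd.DataFrame(
        rows,
        columns=["frame_index", "time_s", "x_mm", "y_mm", "radius_mm", "area_mm2", "mean_intensity"],
    )


def read_tracks_csv(path: str | Path) -> list["BubbleTrack"]:
    """Re-hydrate tracks from a ``tracks.csv`` written by this package.

    Each row becomes a single-summary track (one synthetic slice carrying the
    track-level position/time/radius), sufficient for dual-stream matching.
    """
    import pandas as pd

    from .detection import BubbleSlice
    from .reconstruction import BubbleTrack, sphere_volume

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path)
    tracks = []
    for row in df.itertuples(index=False):
        sl = BubbleSlice(
            centroid=np.array([row.x_mm, row.y_mm]),
            equivalent_radius=float(row.radius_mm),
            area=float(np.pi * row.radius_mm**2),
            mean_intensity=255.0,
            frame_index=0,
            time=float(row.t_s),
        )
        tracks.append(
            BubbleTrack(
                track_id=int(row.track_id),
                slices=[sl],
                position=np.array([row.x_mm, row.y_mm]),
                time=float(row.t_s),
                radius=float(row.radius_mm),
                volume=float(sphere_volume(row.radius_mm)),
            )
        )
    return tracks


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write report.json, tracks.csv, slices.csv, recon3d.csv and histogram.csv."""
    from .reporting import export_report

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    export_report(result.report, out)
    tracks_to_frame(result.tracks).to_csv(out / "tracks.csv", index=False)
    slices_to_frame(result.slices).to_csv(out / "slices.csv", index=False)
    recon = tracks_to_frame(result.tracks)[["x_mm", "y_mm", "t_s", "radius_mm"]]
    recon.to_csv(out / "recon3d.csv", index=False)


def dump_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, stable float repr)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
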