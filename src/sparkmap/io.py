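"""Reading and writing recordings, pacing traces, ROI polygons and result tables.

Stacks are interchanged as multi-frame TIFF / OME-TIFF; pacing traces as CSV
with columns ``time_ms, level``; nucleus outlines as a JSON polygon list
(``[[[x, y], ...], ...]`` or GeoJSON-like ``{"polygons": [...]}``); results as
CSV tables with documented headers.  All intensities are handled as floating
point internally regardless of input bit depth; the calcium channel is the
quantitative channel and is never resampled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from sparkmap.config import AnalysisConfig

__all__ = [
    "TimelapseStack",
    "PacingTrace",
    "RecordingBundle",
    "detect_pacing_edges",
    "read_pacing_csv",
    "read_polygons",
    "read_recording",
    "write_stack",
    "write_results",
]

#: Columns of the spark result table, one row per retained spark.
SPARK_TABLE_COLUMNS = [
    "id",
    "block",
    "t_on_frames",
    "area_px",
    "area_um2",
    "com_x_px",
    "com_y_px",
    "amplitude",
    "fdhm_ms",
    "fwhm_x_um",
    "fwhm_y_um",
    "mass_ms_um",
    "dnt_px",
    "category",
    "flags",
]


@dataclass
class TimelapseStack:
    """One channel's x-y-t data: ``intensities[frame, row, col]`` plus geometry."""

    intensities: np.ndarray
    channel_label: str
    frame_rate_hz: float
    pixel_size_um: float
    origin_frame_index: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3 or self.intensities.shape[0] < 1:
            raise ValueError("intensities must be a (frames, rows, cols) array with >= 1 frame")
        if self.channel_label not in ("calcium", "membrane"):
            raise ValueError("channel_label must be 'calcium' or 'membrane'")
        if self.frame_rate_hz <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame_rate_hz and pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape[1:]

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    def temporal_mean(self) -> np.ndarray:
        return self.intensities.mean(axis=0)

    def frame_time_ms(self, frame: int) -> float:
        """Acquisition time of a frame relative to the start of the full recording."""
        return (self.origin_frame_index + frame) * self.frame_period_ms

    def crop_frames(self, start: int, stop: int) -> "TimelapseStack":
        if not (0 <= start < stop <= self.n_frames):
            raise ValueError(f"invalid frame range [{start}, {stop}) for {self.n_frames} frames")
        return TimelapseStack(
            self.intensities[start:stop],
            self.channel_label,
            self.frame_rate_hz,
            self.pixel_size_um,
            origin_frame_index=self.origin_frame_index + start,
        )


@dataclass
class PacingTrace:
    """Electrical-stimulation synchronization signal at its native sampling.

    The stimulus pulses are top-hat shaped and shorter than a frame period, so
    edge times are kept in milliseconds rather than snapped to frames; callers
    that need a frame index floor-convert.
    """

    time_ms: np.ndarray
    level: np.ndarray
    edge_times_ms: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        self.level = np.asarray(self.level, dtype=np.float64)
        if self.time_ms.shape != self.level.shape:
            raise ValueError("time_ms and level must have the same shape")
        if self.edge_times_ms is None:
            self.edge_times_ms = detect_pacing_edges(self.time_ms, self.level)
        self.edge_times_ms = np.asarray(self.edge_times_ms, dtype=np.float64)
        if np.any(np.diff(self.edge_times_ms) <= 0):
            raise ValueError("pacing edges must be strictly ascending")

    @property
    def n_edges(self) -> int:
        return int(self.edge_times_ms.size)

    @property
    def is_paced(self) -> bool:
        return self.n_edges > 0

    def check_period(self, pacing_hz: float, tol: float = 0.05) -> bool:
        """True when consecutive edges match the nominal pacing period within tol."""
        if self.n_edges < 2:
            return True
        gaps = np.diff(self.edge_times_ms)
        period_ms = 1000.0 / pacing_hz
        return bool(np.all(np.abs(gaps - period_ms) <= tol * period_ms))

    def last_edge_before(self, t_ms: float) -> float | None:
        earlier = self.edge_times_ms[self.edge_times_ms <= t_ms]
        return float(earlier[-1]) if earlier.size else None


@dataclass
class RecordingBundle:
    """Co-registered dual-channel recording plus pacing and provenance metadata."""

    calcium: TimelapseStack
    membrane: TimelapseStack
    pacing: PacingTrace | None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.calcium.n_frames != self.membrane.n_frames:
            raise ValueError(
                f"channel frame counts differ: calcium {self.calcium.n_frames}, "
                f"membrane {self.membrane.n_frames}"
            )

    @property
    def is_paced(self) -> bool:
        return self.pacing is not None and self.pacing.is_paced


def detect_pacing_edges(time_ms: np.ndarray, level: np.ndarray) -> np.ndarray:
    """Rising-edge times of a top-hat pulse train.

    The threshold is the midpoint of the observed dynamic range; a constant
    trace has no edges.
    """
    time_ms = np.asarray(time_ms, dtype=np.float64)
    level = np.asarray(level, dtype=np.float64)
    lo, hi = level.min(), level.max()
    if hi - lo <= 0:
        return np.empty(0)
    high = level > (lo + hi) / 2.0
    rising = np.flatnonzero(~high[:-1] & high[1:]) + 1
    return time_ms[rising]


def read_pacing_csv(path: str | Path) -> PacingTrace:
    df = pd.read_csv(path)
    if not {"time_ms", "level"} <= set(df.columns):
        raise ValueError(f"pacing CSV must have columns time_ms, level; got {list(df.columns)}")
    return PacingTrace(df["time_ms"].to_numpy(), df["level"].to_numpy())


def write_pacing_csv(trace: PacingTrace, path: str | Path) -> None:
    pd.DataFrame({"time_ms": trace.time_ms, "level": trace.level}).to_csv(path, index=False)


def read_polygons(path: str | Path) -> list[np.ndarray]:
    """Read nucleus outlines from a JSON polygon list.

    Accepts a bare list of polygons (each ``[[x, y], ...]`` in pixel
    coordinates) or an object with a ``"polygons"`` key.
    """
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = data.get("polygons", [])
    return [np.asarray(p, dtype=np.float64) for p in data]


def write_stack(stack: TimelapseStack, path: str | Path, dtype=None) -> None:
    """Write a stack as multi-frame TIFF, preserving integer inputs exactly."""
    data = stack.intensities
    if dtype is not None:
        data = data.astype(dtype)
    elif np.allclose(data, np.round(data)) and data.min() >= 0 and data.max() < 2**16:
        data = data.astype(np.uint16)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(
        str(path),
        data,
        metadata={
            "axes": "TYX",
            "channel_label": stack.channel_label,
            "frame_rate_hz": stack.frame_rate_hz,
            "pixel_size_um": stack.pixel_size_um,
        },
    )


def read_stack(
    path: str | Path,
    channel_label: str,
    config: AnalysisConfig,
    origin_frame_index: int = 0,
) -> TimelapseStack:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return TimelapseStack(
        data.astype(np.float64),
        channel_label,
        config.frame_rate_hz,
        config.pixel_size_um,
        origin_frame_index=origin_frame_index,
    )


def read_recording(
    calcium_path: str | Path,
    membrane_path: str | Path,
    pacing_path: str | Path | None,
    config: AnalysisConfig,
    metadata: dict | None = None,
) -> RecordingBundle:
    """Load a dual-channel recording and its pacing trace into a bundle.

    Mismatched frame counts are a hard error.  A missing or edge-free pacing
    trace flags the bundle "unpaced": spark analysis still runs, transient
    stages refuse to.
    """
    calcium = read_stack(calcium_path, "calcium", config)
    membrane = read_stack(membrane_path, "membrane", config)
    if calcium.n_frames != membrane.n_frames:
        raise ValueError(
            f"channel frame counts differ: {calcium.n_frames} vs {membrane.n_frames}"
        )
    pacing: PacingTrace | None = None
    meta = dict(metadata or {})
    if pacing_path is not None and Path(pacing_path).exists():
        pacing = read_pacing_csv(pacing_path)
        if not pacing.is_paced:
            warnings.warn("pacing trace contains no rising edges; bundle is unpaced")
            meta["unpaced"] = True
    else:
        warnings.warn("no pacing trace; bundle is unpaced (spark analysis only)")
        meta["unpaced"] = True
    return RecordingBundle(calcium, membrane, pacing, meta)


def sparks_to_table(sparks: list) -> pd.DataFrame:
    """Spark events to a result table; an empty list yields a header-only table."""
    rows = []
    for s in sparks:
        rows.append(
            {
                "id": s.id,
                "block": s.block,
                "t_on_frames": s.t_on_frames,
                "area_px": s.area_px,
                "area_um2": s.area_um2,
                "com_x_px": s.com_xy[0],
                "com_y_px": s.com_xy[1],
                "amplitude": s.amplitude,
                "fdhm_ms": s.fdhm_ms,
                "fwhm_x_um": s.fwhm_x_um,
                "fwhm_y_um": s.fwhm_y_um,
                "mass_ms_um": s.mass_ms_um,
                "dnt_px": s.dnt_px,
                "category": s.category,
                "flags": ";".join(sorted(s.flags)),
            }
        )
    return pd.DataFrame(rows, columns=SPARK_TABLE_COLUMNS)


def write_results(sparks, t50, regions, out_dir: str | Path) -> dict[str, Path]:
    """Write the spark table, T50 maps and regional summary to ``out_dir``.

    Returns a name -> path map of everything written.  Any of the three inputs
    may be None and is then skipped.  T50 maps are written as 32-bit float TIFF
    with NaN outside the valid mask.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if sparks is not None:
        path = out_dir / "sparks.csv"
        sparks_to_table(sparks).to_csv(path, index=False)
        written["sparks"] = path

    if t50 is not None:
        path = out_dir / "t50_mean_ms.tif"
        mean_map = np.where(t50.valid_mask, t50.mean_ms, np.nan).astype(np.float32)
        tifffile.imwrite(str(path), mean_map)
        written["t50_mean"] = path
        path = out_dir / "t50_sd_ms.tif"
        sd_map = np.where(t50.valid_mask, t50.sd_ms, np.nan).astype(np.float32)
        tifffile.imwrite(str(path), sd_map)
        written["t50_sd"] = path

    if regions is not None:
        path = out_dir / "t50_regions.csv"
        regions.to_frame().to_csv(path, index=False)
        written["regions"] = path

    return written
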