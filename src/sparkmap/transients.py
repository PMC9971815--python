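"""Pixel-wise transient time-to-half-maximum (T50) mapping and regional summaries.

For each paced transient the calcium stack is smoothed (5 x 5 spatial median,
3-frame moving average), cropped to a window centred on the cell-average peak
and paired with the preceding pacing rising edge.  Per pixel, the baseline is
the mean over a 50-frame window up to the stimulus edge and the peak is the
mean over 20 frames from the cell-average peak frame; T50 is the time from
the stimulus edge until the signal first crosses F50 = (baseline + peak)/2 on
the rising limb, located by linear interpolation between the bracketing
frames.  Maps from three consecutive transients are aggregated pixel-wise
into mean and SD maps.  Regional summaries compare nuclear vs exonuclear and
central-half vs outer-quarter medians and report the dyssynchrony index (the
IQR of the per-pixel T50 distribution); T50-vs-DNT correlation is quantified
by ordinary least squares separately for tubulated (DNT <= 5 px) and
detubulated (DNT > 5 px) pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, stats

from sparkmap.config import AnalysisConfig
from sparkmap.io import PacingTrace, TimelapseStack
from sparkmap.preprocess import CellMask
from sparkmap.structure import DNTMap, NucleusMask

__all__ = [
    "TransientWindow",
    "T50Map",
    "RegionalT50Summary",
    "T50DNTFit",
    "locate_transients",
    "compute_t50_map",
    "aggregate_t50_maps",
    "summarize_regions",
    "fit_t50_vs_dnt",
]


@dataclass
class TransientWindow:
    """One cropped transient plus its stimulus reference and baseline/peak maps."""

    data: np.ndarray  # (frames, rows, cols), smoothed
    start_frame: int  # window start, frames relative to the full stack
    frame_rate_hz: float
    edge_time_ms: float  # pacing rising edge, ms on the full-recording clock
    peak_frame: int  # cell-average peak, frames relative to the full stack
    baseline_map: np.ndarray
    peak_map: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("window data must be (frames, rows, cols)")

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    def frame_time_ms(self, frame_in_window: int) -> float:
        return (self.start_frame + frame_in_window) * self.frame_period_ms

    @property
    def dff_peak_map(self) -> np.ndarray:
        """dF/F0 at the transient peak (peak - baseline) / baseline."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (self.peak_map - self.baseline_map) / self.baseline_map
        out[~np.isfinite(out)] = np.nan
        return out


@dataclass
class T50Map:
    """Per-transient and aggregate stimulus-referenced T50 maps, in ms."""

    per_transient_ms: list[np.ndarray]
    mean_ms: np.ndarray
    sd_ms: np.ndarray
    valid_mask: np.ndarray

    @property
    def n_transients(self) -> int:
        return len(self.per_transient_ms)

    def values(self) -> np.ndarray:
        """Defined T50 values of the aggregate map, flattened."""
        return self.mean_ms[self.valid_mask]


@dataclass
class RegionalT50Summary:
    median_nuclear_ms: float | None
    median_exonuclear_ms: float
    median_central_ms: float
    median_outer_ms: float
    delta_nuclear_ms: float | None  # nucleus - exonuclear
    delta_central_outer_ms: float  # central - outer
    dyssynchrony_iqr_ms: float
    n_pixels: dict[str, int]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "median_nuclear_ms": self.median_nuclear_ms,
                    "median_exonuclear_ms": self.median_exonuclear_ms,
                    "median_central_ms": self.median_central_ms,
                    "median_outer_ms": self.median_outer_ms,
                    "delta_nuclear_ms": self.delta_nuclear_ms,
                    "delta_central_outer_ms": self.delta_central_outer_ms,
                    "dyssynchrony_iqr_ms": self.dyssynchrony_iqr_ms,
                }
            ]
        )


@dataclass
class T50DNTFit:
    """OLS fit of T50 (ms) on DNT (px) for one pixel-population class."""

    region_class: str  # "tubulated" or "detubulated"
    slope_ms_per_px: float
    intercept_ms: float
    ci95: tuple[float, float]
    n_pixels: int


def _smooth_transient_stack(data: np.ndarray) -> np.ndarray:
    """5 x 5 spatial median then 3-frame centred moving average."""
    out = ndimage.median_filter(data, size=(1, 5, 5), mode="nearest")
    return ndimage.uniform_filter1d(out, size=3, axis=0, mode="nearest")


def locate_transients(
    calcium: TimelapseStack,
    pacing: PacingTrace | None,
    cell: CellMask,
    config: AnalysisConfig,
) -> list[TransientWindow]:
    """Find paced transient peaks and crop one window per selected transient.

    The cell-average trace of the smoothed stack is scanned for peaks with a
    minimum separation of 95% of a pacing period; the first ``n_transients``
    consecutive peaks that have a preceding pacing edge inside their window
    are selected.  Each window is ``crop_frames`` long, centred on its peak,
    with the baseline map from ``baseline_window_frames`` before the edge and
    the peak map from ``peak_window_frames`` starting at the peak.
    """
    if pacing is None or not pacing.is_paced:
        raise ValueError("transient analysis requires a paced recording")
    dt_ms = calcium.frame_period_ms
    smoothed = _smooth_transient_stack(calcium.intensities)
    trace = smoothed[:, cell.mask].mean(axis=1)

    min_sep = int(round(config.min_peak_separation_fraction * config.pacing_period_s
                        * calcium.frame_rate_hz))
    prominence = 0.25 * (trace.max() - trace.min())
    peaks, _ = signal.find_peaks(trace, distance=max(min_sep, 1), prominence=prominence)
    if peaks.size < config.n_transients:
        raise ValueError(
            f"found {peaks.size} transient peaks, need {config.n_transients}"
        )

    half = config.crop_frames // 2
    windows: list[TransientWindow] = []
    for pk in peaks:
        if len(windows) == config.n_transients:
            break
        start = pk - half
        stop = start + config.crop_frames
        if start < 0 or stop > calcium.n_frames:
            continue
        peak_time_ms = calcium.frame_time_ms(int(pk))
        window_start_ms = calcium.frame_time_ms(int(start))
        edge = pacing.last_edge_before(peak_time_ms)
        if edge is None or edge < window_start_ms:
            warnings.warn("transient peak without a preceding pacing edge in-window; dropped")
            continue
        edge_frame = int(np.floor(edge / dt_ms)) - calcium.origin_frame_index
        base_lo = edge_frame - config.baseline_window_frames
        if base_lo < start:
            warnings.warn("baseline window does not fit before the pacing edge; dropped")
            continue
        baseline_map = smoothed[base_lo:edge_frame].mean(axis=0)
        peak_map = smoothed[pk : pk + config.peak_window_frames].mean(axis=0)
        windows.append(
            TransientWindow(
                data=smoothed[start:stop],
                start_frame=int(start) + calcium.origin_frame_index,
                frame_rate_hz=calcium.frame_rate_hz,
                edge_time_ms=float(edge),
                peak_frame=int(pk) + calcium.origin_frame_index,
                baseline_map=baseline_map,
                peak_map=peak_map,
            )
        )
    if len(windows) < config.n_transients:
        raise ValueError(
            f"only {len(windows)} usable transients, need {config.n_transients}"
        )
    return windows


def compute_t50_map(window: TransientWindow, cell: CellMask) -> np.ndarray:
    """Per-pixel T50 in ms from the stimulus edge; NaN where undefined.

    F50 = (peak + baseline) / 2.  The crossing is searched on the rising limb
    between the stimulus edge and the cell-average peak frame; the first
    crossing is taken, linearly interpolated between the last frame below and
    the first frame at/above F50.  Pixels with peak <= baseline, or with no
    crossing in the search window, are undefined.
    """
    dt_ms = window.frame_period_ms
    edge_frame_abs = int(np.floor(window.edge_time_ms / dt_ms))
    lo = max(edge_frame_abs - window.start_frame, 0)
    hi = window.peak_frame - window.start_frame + 1
    if hi <= lo + 1:
        raise ValueError("empty rising-limb search window")
    seg = window.data[lo:hi]  # (n, rows, cols)
    f50 = (window.peak_map + window.baseline_map) / 2.0

    defined = (window.peak_map > window.baseline_map) & cell.mask
    above = seg >= f50[None, :, :]
    # first frame at/above F50 within the search window
    any_above = above.any(axis=0)
    first_idx = above.argmax(axis=0)
    ok = defined & any_above & (first_idx > 0)  # need a bracketing frame below

    t50 = np.full(cell.mask.shape, np.nan)
    rr, cc = np.nonzero(ok)
    if rr.size:
        fi = first_idx[rr, cc]
        before = seg[fi - 1, rr, cc]
        after = seg[fi, rr, cc]
        level = f50[rr, cc]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = (level - before) / (after - before)
        frac = np.clip(np.where(np.isfinite(frac), frac, 0.0), 0.0, 1.0)
        cross_frame = (lo + fi - 1) + frac  # frames, window-relative
        cross_ms = (window.start_frame + cross_frame) * dt_ms
        t50[rr, cc] = cross_ms - window.edge_time_ms
    return t50


def aggregate_t50_maps(maps_ms: list[np.ndarray]) -> T50Map:
    """Pixel-wise mean and sample SD over transients where all maps are defined."""
    if len(maps_ms) < 2:
        raise ValueError("need at least 2 per-transient maps to aggregate")
    stack = np.stack(maps_ms)
    valid = np.all(np.isfinite(stack), axis=0)
    mean = np.where(valid, stack.mean(axis=0), np.nan)
    sd = np.where(valid, stack.std(axis=0, ddof=1), np.nan)
    return T50Map(per_transient_ms=list(maps_ms), mean_ms=mean, sd_ms=sd, valid_mask=valid)


def summarize_regions(
    t50: T50Map, cell: CellMask, nuclei: NucleusMask | None = None
) -> RegionalT50Summary:
    """Regional medians, deltas and the dyssynchrony index of the aggregate map.

    The cell is assumed approximately horizontal: its length is taken from the
    first and last columns with defined T50; the central ROI spans the middle
    half of that length and the two outer quarters are grouped.  Nuclear
    pixels are excluded from the central/outer and exonuclear populations.
    """
    valid = t50.valid_mask & cell.mask
    if not valid.any():
        raise ValueError("T50 map has no defined pixels inside the cell")
    vals = t50.mean_ms

    nuc_mask = nuclei.mask if nuclei is not None else np.zeros_like(cell.mask)
    n_nuclei = nuclei.n_nuclei if nuclei is not None else 0

    cols = np.nonzero(valid.any(axis=0))[0]
    c0, c1 = int(cols[0]), int(cols[-1])
    length = c1 - c0 + 1
    q = length / 4.0
    col_idx = np.arange(valid.shape[1])
    central_cols = (col_idx >= c0 + q) & (col_idx <= c1 - q)
    outer_cols = ((col_idx >= c0) & (col_idx < c0 + q)) | ((col_idx > c1 - q) & (col_idx <= c1))

    central = valid & central_cols[None, :] & ~nuc_mask
    outer = valid & outer_cols[None, :] & ~nuc_mask
    exonuclear = valid & ~nuc_mask
    nuclear = valid & nuc_mask

    def med(mask: np.ndarray) -> float | None:
        return float(np.median(vals[mask])) if mask.any() else None

    median_nuclear = med(nuclear) if n_nuclei > 0 else None
    median_exonuclear = med(exonuclear)
    median_central = med(central)
    median_outer = med(outer)
    if median_exonuclear is None or median_central is None or median_outer is None:
        raise ValueError("a required region has no defined T50 pixels")

    all_vals = vals[valid]
    q25, q75 = np.percentile(all_vals, [25, 75])

    return RegionalT50Summary(
        median_nuclear_ms=median_nuclear,
        median_exonuclear_ms=median_exonuclear,
        median_central_ms=median_central,
        median_outer_ms=median_outer,
        delta_nuclear_ms=(median_nuclear - median_exonuclear) if median_nuclear is not None else None,
        delta_central_outer_ms=median_central - median_outer,
        dyssynchrony_iqr_ms=float(q75 - q25),
        n_pixels={
            "nuclear": int(nuclear.sum()),
            "exonuclear": int(exonuclear.sum()),
            "central": int(central.sum()),
            "outer": int(outer.sum()),
        },
    )


def fit_t50_vs_dnt(
    t50: T50Map, dnt: DNTMap, paratubular_max_px: float = 5.0
) -> dict[str, T50DNTFit]:
    """OLS of per-pixel T50 (ms) on DNT (px), per region class.

    "Tubulated" pixels have DNT <= the paratubular bound (epitubular +
    paratubular); "detubulated" pixels lie beyond it.  The 95% CI of the slope
    comes from its standard error and the t distribution.  Classes with fewer
    than 3 pixels or with degenerate DNT variance are omitted.
    """
    valid = t50.valid_mask & dnt.cell.mask & np.isfinite(dnt.dnt_px)
    d = dnt.dnt_px[valid]
    y = t50.mean_ms[valid]
    classes = {
        "tubulated": d <= paratubular_max_px,
        "detubulated": d > paratubular_max_px,
    }
    fits: dict[str, T50DNTFit] = {}
    for name, sel in classes.items():
        if sel.sum() < 3 or np.ptp(d[sel]) == 0:
            continue
        res = stats.linregress(d[sel], y[sel])
        n = int(sel.sum())
        tcrit = stats.t.ppf(0.975, n - 2)
        fits[name] = T50DNTFit(
            region_class=name,
            slope_ms_per_px=float(res.slope),
            intercept_ms=float(res.intercept),
            ci95=(
                float(res.slope - tcrit * res.stderr),
                float(res.slope + tcrit * res.stderr),
            ),
            n_pixels=n,
        )
    return fits
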