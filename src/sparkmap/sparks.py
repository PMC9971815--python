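"""Two-pass calcium spark detection and morphometric characterization.

Detection operates on the unpaced segment of the recording (by default the
last 5 x 1000-frame blocks), smoothed with a normalized 5 x 5 x 3 box kernel
and divided by a per-block per-pixel baseline map F0 so that the working
signal is dF/F0.  Candidate events are x-y-t connected components above the
per-pixel lower threshold T_L = mu + 2.9 sigma that contain at least one
voxel above the upper threshold T_H = mu + 5.4 sigma, where mu and sigma are
the per-pixel dF/F0 statistics over each block (hysteresis thresholding).
Because any sparks present bias mu, sigma and F0, the algorithm runs twice:
pass-1 events are masked out, F0 is re-estimated from the first 100 frames of
each block with spark voxels excluded, the statistics are recomputed, and
detection is repeated.  Events are then characterized (area, amplitude, FDHM,
FWHM in x and y, spark mass = amplitude x mean FWHM x FDHM, centre of mass,
DNT category) and filtered: area < 50 px or on-time < 4 frames rejected,
"unfinished" events that never fall back below F50 excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from sparkmap.config import AnalysisConfig
from sparkmap.io import TimelapseStack
from sparkmap.preprocess import CellMask
from sparkmap.structure import CATEGORIES, DNTMap

__all__ = [
    "SparkDetectionState",
    "SparkEvent",
    "SparkRateSummary",
    "prepare_spark_segment",
    "detect_spark_candidates",
    "characterize_spark",
    "filter_sparks",
    "detect_sparks",
    "compute_spark_rates",
]

_SIGMA_FLOOR = np.finfo(np.float32).eps


@dataclass
class SparkDetectionState:
    """Per-block baseline maps and thresholds for one detection pass."""

    block_bounds: list[tuple[int, int]]
    f0: np.ndarray  # (n_blocks, rows, cols) baseline maps
    mu: np.ndarray  # per-block per-pixel mean of dF/F0
    sigma: np.ndarray  # per-block per-pixel SD of dF/F0
    k_low: float
    k_high: float
    cell_mask: np.ndarray
    pass_index: int = 1

    @property
    def t_low(self) -> np.ndarray:
        return self.mu + self.k_low * self.sigma

    @property
    def t_high(self) -> np.ndarray:
        return self.mu + self.k_high * self.sigma

    @property
    def n_blocks(self) -> int:
        return len(self.block_bounds)


@dataclass
class SparkComponent:
    """A raw connected component in x-y-t, before characterization."""

    block: int
    frames: np.ndarray  # voxel frame indices (segment-relative)
    rows: np.ndarray
    cols: np.ndarray


@dataclass
class SparkEvent:
    id: int
    block: int
    frame_span: tuple[int, int]  # [first, last] segment-relative frames above T_L
    mask_2d: np.ndarray
    area_px: int
    area_um2: float
    com_xy: tuple[float, float]  # (x = col, y = row), intensity-weighted, pixels
    amplitude: float
    fdhm_ms: float
    fwhm_x_um: float
    fwhm_y_um: float
    fwhm_mean_um: float
    mass_ms_um: float
    dnt_px: float = float("nan")
    category: str = ""
    flags: set[str] = field(default_factory=set)

    @property
    def t_on_frames(self) -> int:
        return self.frame_span[1] - self.frame_span[0] + 1


@dataclass
class SparkRateSummary:
    """Spark counts and rates per 100 um^2 per second, per DNT category."""

    n_sparks: dict[str, int]
    area_um2: dict[str, float]
    duration_s: float
    rate_per_100um2_s: dict[str, float | None]
    fraction: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.n_sparks.values())


def smooth_stack(data: np.ndarray, kernel: tuple[int, int, int]) -> np.ndarray:
    """Normalized box smoothing; kernel is (rows, cols, frames)."""
    kr, kc, kt = kernel
    return ndimage.uniform_filter(data, size=(kt, kr, kc), mode="nearest")


def prepare_spark_segment(
    calcium: TimelapseStack,
    cell: CellMask,
    config: AnalysisConfig,
) -> tuple[np.ndarray, SparkDetectionState]:
    """Smooth and per-block normalize the spark segment; build pass-1 state.

    Uses the last ``n_blocks x block_len_frames`` frames of the stack (the
    unpaced tail of the acquisition).  Returns the dF/F0 stack (dimensionless,
    segment-relative frames) and the detection state whose pass-1 baseline F0
    is the per-block per-pixel temporal mean — identical to the normalization
    map.
    """
    seg_len = config.n_blocks * config.block_len_frames
    if calcium.n_frames < config.block_len_frames:
        raise ValueError(
            f"segment of {calcium.n_frames} frames is shorter than one "
            f"{config.block_len_frames}-frame block"
        )
    n_blocks = min(config.n_blocks, calcium.n_frames // config.block_len_frames)
    seg_len = n_blocks * config.block_len_frames
    data = calcium.intensities[-seg_len:].astype(np.float32)

    smoothed = smooth_stack(data, config.smooth_kernel)
    bounds = [
        (b * config.block_len_frames, (b + 1) * config.block_len_frames) for b in range(n_blocks)
    ]
    rows, cols = data.shape[1:]
    f0 = np.empty((n_blocks, rows, cols), dtype=np.float32)
    dff = np.empty_like(smoothed)
    for b, (lo, hi) in enumerate(bounds):
        f0[b] = smoothed[lo:hi].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            dff[lo:hi] = smoothed[lo:hi] / f0[b] - 1.0
    dff[~np.isfinite(dff)] = 0.0

    mu = np.empty_like(f0)
    sigma = np.empty_like(f0)
    for b, (lo, hi) in enumerate(bounds):
        mu[b] = dff[lo:hi].mean(axis=0)
        sigma[b] = dff[lo:hi].std(axis=0)
    sigma = np.maximum(sigma, _SIGMA_FLOOR)

    state = SparkDetectionState(
        block_bounds=bounds,
        f0=f0,
        mu=mu,
        sigma=sigma,
        k_low=config.k_low,
        k_high=config.k_high,
        cell_mask=cell.mask,
        pass_index=1,
    )
    # keep the smoothed raw segment for the second-pass F0 re-estimate
    state._smoothed = smoothed  # type: ignore[attr-defined]
    return dff, state


def _structure(connectivity: str) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == "face" else 3)


def _label_pass(
    dff: np.ndarray, state: SparkDetectionState, connectivity: str
) -> list[SparkComponent]:
    """One hysteresis-labelling pass: components >= T_L seeded by >= T_H."""
    comps: list[SparkComponent] = []
    cell = state.cell_mask
    seedable = state.sigma > _SIGMA_FLOOR  # noiseless pixels cannot seed
    structure = _structure(connectivity)
    for b, (lo, hi) in enumerate(state.block_bounds):
        block = dff[lo:hi]
        above_low = (block >= state.t_low[b]) & cell
        labels, n = ndimage.label(above_low, structure=structure)
        if n == 0:
            continue
        seeds = above_low & (block >= state.t_high[b]) & seedable[b]
        seeded = np.unique(labels[seeds])
        seeded = seeded[seeded > 0]
        for lab in seeded:
            t, r, c = np.nonzero(labels == lab)
            comps.append(SparkComponent(block=b, frames=t + lo, rows=r, cols=c))
    return comps


def detect_spark_candidates(
    state: SparkDetectionState,
    dff: np.ndarray,
    config: AnalysisConfig,
) -> tuple[list[SparkComponent], np.ndarray, SparkDetectionState]:
    """Run both detection passes; return final components, dF/F0 and state.

    Pass 1 detects preliminary events on the prepared dF/F0.  Their voxels are
    then excluded, F0 is recomputed over the first ``baseline_frames`` of each
    block with spark voxels masked (pixels fully masked there fall back to the
    block mean), mu and sigma are recomputed with spark voxels excluded, and
    pass 2 re-detects on the refreshed dF/F0.
    """
    prelim = _label_pass(dff, state, config.connectivity)
    smoothed = state._smoothed  # type: ignore[attr-defined]

    spark_voxels = np.zeros(dff.shape, dtype=bool)
    for comp in prelim:
        spark_voxels[comp.frames, comp.rows, comp.cols] = True

    n_blocks = state.n_blocks
    f0 = np.empty_like(state.f0)
    mu = np.empty_like(state.mu)
    sigma = np.empty_like(state.sigma)
    dff2 = np.empty_like(dff)
    for b, (lo, hi) in enumerate(state.block_bounds):
        base_hi = min(lo + config.baseline_frames, hi)
        base = smoothed[lo:base_hi]
        base_ok = ~spark_voxels[lo:base_hi]
        counts = base_ok.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f0_b = np.where(base_ok, base, 0.0).sum(axis=0) / counts
        f0_b = np.where(counts > 0, f0_b, state.f0[b])  # fully-masked fallback
        f0[b] = f0_b
        with np.errstate(divide="ignore", invalid="ignore"):
            dff2[lo:hi] = smoothed[lo:hi] / f0_b - 1.0
        dff2[lo:hi][~np.isfinite(dff2[lo:hi])] = 0.0
        blk_ok = ~spark_voxels[lo:hi]
        n_ok = blk_ok.sum(axis=0)
        blk = np.where(blk_ok, dff2[lo:hi], 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            m = blk.sum(axis=0) / n_ok
            v = (np.where(blk_ok, (dff2[lo:hi] - m) ** 2, 0.0)).sum(axis=0) / n_ok
        m = np.where(n_ok > 0, m, 0.0)
        v = np.where(n_ok > 0, v, 0.0)
        mu[b] = m
        sigma[b] = np.sqrt(v)
    sigma = np.maximum(sigma, _SIGMA_FLOOR)

    state2 = SparkDetectionState(
        block_bounds=state.block_bounds,
        f0=f0,
        mu=mu,
        sigma=sigma,
        k_low=state.k_low,
        k_high=state.k_high,
        cell_mask=state.cell_mask,
        pass_index=2,
    )
    state2._smoothed = smoothed  # type: ignore[attr-defined]
    final = _label_pass(dff2, state2, config.connectivity)
    return final, dff2, state2


def characterize_spark(
    comp: SparkComponent,
    dff: np.ndarray,
    state: SparkDetectionState,
    config: AnalysisConfig,
    dnt: DNTMap | None = None,
    spark_id: int = 0,
) -> SparkEvent:
    """Full morphometry of one detected component.

    The x-y-t mask is collapsed along time to a 2D footprint; the temporal
    profile is the footprint-mean of F/F0 per frame.  Amplitude is
    (peak - baseline) / baseline with the peak taken at the event's brightest
    voxel (the footprint mean would dilute a localized Gaussian event by the
    ratio of its core to the threshold contour).  FDHM is the time between the
    first and last frames at or above F50 (baseline + half of the profile's
    peak-above-baseline); for a separable event the footprint-mean profile is
    proportional to the true time course, so FDHM is unaffected by the
    footprint extent.  FWHM in x / y counts the contiguous run of pixels at or above the
    per-line F50 along the row / column through the centre of mass at the peak
    frame.  Mass = amplitude x mean(FWHM_x, FWHM_y) x FDHM by construction.
    """
    lo, hi = state.block_bounds[comp.block]
    mask2d = np.zeros(dff.shape[1:], dtype=bool)
    mask2d[comp.rows, comp.cols] = True
    area_px = int(mask2d.sum())
    px = config.pixel_size_um
    dt_ms = config.frame_period_ms

    # temporal profile of F/F0 over the footprint, within the block
    norm = dff[lo:hi][:, mask2d] + 1.0  # (block_frames, area)
    profile = norm.mean(axis=1)
    baseline = float((state.mu[comp.block][mask2d] + 1.0).mean())

    t0, t1 = int(comp.frames.min()), int(comp.frames.max())
    span = profile[t0 - lo : t1 - lo + 1]
    peak_rel = int(np.argmax(span))
    peak_idx = t0 - lo + peak_rel
    peak = float(profile[peak_idx])
    peak_voxel = float(dff[comp.frames, comp.rows, comp.cols].max()) + 1.0
    amplitude = (peak_voxel - baseline) / baseline
    f50 = baseline + (peak - baseline) / 2.0

    flags: set[str] = set()
    if t0 == lo or t1 == hi - 1:
        flags.add("boundary-truncated")

    # FDHM: frames at/above F50 contiguous around the peak
    first_above = peak_idx
    while first_above > 0 and profile[first_above - 1] >= f50:
        first_above -= 1
    last_above = peak_idx
    n_frames_block = profile.size
    while last_above < n_frames_block - 1 and profile[last_above + 1] >= f50:
        last_above += 1
    if last_above == n_frames_block - 1 and profile[last_above] >= f50:
        flags.add("unfinished")
    fdhm_ms = (last_above - first_above) * dt_ms

    # centre of mass: dF/F0-weighted centroid of the footprint at the peak frame
    # (peak-frame weighting; accumulating over all frames integrates clipped
    # noise over the footprint and biases the centroid)
    weights = np.where(mask2d, np.maximum(dff[lo + peak_idx], 0.0), 0.0)
    total = weights.sum()
    if total <= 0:
        weights = mask2d.astype(np.float64)
        total = weights.sum()
    rr, cc = np.nonzero(weights > 0)
    com_row = float((rr * weights[rr, cc]).sum() / total)
    com_col = float((cc * weights[rr, cc]).sum() / total)

    # FWHM: contiguous runs at/above the per-line F50 through the COM at the peak frame
    peak_frame = dff[lo + peak_idx] + 1.0
    r_i, c_i = int(round(com_row)), int(round(com_col))
    fwhm_x_px = _line_fwhm(peak_frame[r_i, :], c_i, baseline)
    fwhm_y_px = _line_fwhm(peak_frame[:, c_i], r_i, baseline)
    fwhm_x_um = fwhm_x_px * px
    fwhm_y_um = fwhm_y_px * px
    fwhm_mean_um = (fwhm_x_um + fwhm_y_um) / 2.0

    event = SparkEvent(
        id=spark_id,
        block=comp.block,
        frame_span=(t0, t1),
        mask_2d=mask2d,
        area_px=area_px,
        area_um2=area_px * px**2,
        com_xy=(com_col, com_row),
        amplitude=amplitude,
        fdhm_ms=fdhm_ms,
        fwhm_x_um=fwhm_x_um,
        fwhm_y_um=fwhm_y_um,
        fwhm_mean_um=fwhm_mean_um,
        mass_ms_um=amplitude * fwhm_mean_um * fdhm_ms,
        flags=flags,
    )
    if dnt is not None:
        event.dnt_px = float(dnt.dnt_px[r_i, c_i])
        event.category = dnt.category_at(com_row, com_col)
    return event


def _line_fwhm(line: np.ndarray, centre: int, baseline: float) -> int:
    """Contiguous pixel count at/above the line's own F50 through ``centre``."""
    peak = float(line[centre])
    # search a short neighbourhood for the true line peak (COM rounding)
    lo = max(0, centre - 2)
    hi = min(line.size, centre + 3)
    local = int(np.argmax(line[lo:hi])) + lo
    peak = max(peak, float(line[local]))
    f50 = baseline + (peak - baseline) / 2.0
    above = line >= f50
    if not above[centre]:
        centre = local
        if not above[centre]:
            return 1
    left = centre
    while left > 0 and above[left - 1]:
        left -= 1
    right = centre
    while right < line.size - 1 and above[right + 1]:
        right += 1
    return right - left + 1


def filter_sparks(events: list[SparkEvent], config: AnalysisConfig) -> list[SparkEvent]:
    """Reject small (< min area), brief (< min duration) and unfinished events."""
    kept = []
    for e in events:
        if e.area_px < config.min_area_px:
            continue
        if e.t_on_frames < config.min_duration_frames:
            continue
        if "unfinished" in e.flags:
            continue
        kept.append(e)
    return kept


def detect_sparks(
    calcium: TimelapseStack,
    cell: CellMask,
    config: AnalysisConfig,
    dnt: DNTMap | None = None,
) -> tuple[list[SparkEvent], SparkDetectionState]:
    """End-to-end spark pipeline: prepare, two-pass detect, characterize, filter."""
    dff, state = prepare_spark_segment(calcium, cell, config)
    comps, dff2, state2 = detect_spark_candidates(state, dff, config)
    events = [
        characterize_spark(c, dff2, state2, config, dnt=dnt, spark_id=i)
        for i, c in enumerate(comps)
    ]
    return filter_sparks(events, config), state2


def compute_spark_rates(
    sparks: list[SparkEvent],
    dnt: DNTMap,
    duration_s: float,
    pixel_size_um: float,
) -> SparkRateSummary:
    """Spark rate per 100 um^2 per second in each DNT category.

    rate = n / (category area / 100 um^2) / duration.  A zero-area category
    has an undefined rate (None), not zero.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    areas_px = dnt.category_areas_px()
    area_um2 = {k: v * pixel_size_um**2 for k, v in areas_px.items()}
    n = {k: 0 for k in CATEGORIES}
    for s in sparks:
        if s.category in n:
            n[s.category] += 1
    total = sum(n.values())
    rate = {
        k: (n[k] / (area_um2[k] / 100.0) / duration_s) if area_um2[k] > 0 else None
        for k in CATEGORIES
    }
    fraction = {k: (n[k] / total if total else 0.0) for k in CATEGORIES}
    return SparkRateSummary(
        n_sparks=n,
        area_um2=area_um2,
        duration_s=duration_s,
        rate_per_100um2_s=rate,
        fraction=fraction,
    )
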