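"""Ground-truthed dual-channel phantom recordings.

The generator emulates the preparation the pipeline targets: an elongated,
horizontally oriented ventricular cardiomyocyte with a transverse t-tubule
lattice of ~2 um period, zero to two nuclei, optional detubulated patches,
stimulus-evoked global calcium transients with a spatially varying onset-delay
field (uniform base latency, extra nuclear delay, a central-vs-ends offset and
an optional DNT-proportional term), stochastic localized sparks whose rate
depends on the DNT category, and Gaussian camera read noise (optional Poisson
shot noise).  The transient time course is the product form
``A (1 - exp(-t/tau_rise)) exp(-t/tau_decay)``: a simple, differentiable
synthetic stand-in with a computable half-rise time — the closed-form oracle
the T50 pipeline is validated against.  Sparks are separable: an isotropic
spatial Gaussian times an asymmetric triangular time course whose base is
twice the nominal FDHM, so the duration above half maximum equals the FDHM
exactly.

Everything is deterministic given the seed: same seed, bit-identical movies
and truth tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sparkmap.io import PacingTrace, RecordingBundle, TimelapseStack
from sparkmap.preprocess import CellMask
from sparkmap.structure import CATEGORIES, DNTMap, NucleusMask, TubuleMask, compute_dnt_map

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "render_recording",
    "analytic_half_rise_ms",
    "analytic_t50_oracle",
    "transient_peak_time_ms",
]


@dataclass
class PhantomSpec:
    # geometry (FOV reduced relative to the instrument's 1152 x 512 so the
    # default phantom stays desk-scale; all lengths are configurable)
    fov_shape: tuple[int, int] = (128, 256)  # rows, cols
    pixel_size_um: float = 0.1477
    frame_rate_hz: float = 395.0
    n_frames: int = 2000
    cell_length_um: float = 34.0
    cell_width_um: float = 14.0
    orientation_deg: float = 0.0

    # structure
    tubule_period_um: float = 2.0
    # rendered stripe width: the mask-equivalent width of a detected tubule
    # (anatomical tubules are ~0.25 um; detected masks are broader), giving
    # ~34% coverage at the 2 um period
    tubule_width_um: float = 0.65
    longitudinal_fraction: float = 0.0  # adds a central longitudinal element if > 0
    detub_patch_count: int = 1
    detub_patch_radius_um: float = 2.5
    n_nuclei: int = 1
    nucleus_axes_um: tuple[float, float] = (6.0, 3.0)  # (along length, across)

    # fluorescence baseline (detector digital numbers)
    f0_cell_dn: float = 1000.0
    background_dn: float = 50.0
    membrane_tubule_dn: float = 600.0
    membrane_cell_dn: float = 150.0

    # transient kinetics (per-pixel onset delay field, ms after the pacing edge)
    include_transients: bool = False
    rise_tau_ms: float = 15.0
    decay_tau_ms: float = 200.0
    transient_amplitude_dff: float = 1.5
    base_delay_ms: float = 5.0
    nuclear_extra_delay_ms: float = 0.0
    central_extra_delay_ms: float = 0.0  # central half later than the outer quarters
    dnt_delay_ms_per_px: float = 0.0
    dnt_delay_detub_only: bool = False  # apply the DNT term only where DNT > 5 px
    pacing_hz: float = 0.5
    pacing_pulse_ms: float = 2.0
    pacing_phase_ms: float = 100.0  # first rising edge
    paced_fraction: float = 1.0  # pace only the first fraction of the movie
    pacing_sample_rate_hz: float = 10000.0

    # spark process (rates per 100 um^2 per s, by DNT category; the paper-scale
    # paratubular rate is ~60% below epitubular)
    include_sparks: bool = True
    spark_rate_per_100um2_s: dict = field(
        default_factory=lambda: {"epitubular": 0.40, "paratubular": 0.16, "detubulated": 0.05}
    )
    spark_amplitude_mean: float = 0.6
    spark_amplitude_sd: float = 0.15
    spark_fwhm_um_mean: float = 2.0
    spark_fwhm_um_sd: float = 0.3
    spark_fdhm_ms_mean: float = 27.0
    spark_fdhm_ms_sd: float = 5.0

    # camera noise: Gaussian SD at the shot-noise-equivalent level for the
    # default 1000 DN baseline (sqrt(F0) scale); optional true Poisson
    noise_sd_dn: float = 30.0
    poisson_noise: bool = False

    # channel misregistration to exercise co-registration
    channel_shift_px: tuple[int, int] = (0, 0)
    channel_scale: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name in ("pixel_size_um", "frame_rate_hz", "cell_length_um", "cell_width_um",
                     "tubule_period_um", "tubule_width_um", "pacing_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v < 0 for v in self.spark_rate_per_100um2_s.values()):
            raise ValueError("spark rates must be >= 0")
        if not 0 <= self.n_nuclei <= 2:
            raise ValueError("n_nuclei must be 0, 1 or 2")
        rows, cols = self.fov_shape
        if (self.cell_length_um / self.pixel_size_um > cols
                or self.cell_width_um / self.pixel_size_um > rows):
            raise ValueError("cell larger than FOV")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    def to_yaml(self, path) -> None:
        import yaml

        data = dataclasses.asdict(self)
        for key in ("fov_shape", "nucleus_axes_um", "channel_shift_px"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class PhantomTruth:
    """Ground truth emitted by the generator: the oracle for every stage."""

    spec: PhantomSpec
    cell: CellMask
    tubules: TubuleMask
    nuclei: NucleusMask
    dnt: DNTMap
    sparks: pd.DataFrame  # onset_frame, com_row, com_col, amplitude, fwhm_um, fdhm_ms, category, truncated
    onset_delay_ms: np.ndarray  # per-pixel onset delay after the pacing edge
    half_rise_ms: np.ndarray  # per-pixel T50 truth (ms after the pacing edge)


# ---------------------------------------------------------------------------
# transient kinetics: c(t) = A_norm (1 - exp(-t/tau_r)) exp(-t/tau_d), t >= 0


def transient_peak_time_ms(rise_tau_ms: float, decay_tau_ms: float) -> float:
    """Peak time of the product rise/decay curve, relative to onset."""
    return rise_tau_ms * np.log((rise_tau_ms + decay_tau_ms) / rise_tau_ms)


def _curve_unit(t_ms: np.ndarray, rise_tau_ms: float, decay_tau_ms: float) -> np.ndarray:
    """The product curve normalized to unit peak; zero before onset."""
    t = np.maximum(np.asarray(t_ms, dtype=np.float64), 0.0)
    raw = (1.0 - np.exp(-t / rise_tau_ms)) * np.exp(-t / decay_tau_ms)
    t_pk = transient_peak_time_ms(rise_tau_ms, decay_tau_ms)
    peak = (1.0 - np.exp(-t_pk / rise_tau_ms)) * np.exp(-t_pk / decay_tau_ms)
    return raw / peak


def analytic_half_rise_ms(
    rise_tau_ms: float,
    decay_tau_ms: float,
    peak_window_ms: float = 0.0,
    tol_ms: float = 1e-6,
) -> float:
    """Half-rise time of the transient curve, relative to onset, by bisection.

    The target level is half of the curve's peak.  When ``peak_window_ms`` is
    positive the peak is instead the mean of the curve over that window
    starting at the peak time — the convention the measurement pipeline uses
    (a 20-frame average from the cell-average peak frame) — so the oracle
    computes the same quantity the pipeline estimates.
    """
    if rise_tau_ms <= 0 or decay_tau_ms <= 0:
        raise ValueError("non-monotone rise: time constants must be positive")
    t_pk = transient_peak_time_ms(rise_tau_ms, decay_tau_ms)
    if peak_window_ms > 0:
        grid = np.linspace(t_pk, t_pk + peak_window_ms, 2049)
        level = float(np.trapezoid(_curve_unit(grid, rise_tau_ms, decay_tau_ms), grid)) / peak_window_ms
    else:
        level = 1.0
    target = level / 2.0
    lo, hi = 0.0, t_pk
    while hi - lo > tol_ms:
        mid = (lo + hi) / 2.0
        if _curve_unit(mid, rise_tau_ms, decay_tau_ms) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def analytic_t50_oracle(
    spec: PhantomSpec,
    pixel: tuple[int, int] | None = None,
    onset_delay_ms: float | np.ndarray = 0.0,
    peak_window_ms: float = 0.0,
) -> float | np.ndarray:
    """Closed-form T50 (ms after the pacing edge) for the phantom kinetics.

    Pure function of the spec: half-rise of the transient curve plus the
    onset delay.  ``pixel`` is accepted for symmetry with the truth field but
    the delay must be supplied (the field lives on :class:`PhantomTruth`).
    """
    half = analytic_half_rise_ms(spec.rise_tau_ms, spec.decay_tau_ms, peak_window_ms)
    delay = np.asarray(onset_delay_ms, dtype=np.float64)
    if pixel is not None and delay.ndim == 2:
        delay = delay[pixel]
    return half + delay


# ---------------------------------------------------------------------------
# structure rasterization


def _rotated_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(u, v) pixel coordinates along / across the cell axis, centred on the FOV."""
    rows, cols = spec.fov_shape
    r, c = np.mgrid[0:rows, 0:cols].astype(np.float64)
    r -= (rows - 1) / 2.0
    c -= (cols - 1) / 2.0
    theta = np.deg2rad(spec.orientation_deg)
    u = c * np.cos(theta) + r * np.sin(theta)
    v = -c * np.sin(theta) + r * np.cos(theta)
    return u, v


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Rasterize the ground-truth structure, spark table and T50 field."""
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    u, v = _rotated_coords(spec)

    a = spec.cell_length_um / 2.0 / px
    b = spec.cell_width_um / 2.0 / px
    cell_mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    cell = CellMask(cell_mask, px)

    # transverse stripes along the cell length
    period_px = spec.tubule_period_um / px
    width_px = max(spec.tubule_width_um / px, 1.0)
    phase = np.mod(u + width_px / 2.0, period_px)
    tubule = (phase < width_px) & cell_mask
    if spec.longitudinal_fraction > 0:
        tubule |= (np.abs(v) < width_px / 2.0) & cell_mask

    # nuclei: ellipses on the cell axis, tubule-free
    nuc_mask = np.zeros_like(cell_mask)
    if spec.n_nuclei > 0:
        na = spec.nucleus_axes_um[0] / 2.0 / px
        nb = spec.nucleus_axes_um[1] / 2.0 / px
        offsets = [0.0] if spec.n_nuclei == 1 else [-a / 3.0, a / 3.0]
        for du in offsets:
            nuc_mask |= ((u - du) / na) ** 2 + (v / nb) ** 2 <= 1.0
    nuc_mask &= cell_mask
    tubule &= ~nuc_mask

    # detubulated patches: circles inside the cell, away from the nuclei
    patch_r = spec.detub_patch_radius_um / px
    placed = 0
    attempts = 0
    while placed < spec.detub_patch_count and attempts < 200:
        attempts += 1
        du = rng.uniform(-0.7 * a, 0.7 * a)
        dv = rng.uniform(-0.6 * b, 0.6 * b)
        patch = (u - du) ** 2 + (v - dv) ** 2 <= patch_r**2
        if not (patch & cell_mask).any() or (patch & nuc_mask).any():
            continue
        tubule &= ~patch
        placed += 1

    from scipy import ndimage as _ndi

    _, n_nuc = _ndi.label(nuc_mask)
    tubules = TubuleMask(tubule, cell)
    nuclei = NucleusMask(nuc_mask, int(n_nuc))
    dnt = compute_dnt_map(tubules, cell)

    onset = np.full(spec.fov_shape, spec.base_delay_ms)
    if spec.nuclear_extra_delay_ms:
        onset[nuc_mask] += spec.nuclear_extra_delay_ms
    if spec.central_extra_delay_ms:
        onset[np.abs(u) <= a / 2.0] += spec.central_extra_delay_ms
    if spec.dnt_delay_ms_per_px:
        finite = np.isfinite(dnt.dnt_px)
        if spec.dnt_delay_detub_only:
            finite &= dnt.dnt_px > dnt.paratubular_max_px
        onset[finite] += spec.dnt_delay_ms_per_px * dnt.dnt_px[finite]

    half = analytic_half_rise_ms(spec.rise_tau_ms, spec.decay_tau_ms)
    half_rise = np.where(cell_mask, onset + half, np.nan)

    sparks = _draw_sparks(spec, dnt, rng)

    return PhantomTruth(
        spec=spec,
        cell=cell,
        tubules=tubules,
        nuclei=nuclei,
        dnt=dnt,
        sparks=sparks,
        onset_delay_ms=onset,
        half_rise_ms=half_rise,
    )


def _masked_centroid(
    spec: PhantomSpec, cell_mask: np.ndarray, r0: int, c0: int, fwhm_um: float
) -> tuple[float, float]:
    """Brightness centroid of a Gaussian spark clipped by the cell footprint.

    Sparks ride on the baseline fluorescence, which is zero outside the cell,
    so an event near the membrane is one-sidedly clipped and its rendered
    centre of mass shifts inward from the placement pixel.  The truth table
    records the rendered centroid, which is what a detector can recover.
    """
    rows, cols = spec.fov_shape
    sigma_px = fwhm_um / spec.pixel_size_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half_ext = int(np.ceil(3.0 * sigma_px))
    r_lo, r_hi = max(r0 - half_ext, 0), min(r0 + half_ext + 1, rows)
    c_lo, c_hi = max(c0 - half_ext, 0), min(c0 + half_ext + 1, cols)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    w = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma_px**2))
    w *= cell_mask[r_lo:r_hi, c_lo:c_hi]
    total = w.sum()
    if total <= 0:
        return float(r0), float(c0)
    return float((rr * w).sum() / total), float((cc * w).sum() / total)


def _draw_sparks(spec: PhantomSpec, dnt: DNTMap, rng: np.random.Generator) -> pd.DataFrame:
    """Poisson spark counts per DNT category, placed uniformly within each."""
    cols = ["onset_frame", "com_row", "com_col", "peak_row", "peak_col",
            "amplitude", "fwhm_um", "fdhm_ms", "category", "truncated"]
    if not spec.include_sparks:
        return pd.DataFrame(columns=cols)
    px = spec.pixel_size_um
    cats = dnt.category_map()
    rows_list = []
    for i, name in enumerate(CATEGORIES):
        sel_r, sel_c = np.nonzero(cats == i)
        if sel_r.size == 0:
            continue
        area_100um2 = sel_r.size * px**2 / 100.0
        lam = spec.spark_rate_per_100um2_s.get(name, 0.0) * area_100um2 * spec.duration_s
        n = int(rng.poisson(lam))
        for _ in range(n):
            j = int(rng.integers(sel_r.size))
            amp = max(float(rng.normal(spec.spark_amplitude_mean, spec.spark_amplitude_sd)), 0.15)
            fwhm = max(float(rng.normal(spec.spark_fwhm_um_mean, spec.spark_fwhm_um_sd)), 0.8)
            fdhm = max(float(rng.normal(spec.spark_fdhm_ms_mean, spec.spark_fdhm_ms_sd)), 10.0)
            base_frames = 2.0 * fdhm / spec.frame_period_ms
            onset = int(rng.integers(0, spec.n_frames))
            truncated = onset + base_frames > spec.n_frames - 1
            com_r, com_c = _masked_centroid(
                spec, dnt.cell.mask, int(sel_r[j]), int(sel_c[j]), fwhm
            )
            rows_list.append(
                dict(
                    onset_frame=onset,
                    com_row=com_r,
                    com_col=com_c,
                    peak_row=int(sel_r[j]),
                    peak_col=int(sel_c[j]),
                    amplitude=amp,
                    fwhm_um=fwhm,
                    fdhm_ms=fdhm,
                    category=name,
                    truncated=truncated,
                )
            )
    df = pd.DataFrame(rows_list, columns=cols)
    return df.sort_values("onset_frame").reset_index(drop=True) if len(df) else df


# ---------------------------------------------------------------------------
# rendering


def _render_transient_dff(spec: PhantomSpec, truth: PhantomTruth,
                          edges_ms: np.ndarray) -> np.ndarray:
    """Per-frame per-pixel transient dF/F0 from the onset-delay field."""
    dt = spec.frame_period_ms
    t_frames = np.arange(spec.n_frames) * dt
    out = np.zeros((spec.n_frames,) + spec.fov_shape, dtype=np.float32)
    onset = truth.onset_delay_ms
    # transients are far apart relative to the decay; render each in a window
    window_ms = transient_peak_time_ms(spec.rise_tau_ms, spec.decay_tau_ms) \
        + 6.0 * spec.decay_tau_ms + float(np.nanmax(onset))
    for edge in edges_ms:
        sel = np.nonzero((t_frames >= edge) & (t_frames <= edge + window_ms))[0]
        for f in sel:
            elapsed = t_frames[f] - edge - onset
            out[f] += (spec.transient_amplitude_dff
                       * _curve_unit(elapsed, spec.rise_tau_ms, spec.decay_tau_ms)
                       ).astype(np.float32)
    return out


def _spark_time_course(fdhm_ms: float, dt_ms: float) -> tuple[np.ndarray, int]:
    """Asymmetric triangle (rise 1/3, decay 2/3) with base 2 x FDHM.

    The duration above half maximum of any triangle equals half its base, so
    the nominal FDHM is exact by construction.
    """
    base_ms = 2.0 * fdhm_ms
    rise_ms = base_ms / 3.0
    n = max(int(np.ceil(base_ms / dt_ms)) + 1, 3)
    t = np.arange(n) * dt_ms
    course = np.where(
        t <= rise_ms, t / rise_ms, np.clip((base_ms - t) / (base_ms - rise_ms), 0.0, None)
    )
    return course, n


def render_recording(
    truth: PhantomTruth, spec: PhantomSpec | None = None
) -> RecordingBundle:
    """Render the dual-channel movie, pacing trace and noise from the truth.

    calcium = background + F0 x (1 + transient dF/F0 + spark dF/F0) + noise;
    membrane = background + diffuse cell + tubule structure + noise, with the
    configured channel scale/shift misregistration applied.  The pacing trace
    is a top-hat train at the pacing frequency (all-zero when the phantom is
    unpaced).
    """
    spec = spec or truth.spec
    rng = np.random.default_rng(spec.seed + 1)  # independent of structure draws
    rows, cols = spec.fov_shape
    dt = spec.frame_period_ms

    # pacing trace at its native sampling
    n_samp = int(spec.duration_s * spec.pacing_sample_rate_hz)
    t_samp = np.arange(n_samp) / spec.pacing_sample_rate_hz * 1000.0
    level = np.zeros(n_samp)
    edges_ms = np.empty(0)
    if spec.include_transients:
        period_ms = 1000.0 / spec.pacing_hz
        edges_ms = np.arange(
            spec.pacing_phase_ms, spec.paced_fraction * spec.duration_s * 1000.0, period_ms
        )
        for e in edges_ms:
            level[(t_samp >= e) & (t_samp < e + spec.pacing_pulse_ms)] = 5.0
    pacing = PacingTrace(t_samp, level)

    f0_map = np.where(truth.cell.mask, spec.f0_cell_dn, 0.0).astype(np.float32)

    dff = np.zeros((spec.n_frames, rows, cols), dtype=np.float32)
    if spec.include_transients and edges_ms.size:
        dff += _render_transient_dff(spec, truth, edges_ms)

    for s in truth.sparks.itertuples():
        sigma_px = s.fwhm_um / spec.pixel_size_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        half_ext = int(np.ceil(3.0 * sigma_px))
        r0, c0 = int(s.peak_row), int(s.peak_col)
        r_lo, r_hi = max(r0 - half_ext, 0), min(r0 + half_ext + 1, rows)
        c_lo, c_hi = max(c0 - half_ext, 0), min(c0 + half_ext + 1, cols)
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        gauss = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma_px**2))
        course, n_t = _spark_time_course(s.fdhm_ms, dt)
        f_lo = int(s.onset_frame)
        f_hi = min(f_lo + n_t, spec.n_frames)
        patch = (s.amplitude * course[: f_hi - f_lo, None, None] * gauss[None]).astype(np.float32)
        dff[f_lo:f_hi, r_lo:r_hi, c_lo:c_hi] += patch

    calcium_dn = spec.background_dn + f0_map[None] * (1.0 + dff)
    del dff

    membrane_img = (
        spec.background_dn
        + np.where(truth.cell.mask, spec.membrane_cell_dn, 0.0)
        + np.where(truth.tubules.mask, spec.membrane_tubule_dn, 0.0)
    ).astype(np.float32)
    if spec.channel_scale != 1.0:
        from sparkmap.preprocess import _rescale_stack

        tmp = TimelapseStack(membrane_img[None], "membrane", spec.frame_rate_hz,
                             spec.pixel_size_um)
        membrane_img = _rescale_stack(tmp, spec.channel_scale).intensities[0].astype(np.float32)
    if spec.channel_shift_px != (0, 0):
        membrane_img = np.roll(membrane_img, spec.channel_shift_px, axis=(0, 1))
    membrane_dn = np.broadcast_to(membrane_img, (spec.n_frames, rows, cols)).copy()

    if spec.poisson_noise:
        calcium_dn = rng.poisson(np.maximum(calcium_dn, 0.0)).astype(np.float32)
        membrane_dn = rng.poisson(np.maximum(membrane_dn, 0.0)).astype(np.float32)
    if spec.noise_sd_dn > 0:
        calcium_dn = calcium_dn + rng.normal(0.0, spec.noise_sd_dn, calcium_dn.shape).astype(np.float32)
        membrane_dn = membrane_dn + rng.normal(0.0, spec.noise_sd_dn, membrane_dn.shape).astype(np.float32)
    calcium_dn = np.maximum(calcium_dn, 0.0)
    membrane_dn = np.maximum(membrane_dn, 0.0)

    calcium = TimelapseStack(calcium_dn, "calcium", spec.frame_rate_hz, spec.pixel_size_um)
    membrane = TimelapseStack(membrane_dn, "membrane", spec.frame_rate_hz, spec.pixel_size_um)
    metadata = {
        "phantom": True,
        "seed": spec.seed,
        "unpaced": not spec.include_transients,
        "cell_id": f"phantom-{spec.seed}",
    }
    return RecordingBundle(calcium, membrane, pacing if spec.include_transients else pacing, metadata)
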