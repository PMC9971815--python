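"""Pixel-wise T50 mapping, aggregation, regional summaries and DNT fits."""

import numpy as np
import pytest

from sparkmap.config import AnalysisConfig
from sparkmap.io import PacingTrace, TimelapseStack
from sparkmap.preprocess import CellMask
from sparkmap.structure import DNTMap, NucleusMask
from sparkmap.synth import analytic_half_rise_ms
from sparkmap.transients import (
    T50Map,
    TransientWindow,
    aggregate_t50_maps,
    compute_t50_map,
    fit_t50_vs_dnt,
    locate_transients,
    summarize_regions,
)

DT_MS = 1000.0 / 395.0


def _ramp_window(shape=(8, 8), delay_frames=0, gain=1.0, n_frames=60,
                 edge_frame=10, ramp_frames=10, f0=100.0, peak=300.0):
    """Linear rise from f0 to peak over ramp_frames, starting at the stimulus."""
    data = np.full((n_frames, *shape), f0)
    start = edge_frame + delay_frames
    for k in range(n_frames - start):
        frac = min(k / ramp_frames, 1.0)
        data[start + k] = f0 + frac * (peak - f0)
    data *= gain
    return TransientWindow(
        data=data,
        start_frame=0,
        frame_rate_hz=395.0,
        edge_time_ms=edge_frame * DT_MS,
        peak_frame=start + ramp_frames,
        baseline_map=np.full(shape, f0 * gain),
        peak_map=np.full(shape, peak * gain),
    )


def _cell(shape=(8, 8)):
    return CellMask(np.ones(shape, dtype=bool), 0.1477)


class TestComputeT50:
    def test_linear_ramp_midpoint(self):
        """A 10-frame linear rise reaches F50 at 5 frame periods (12.66 ms)."""
        t50 = compute_t50_map(_ramp_window(), _cell())
        np.testing.assert_allclose(t50, 5 * DT_MS, atol=1e-9)

    def test_shift_equivariance(self):
        base = compute_t50_map(_ramp_window(), _cell())
        for k in (1, 3, 7):
            shifted = compute_t50_map(_ramp_window(delay_frames=k), _cell())
            np.testing.assert_allclose(shifted - base, k * DT_MS, atol=1e-9)

    def test_gain_invariance(self):
        a = compute_t50_map(_ramp_window(gain=1.0), _cell())
        b = compute_t50_map(_ramp_window(gain=13.0), _cell())
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_peak_below_baseline_undefined(self):
        w = _ramp_window()
        w.peak_map = w.baseline_map - 1.0
        t50 = compute_t50_map(w, _cell())
        assert np.isnan(t50).all()

    def test_noiseless_phantom_matches_analytic_oracle(self, noiseless_results,
                                                       transient_config):
        """Per-pixel T50 within half a frame period of the closed-form truth."""
        truth = noiseless_results["truth"]
        t50 = noiseless_results["t50"]
        cfg = transient_config
        half = analytic_half_rise_ms(
            truth.spec.rise_tau_ms,
            truth.spec.decay_tau_ms,
            peak_window_ms=cfg.peak_window_frames * cfg.frame_period_ms,
        )
        oracle = truth.onset_delay_ms + half
        valid = t50.valid_mask & truth.cell.mask
        assert valid.sum() >= 0.99 * truth.cell.area_px
        err = np.abs(t50.mean_ms - oracle)[valid]
        assert err.max() <= cfg.frame_period_ms / 2.0


class TestAggregate:
    def test_identical_maps_zero_sd(self):
        m = np.full((4, 4), 25.0)
        agg = aggregate_t50_maps([m, m, m])
        np.testing.assert_allclose(agg.sd_ms[agg.valid_mask], 0.0)

    def test_mean_and_sample_sd(self):
        maps = [np.full((2, 2), v) for v in (10.0, 20.0, 30.0)]
        agg = aggregate_t50_maps(maps)
        np.testing.assert_allclose(agg.mean_ms, 20.0)
        np.testing.assert_allclose(agg.sd_ms, 10.0)

    def test_valid_mask_is_intersection(self):
        a = np.full((2, 2), 5.0)
        b = a.copy()
        b[0, 0] = np.nan
        agg = aggregate_t50_maps([a, b])
        assert not agg.valid_mask[0, 0] and agg.valid_mask[1, 1]

    def test_single_map_rejected(self):
        with pytest.raises(ValueError):
            aggregate_t50_maps([np.ones((2, 2))])


class TestLocate:
    def test_unpaced_recording_is_an_error(self, transient_config):
        stack = TimelapseStack(np.ones((100, 8, 8)), "calcium", 395.0, 0.1477)
        with pytest.raises(ValueError, match="paced"):
            locate_transients(stack, None, _cell(), transient_config)

    def test_phantom_three_windows_at_pacing_spacing(self, regional_results):
        windows = regional_results["windows"]
        assert len(windows) == 3
        peaks_s = np.array([w.peak_frame for w in windows]) / 395.0
        np.testing.assert_allclose(np.diff(peaks_s), 2.0, atol=0.05)
        for w in windows:
            # baseline window precedes the stimulus edge inside the crop
            assert w.edge_time_ms >= w.frame_time_ms(0)
            assert w.edge_time_ms <= w.peak_frame / 395.0 * 1000.0


class TestRegions:
    def test_uniform_map_zero_deltas_and_iqr(self):
        cell = _cell((16, 40))
        vals = np.full((16, 40), 30.0)
        t50 = T50Map([vals, vals], vals, np.zeros_like(vals), np.ones_like(vals, bool))
        nuc = np.zeros((16, 40), dtype=bool)
        nuc[6:10, 18:22] = True
        summary = summarize_regions(t50, cell, NucleusMask(nuc, 1))
        assert summary.median_nuclear_ms == 30.0
        assert summary.delta_nuclear_ms == 0.0
        assert summary.delta_central_outer_ms == 0.0
        assert summary.dyssynchrony_iqr_ms == 0.0

    def test_no_nucleus_reports_missing_not_zero(self):
        cell = _cell((8, 24))
        vals = np.full((8, 24), 20.0)
        t50 = T50Map([vals, vals], vals, np.zeros_like(vals), np.ones_like(vals, bool))
        summary = summarize_regions(t50, cell, NucleusMask(np.zeros((8, 24), bool), 0))
        assert summary.median_nuclear_ms is None
        assert summary.delta_nuclear_ms is None

    def test_nuclear_pixels_never_in_exonuclear_regions(self, regional_results):
        truth = regional_results["truth"]
        cell = regional_results["cell"]
        t50 = regional_results["t50"]
        summary = summarize_regions(t50, cell, truth.nuclei)
        n_total = summary.n_pixels["nuclear"] + summary.n_pixels["exonuclear"]
        assert n_total == (t50.valid_mask & cell.mask).sum()

    def test_phantom_regional_deltas_recovered(self, regional_results):
        """Nuclear +3.47 ms and central-vs-outer +1.97 ms delay fields."""
        truth = regional_results["truth"]
        summary = summarize_regions(
            regional_results["t50"], regional_results["cell"], truth.nuclei
        )
        assert summary.delta_nuclear_ms == pytest.approx(3.47, abs=0.3)
        assert summary.delta_central_outer_ms == pytest.approx(1.97, abs=0.3)


class TestT50DNTFit:
    def _map_from(self, vals):
        valid = np.isfinite(vals)
        return T50Map([vals, vals], vals, np.zeros_like(vals), valid)

    def _dnt(self, dnt_px, shape):
        cell = CellMask(np.ones(shape, dtype=bool), 0.1477)
        return DNTMap(np.asarray(dnt_px, dtype=float), cell)

    def test_perfect_linear_data_recovers_slope(self):
        rng = np.random.default_rng(0)
        dnt_px = rng.uniform(0, 12, (20, 30))
        vals = 2.0 * dnt_px + 20.0
        fits = fit_t50_vs_dnt(self._map_from(vals), self._dnt(dnt_px, (20, 30)))
        for fit in fits.values():
            assert fit.slope_ms_per_px == pytest.approx(2.0, abs=1e-9)
            assert fit.ci95[1] - fit.ci95[0] < 1e-6
            assert fit.ci95[0] <= fit.slope_ms_per_px <= fit.ci95[1]

    def test_null_association_ci_covers_zero(self):
        """With T50 independent of DNT the slope CI contains 0 ~95% of the time."""
        rng = np.random.default_rng(12345)
        covered = 0
        n_seeds = 50
        for _ in range(n_seeds):
            dnt_px = rng.uniform(0, 4, (12, 20))
            vals = 25.0 + rng.normal(0, 2.0, (12, 20))
            fit = fit_t50_vs_dnt(self._map_from(vals), self._dnt(dnt_px, (12, 20)))[
                "tubulated"
            ]
            if fit.ci95[0] <= 0.0 <= fit.ci95[1]:
                covered += 1
        assert covered >= 0.9 * n_seeds

    def test_degenerate_dnt_variance_omitted(self):
        dnt_px = np.zeros((5, 5))
        vals = np.full((5, 5), 30.0)
        fits = fit_t50_vs_dnt(self._map_from(vals), self._dnt(dnt_px, (5, 5)))
        assert "tubulated" not in fits

    def test_detubulated_delay_gives_larger_detubulated_slope(self, transient_config):
        """DNT-proportional delay confined to detubulated patches: the
        detubulated-region slope must exceed the tubulated one (sign test)."""
        from sparkmap.structure import compute_dnt_map, extract_tubule_mask
        from sparkmap.preprocess import segment_cell, subtract_background
        from sparkmap.synth import generate_phantom, render_recording
        from tests.conftest import make_transient_spec, run_t50_pipeline

        wins = 0
        n_seeds = 3
        for seed in range(n_seeds):
            spec = make_transient_spec(
                seed=40 + seed,
                fov_shape=(64, 144),
                cell_length_um=19.0,
                cell_width_um=8.0,
                dnt_delay_ms_per_px=2.0,
                dnt_delay_detub_only=True,
                detub_patch_count=2,
            )
            truth = generate_phantom(spec)
            bundle = render_recording(truth)
            calcium, cell, _, t50 = run_t50_pipeline(bundle, transient_config)
            membrane = subtract_background(bundle.membrane)
            tubules = extract_tubule_mask(membrane, cell, 0.3)
            dnt = compute_dnt_map(tubules, cell)
            fits = fit_t50_vs_dnt(t50, dnt)
            if fits["detubulated"].slope_ms_per_px > fits["tubulated"].slope_ms_per_px:
                wins += 1
        assert wins == n_seeds
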