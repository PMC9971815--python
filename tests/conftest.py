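"""Shared phantom fixtures.

Phantoms are rendered once per session and reused: a spark phantom (unpaced,
four 500-frame detection blocks), a paced transient phantom with nuclear and
central onset-delay fields, and a noiseless paced phantom with a uniform
delay field for the closed-form T50 oracle comparison.
"""

from __future__ import annotations

import numpy as np
import pytest

from sparkmap.config import AnalysisConfig
from sparkmap.preprocess import segment_cell, subtract_background
from sparkmap.sparks import detect_sparks
from sparkmap.structure import compute_dnt_map, extract_tubule_mask
from sparkmap.synth import PhantomSpec, generate_phantom, render_recording
from sparkmap.transients import aggregate_t50_maps, compute_t50_map, locate_transients

# ~1.5x the paper-scale areal event density: enough events per phantom for
# statistics while keeping concurrent overlapping sparks (which a connected-
# component detector cannot split) rare
SPARK_RATES = {"epitubular": 1.0, "paratubular": 0.4, "detubulated": 0.15}


def make_spark_spec(seed: int) -> PhantomSpec:
    """Desk-scale unpaced spark phantom: 4 x 500-frame blocks at 395 fps."""
    return PhantomSpec(
        seed=seed,
        n_frames=2000,
        fov_shape=(96, 192),
        cell_length_um=26.0,
        cell_width_um=11.0,
        spark_rate_per_100um2_s=dict(SPARK_RATES),
    )


def run_spark_pipeline(bundle, config):
    calcium = subtract_background(bundle.calcium)
    membrane = subtract_background(bundle.membrane)
    cell = segment_cell(calcium)
    tubules = extract_tubule_mask(membrane, cell, config.tubule_width_um)
    dnt = compute_dnt_map(tubules, cell, config.dnt_paratubular_max_px)
    events, state = detect_sparks(calcium, cell, config, dnt=dnt)
    return calcium, cell, tubules, dnt, events, state


def match_sparks(events, truth_df, max_dist_px: float = 2.0, max_frames: int = 2):
    """Greedy truth-to-event matching within a COM distance and onset offset."""
    matched_truth: set[int] = set()
    matched_events: set[int] = set()
    for i, e in enumerate(events):
        for j, row in truth_df.iterrows():
            if j in matched_truth:
                continue
            d = np.hypot(row.com_row - e.com_xy[1], row.com_col - e.com_xy[0])
            if d <= max_dist_px and abs(e.frame_span[0] - row.onset_frame) <= max_frames:
                matched_truth.add(j)
                matched_events.add(i)
                break
    return matched_truth, matched_events


@pytest.fixture(scope="session")
def spark_config() -> AnalysisConfig:
    return AnalysisConfig(block_len_frames=500, n_blocks=4)


@pytest.fixture(scope="session")
def spark_phantom():
    spec = make_spark_spec(seed=3)
    truth = generate_phantom(spec)
    bundle = render_recording(truth)
    return spec, truth, bundle


@pytest.fixture(scope="session")
def spark_results(spark_phantom, spark_config):
    _, truth, bundle = spark_phantom
    calcium, cell, tubules, dnt, events, state = run_spark_pipeline(bundle, spark_config)
    return dict(
        truth=truth,
        calcium=calcium,
        cell=cell,
        tubules=tubules,
        dnt=dnt,
        events=events,
        state=state,
    )


def make_transient_spec(seed: int, **overrides) -> PhantomSpec:
    """Paced phantom: 0.5 Hz pacing at 395 fps, three usable transients."""
    kwargs = dict(
        seed=seed,
        n_frames=2700,
        fov_shape=(80, 160),
        cell_length_um=22.0,
        cell_width_um=10.0,
        include_transients=True,
        include_sparks=False,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def run_t50_pipeline(bundle, config):
    calcium = subtract_background(bundle.calcium)
    cell = segment_cell(calcium)
    windows = locate_transients(calcium, bundle.pacing, cell, config)
    maps = [compute_t50_map(w, cell) for w in windows]
    return calcium, cell, windows, aggregate_t50_maps(maps)


@pytest.fixture(scope="session")
def transient_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def regional_phantom():
    """Paced phantom with the delay fields the regional summary must recover."""
    spec = make_transient_spec(
        seed=11, nuclear_extra_delay_ms=3.47, central_extra_delay_ms=1.97
    )
    truth = generate_phantom(spec)
    bundle = render_recording(truth)
    return spec, truth, bundle


@pytest.fixture(scope="session")
def regional_results(regional_phantom, transient_config):
    _, truth, bundle = regional_phantom
    calcium, cell, windows, t50 = run_t50_pipeline(bundle, transient_config)
    return dict(truth=truth, calcium=calcium, cell=cell, windows=windows, t50=t50)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Zero-noise paced phantom with a uniform onset delay: oracle comparison."""
    spec = make_transient_spec(seed=7, noise_sd_dn=0.0)
    truth = generate_phantom(spec)
    bundle = render_recording(truth)
    return spec, truth, bundle


@pytest.fixture(scope="session")
def noiseless_results(noiseless_phantom, transient_config):
    _, truth, bundle = noiseless_phantom
    calcium, cell, windows, t50 = run_t50_pipeline(bundle, transient_config)
    return dict(truth=truth, calcium=calcium, cell=cell, windows=windows, t50=t50)
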