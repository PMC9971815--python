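"""Analysis configuration.

All tunable constants of the pipeline live in :class:`AnalysisConfig`.  The
defaults encode the acquisition geometry of the instrument the pipeline was
designed around (395 fps, 44x magnification onto a 6.5 um camera pixel, i.e.
0.1477 um in sample space) and the published detection constants: the spark
threshold multipliers k_low = 2.9 and k_high = 5.4 applied to the per-pixel
sigma of dF/F0, the 5 x 5 x 3 smoothing kernel, 1000-frame detection blocks,
the 50-pixel / 4-frame spark rejection filters, the 5-pixel
paratubular/detubulated DNT boundary, and the transient windowing constants
(525-frame crop, 50-frame baseline, 20-frame peak window, peak separation at
95% of a pacing period).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    # acquisition
    frame_rate_hz: float = 395.0
    pixel_size_um: float = 0.1477
    camera_pixel_um: float | None = 6.5
    magnification: float | None = 44.0
    pacing_hz: float = 0.5
    pacing_pulse_ms: float = 2.0

    # spark detection
    block_len_frames: int = 1000
    n_blocks: int = 5
    smooth_kernel: tuple[int, int, int] = (5, 5, 3)  # (rows, cols, frames)
    k_low: float = 2.9
    k_high: float = 5.4
    baseline_frames: int = 100
    min_area_px: int = 50
    min_duration_frames: int = 4
    connectivity: str = "face"  # "face" (6-neighborhood in x-y-t) or "vertex"

    # DNT categories
    dnt_paratubular_max_px: float = 5.0

    # transient analysis
    transient_window_s: float = 8.0
    crop_frames: int = 525
    baseline_window_frames: int = 50
    peak_window_frames: int = 20
    min_peak_separation_fraction: float = 0.95
    n_transients: int = 3

    # preprocessing
    channel_scale_ratio: float = 1.0  # 0.9 for the instrument's calcium channel
    tubule_width_um: float = 0.3
    closing_radius_um: float = 0.5

    def __post_init__(self) -> None:
        counts = {
            "block_len_frames": self.block_len_frames,
            "n_blocks": self.n_blocks,
            "baseline_frames": self.baseline_frames,
            "min_area_px": self.min_area_px,
            "min_duration_frames": self.min_duration_frames,
            "crop_frames": self.crop_frames,
            "baseline_window_frames": self.baseline_window_frames,
            "peak_window_frames": self.peak_window_frames,
            "n_transients": self.n_transients,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        for name in ("frame_rate_hz", "pixel_size_um", "pacing_hz", "pacing_pulse_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.k_high <= self.k_low:
            raise ValueError(f"k_high ({self.k_high}) must exceed k_low ({self.k_low})")
        if any(k <= 0 for k in self.smooth_kernel):
            raise ValueError("smooth_kernel sizes must be strictly positive")
        if self.camera_pixel_um is not None and self.magnification is not None:
            implied = self.camera_pixel_um / self.magnification
            if abs(implied - self.pixel_size_um) > 1e-4:
                raise ValueError(
                    f"pixel_size_um {self.pixel_size_um} inconsistent with "
                    f"camera_pixel_um/magnification = {implied:.6f}"
                )
        if self.connectivity not in ("face", "vertex"):
            raise ValueError("connectivity must be 'face' or 'vertex'")

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    @property
    def pacing_period_s(self) -> float:
        return 1.0 / self.pacing_hz

    @property
    def dnt_paratubular_max_um(self) -> float:
        """The paratubular/detubulated boundary in um (stored in pixels)."""
        return self.dnt_paratubular_max_px * self.pixel_size_um

    def px_to_um(self, px: float) -> float:
        return px * self.pixel_size_um

    def um_to_px(self, um: float) -> float:
        return um / self.pixel_size_um

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "smooth_kernel" in data:
            data["smooth_kernel"] = tuple(data["smooth_kernel"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["smooth_kernel"] = list(self.smooth_kernel)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
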