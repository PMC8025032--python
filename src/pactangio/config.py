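"""Run configuration: every tunable parameter of the pipeline in one place.

Defaults are the values used throughout the analysis: entropy window 1 mm
with 32 bins, rotation step 10 deg, k = 30, eps = 0.01, beta = 0.07,
segmentation multiplier 1.4, density window 2 mm, blend weights 0.35/0.65,
and the 220 mm / 512-element / 2.25 MHz ring geometry.  Any override is
logged when a pipeline runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "pactangio_out"

    # irregularity
    entropy_window_mm: float = 1.0
    entropy_bins: int = 32
    rotation_step_deg: float = 10.0
    k: float = 30.0
    epsilon: float = 0.01
    beta: float = 0.07
    sd_multiplier: float = 1.4
    directionality_stride: int = 3

    # preprocessing
    blend_weight: float = 0.35
    vessel_scales_mm: tuple = (0.15, 0.25, 0.4, 0.6)

    # vessel metrics
    density_window_mm: float = 2.0
    min_segment_px: int = 3
    highlight_threshold_per_mm2: float = 2.5
    highlight_min_area_mm2: float = 4.0

    # statistics
    stats_window_mm: float = 2.0

    # ring-array geometry
    ring_diameter_mm: float = 220.0
    n_elements: int = 512
    center_frequency_mhz: float = 2.25
    fractional_bandwidth: float | None = 0.7
    sampling_rate_mhz: float = 40.0
    record_window_us: float = 100.0
    speed_of_sound_mm_us: float = 1.5
    recon_pixel_mm: float = 0.1

    def overrides(self) -> dict:
        """Fields that differ from the defaults (for run logging)."""
        ref = RunConfig()
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if getattr(self, f.name) != getattr(ref, f.name)
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vessel_scales_mm"] = list(d["vessel_scales_mm"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "vessel_scales_mm" in data:
        data["vessel_scales_mm"] = tuple(data["vessel_scales_mm"])
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
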