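"""Run configuration with per-module parameter blocks.

Every analysis knob exposed by the modules has its default mirrored
here; unknown keys are rejected up front so typos cannot silently fall
back to defaults.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

from .io import load_yaml

__all__ = ["RunConfig", "DEFAULTS", "ConfigError"]


class ConfigError(ValueError):
    pass


DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "results",
    "mosaic": {
        "dr_um": 10.0,
        "r_max_um": 300.0,
        "edge_policy": "buffer",
        "ri_mode": "sem",
        "fit_order": 7,
        "n_boot": 1000,
        "map_bin_um": 100.0,
    },
    "straighten": {
        "nuclear_channel": "nuclear",
        "smooth_sigma_px": 5.0,
        "threshold_mode": "otsu",
        "out_rows": 100,
    },
    "morphology": {
        "bin_pct": 2.0,
        "prominence": 0.2,
        "min_peak_fraction": 0.15,
    },
    "ephys": {
        "z_thresh": 3.0,
        "dsi_mode": "vector_sum",
        "adaptation_variant": "literal",
        "transient_window_s": 0.3,
    },
    "synth": {
        "poisson_density_per_mm2": 100.0,
        "hardcore_density_per_mm2": 50.0,
        "hardcore_dmin_um": 50.0,
        "window_um": [0.0, 0.0, 2000.0, 2000.0],
        "lattice_spacing_um": 100.0,
        "lattice_jitter_um": 5.0,
        "flash_on_rate_hz": 40.0,
        "flash_baseline_hz": 2.0,
        "flash_diameters_um": [50, 100, 200, 300, 600, 1200],
        "direction_kappa": 8.0,
        "direction_base_count": 50.0,
        "n_trials": 10,
        "morph_strat_depths_pct": [30.0, 70.0],
        "section_amplitude_px": 6.0,
        "section_band_depths_pct": [40.0],
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


@dataclass
class RunConfig:
    """Validated configuration tree; see :data:`DEFAULTS` for the schema."""

    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def from_dict(cls, override: dict) -> "RunConfig":
        return cls(data=_merge(DEFAULTS, override))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(load_yaml(path))

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def output_dir(self) -> Path:
        return Path(self.data["output_dir"])
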