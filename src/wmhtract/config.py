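"""Configuration objects for simulation, subgrouping, and pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigError
from .registry import AFFECTED_TRACTS, TRACTS

#: Outcome-noise standard deviations (score units) used when a config does
#: not override them. TMT-A in seconds; the rest in raw test scores.
DEFAULT_NOISE_SD: dict[str, float] = {
    "tmta": 45.0,
    "dsc": 12.0,
    "fds": 1.3,
    "bds": 1.2,
    "vf": 4.5,
}

#: Lesion-field peak probability per group (amplitude of the planted blobs).
DEFAULT_LESION_INTENSITY: dict[str, float] = {"mTBI": 0.95, "HC": 0.95}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-cohort generator.

    The defaults are the study conditions every seeded simulation runs
    under: 85 patients and 52 controls, 180 volumes at TR 2.5 s, 50-TR
    sliding windows, two latent connectivity states, and a planted
    processing-speed slope of 65.6 s per mL of left-thalamic-radiation
    lesion volume. ``n_rois`` defaults to 50 for tractable grids; 227 (the
    full parcellation size) is supported.
    """

    seed: int = 0
    n_patients: int = 85
    n_controls: int = 52
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 2.0  # mm, isotropic
    n_rois: int = 50
    n_volumes: int = 180
    tr: float = 2.5  # seconds
    window_length: int = 50  # TRs
    planted_k: int = 2
    stay_prob: float = 0.96  # per-TR probability of remaining in a state
    occupancy_slope: float = 2.0  # stay-log-odds of state 2 per mL of LTR load
    slope_tmta_per_ml: float = 65.6  # seconds per mL
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    covariate_effect_scale: float = 1.0  # scales the planted age/education effects
    lesion_intensity: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LESION_INTENSITY)
    )
    lesion_radius_mm: float = 8.0  # base blob radius before severity scaling
    patient_severity: tuple[float, float] = (0.4, 1.2)
    control_severity: tuple[float, float] = (0.3, 1.0)
    plant_severe: bool = True  # force the first patient to the severity maximum
    tube_radius_mm: float = 4.0  # atlas tube Gaussian radius
    fd_spike_frac: float = 0.02  # fraction of frames with FD > 1 mm
    include_cytokines: bool = True
    # latent-state covariance structure
    n_blocks: int = 5
    within_block_r: float = 0.6
    hub_block_r: float = 0.4  # coupling of the hub ("DMN") block to all others
    background_r: float = 0.1
    sparse_r: float = 0.1  # off-diagonal level of the segregated state
    # planted along-tract profile effect
    profile_effect: float = 0.1
    profile_effect_nodes: tuple[int, int] = (20, 40)  # 1-based inclusive node range
    profile_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_controls", "n_rois", "n_volumes",
                     "window_length", "planted_k", "n_blocks"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ConfigError("grid_shape must be 3 positive integers")
        if int(np.prod(self.grid_shape)) < 8:
            raise ConfigError("grid volume must be at least 8 voxels")
        if not 0 < self.stay_prob < 1:
            raise ConfigError("stay_prob must lie in (0, 1)")
        if not 0 <= self.fd_spike_frac < 1:
            raise ConfigError("fd_spike_frac must lie in [0, 1)")
        if self.window_length >= self.n_volumes:
            raise ConfigError("window_length must be smaller than n_volumes")
        if self.voxel_size <= 0 or self.tr <= 0:
            raise ConfigError("voxel_size and tr must be positive")
        lo, hi = self.profile_effect_nodes
        if not (1 <= lo <= hi <= 100):
            raise ConfigError("profile_effect_nodes must lie within 1..100")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise_sd"] = dict(self.noise_sd)
        d["lesion_intensity"] = dict(self.lesion_intensity)
        return d


@dataclass
class GroupingConfig:
    """Severity-subgrouping rule: residualized z > threshold on >= min_tracts."""

    z_threshold: float = 1.5
    min_tracts: int = 2
    tract_set: Sequence[str] = AFFECTED_TRACTS
    covariates: Sequence[str] = ("age", "sex", "education")
    value: str = "load_ratio_pct"  # or "wmh_ml"
    strict: bool = True  # exceedance is z > threshold (not >=)

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ConfigError("z_threshold must be positive")
        if self.min_tracts < 1:
            raise ConfigError("min_tracts must be >= 1")
        unknown = set(self.tract_set) - set(TRACTS)
        if unknown:
            raise ConfigError(f"unknown tracts in tract_set: {sorted(unknown)}")
        if self.value not in ("load_ratio_pct", "wmh_ml"):
            raise ConfigError("value must be 'load_ratio_pct' or 'wmh_ml'")
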