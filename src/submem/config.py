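"""Pipeline configuration.

A nested configuration (YAML-backed) with one block per stage and two
profiles: ``desk`` -- a small cohort sized so that the whole pipeline runs
on a laptop in minutes -- and ``paper`` -- the study-scale settings (420
volumes per run, 72 + 24 + 4 pictures, K = 60 components, 5000
permutations and resampling replicates).  Unknown keys are rejected, and
every CLI stage writes a resolved snapshot next to its outputs so each
artifact is reproducible from the manifest alone.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "default_config"]

_DESK: dict[str, Any] = {
    "profile": "desk",
    "seed": 0,
    "cohort": {
        "n_subjects": 30,
        "n_items": 24,
        "n_scrambled": 8,
        "n_primacy_recency": 4,
        "grid_shape": [12, 12, 8],
        "tr": 3.0,
        "picture_dur": 2.5,
        "fixation_dur": 0.5,
        "iti_range": [9.0, 12.0],
        "noise_sigma": 1.0,
        "ar_rho": 0.3,
        "drift_amp": 1.0,
        "n_networks": 4,
        "n_linked_networks": 2,
        "network_gain_corr": 0.7,
    },
    "glm": {"fwhm_mm": 8.0, "voxel_size_mm": 3.0},
    "group": {"n_perm": 500, "alpha": 0.05, "min_cluster": 20, "connectivity": 6},
    "bbcorr": {"sample_sizes": [10, 14, 20, 30], "n_reps": 200, "n_rois": 4},
    "netica": {"k": 10, "threshold_method": "zscore", "threshold_level": 3.0},
}

_PAPER_OVERRIDES: dict[str, Any] = {
    "profile": "paper",
    "cohort": {
        "n_subjects": 1498,
        "n_items": 72,
        "n_scrambled": 24,
        "grid_shape": [16, 16, 10],
    },
    "group": {"n_perm": 5000},
    "bbcorr": {
        "sample_sizes": [26, 38, 55, 78, 113, 162, 234, 336, 483, 695, 1000],
        "n_reps": 5000,
    },
    "netica": {"k": 60},
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in base:
            raise KeyError(f"unknown configuration key: {path}{key}")
        if isinstance(value, dict):
            out[key] = _merge(base[key], value, f"{path}{key}.")
        else:
            out[key] = value
    return out


@dataclass
class PipelineConfig:
    """Resolved per-stage parameters plus the master seed."""

    data: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(_DESK))

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def profile(self) -> str:
        return str(self.data["profile"])

    def with_overrides(self, **blocks: Any) -> "PipelineConfig":
        return PipelineConfig(_merge(self.data, blocks))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        user = yaml.safe_load(Path(path).read_text()) or {}
        base = default_config(str(user.get("profile", "desk"))).data
        return cls(_merge(base, user))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=False))


def default_config(profile: str = "desk") -> PipelineConfig:
    """Built-in configuration for a profile (``desk`` or ``paper``)."""
    if profile == "desk":
        return PipelineConfig(copy.deepcopy(_DESK))
    if profile == "paper":
        return PipelineConfig(_merge(_DESK, _PAPER_OVERRIDES))
    raise ValueError(f"unknown profile {profile!r} (expected 'desk' or 'paper')")
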