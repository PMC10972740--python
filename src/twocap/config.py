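"""Analysis configuration.

Collects the pipeline's printed constants: the 9-px approach radius, the
0.90 tracker-likelihood floor, 100 ms rate bins, the [-4, 18] s cue-centered
and [-2, 2] s approach-centered windows, the first-15-trials rule, the
+/-0.01 loading-split threshold, and the 1,000-pair bootstrap.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import yaml

from .types import ValidationError


@dataclass
class AnalysisConfig:
    approach_radius_px: float = 9.0
    likelihood_floor: float = 0.90
    bin_width_s: float = 0.1
    cue_window_s: tuple[float, float] = (-4.0, 18.0)
    approach_window_s: tuple[float, float] = (-2.0, 2.0)
    behavior_window_s: tuple[float, float] = (-5.0, 20.0)
    n_trials_used: int = 15
    loading_threshold: float = 0.01
    n_bootstrap: int = 1000
    subspace_dim: int = 3
    fps: float = 30.0
    iti_s: float = 30.0
    max_isi_violation: float = 0.05
    refractory_s: float = 0.002
    sigma_max_s: float = 2.0
    rng_seed: int = 0

    def validate(self) -> None:
        for name in (
            "approach_radius_px",
            "bin_width_s",
            "n_trials_used",
            "loading_threshold",
            "n_bootstrap",
            "subspace_dim",
            "fps",
            "sigma_max_s",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config: {name} must be positive")
        if not 0.0 < self.likelihood_floor <= 1.0:
            raise ValidationError("config: likelihood_floor must be in (0, 1]")
        for name in ("cue_window_s", "approach_window_s", "behavior_window_s"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"config: {name} not ordered")

    @classmethod
    def from_yaml(cls, path, overrides: Optional[dict] = None) -> "AnalysisConfig":
        """Load a flat YAML key set; ``overrides`` (e.g. CLI flags) win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if overrides:
            raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"config: unknown keys {sorted(unknown)}")
        for key in ("cue_window_s", "approach_window_s", "behavior_window_s"):
            if key in raw:
                raw[key] = tuple(float(v) for v in raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("cue_window_s", "approach_window_s", "behavior_window_s"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
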