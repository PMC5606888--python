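"""Run configuration: a single declarative object validated up front and
serialized verbatim into every output manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # paths
    input_dir: str = "."
    output_dir: str = "out"
    # seeds (every stochastic stage draws from a named seed)
    seeds: dict = field(
        default_factory=lambda: {
            "thinning": [101, 102, 103, 104, 105],
            "maxent": 7,
            "occupancy": 11,
            "gof": 13,
        }
    )
    # occurrence prep
    min_dist: float = 2000.0
    max_accuracy: float = 100.0
    elevation_threshold: float = 500.0
    n_sets: int = 5
    correlation_threshold: float = 0.75
    # bias
    bias_bandwidth: float | None = None
    # maxent
    reg_multiplier: float = 2.0
    tol: float = 1e-5
    max_iter: int = 1000
    n_background: int = 10000
    knots_per_variable: int = 50
    n_replicates: int = 20
    train_frac: float = 0.75
    # occupancy
    detection_specs: tuple = ("psi(.),p(.)", "psi(.),p(trip)", "psi(.),p(rainfall)")
    occupancy_covariates: tuple = ("suitability", "habitat_quality")
    n_gof_boot: int = 0
    # habitat quality
    browse_weights: dict = field(default_factory=lambda: {1: 3.0, 2: 2.0, 3: 1.0, 4: 0.0})
    diversity_bonus: float = 0.1

    def validate(self) -> None:
        required = {"thinning", "maxent", "occupancy"}
        missing = required - set(self.seeds)
        if missing:
            raise ValueError(f"config missing seeds: {sorted(missing)}")
        thin = self.seeds["thinning"]
        if not isinstance(thin, (list, tuple)) or len(thin) < self.n_sets:
            raise ValueError("seeds['thinning'] must list one seed per sample set")
        if self.min_dist <= 0 or self.max_accuracy <= 0:
            raise ValueError("distances must be positive")
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            text = fh.read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=str)
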