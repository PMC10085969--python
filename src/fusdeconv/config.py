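"""Run configuration with schema validation and seed fan-out."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields

import numpy as np


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Structural hyperparameters of a full pipeline run.

    Defaults follow the simulation protocol: 2 Hz sampling, an 8-second
    HRF support (L = 16 samples), lag window Lp = 2(L+1), K = L+1
    autocorrelation lags, one task and one artifact source, 20 restarts.
    """

    fs: float = 2.0
    L: int | None = None          # None -> round(8 s * fs)
    Lp: int | None = None         # None -> 2 (L + 1)
    K: int | None = None          # None -> L + 1
    R_task: int = 1
    R_artifact: int = 1
    n_runs: int = 20
    max_iter: int = 500
    t_cut: float = 0.5
    svd_tol: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.L is None:
            self.L = int(round(8.0 * self.fs))
        if self.Lp is None:
            self.Lp = 2 * (self.L + 1)
        if self.K is None:
            self.K = self.L + 1
        for name in ("L", "Lp", "K", "R_task", "n_runs", "max_iter"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.R_artifact < 0:
            raise ConfigError("R_artifact must be >= 0")

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def stage_seed(self, stage: int) -> int:
        """Deterministic per-stage seed fan-out from the master seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(stage,))
        return int(ss.generate_state(1)[0] % (2 ** 31))
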