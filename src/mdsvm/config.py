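"""Flat run configuration shared by the command-line pipeline.

All tunables of the pipeline live in one flat key-value namespace so a run
can be reproduced from a single ``key = value`` config file. Precedence is
command-line flag > config file > built-in default, and the effective
configuration is echoed into every output directory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, fields, asdict

from .bags import BagConfig
from .mil import TrainingConfig


@dataclass
class RunConfig:
    # bag construction
    window: int = 10
    step: int = 1
    probe_length: int = 35
    strand_mode: str = "forward-only"
    trim_flank: int = 0
    # training
    algorithm: str = "md-svm"
    C: float = 1.0
    kernel: str = "gaussian"
    gamma: float = 0.0  # 0 means the default 1 / (4 * window)
    max_iter: int = 50
    witness_change_tol: float = 0.01
    objective_rel_tol: float = 1e-4
    seed: int = 0
    # intensity labeling
    n_top: int = 200
    n_bottom: int = 200
    # motif extraction
    pseudocount: float = 0.5
    # simulation
    n_pos: int = 200
    n_neg: int = 200
    motif_length: int = 10
    motif_ic_target: float = 1.5
    intensity_gap: float = 0.5
    plant_position: str = "uniform"

    def bag_config(self) -> BagConfig:
        return BagConfig(
            window=self.window,
            step=self.step,
            probe_length=self.probe_length,
            strand_mode=self.strand_mode,
        )

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            C=self.C,
            kernel=self.kernel,
            gamma=self.gamma if self.gamma > 0 else None,
            max_iter=self.max_iter,
            witness_change_tol=self.witness_change_tol,
            objective_rel_tol=self.objective_rel_tol,
            seed=self.seed,
        )

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as handle:
            for key, value in asdict(self).items():
                handle.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        types = {f.name: type(getattr(cls(), f.name)) for f in fields(cls)}
        values: dict[str, object] = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, raw = (part.strip() for part in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = types[key](raw)
        return cls(**values)
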