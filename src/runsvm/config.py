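"""Flat pipeline configuration with YAML round-trip.

A :class:`PipelineConfig` bundles every knob of the filter → wrapper →
experiment pipeline.  Defaults mirror the standard evaluation protocol:
30 search agents, 100 iterations, 30 independent runs, 10-fold CV.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .optimizer import RunParams
from .wrapper import SvmConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    relieff_k_neighbors: int = 10
    top_m: int = 100
    pop_size: int = 30
    max_iter: int = 100
    a: float = 20.0
    b: float = 12.0
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    svm_gamma: float | str = "auto"
    n_folds: int = 10
    threshold: float = 0.5
    n_runs: int = 30
    master_seed: int = 0

    def run_params(self, seed: int) -> RunParams:
        return RunParams(
            pop_size=self.pop_size,
            max_iter=self.max_iter,
            r_min=0.0,
            r_max=1.0,
            a=self.a,
            b=self.b,
            seed=seed,
        )

    def svm_config(self) -> SvmConfig:
        return SvmConfig(
            kernel=self.svm_kernel,
            c=self.svm_c,
            gamma=self.svm_gamma,
            n_folds=self.n_folds,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML config; keyword overrides (CLI flags) win over file values."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must hold a flat mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    merged = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    return PipelineConfig(**merged)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path
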