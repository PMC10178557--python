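"""Multi-run evaluation protocol: repeated independent wrapper runs with
best / worst / mean / STD aggregation and convergence-trace retention.

ReliefF filtering is deterministic, so it is performed once; each of the
``n_runs`` wrapper runs then gets a fresh optimizer seed and fold seed
derived from the master seed through a prefix-stable counter scheme
(``numpy.random.SeedSequence(master).generate_state``), so adding runs never
perturbs earlier ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .dataset import ExpressionDataset, minmax_normalize
from .errors import ConfigurationError, ContractError
from .relieff import relieff_weights, top_m_features
from .wrapper import SelectionResult, select_genes

logger = logging.getLogger(__name__)

__all__ = ["ExperimentSummary", "run_experiment", "aggregate_stats", "derive_run_seeds"]


@dataclass(frozen=True)
class ExperimentSummary:
    """Per-run best accuracies plus their best/worst/mean/STD aggregate."""

    per_run_best: np.ndarray
    best: float
    worst: float
    mean: float
    std: float
    traces: list[np.ndarray]
    best_run_result: SelectionResult | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "per_run_best", np.asarray(self.per_run_best, dtype=float)
        )


def aggregate_stats(per_run_best: np.ndarray, population_std: bool = False) -> dict:
    """best = max, worst = min, mean, std (sample n-1 divisor by default).

    A single run has zero dispersion by convention.
    """
    values = np.asarray(per_run_best, dtype=float)
    if values.size == 0:
        raise ContractError("aggregate_stats requires a non-empty vector")
    if values.size == 1:
        std = 0.0
    else:
        std = float(np.std(values, ddof=0 if population_std else 1))
    return {
        "best": float(values.max()),
        "worst": float(values.min()),
        "mean": float(values.mean()),
        "std": std,
    }


def derive_run_seeds(master_seed: int, n_runs: int) -> list[tuple[int, int]]:
    """(optimizer_seed, fold_seed) per run; prefix-stable in ``n_runs``."""
    state = np.random.SeedSequence(master_seed).generate_state(2 * n_runs)
    seeds = (state & 0x7FFFFFFF).astype(int)
    return [(int(seeds[2 * i]), int(seeds[2 * i + 1])) for i in range(n_runs)]


def run_experiment(
    ds: ExpressionDataset,
    config: PipelineConfig = PipelineConfig(),
    n_runs: int | None = None,
    normalize: bool = True,
) -> ExperimentSummary:
    """Filter once with ReliefF, then run ``n_runs`` independent wrapper runs.

    Returns the per-run best CV accuracies, their aggregate statistics, every
    convergence trace, and the full result of the best run (ties resolved to
    the earlier run).
    """
    n_runs = config.n_runs if n_runs is None else n_runs
    if n_runs < 1:
        raise ConfigurationError(f"n_runs must be >= 1, got {n_runs}")
    if normalize:
        ds = minmax_normalize(ds)
    weights = relieff_weights(ds, config.relieff_k_neighbors)
    m = min(config.top_m, ds.n_genes)
    filtered, _ = top_m_features(weights, m, ds)
    logger.info("ReliefF retained %d of %d genes", m, ds.n_genes)

    results: list[SelectionResult] = []
    for run, (opt_seed, fold_seed) in enumerate(derive_run_seeds(config.master_seed, n_runs)):
        logger.info("run %d: optimizer seed %d, fold seed %d", run, opt_seed, fold_seed)
        results.append(
            select_genes(
                filtered,
                config.run_params(opt_seed),
                config.svm_config(),
                config.threshold,
                fold_seed=fold_seed,
            )
        )
    per_run_best = np.array([r.best_fitness for r in results])
    stats = aggregate_stats(per_run_best)
    best_run = int(np.argmax(per_run_best))
    return ExperimentSummary(
        per_run_best=per_run_best,
        best=stats["best"],
        worst=stats["worst"],
        mean=stats["mean"],
        std=stats["std"],
        traces=[r.trace for r in results],
        best_run_result=results[best_run],
    )
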