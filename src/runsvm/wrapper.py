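"""Wrapper gene selection: map continuous RUN positions to gene subsets and
score each subset by SVM cross-validation accuracy.

The search box is [0, 1]^d over the filtered gene pool; a position component
above the threshold (default 0.5) switches its gene on.  A subset's fitness
is the percentage of samples correctly classified, ``C / T * 100``, pooled
over the folds of a stratified K-fold cross-validation of a support-vector
classifier restricted to the subset.  The fold assignment is fixed for an
entire optimizer run, so fitness is a deterministic function of the mask and
repeated masks are served from a cache.

Internally the optimizer minimizes ``100 - accuracy`` so that its strict
less-than comparisons apply unchanged; every reported number is an accuracy
percentage in [0, 100].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .dataset import ExpressionDataset, FoldAssignment, stratified_folds
from .errors import ConfigurationError, ContractError
from .optimizer import OptimizationResult, RunParams, optimize

logger = logging.getLogger(__name__)

__all__ = ["SvmConfig", "SelectionResult", "binarize_position", "svm_cv_fitness", "select_genes"]


@dataclass(frozen=True)
class SvmConfig:
    """Support-vector classifier settings for the fitness evaluation.

    ``gamma="auto"`` resolves, per training fold, to
    ``1 / (n_selected_genes * mean per-gene variance)`` — the RBF width that
    keeps kernel distances comparable as the subset size changes.
    """

    kernel: str = "rbf"
    c: float = 1.0
    gamma: float | str = "auto"
    n_folds: int = 10

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ConfigurationError(f"kernel must be 'rbf' or 'linear', got {self.kernel!r}")
        if self.c <= 0:
            raise ConfigurationError(f"C must be positive, got {self.c}")
        if isinstance(self.gamma, str):
            if self.gamma != "auto":
                raise ConfigurationError(f"gamma must be positive or 'auto', got {self.gamma!r}")
        elif self.gamma <= 0:
            raise ConfigurationError(f"gamma must be positive, got {self.gamma}")
        if self.n_folds < 2:
            raise ConfigurationError(f"n_folds must be >= 2, got {self.n_folds}")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one wrapper run over a filtered gene pool."""

    mask: np.ndarray  # boolean over the filtered pool
    gene_ids: np.ndarray  # identifiers of the selected genes
    best_fitness: float  # CV accuracy % of the selected mask
    trace: np.ndarray  # best accuracy % per iteration, non-decreasing
    n_selected: int
    seed: int
    fold_seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        object.__setattr__(self, "trace", np.asarray(self.trace, dtype=float))
        if self.n_selected != int(self.mask.sum()) or self.n_selected < 1:
            raise ContractError("n_selected must equal popcount(mask) and be >= 1")
        if not 0.0 <= self.best_fitness <= 100.0:
            raise ContractError("best_fitness must be an accuracy percentage")


def binarize_position(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Turn a continuous position in [0,1]^d into a boolean gene mask.

    ``mask[j] = position[j] > threshold``; if no component clears the
    threshold the single gene with the maximal position value is selected
    (ties resolve to the lowest index), so the mask is never empty.
    """
    position = np.asarray(position, dtype=float)
    mask = position > threshold
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(position))] = True
    return mask


def _fold_accuracy_count(
    x: np.ndarray,
    y: np.ndarray,
    svm: SvmConfig,
    folds: FoldAssignment,
) -> int:
    """Pooled count of correct held-out predictions over all folds."""
    correct = 0
    for fold in range(folds.k):
        train = folds.train_indices(fold)
        test = folds.test_indices(fold)
        y_train = y[train]
        classes = np.unique(y_train)
        if len(classes) < 2:
            # degenerate training fold: predict the (single) majority class
            logger.warning("training fold %d holds one class; predicting it", fold)
            predictions = np.full(len(test), classes[0])
        else:
            x_train, x_test = x[train], x[test]
            gamma = svm.gamma
            if gamma == "auto":
                mean_var = float(np.mean(x_train.var(axis=0)))
                gamma = 1.0 / (x.shape[1] * mean_var) if mean_var > 0 else 1.0
            model = SVC(kernel=svm.kernel, C=svm.c, gamma=gamma)
            model.fit(x_train, y_train)
            predictions = model.predict(x_test)
        correct += int(np.sum(predictions == y[test]))
    return correct


def svm_cv_fitness(
    ds: ExpressionDataset,
    mask: np.ndarray,
    svm: SvmConfig,
    folds: FoldAssignment,
) -> float:
    """Cross-validated accuracy percentage of an SVM on the masked genes.

    ``fitness = C / T * 100`` where C is the number of correctly classified
    held-out samples pooled over all folds and T the total sample count.
    Deterministic given the mask and the fold assignment.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (ds.n_genes,):
        raise ContractError("mask length must equal the gene-pool size")
    if not mask.any():
        raise ContractError("empty mask; callers must apply the argmax fallback")
    if len(folds.fold_index) != ds.n_samples:
        raise ContractError("fold assignment does not match the dataset")
    correct = _fold_accuracy_count(ds.matrix[:, mask], ds.labels, svm, folds)
    return correct / ds.n_samples * 100.0


def select_genes(
    ds_filtered: ExpressionDataset,
    params: RunParams,
    svm: SvmConfig = SvmConfig(),
    threshold: float = 0.5,
    fold_seed: int | None = None,
) -> SelectionResult:
    """Run the combined wrapper search over a (ReliefF-filtered) gene pool.

    The optimizer minimizes ``100 - accuracy``; among masks of equal accuracy
    the one with fewer genes is preferred when reporting the final subset
    (supporting compact signatures without adding a size penalty to the
    fitness itself).  ``fold_seed`` defaults to the optimizer seed; the fold
    assignment is drawn once and reused for every fitness call.
    """
    if not 0.0 <= threshold < 1.0:
        raise ConfigurationError(f"threshold must be in [0, 1), got {threshold}")
    d = ds_filtered.n_genes
    if fold_seed is None:
        fold_seed = params.seed
    folds = stratified_folds(ds_filtered.labels, svm.n_folds, fold_seed)
    bounded = RunParams(
        pop_size=params.pop_size,
        max_iter=params.max_iter,
        r_min=0.0,
        r_max=1.0,
        a=params.a,
        b=params.b,
        seed=params.seed,
    )

    cache: dict[bytes, float] = {}
    incumbent: dict[str, object] = {"accuracy": -1.0, "n": d + 1, "mask": None}

    def objective(position: np.ndarray) -> float:
        mask = binarize_position(position, threshold)
        key = np.packbits(mask).tobytes()
        accuracy = cache.get(key)
        if accuracy is None:
            accuracy = svm_cv_fitness(ds_filtered, mask, svm, folds)
            cache[key] = accuracy
        n_sel = int(mask.sum())
        if accuracy > incumbent["accuracy"] or (
            accuracy == incumbent["accuracy"] and n_sel < incumbent["n"]  # type: ignore[operator]
        ):
            incumbent.update(accuracy=accuracy, n=n_sel, mask=mask.copy())
        return 100.0 - accuracy

    result: OptimizationResult = optimize(objective, bounded, d)
    mask = incumbent["mask"]
    assert mask is not None  # objective is called at least pop_size times
    return SelectionResult(
        mask=mask,
        gene_ids=ds_filtered.gene_ids[mask],
        best_fitness=float(incumbent["accuracy"]),  # type: ignore[arg-type]
        trace=100.0 - result.trace,
        n_selected=int(np.asarray(mask).sum()),
        seed=params.seed,
        fold_seed=fold_seed,
    )
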