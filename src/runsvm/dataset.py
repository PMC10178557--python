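"""Expression-matrix container, delimited I/O, normalization and stratified folds.

The central object is :class:`ExpressionDataset`: an ``S x F`` matrix of
expression values (samples as rows, genes as columns) with one integer class
code per sample.  Everything downstream — ReliefF weighting, the wrapper
search, the experiment harness — consumes this container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "FoldAssignment",
    "load_expression_matrix",
    "minmax_normalize",
    "stratified_folds",
    "write_results",
]


@dataclass(frozen=True)
class ExpressionDataset:
    """An S x F expression matrix with per-sample class labels.

    Attributes
    ----------
    matrix : (S, F) float array of expression values, no missing entries.
    labels : (S,) int array of class codes ``0..n_classes-1``.
    gene_ids : (F,) unique gene identifiers.
    sample_ids : (S,) unique sample identifiers.
    n_classes : number of distinct classes (>= 2).
    class_names : original string form of each class code, lexicographically
        ordered so that encoding is reproducible across file orderings.
    """

    matrix: np.ndarray
    labels: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    n_classes: int
    class_names: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        gene_ids = np.asarray(self.gene_ids, dtype=str)
        sample_ids = np.asarray(self.sample_ids, dtype=str)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        if self.class_names is None:
            object.__setattr__(
                self, "class_names", np.array([str(c) for c in range(self.n_classes)])
            )
        self.validate()

    def validate(self) -> None:
        s, f = self.matrix.shape
        if self.labels.shape != (s,):
            raise ValidationError(f"labels length {self.labels.shape} != S={s}")
        if self.gene_ids.shape != (f,):
            raise ValidationError(f"gene_ids length {self.gene_ids.shape} != F={f}")
        if self.sample_ids.shape != (s,):
            raise ValidationError("sample_ids length mismatch")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("expression matrix contains missing/non-finite values")
        if len(np.unique(self.gene_ids)) != f:
            raise ValidationError("gene identifiers are not unique")
        if len(np.unique(self.sample_ids)) != s:
            raise ValidationError("sample identifiers are not unique")
        codes, counts = np.unique(self.labels, return_counts=True)
        if len(codes) != self.n_classes or not np.array_equal(
            codes, np.arange(self.n_classes)
        ):
            raise ValidationError(
                f"labels must take exactly the codes 0..{self.n_classes - 1}"
            )
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if counts.min() < 2:
            small = self.class_names[int(codes[np.argmin(counts)])]
            raise ValidationError(
                f"class {small!r} has {counts.min()} sample(s); every class needs >= 2"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset_genes(self, indices: Sequence[int]) -> "ExpressionDataset":
        """Return the dataset restricted to ``indices``, in the given order."""
        idx = np.asarray(indices, dtype=int)
        return replace(self, matrix=self.matrix[:, idx], gene_ids=self.gene_ids[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.gene_ids)
        df.insert(0, "sample_id", self.sample_ids)
        df["class"] = self.class_names[self.labels]
        return df

    def to_csv(self, path: str | Path, delimiter: str = ",") -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep=delimiter, index=False)
        return path


@dataclass(frozen=True)
class FoldAssignment:
    """A stratified K-fold partition: one fold index in ``[0, K)`` per sample."""

    fold_index: np.ndarray
    k: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "fold_index", np.asarray(self.fold_index, dtype=int))
        if self.k < 2:
            raise ConfigurationError(f"K must be >= 2, got {self.k}")
        present = np.unique(self.fold_index)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValidationError("every fold in [0, K) must be non-empty")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def load_expression_matrix(
    path: str | Path,
    label_column: str = "class",
    delimiter: str = ",",
    *,
    sample_column: str = "sample_id",
    transpose: bool = False,
    impute_median: bool = False,
) -> ExpressionDataset:
    """Read a delimited expression table into an :class:`ExpressionDataset`.

    The expected layout is samples as rows, a header of gene identifiers, one
    label column (default ``"class"``) and optionally a sample-identifier
    column.  With ``transpose=True`` the file holds genes as rows and samples
    as columns (first column = gene id, one row named ``label_column`` holding
    the class labels).

    Class labels are encoded ``0..n_classes-1`` in lexicographic order of
    their string form.  Missing expression values are rejected unless
    ``impute_median=True``, in which case each gene's median fills its gaps.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if transpose:
        df = df.set_index(df.columns[0]).T.reset_index(names=sample_column)
    if label_column not in df.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not found in header of {path.name}"
        )
    raw_labels = df[label_column].astype(str).to_numpy()
    df = df.drop(columns=[label_column])
    if sample_column in df.columns:
        sample_ids = df[sample_column].astype(str).to_numpy()
        df = df.drop(columns=[sample_column])
    else:
        sample_ids = np.array([f"S{i}" for i in range(len(df))])

    gene_ids = df.columns.to_numpy(dtype=str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy() & df.notna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"non-numeric expression value {df.iat[r, c]!r} at sample "
            f"{sample_ids[r]!r}, gene {gene_ids[c]!r}"
        )
    matrix = numeric.to_numpy(dtype=float)
    if np.isnan(matrix).any():
        if not impute_median:
            r, c = np.argwhere(np.isnan(matrix))[0]
            raise ValidationError(
                f"missing expression value at sample {sample_ids[r]!r}, gene "
                f"{gene_ids[c]!r} (pass impute_median=True to fill with the "
                "per-gene median)"
            )
        medians = np.nanmedian(matrix, axis=0)
        rows, cols = np.where(np.isnan(matrix))
        matrix[rows, cols] = medians[cols]
        logger.info("imputed %d missing values with per-gene medians", len(rows))

    class_names = np.array(sorted(set(raw_labels)))
    code_of = {name: i for i, name in enumerate(class_names)}
    labels = np.array([code_of[v] for v in raw_labels], dtype=int)
    return ExpressionDataset(
        matrix=matrix,
        labels=labels,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        n_classes=len(class_names),
        class_names=class_names,
    )


def minmax_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Rescale every gene to [0, 1] by ``(x - min) / (max - min)``.

    A constant gene has zero range and maps to all zeros.  Idempotent on
    already-normalized data.
    """
    lo = ds.matrix.min(axis=0)
    hi = ds.matrix.max(axis=0)
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    scaled = (ds.matrix - lo) / safe
    scaled[:, span == 0] = 0.0
    return replace(ds, matrix=scaled)


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> FoldAssignment:
    """Deterministic stratified K-fold assignment.

    If the smallest class has fewer than ``k`` samples, ``k`` is reduced to
    that size (with a logged warning) rather than failing — expression-study
    classes are routinely tiny.
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ConfigurationError(f"K must be >= 2, got {k}")
    smallest = np.bincount(labels).min()
    if smallest < k:
        logger.warning(
            "smallest class has %d samples < K=%d; reducing K to %d", smallest, k, smallest
        )
        k = int(smallest)
        if k < 2:
            raise ValidationError("smallest class has < 2 samples; cannot fold")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        fold_index[test_idx] = fold
    return FoldAssignment(fold_index=fold_index, k=k)


def _write_trace(trace: Iterable[float], path: Path) -> Path:
    trace = list(trace)
    pd.DataFrame({"iteration": np.arange(len(trace)), "best_fitness": trace}).to_csv(
        path, index=False
    )
    return path


def write_results(result, out_dir: str | Path, prefix: str = "") -> list[Path]:
    """Write a selection or experiment result as plain CSV/text files.

    For a single wrapper run (``SelectionResult``): the selected-genes list
    (one gene id per line) and the convergence trace CSV.  For a multi-run
    experiment (``ExperimentSummary``): additionally the per-run best-fitness
    CSV (boxplot data), the aggregate-stats CSV with header
    ``STD,Best,Mean,Worst``, and one trace CSV per run.
    """
    from .experiment import ExperimentSummary
    from .wrapper import SelectionResult

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    paths: list[Path] = []
    if isinstance(result, SelectionResult):
        genes = out_dir / f"{prefix}selected_genes.txt"
        genes.write_text("".join(f"{g}\n" for g in result.gene_ids))
        paths.append(genes)
        paths.append(_write_trace(result.trace, out_dir / f"{prefix}convergence.csv"))
    elif isinstance(result, ExperimentSummary):
        runs = out_dir / f"{prefix}per_run_best.csv"
        pd.DataFrame(
            {"run": np.arange(len(result.per_run_best)), "best_fitness": result.per_run_best}
        ).to_csv(runs, index=False)
        paths.append(runs)
        stats = out_dir / f"{prefix}aggregate_stats.csv"
        pd.DataFrame(
            [
                {
                    "STD": result.std,
                    "Best": result.best,
                    "Mean": result.mean,
                    "Worst": result.worst,
                }
            ]
        ).to_csv(stats, index=False)
        paths.append(stats)
        for i, trace in enumerate(result.traces):
            paths.append(_write_trace(trace, out_dir / f"{prefix}convergence_run{i:02d}.csv"))
        if result.best_run_result is not None:
            genes = out_dir / f"{prefix}best_run_selected_genes.txt"
            genes.write_text("".join(f"{g}\n" for g in result.best_run_result.gene_ids))
            paths.append(genes)
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot serialize result of type {type(result).__name__}")
    return paths
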