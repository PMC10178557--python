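"""Ground-truthed synthetic expression datasets.

Emulates the statistical shape of cancer microarray studies — many genes,
few samples, a handful of class-informative genes — so every pipeline stage
is testable without external downloads.  The generative model is Gaussian
class shift: an informative gene for class ``c`` is drawn
``N(c * effect_size * noise_sd, noise_sd^2)``, a redundant gene copies a
random informative gene plus small jitter ``N(0, (noise_sd/4)^2)`` (genes in
real arrays are heavily inter-correlated), and every remaining gene is pure
``N(0, noise_sd^2)`` noise.  ``effect_size`` (class-mean shift in
within-class SD units) is the single difficulty knob.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .dataset import ExpressionDataset
from .errors import ConfigurationError

__all__ = ["SyntheticSpec", "generate_synthetic_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults give a desk-scale instance (60 samples x 100 genes, 5 informative
    at a 2-SD shift, 2 balanced classes) preserving the defining property of
    the real data — genes vastly outnumbering samples with few truly
    informative ones — at a size every test can afford.
    """

    n_samples: int = 60
    n_genes: int = 100
    n_informative: int = 5
    n_redundant: int = 10
    n_classes: int = 2
    effect_size: float = 2.0
    noise_sd: float = 1.0
    imbalance_ratio: float = 1.0
    seed: int = 0
    informative_indices: tuple[int, ...] | None = None  # filled by the generator

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_genes:
            raise ConfigurationError("n_informative + n_redundant must be <= n_genes")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.n_informative < 1:
            raise ConfigurationError("need at least one informative gene")
        if self.imbalance_ratio < 1.0:
            raise ConfigurationError("imbalance_ratio must be >= 1")
        if self.n_samples < 2 * self.n_classes:
            raise ConfigurationError("need at least 2 samples per class")
        if self.informative_indices is not None and len(self.informative_indices) != self.n_informative:
            raise ConfigurationError("informative_indices must have n_informative members")


def _class_labels(spec: SyntheticSpec) -> np.ndarray:
    """Class codes, balanced to +-1 by default; imbalance_ratio tilts the
    largest class against the smallest geometrically."""
    if spec.imbalance_ratio == 1.0:
        return np.arange(spec.n_samples) % spec.n_classes
    weights = spec.imbalance_ratio ** (
        np.arange(spec.n_classes) / max(spec.n_classes - 1, 1)
    )
    counts = np.maximum(2, np.round(weights / weights.sum() * spec.n_samples).astype(int))
    # adjust the largest class so counts sum to n_samples
    counts[np.argmax(counts)] += spec.n_samples - counts.sum()
    return np.repeat(np.arange(spec.n_classes), counts)


def generate_synthetic_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionDataset, SyntheticSpec]:
    """Draw one dataset; returns it with the spec's ground truth filled in.

    Deterministic given ``spec.seed``.  The informative gene positions are a
    random subset of the gene index range unless pinned via
    ``spec.informative_indices``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _class_labels(spec)
    s, f = spec.n_samples, spec.n_genes

    perm = rng.permutation(f)
    if spec.informative_indices is not None:
        informative = np.asarray(spec.informative_indices, dtype=int)
        remaining = np.setdiff1d(perm, informative, assume_unique=False)
        redundant = remaining[: spec.n_redundant]
    else:
        informative = np.sort(perm[: spec.n_informative])
        redundant = perm[spec.n_informative : spec.n_informative + spec.n_redundant]

    matrix = rng.normal(0.0, spec.noise_sd, size=(s, f))
    shift = labels[:, None] * spec.effect_size * spec.noise_sd
    matrix[:, informative] += shift
    for j in redundant:
        parent = informative[rng.integers(len(informative))]
        matrix[:, j] = matrix[:, parent] + rng.normal(0.0, spec.noise_sd / 4.0, size=s)

    ds = ExpressionDataset(
        matrix=matrix,
        labels=labels,
        gene_ids=np.array([f"G{j:05d}" for j in range(f)]),
        sample_ids=np.array([f"S{i:04d}" for i in range(s)]),
        n_classes=spec.n_classes,
        class_names=np.array([f"C{c}" for c in range(spec.n_classes)]),
    )
    filled = replace(spec, informative_indices=tuple(int(j) for j in informative))
    return ds, filled


def write_synthetic(
    ds: ExpressionDataset, spec: SyntheticSpec, out_dir: str | Path, delimiter: str = ","
) -> tuple[Path, Path]:
    """Write the dataset CSV plus a ground-truth sidecar of informative gene ids."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_path = ds.to_csv(out_dir / "synthetic_expression.csv", delimiter=delimiter)
    truth_path = out_dir / "informative_genes.txt"
    assert spec.informative_indices is not None
    truth_path.write_text(
        "".join(f"{ds.gene_ids[j]}\n" for j in spec.informative_indices)
    )
    return data_path, truth_path
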