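"""Shared fixtures: tiny delimited files and small datasets."""

from __future__ import annotations

import numpy as np
import pytest

from runsvm import ExpressionDataset


@pytest.fixture
def tiny_csv(tmp_path):
    """6 samples x 4 genes, two classes A/B, samples as rows."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "sample_id,g1,g2,g3,g4,class\n"
        "s1,1.0,2.0,0.1,5.0,A\n"
        "s2,1.1,2.2,0.2,5.1,A\n"
        "s3,0.9,1.9,0.15,5.2,A\n"
        "s4,3.0,0.5,0.9,5.0,B\n"
        "s5,3.2,0.4,0.8,5.3,B\n"
        "s6,2.9,0.6,0.95,4.9,B\n"
    )
    return path


@pytest.fixture
def small_dataset():
    """12 samples x 5 genes in [0,1], 2 balanced classes; gene 0 separates."""
    rng = np.random.default_rng(42)
    labels = np.array([0, 1] * 6)
    matrix = rng.uniform(size=(12, 5))
    matrix[:, 0] = labels * 0.9 + rng.uniform(0, 0.05, 12)
    return ExpressionDataset(
        matrix=matrix,
        labels=labels,
        gene_ids=np.array([f"g{j}" for j in range(5)]),
        sample_ids=np.array([f"s{i}" for i in range(12)]),
        n_classes=2,
    )


def random_normalized_dataset(rng, s=None, f=None, n_classes=2):
    """A random dataset with values in [0,1] and >= 2 samples per class."""
    s = int(rng.integers(2 * n_classes + 2, 13)) if s is None else s
    f = int(rng.integers(2, 7)) if f is None else f
    while True:
        labels = rng.integers(0, n_classes, size=s)
        if np.all(np.bincount(labels, minlength=n_classes) >= 2):
            break
    return ExpressionDataset(
        matrix=rng.uniform(size=(s, f)),
        labels=labels,
        gene_ids=np.array([f"g{j}" for j in range(f)]),
        sample_ids=np.array([f"s{i}" for i in range(s)]),
        n_classes=n_classes,
    )
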