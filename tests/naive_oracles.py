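"""Independent brute-force oracles used only by the test suite.

These deliberately avoid vectorization and share no code with the package:
plain double loops, Python sorting with explicit (distance, index) tie
breaking, sequential accumulation.
"""

from __future__ import annotations

import numpy as np


def naive_relieff_weights(x: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """O(S^2 F) prior-weighted multiclass ReliefF, all samples as anchors."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=int)
    s, f = x.shape
    classes = sorted(set(labels.tolist()))
    priors = {c: float(np.sum(labels == c)) / s for c in classes}
    weights = np.zeros(f)
    for i in range(s):
        ci = labels[i]
        for c in classes:
            if c == ci:
                idx = [j for j in range(s) if labels[j] == c and j != i]
            else:
                idx = [j for j in range(s) if labels[j] == c]
            ranked = sorted(idx, key=lambda j: (float(np.sum(np.abs(x[i] - x[j]))), j))
            k_eff = min(k, len(idx))
            neighbors = ranked[:k_eff]
            contribution = np.zeros(f)
            for j in neighbors:
                contribution = contribution + np.abs(x[i] - x[j])
            if c == ci:
                weights = weights - contribution / (s * k_eff)
            else:
                weights = weights + priors[c] / (1.0 - priors[ci]) * contribution / (
                    s * k_eff
                )
    return weights


def random_search(objective, lo, hi, n_evals: int, seed: int) -> float:
    """Pure uniform random search: the equal-budget baseline."""
    rng = np.random.default_rng(seed)
    d = len(lo)
    best = np.inf
    for _ in range(n_evals):
        y = lo + rng.uniform(size=d) * (hi - lo)
        best = min(best, float(objective(y)))
    return best
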