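"""Independent differentiation and counting oracles used by the tests.

These deliberately avoid the backpropagation code paths under test: the
complex-step oracle perturbs one coordinate of the *forward* map with an
imaginary step (machine-precision first derivatives for analytic maps),
and the finite-difference oracle uses plain central differences.
"""

from __future__ import annotations

import numpy as np


def complex_step_grad(f, x: np.ndarray, h: float = 1e-20) -> np.ndarray:
    """Gradient of scalar ``f`` at real vector ``x`` via complex-step."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        xc = x.astype(complex)
        xc[i] += 1j * h
        g[i] = f(xc).imag / h
    return g


def central_diff_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = eps
        g[i] = (f(x + e) - f(x - e)) / (2 * eps)
    return g


def pairwise_auc(y_true, scores) -> float:
    """O(n^2) Mann-Whitney AUC with half credit for tied scores."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))
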