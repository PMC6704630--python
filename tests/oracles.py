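"""Independent oracles used by the tests.

These deliberately avoid the package's solver path: a generic
quasi-Newton optimizer over the same penalized objective, a brute-force
filter scan, an ordinary least-squares slope fit, and pair-counting
AUC.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from immunosig.elasticnet import elastic_net_objective


def optimize_elastic_net(
    X: np.ndarray, y, alpha: float, lam: float, grouped: bool, kind: str,
    warm: tuple[np.ndarray, np.ndarray] | None = None, n_starts: int = 3,
) -> float:
    """Best objective a generic L-BFGS multi-start finds on the same
    objective (optionally also polishing a provided point)."""
    classes = np.unique(np.asarray(y))
    K = 1 if kind == "binary" else len(classes)
    p = X.shape[1]

    def unpack(theta):
        return theta[:K], theta[K:].reshape(p, K)

    def obj(theta):
        b0, B = unpack(theta)
        return elastic_net_objective(
            X, y, b0, B, alpha, lam, grouped=grouped, kind=kind,
            class_labels=classes,
        )

    starts = [
        np.random.default_rng(s).normal(0.0, 0.1, K + p * K) for s in range(n_starts)
    ]
    if warm is not None:
        b0w, Bw = warm
        starts.append(np.concatenate([np.ravel(b0w), np.ravel(Bw)]))
    best = np.inf
    for x0 in starts:
        res = minimize(
            obj, x0, method="L-BFGS-B",
            options=dict(maxiter=20000, maxfun=100000, ftol=1e-15, gtol=1e-12),
        )
        best = min(best, float(res.fun), obj(res.x))
    return best


def brute_force_filter(values: np.ndarray, mask: np.ndarray, min_count: float, min_samples: int):
    """Indices of genes passing the low-expression rule, by explicit scan."""
    keep = []
    for i in range(values.shape[0]):
        n_ok = 0
        for j in range(values.shape[1]):
            if not mask[i, j] and values[i, j] >= min_count:
                n_ok += 1
        if n_ok >= min_samples:
            keep.append(i)
    return keep


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x."""
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[1])


def pair_counting_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the fraction of (positive, negative) pairs ranked correctly."""
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
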