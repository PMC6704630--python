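"""Penalized logistic regression: binary and grouped-multinomial elastic net.

The multinomial objective minimized here is

    -(1/N) sum_i [ s_{y_i}(x_i) - log sum_k exp(s_k(x_i)) ] + lam * sum_j P_j

with per-class scores ``s_k(x) = b0_k + x' b_k`` and a per-gene penalty

    grouped:   P_j = (1-alpha)/2 * ||b_j.||_2^2 + alpha * sqrt(K) * ||b_j.||_2
    ungrouped: P_j = (1-alpha)/2 * ||b_j.||_2^2 + alpha * ||b_j.||_1

The grouped penalty zeroes all K class coefficients of a gene at once,
so a gene enters or leaves the classifier as a whole.  Binary models use
a single coefficient vector (K = 2 parameterized with one column) and
the scalar penalty.  Intercepts are never penalized.

The solver is an accelerated proximal-gradient iteration (FISTA with
gradient-based adaptive restart): the smooth multinomial/logistic loss
is handled by dense gradient steps, the nonsmooth penalty by exact
group/scalar soft-thresholding, and fits along a lambda grid are warm
started from the largest penalty downward.  Convergence is declared when
the relative objective change drops below ``tol``.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .errors import ConvergenceWarning, ValidationError
from .model import ClassifierModel, PenaltySpec, softmax

__all__ = [
    "ElasticNetLogistic",
    "penalty_value",
    "elastic_net_objective",
    "lambda_max",
    "fit_multinomial_elasticnet",
    "fit_binary_elasticnet",
    "cross_validate",
]


# ----------------------------------------------------------------------
# objective pieces (shared with tests / oracles)
# ----------------------------------------------------------------------

def penalty_value(
    coef: np.ndarray, alpha: float, grouped: bool, kind: str = "multinomial"
) -> float:
    """Sum over genes of the elastic-net penalty (without lambda)."""
    B = np.atleast_2d(np.asarray(coef, dtype=float))
    if B.ndim == 1:
        B = B[:, None]
    ridge = 0.5 * (1.0 - alpha) * float(np.sum(B * B))
    if kind == "binary" or not grouped:
        l1 = alpha * float(np.sum(np.abs(B)))
    else:
        k = B.shape[1]
        l1 = alpha * np.sqrt(k) * float(np.sum(np.linalg.norm(B, axis=1)))
    return ridge + l1


def _nll_multinomial(X: np.ndarray, Y: np.ndarray, b0: np.ndarray, B: np.ndarray) -> float:
    S = b0 + X @ B
    m = S.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(S - m).sum(axis=1))
    return float(np.mean(lse - (S * Y).sum(axis=1)))


def _nll_binary(X: np.ndarray, y01: np.ndarray, b0: float, b: np.ndarray) -> float:
    s = b0 + X @ b
    # log(1 + e^s) - y*s, stably
    return float(np.mean(np.logaddexp(0.0, s) - y01 * s))


def elastic_net_objective(
    X: np.ndarray,
    y,
    intercepts: np.ndarray,
    coef: np.ndarray,
    alpha: float,
    lam: float,
    grouped: bool = True,
    kind: str = "multinomial",
    class_labels: Sequence | None = None,
) -> float:
    """Penalized objective evaluated on the given (unstandardized) matrix.

    This is the quantity the solver minimizes when ``standardize=False``;
    it is deliberately a plain function of the inputs so independent
    optimizers can target the identical objective.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if kind == "binary":
        if class_labels is None:
            class_labels = np.unique(y)
        y01 = (y == class_labels[1]).astype(float)
        b = np.asarray(coef, dtype=float).reshape(-1)
        nll = _nll_binary(X, y01, float(np.asarray(intercepts).reshape(-1)[0]), b)
        return nll + lam * penalty_value(b[:, None], alpha, grouped, kind="binary")
    if class_labels is None:
        class_labels = np.unique(y)
    class_labels = list(class_labels)
    Y = np.zeros((len(y), len(class_labels)))
    for k, c in enumerate(class_labels):
        Y[y == c, k] = 1.0
    B = np.asarray(coef, dtype=float)
    nll = _nll_multinomial(X, Y, np.asarray(intercepts, dtype=float), B)
    return nll + lam * penalty_value(B, alpha, grouped, kind="multinomial")


def _spectral_norm_sq(X: np.ndarray, n_iter: int = 100, tol: float = 1e-8) -> float:
    """Largest squared singular value via deterministic power iteration."""
    v = np.ones(X.shape[1]) / np.sqrt(X.shape[1])
    prev = 0.0
    for _ in range(n_iter):
        w = X.T @ (X @ v)
        ev = float(np.linalg.norm(w))
        if ev == 0.0:
            return 0.0
        v = w / ev
        if abs(ev - prev) <= tol * max(ev, 1.0):
            break
        prev = ev
    return ev


def lambda_max(
    X: np.ndarray, y, alpha: float, grouped: bool = True, kind: str = "multinomial",
    standardize: bool = True,
) -> float:
    """Smallest penalty at which the solution is exactly intercept-only."""
    X = np.asarray(X, dtype=float)
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd
    n = X.shape[0]
    if alpha == 0.0:
        return np.inf
    if kind == "binary":
        classes = np.unique(y)
        y01 = (np.asarray(y) == classes[1]).astype(float)
        g = X.T @ (np.full(n, y01.mean()) - y01) / n
        return float(np.max(np.abs(g)) / alpha)
    classes = np.unique(y)
    K = len(classes)
    Y = np.zeros((n, K))
    for k, c in enumerate(classes):
        Y[np.asarray(y) == c, k] = 1.0
    P0 = np.tile(Y.mean(axis=0), (n, 1))
    G = X.T @ (P0 - Y) / n
    if grouped:
        return float(np.max(np.linalg.norm(G, axis=1)) / (alpha * np.sqrt(K)))
    return float(np.max(np.abs(G)) / alpha)


# ----------------------------------------------------------------------
# estimator
# ----------------------------------------------------------------------

class ElasticNetLogistic(BaseEstimator, ClassifierMixin):
    """Elastic-net logistic regression with an optional grouped penalty.

    Parameters
    ----------
    alpha : float in [0, 1]
        Lasso/ridge mixing (1 = pure lasso).  Default 0.93.
    lam : float
        Penalty strength.
    grouped : bool
        Multinomial only: tie the K class coefficients of each gene into
        one group (all-in or all-out).
    standardize : bool
        Penalize unit-variance features (population 1/N variance);
        coefficients are returned on the input scale.
    mode : {"auto", "multinomial", "binary"}
        "binary" requires exactly two classes and fits a single
        coefficient vector; "auto" picks binary for two classes.
    tol : float
        Relative objective-change convergence threshold.
    max_iter : int
        Iteration cap; hitting it flags the model and warns.

    Attributes
    ----------
    classes_, coef_ (n_classes_or_1 x p), intercept_, n_iter_,
    converged_, objective_ (final penalized objective in fitting space),
    lambda_max_.
    """

    def __init__(
        self,
        alpha: float = 0.93,
        lam: float = 0.01,
        grouped: bool = True,
        standardize: bool = True,
        mode: str = "auto",
        tol: float = 1e-7,
        max_iter: int = 100_000,
    ):
        self.alpha = alpha
        self.lam = lam
        self.grouped = grouped
        self.standardize = standardize
        self.mode = mode
        self.tol = tol
        self.max_iter = max_iter

    # -- internals -----------------------------------------------------
    def _prepare(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D samples x genes matrix")
        if not np.all(np.isfinite(X)):
            raise ValidationError("X contains non-finite values")
        if X.shape[0] != y.shape[0]:
            raise ValidationError("X and y length mismatch")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValidationError("need at least two classes")
        if counts.min() < 2:
            c = classes[np.argmin(counts)]
            raise ValidationError(f"class {c!r} has fewer than 2 samples")
        kind = self.mode
        if kind == "auto":
            kind = "binary" if len(classes) == 2 else "multinomial"
        if kind == "binary" and len(classes) != 2:
            raise ValidationError("binary mode requires exactly two classes")
        if kind not in ("binary", "multinomial"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must be in [0, 1]")
        if self.lam <= 0:
            raise ValidationError("lam must be positive")
        return X, y, classes, kind

    def _standardize(self, X):
        if not self.standardize:
            return X, np.zeros(X.shape[1]), np.ones(X.shape[1])
        mu = X.mean(axis=0)
        sd = X.std(axis=0)  # population variance
        sd = np.where(sd > 0, sd, 1.0)
        return (X - mu) / sd, mu, sd

    def _prox(self, V: np.ndarray, step: float, kind: str) -> np.ndarray:
        lam, alpha = self.lam, self.alpha
        denom = 1.0 + step * lam * (1.0 - alpha)
        if kind == "multinomial" and self.grouped:
            k = V.shape[1]
            thr = step * lam * alpha * np.sqrt(k)
            norms = np.linalg.norm(V, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                scale = np.where(norms > thr, (norms - thr) / norms, 0.0)
            return V * (scale / denom)[:, None]
        thr = step * lam * alpha
        return np.sign(V) * np.maximum(np.abs(V) - thr, 0.0) / denom

    def _fit_core(self, Xs, Y, kind, B0=None, b00=None):
        """FISTA on the standardized-space objective; returns (b0, B, iters, conv, obj)."""
        n, p = Xs.shape
        K = Y.shape[1]
        h = 0.25 if kind == "binary" else 0.5
        if self._lip is None:
            self._lip = h * _spectral_norm_sq(np.hstack([Xs, np.ones((n, 1))])) / n
        L = max(self._lip, 1e-12)
        step = 1.0 / (1.05 * L)
        lam, alpha = self.lam, self.alpha

        def smooth_and_resid(b0, B, S=None):
            if S is None:
                S = b0 + Xs @ B
            if kind == "binary":
                s = S[:, 0]
                P = 1.0 / (1.0 + np.exp(-np.clip(s, -500, 500)))
                nll = float(np.mean(np.logaddexp(0.0, s) - Y[:, 0] * s))
                R = (P - Y[:, 0])[:, None]
            else:
                m = S.max(axis=1, keepdims=True)
                E = np.exp(S - m)
                Z = E.sum(axis=1, keepdims=True)
                P = E / Z
                nll = float(np.mean(np.log(Z[:, 0]) + m[:, 0] - (S * Y).sum(axis=1)))
                R = P - Y
            return nll, R

        def objective(b0, B, S=None):
            nll, _ = smooth_and_resid(b0, B, S)
            return nll + lam * penalty_value(B, alpha, self.grouped, kind=kind)

        B = np.zeros((p, K)) if B0 is None else B0.copy()
        b0 = np.zeros(K) if b00 is None else b00.copy()
        B_prev, b0_prev = B.copy(), b0.copy()
        SX = Xs @ B
        SX_prev = SX.copy()
        t = 1.0
        w = 0.0  # momentum weight used to form the look-ahead point
        obj = objective(b0, B, S=b0 + SX)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # momentum point (scores maintained linearly: no extra matmul)
            if w:
                By = B + w * (B - B_prev)
                b0y = b0 + w * (b0 - b0_prev)
                Sy = b0y + SX + w * (SX - SX_prev)
            else:
                By, b0y, Sy = B, b0, b0 + SX
            _, R = smooth_and_resid(b0y, By, S=Sy)
            G = Xs.T @ R / n
            g0 = R.mean(axis=0)
            B_new = self._prox(By - step * G, step, kind)
            b0_new = b0y - step * g0
            SX_new = Xs @ B_new
            obj_new = objective(b0_new, B_new, S=b0_new + SX_new)
            if obj_new > obj + 1e-15:
                # adaptive restart: drop momentum, retake a plain descent
                # step from the current iterate (guaranteed monotone)
                if w:
                    _, R = smooth_and_resid(b0, B, S=b0 + SX)
                    G = Xs.T @ R / n
                    g0 = R.mean(axis=0)
                    B_new = self._prox(B - step * G, step, kind)
                    b0_new = b0 - step * g0
                    SX_new = Xs @ B_new
                    obj_new = objective(b0_new, B_new, S=b0_new + SX_new)
                t, w = 1.0, 0.0
            else:
                t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
                w = (t - 1.0) / t_next
                t = t_next
            B_prev, b0_prev, SX_prev = B, b0, SX
            B, b0, SX = B_new, b0_new, SX_new
            if abs(obj - obj_new) <= self.tol * max(1.0, abs(obj_new)):
                obj = obj_new
                converged = True
                break
            obj = obj_new
        if not converged:
            warnings.warn(
                f"elastic-net solver hit max_iter={self.max_iter} "
                f"(last objective {obj:.6g})",
                ConvergenceWarning,
            )
        return b0, B, it, converged, obj

    # -- public API ----------------------------------------------------
    def fit(self, X, y):
        X, y, classes, kind = self._prepare(X, y)
        Xs, mu, sd = self._standardize(X)
        self._lip = None
        n = X.shape[0]
        if kind == "binary":
            Y = (y == classes[1]).astype(float)[:, None]
        else:
            Y = np.zeros((n, len(classes)))
            for k, c in enumerate(classes):
                Y[y == c, k] = 1.0
        b0, B, n_iter, conv, obj = self._fit_core(Xs, Y, kind)
        self._finalize(classes, kind, b0, B, mu, sd, n_iter, conv, obj)
        self.lambda_max_ = lambda_max(
            X, y, self.alpha, grouped=self.grouped, kind=kind,
            standardize=self.standardize,
        )
        return self

    def _finalize(self, classes, kind, b0, B, mu, sd, n_iter, conv, obj):
        self.classes_ = classes
        self.kind_ = kind
        coef_std = B  # (p, K) in standardized space
        coef = coef_std / sd[:, None]
        intercept = b0 - (mu / sd) @ coef_std
        self.coef_ = coef.T  # sklearn convention (K, p)
        self.intercept_ = intercept
        self.n_iter_ = n_iter
        self.converged_ = conv
        self.objective_ = obj

    def path(self, X, y, lambdas: Sequence[float]):
        """Fit along a descending lambda grid with warm starts.

        Returns a list of dicts (lam, coef, intercept, n_nonzero_genes,
        n_iter, converged, objective) in the order given.
        """
        lambdas = list(lambdas)
        if not lambdas:
            raise ValidationError("lambda grid is empty")
        if any(l <= 0 for l in lambdas):
            raise ValidationError("lambda grid values must be positive")
        X, y, classes, kind = self._prepare(X, y)
        self.classes_ = classes
        self.kind_ = kind
        Xs, mu, sd = self._standardize(X)
        self._lip = None
        n = X.shape[0]
        if kind == "binary":
            Y = (y == classes[1]).astype(float)[:, None]
        else:
            Y = np.zeros((n, len(classes)))
            for k, c in enumerate(classes):
                Y[y == c, k] = 1.0
        order = np.argsort(lambdas)[::-1]
        results: dict[int, dict] = {}
        saved_lam = self.lam
        B_ws, b0_ws = None, None
        try:
            for idx in order:
                self.lam = float(lambdas[idx])
                b0, B, n_iter, conv, obj = self._fit_core(Xs, Y, kind, B0=B_ws, b00=b0_ws)
                B_ws, b0_ws = B.copy(), b0.copy()
                coef = (B / sd[:, None]).T
                intercept = b0 - (mu / sd) @ B
                results[idx] = {
                    "lam": float(lambdas[idx]),
                    "coef": coef,
                    "intercept": intercept,
                    "n_nonzero_genes": int(np.sum(np.any(B != 0.0, axis=1))),
                    "n_iter": n_iter,
                    "converged": conv,
                    "objective": obj,
                }
        finally:
            self.lam = saved_lam
        return [results[i] for i in range(len(lambdas))]

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_.T

    def predict_proba(self, X):
        S = self.decision_function(X)
        if self.kind_ == "binary":
            p1 = 1.0 / (1.0 + np.exp(-S[:, 0]))
            return np.column_stack([1.0 - p1, p1])
        return softmax(S)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def to_model(self, gene_ids: Sequence[str], provenance: dict | None = None) -> ClassifierModel:
        """Export fitted parameters as a :class:`ClassifierModel`."""
        spec = PenaltySpec(
            alpha=self.alpha, lam=self.lam, grouped=self.grouped,
            standardize=self.standardize, tol=self.tol, max_iter=self.max_iter,
        )
        if self.kind_ == "binary":
            coefficients = self.coef_.T  # (p, 1)
            intercepts = np.asarray([self.intercept_[0]])
        else:
            coefficients = self.coef_.T
            intercepts = self.intercept_
        return ClassifierModel(
            kind=self.kind_,
            class_labels=[str(c) for c in self.classes_],
            gene_ids=list(gene_ids),
            intercepts=intercepts,
            coefficients=coefficients,
            penalty=spec,
            training_provenance=provenance or {},
            converged=self.converged_,
        )


# ----------------------------------------------------------------------
# spec-level wrappers
# ----------------------------------------------------------------------

def _estimator(spec: PenaltySpec, mode: str) -> ElasticNetLogistic:
    return ElasticNetLogistic(
        alpha=spec.alpha, lam=spec.lam, grouped=spec.grouped,
        standardize=spec.standardize, mode=mode, tol=spec.tol,
        max_iter=spec.max_iter,
    )


def fit_multinomial_elasticnet(
    X: np.ndarray, y, spec: PenaltySpec,
    gene_ids: Sequence[str] | None = None,
    provenance: dict | None = None,
) -> ClassifierModel:
    """Fit a multinomial elastic net (log2-scale matrix, -1 dummies allowed)."""
    est = _estimator(spec, "multinomial").fit(X, y)
    ids = list(gene_ids) if gene_ids is not None else [f"g{j}" for j in range(np.shape(X)[1])]
    return est.to_model(ids, provenance)


def fit_binary_elasticnet(
    X: np.ndarray, y, spec: PenaltySpec,
    gene_ids: Sequence[str] | None = None,
    provenance: dict | None = None,
) -> ClassifierModel:
    """Fit a binary elastic net; one-vs-rest encoding is the caller's job."""
    est = _estimator(spec, "binary").fit(X, y)
    ids = list(gene_ids) if gene_ids is not None else [f"g{j}" for j in range(np.shape(X)[1])]
    return est.to_model(ids, provenance)


def cross_validate(
    X: np.ndarray, y, lambdas: Sequence[float], spec: PenaltySpec,
    nfolds: int = 10, seed: int = 0,
) -> dict:
    """Stratified K-fold CV returning mean held-out deviance per lambda.

    Deviance is -2x the mean held-out log-likelihood.  Fold assignment
    is deterministic given ``seed``.
    """
    lambdas = list(lambdas)
    if not lambdas:
        raise ValidationError("lambda grid is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    k = nfolds
    if counts.min() < nfolds:
        k = max(2, int(counts.min()))
        warnings.warn(
            f"smallest class has {counts.min()} samples; reducing folds "
            f"from {nfolds} to {k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_dev = np.zeros((k, len(lambdas)))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        est = _estimator(spec, "multinomial" if len(classes) > 2 else "auto")
        fits = est.path(X[tr], y[tr], lambdas)
        for li, fit in enumerate(fits):
            S = fit["intercept"] + X[te] @ fit["coef"].T
            if S.shape[1] == 1:  # binary
                y01 = (y[te] == classes[1]).astype(float)
                ll = -(np.logaddexp(0.0, S[:, 0]) - y01 * S[:, 0])
            else:
                m = S.max(axis=1, keepdims=True)
                lse = m[:, 0] + np.log(np.exp(S - m).sum(axis=1))
                idx = np.searchsorted(classes, y[te])
                ll = S[np.arange(len(te)), idx] - lse
            fold_dev[f, li] = -2.0 * float(np.mean(ll))
    return {
        "lambdas": lambdas,
        "mean_deviance": fold_dev.mean(axis=0),
        "fold_deviance": fold_dev,
        "nfolds": k,
    }
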