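"""Fitted-model container shared by the solver, IO and annotation layers.

A :class:`ClassifierModel` stores per-class intercepts and a gene x class
coefficient matrix together with the penalty that produced it.  Binary
models (used for per-cell-type gene signatures) are stored as a single
coefficient column for the positive class; multinomial models store one
column per class.  Prediction applies the softmax (or logistic) link and
is invariant to adding a constant to all class scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import DUMMY_VALUE, ExpressionDataset
from .errors import ValidationError


@dataclass(frozen=True)
class PenaltySpec:
    """Elastic-net penalty configuration.

    ``alpha`` mixes lasso (1) and ridge (0); ``lam`` is the overall
    strength.  With ``grouped=True`` the multinomial penalty ties all
    class coefficients of a gene together (group lasso with a sqrt(K)
    group scaling), so a gene enters or leaves the model as a whole.
    ``standardize`` penalizes unit-variance-scaled features and
    back-transforms the coefficients to the input scale.
    """

    alpha: float = 0.93
    lam: float = 0.01
    grouped: bool = True
    standardize: bool = True
    tol: float = 1e-7
    max_iter: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lam <= 0:
            raise ValidationError(f"lambda must be positive, got {self.lam}")
        if self.tol <= 0 or self.max_iter <= 0:
            raise ValidationError("tol and max_iter must be positive")


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=1, keepdims=True)
    return z


@dataclass
class ClassifierModel:
    """Intercepts + coefficients of a fitted penalized logistic model."""

    kind: str  # "multinomial" | "binary"
    class_labels: list[str]
    gene_ids: list[str]
    intercepts: np.ndarray  # (K,) multinomial; (1,) binary
    coefficients: np.ndarray  # (p, K) multinomial; (p, 1) binary
    penalty: PenaltySpec
    training_provenance: dict = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.kind not in ("multinomial", "binary"):
            raise ValidationError(f"unknown model kind {self.kind!r}")
        p, k = self.coefficients.shape
        if p != len(self.gene_ids):
            raise ValidationError("coefficient rows != number of genes")
        if self.kind == "multinomial":
            if k != len(self.class_labels) or self.intercepts.shape != (k,):
                raise ValidationError("class dimension mismatch")
        else:
            if k != 1 or len(self.class_labels) != 2 or self.intercepts.shape != (1,):
                raise ValidationError("binary model must have one coefficient column")
        if not np.all(np.isfinite(self.coefficients)) or not np.all(
            np.isfinite(self.intercepts)
        ):
            raise ValidationError("non-finite model parameters")

    # ------------------------------------------------------------------
    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def selected_genes(self) -> list[str]:
        """Genes with at least one nonzero coefficient."""
        nz = np.any(self.coefficients != 0.0, axis=1)
        return [g for g, keep in zip(self.gene_ids, nz) if keep]

    def align_matrix(
        self,
        X: np.ndarray | ExpressionDataset,
        gene_ids: Sequence[str] | None = None,
        fill_missing: bool = False,
    ) -> np.ndarray:
        """Samples x model-genes matrix aligned to ``self.gene_ids``.

        Genes absent from the input are filled with the dummy value -1,
        but only when ``fill_missing`` is set; otherwise a misaligned
        gene set is an error.
        """
        if isinstance(X, ExpressionDataset):
            gene_ids = X.gene_ids
            X = X.encoded_matrix()
        X = np.asarray(X, dtype=float)
        if gene_ids is None:
            if X.shape[1] != len(self.gene_ids):
                raise ValidationError(
                    f"matrix has {X.shape[1]} columns but model has "
                    f"{len(self.gene_ids)} genes and no gene_ids were given"
                )
            return X
        index = {g: j for j, g in enumerate(gene_ids)}
        absent = [g for g in self.gene_ids if g not in index]
        if absent and not fill_missing:
            raise ValidationError(
                f"{len(absent)} model genes absent from input (e.g. "
                f"{absent[:5]}); pass fill_missing=True to encode them as -1"
            )
        out = np.full((X.shape[0], len(self.gene_ids)), DUMMY_VALUE, dtype=float)
        for j, g in enumerate(self.gene_ids):
            if g in index:
                out[:, j] = X[:, index[g]]
        return out

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Per-class linear scores for an aligned samples x genes matrix."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.gene_ids):
            raise ValidationError("matrix not aligned to model genes")
        return self.intercepts + X @ self.coefficients

    def predict_proba(
        self,
        X: np.ndarray | ExpressionDataset,
        gene_ids: Sequence[str] | None = None,
        fill_missing: bool = False,
    ) -> np.ndarray:
        """Class posterior probabilities, rows summing to one."""
        Xa = self.align_matrix(X, gene_ids=gene_ids, fill_missing=fill_missing)
        scores = self.decision_function(Xa)
        if self.kind == "binary":
            p1 = 1.0 / (1.0 + np.exp(-scores[:, 0]))
            return np.column_stack([1.0 - p1, p1])
        return softmax(scores)

    def predict(
        self,
        X: np.ndarray | ExpressionDataset,
        gene_ids: Sequence[str] | None = None,
        fill_missing: bool = False,
    ) -> np.ndarray:
        """Argmax class labels; ties resolve to the first class in order."""
        proba = self.predict_proba(X, gene_ids=gene_ids, fill_missing=fill_missing)
        return np.asarray(self.class_labels, dtype=object)[np.argmax(proba, axis=1)]

    # equality to fitting precision, used by serialization round-trips
    def allclose(self, other: "ClassifierModel", tol: float = 1e-12) -> bool:
        return (
            self.kind == other.kind
            and self.class_labels == other.class_labels
            and self.gene_ids == other.gene_ids
            and np.allclose(self.intercepts, other.intercepts, atol=tol, rtol=0)
            and np.allclose(self.coefficients, other.coefficients, atol=tol, rtol=0)
            and self.penalty == other.penalty
        )
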