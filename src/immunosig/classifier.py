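"""Classifier construction: augmentation, bootstrap negatives, lambda selection.

The workflow mirrors a two-part evaluation: the model is fitted on a
missing-value-augmented training set (the training samples duplicated
``duplication_factor`` times with a random ``dropout_fraction`` of
observed entries knocked out to the dummy value -1), then each penalty
strength on the grid is scored by a ROC built from real held-out
samples (true positives) against bootstrap synthetic negatives whose
per-gene marginals match the test data but whose cross-gene correlation
is destroyed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dataset import DUMMY_VALUE, ExpressionDataset
from .elasticnet import ElasticNetLogistic, cross_validate
from .errors import ValidationError
from .model import ClassifierModel, PenaltySpec

#: The seven penalty strengths evaluated by default.
DEFAULT_LAMBDA_GRID = (0.1, 0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001)


@dataclass(frozen=True)
class AugmentParams:
    """Missing-value augmentation: duplicate the training set
    ``duplication_factor`` times and knock out ``dropout_fraction`` of
    the observed entries per replicate, encoding all absent entries as
    the dummy constant -1."""

    duplication_factor: int = 100
    dropout_fraction: float = 0.10
    dummy_value: float = DUMMY_VALUE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duplication_factor < 1:
            raise ValidationError("duplication_factor must be a positive integer")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValidationError("dropout_fraction must be in [0, 1)")
        if self.dummy_value != DUMMY_VALUE:
            raise ValidationError("the dummy value is fixed at -1")


@dataclass
class LambdaEvaluation:
    """ROC/AUC evaluation of one penalty strength."""

    lam: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_nonzero_genes: int
    converged: bool = True
    cv_deviance: float | None = None
    model: ClassifierModel | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        for arr, name in ((self.fpr, "fpr"), (self.tpr, "tpr")):
            if np.any(np.diff(arr) < 0):
                raise ValidationError(f"ROC {name} must be non-decreasing")
        if not (
            np.isclose(self.fpr[0], 0) and np.isclose(self.tpr[0], 0)
            and np.isclose(self.fpr[-1], 1) and np.isclose(self.tpr[-1], 1)
        ):
            raise ValidationError("ROC must run from (0,0) to (1,1)")
        area = float(np.trapezoid(self.tpr, self.fpr))
        if abs(area - self.auc) > 1e-12:
            raise ValidationError("auc does not equal the trapezoidal ROC area")


def roc_from_scores(
    pos_scores: np.ndarray, neg_scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by sweeping the score threshold; AUC by the trapezoid rule."""
    pos_scores = np.asarray(pos_scores, dtype=float)
    neg_scores = np.asarray(neg_scores, dtype=float)
    y = np.concatenate([np.ones(pos_scores.size), np.zeros(neg_scores.size)])
    s = np.concatenate([pos_scores, neg_scores])
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def augment_training_set(
    ds_train: ExpressionDataset, params: AugmentParams = AugmentParams()
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Return (X_aug, y_aug, gene_ids) for the duplicated/dropped-out set.

    ``X_aug`` is samples x genes with ``duplication_factor * n_train``
    rows; originally missing entries are -1 in every replicate and each
    replicate additionally drops an independent ``dropout_fraction`` of
    the observed entries.  Deterministic given ``params.seed``.
    """
    if ds_train.value_scale != "log2":
        raise ValidationError("augmentation expects a log2-scale dataset")
    y = ds_train.labels
    if y.isna().any():
        raise ValidationError("all training samples must be labeled")
    rng = np.random.default_rng(params.seed)
    base = ds_train.encoded_matrix(dummy=params.dummy_value)  # n x p
    observed = ~ds_train.missing_mask.T  # n x p
    n, p = base.shape
    f = params.duplication_factor
    X_aug = np.tile(base, (f, 1))
    if params.dropout_fraction > 0:
        drop = rng.random((f * n, p)) < params.dropout_fraction
        drop &= np.tile(observed, (f, 1))
        X_aug[drop] = params.dummy_value
    y_aug = np.tile(y.to_numpy(dtype=object), f)
    return X_aug, y_aug, list(ds_train.gene_ids)


def make_bootstrap_negatives(
    ds_test: ExpressionDataset, n_negatives: int | None = None, seed: int = 0
) -> np.ndarray:
    """Synthetic negatives: per gene, each synthetic sample draws its
    value from a random real test sample.

    Per-gene marginal distributions are preserved while cross-gene
    correlation is broken, giving a negative class of "similar size and
    complexity" but no biological structure.  Returns samples x genes
    (with the -1 encoding of genuinely missing test entries).
    """
    if ds_test.n_samples == 0:
        raise ValidationError("test dataset is empty")
    if n_negatives is None:
        n_negatives = ds_test.n_samples
    rng = np.random.default_rng(seed)
    encoded = ds_test.encoded_matrix()  # n x p
    n, p = encoded.shape
    donor = rng.integers(0, n, size=(n_negatives, p))
    return encoded[donor, np.arange(p)[None, :]]


def score_confidence(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """Per-sample confidence: the maximum class posterior, in [1/K, 1]."""
    proba = model.predict_proba(X)
    return proba.max(axis=1)


def evaluate_lambda(
    ds_train: ExpressionDataset,
    ds_test: ExpressionDataset,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    spec: PenaltySpec | None = None,
    augment_params: AugmentParams | None = None,
    seed: int = 0,
    n_negatives: int | None = None,
    compute_cv: bool = False,
    nfolds: int = 10,
) -> list[LambdaEvaluation]:
    """Fit the penalty grid on augmented training data and score each
    lambda by the bootstrap-negative ROC.

    Per lambda: fit (warm-started along the grid), score real test
    samples as positives and bootstrap synthetic samples as negatives
    with the max-posterior confidence, sweep the threshold for the ROC
    and record AUC and the nonzero-gene count.  Fit failures flag the
    entry and the grid continues.
    """
    lambda_grid = list(lambda_grid)
    if not lambda_grid:
        raise ValidationError("lambda grid is empty")
    if ds_train.gene_ids != ds_test.gene_ids:
        raise ValidationError("train/test gene sets differ")
    spec = spec or PenaltySpec()
    augment_params = augment_params or AugmentParams(seed=seed)
    X_aug, y_aug, gene_ids = augment_training_set(ds_train, augment_params)
    X_test = ds_test.encoded_matrix()
    X_neg = make_bootstrap_negatives(ds_test, n_negatives=n_negatives, seed=seed + 1)

    est = ElasticNetLogistic(
        alpha=spec.alpha, lam=lambda_grid[0], grouped=spec.grouped,
        standardize=spec.standardize, mode="multinomial", tol=spec.tol,
        max_iter=spec.max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits = est.path(X_aug, y_aug, lambda_grid)
    cv = None
    if compute_cv:
        cv = cross_validate(X_aug, y_aug, lambda_grid, spec, nfolds=nfolds, seed=seed)
    evals: list[LambdaEvaluation] = []
    classes = [str(c) for c in est.classes_]
    for li, fit in enumerate(fits):
        pen = PenaltySpec(
            alpha=spec.alpha, lam=fit["lam"], grouped=spec.grouped,
            standardize=spec.standardize, tol=spec.tol, max_iter=spec.max_iter,
        )
        model = ClassifierModel(
            kind="multinomial",
            class_labels=classes,
            gene_ids=gene_ids,
            intercepts=fit["intercept"],
            coefficients=fit["coef"].T,
            penalty=pen,
            training_provenance={
                "augment": {
                    "duplication_factor": augment_params.duplication_factor,
                    "dropout_fraction": augment_params.dropout_fraction,
                    "seed": augment_params.seed,
                },
                "n_train_samples": ds_train.n_samples,
            },
            converged=fit["converged"],
        )
        pos = score_confidence(model, X_test)
        neg = score_confidence(model, X_neg)
        fpr, tpr, area = roc_from_scores(pos, neg)
        evals.append(
            LambdaEvaluation(
                lam=fit["lam"], fpr=fpr, tpr=tpr, auc=area,
                n_nonzero_genes=fit["n_nonzero_genes"],
                converged=fit["converged"],
                cv_deviance=None if cv is None else float(cv["mean_deviance"][li]),
                model=model,
            )
        )
    return evals


def select_lambda(
    evals: list[LambdaEvaluation],
    rule: str = "max_auc_smallest_lambda",
    tie_tol: float = 1e-3,
) -> float:
    """Pick the penalty from the grid evaluations.

    ``max_auc_smallest_lambda``: among lambdas whose AUC is within
    ``tie_tol`` of the maximum, the smallest (most genes).
    ``inflection``: the lambda maximizing AUC, ties resolving to the
    larger lambda (the point beyond which growing lambda hurts).
    """
    if not evals:
        raise ValidationError("no lambda evaluations given")
    if rule not in ("max_auc_smallest_lambda", "inflection"):
        raise ValidationError(f"unknown selection rule {rule!r}")
    aucs = np.array([e.auc for e in evals])
    lams = np.array([e.lam for e in evals])
    if len(evals) == 1:
        return float(lams[0])
    if aucs.max() - aucs.min() <= tie_tol:
        warnings.warn(
            "all AUCs are tied; the selection rule is degenerate -- "
            "returning the smallest lambda"
        )
        return float(lams.min())
    near = lams[aucs >= aucs.max() - tie_tol]
    return float(near.min() if rule == "max_auc_smallest_lambda" else near.max())


def train_classifier(
    ds_train: ExpressionDataset,
    ds_test: ExpressionDataset,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    spec: PenaltySpec | None = None,
    augment_params: AugmentParams | None = None,
    seed: int = 0,
    rule: str = "max_auc_smallest_lambda",
    n_negatives: int | None = None,
    compute_cv: bool = False,
) -> tuple[ClassifierModel, list[LambdaEvaluation], float]:
    """Full first-step workflow: evaluate the grid, select lambda, and
    return (selected model, all evaluations, selected lambda)."""
    evals = evaluate_lambda(
        ds_train, ds_test, lambda_grid=lambda_grid, spec=spec,
        augment_params=augment_params, seed=seed, n_negatives=n_negatives,
        compute_cv=compute_cv,
    )
    chosen = select_lambda(evals, rule=rule)
    model = next(e.model for e in evals if e.lam == chosen)
    model.training_provenance["lambda_grid"] = list(lambda_grid)
    model.training_provenance["selection_rule"] = rule
    model.training_provenance["selected_lambda"] = chosen
    return model, evals, chosen
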