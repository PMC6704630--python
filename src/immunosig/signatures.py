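"""Second step of the two-step procedure: per-cell-type gene signatures.

Genes selected by the multiclass classifier become the candidate pool;
for each cell type a binary elastic net (that type vs all others in the
same group) is fitted on the augmented training data across the lambda
grid, scored by the bootstrap-negative ROC on held-out samples of the
type, and the nonzero coefficients of the selected fit form the
signature.  Negative coefficients mark genes whose presence argues
*against* the cell type.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classifier import (
    AugmentParams,
    DEFAULT_LAMBDA_GRID,
    LambdaEvaluation,
    augment_training_set,
    make_bootstrap_negatives,
    roc_from_scores,
    select_lambda,
)
from .dataset import ExpressionDataset
from .elasticnet import ElasticNetLogistic
from .errors import ValidationError
from .model import ClassifierModel, PenaltySpec

_REST_LABEL = "__rest__"


@dataclass
class GeneSignature:
    """One cell type's signed gene list."""

    cell_type: str
    entries: list[tuple[str, float]]  # (gene_id, nonzero coefficient)
    lambda_used: float
    auc_at_selection: float
    ovr_auc: float | None = None  # one-vs-rest real-negative diagnostic

    def __post_init__(self) -> None:
        if any(c == 0.0 for _, c in self.entries):
            raise ValidationError("signature entries must have nonzero coefficients")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def negative_genes(self) -> list[str]:
        """Genes whose presence lowers the odds of this cell type."""
        return [g for g, c in self.entries if c < 0]


def build_signature(
    ds_train: ExpressionDataset,
    ds_test: ExpressionDataset,
    parent_model: ClassifierModel,
    cell_type: str,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    spec: PenaltySpec | None = None,
    augment_params: AugmentParams | None = None,
    seed: int = 0,
    rule: str = "max_auc_smallest_lambda",
) -> GeneSignature:
    """Binary refinement of the parent classifier's genes for one type.

    Both splits are restricted to the parent-selected genes; training
    labels become one-vs-rest; the training half is augmented exactly as
    in the first step; each lambda is scored by ROC with positives =
    held-out samples of ``cell_type`` (class-1 probability) and
    negatives = bootstrap synthetic samples.
    """
    selected = parent_model.selected_genes
    if not selected:
        raise ValidationError("parent model has no selected genes")
    labels_train = ds_train.labels
    n_pos_train = int((labels_train == cell_type).sum())
    if n_pos_train < 2:
        raise ValidationError(
            f"cell type {cell_type!r} has {n_pos_train} training sample(s); need >= 2"
        )
    spec = spec or PenaltySpec()
    augment_params = augment_params or AugmentParams(seed=seed)
    tr = ds_train.subset_genes(selected)
    te = ds_test.subset_genes(selected)

    # one-vs-rest labels, positive class sorts after the rest label
    binary_meta = tr.sample_meta.copy()
    binary_meta["cell_type"] = np.where(
        labels_train.reindex(tr.sample_ids) == cell_type, cell_type, _REST_LABEL
    )
    tr_bin = tr.copy()
    tr_bin.sample_meta = binary_meta

    X_aug, y_aug, gene_ids = augment_training_set(tr_bin, augment_params)
    est = ElasticNetLogistic(
        alpha=spec.alpha, lam=lambda_grid[0], grouped=spec.grouped,
        standardize=spec.standardize, mode="binary", tol=spec.tol,
        max_iter=spec.max_iter,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits = est.path(X_aug, y_aug, list(lambda_grid))

    pos_class_index = int(np.where(est.classes_ == cell_type)[0][0])
    X_test = te.encoded_matrix()
    test_labels = te.labels.to_numpy(dtype=object)
    pos_mask = test_labels == cell_type
    if not pos_mask.any():
        raise ValidationError(f"no held-out samples of type {cell_type!r}")
    X_neg = make_bootstrap_negatives(te, seed=seed + 1)

    evals: list[LambdaEvaluation] = []
    for fit in fits:
        model = ClassifierModel(
            kind="binary",
            class_labels=[str(c) for c in est.classes_],
            gene_ids=gene_ids,
            intercepts=np.atleast_1d(fit["intercept"]),
            coefficients=fit["coef"].T,
            penalty=PenaltySpec(
                alpha=spec.alpha, lam=fit["lam"], grouped=spec.grouped,
                standardize=spec.standardize, tol=spec.tol, max_iter=spec.max_iter,
            ),
            converged=fit["converged"],
        )
        p1 = model.predict_proba(X_test)[:, pos_class_index]
        p1_neg = model.predict_proba(X_neg)[:, pos_class_index]
        fpr, tpr, area = roc_from_scores(p1[pos_mask], p1_neg)
        evals.append(
            LambdaEvaluation(
                lam=fit["lam"], fpr=fpr, tpr=tpr, auc=area,
                n_nonzero_genes=fit["n_nonzero_genes"],
                converged=fit["converged"], model=model,
            )
        )
    non_empty = [e for e in evals if e.n_nonzero_genes > 0]
    if not non_empty:
        raise ValidationError(
            f"signature for {cell_type!r} is empty at every lambda in "
            f"{list(lambda_grid)}; extend the grid toward smaller penalties"
        )
    chosen = select_lambda(non_empty, rule=rule)
    best = next(e for e in non_empty if e.lam == chosen)
    model = best.model
    # one-vs-rest diagnostic on real held-out negatives
    p1 = model.predict_proba(X_test)[:, pos_class_index]
    ovr_auc = None
    if (~pos_mask).any():
        _, _, ovr_auc = roc_from_scores(p1[pos_mask], p1[~pos_mask])
    coefs = model.coefficients[:, 0]
    entries = [
        (g, float(c)) for g, c in zip(model.gene_ids, coefs) if c != 0.0
    ]
    return GeneSignature(
        cell_type=cell_type, entries=entries, lambda_used=chosen,
        auc_at_selection=best.auc, ovr_auc=ovr_auc,
    )


def build_all_signatures(
    ds_train: ExpressionDataset,
    ds_test: ExpressionDataset,
    parent_model: ClassifierModel,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    spec: PenaltySpec | None = None,
    augment_params: AugmentParams | None = None,
    seed: int = 0,
    rule: str = "max_auc_smallest_lambda",
) -> list[GeneSignature]:
    """One signature per class of the parent model, in class order."""
    sigs = []
    for i, cell_type in enumerate(parent_model.class_labels):
        sigs.append(
            build_signature(
                ds_train, ds_test, parent_model, cell_type,
                lambda_grid=lambda_grid, spec=spec,
                augment_params=augment_params, seed=seed + 101 * i, rule=rule,
            )
        )
    return sigs


def export_signatures(signatures: list[GeneSignature], path: str | Path) -> None:
    """TSV with cell_type, gene, coefficient and sign flag (lossless)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["cell_type", "gene_id", "coefficient", "sign", "lambda_used", "auc_at_selection"]
        )
        for sig in signatures:
            for g, c in sig.entries:
                w.writerow(
                    [
                        sig.cell_type, g, repr(c),
                        "negative" if c < 0 else "positive",
                        repr(sig.lambda_used), repr(sig.auc_at_selection),
                    ]
                )


def read_signatures(path: str | Path) -> list[GeneSignature]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    by_type: dict[str, list[dict]] = {}
    for r in rows:
        by_type.setdefault(r["cell_type"], []).append(r)
    sigs = []
    for cell_type, entries in by_type.items():
        sigs.append(
            GeneSignature(
                cell_type=cell_type,
                entries=[(r["gene_id"], float(r["coefficient"])) for r in entries],
                lambda_used=float(entries[0]["lambda_used"]),
                auc_at_selection=float(entries[0]["auc_at_selection"]),
            )
        )
    return sigs
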