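"""Applying a trained classifier to single cells and downstream analysis.

Cells are aligned to the model's gene panel (absent genes encoded as
the dummy -1), log2-transformed when given as counts, and labeled by
the maximum posterior.  Per-specimen label percentages feed a PCA whose
component retention is calibrated against column-scrambled data (a
parallel-analysis style negative control) and a hierarchical clustering
of the composition rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as _linkage

from .dataset import ExpressionDataset
from .errors import ValidationError
from .model import ClassifierModel


@dataclass
class CellAnnotation:
    """Predicted label and class posteriors for one cell."""

    cell_id: str
    assigned_label: str
    probabilities: dict[str, float]
    specimen_id: str | None = None

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("cell probabilities must sum to 1")
        best = max(self.probabilities.items(), key=lambda kv: kv[1])[1]
        if self.probabilities[self.assigned_label] != best:
            raise ValidationError("assigned_label is not the argmax class")


@dataclass
class CompositionTable:
    """Specimen x cell-type percentages (rows sum to 100)."""

    table: pd.DataFrame  # index: specimen, columns: cell types, values: %
    group_metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        sums = self.table.sum(axis=1)
        if len(self.table) and not np.allclose(sums, 100.0, atol=1e-9):
            raise ValidationError("composition rows must sum to 100")


def annotate_cells(
    model: ClassifierModel,
    sc_ds: ExpressionDataset,
    preprocess_like_training: bool = False,
    min_overlap: float = 0.5,
    unassigned_floor: float = 0.0,
) -> list[CellAnnotation]:
    """Classify every cell in ``sc_ds`` with the trained model.

    The cell matrix is restricted/aligned to the model genes; genes the
    cells lack are encoded as -1; a counts-scale input is log2(v+1)
    transformed first.  ``preprocess_like_training`` additionally runs
    between-lane full-quantile normalization across cells before the
    transform (off by default: cells are not bulk lanes).  Cells whose
    top posterior falls below ``unassigned_floor`` are labeled
    ``"unassigned"`` (default 0: always assign).
    """
    overlap = set(model.gene_ids) & set(sc_ds.gene_ids)
    frac = len(overlap) / len(model.gene_ids)
    if frac < min_overlap:
        missing = sorted(set(model.gene_ids) - overlap)
        raise ValidationError(
            f"only {frac:.1%} of model genes present (floor {min_overlap:.0%}); "
            f"missing e.g. {missing[:5]}"
        )
    present = [g for g in sc_ds.gene_ids if g in overlap]
    ds = sc_ds.subset_genes(present)
    if preprocess_like_training:
        from .preprocess import between_lane_full_quantile

        ds = between_lane_full_quantile(ds)
    if ds.value_scale != "log2":
        from .preprocess import log2_transform

        ds = log2_transform(ds)
    proba = model.predict_proba(ds.encoded_matrix(), gene_ids=ds.gene_ids, fill_missing=True)
    specimen = None
    if ds.sample_meta is not None and "specimen_id" in ds.sample_meta.columns:
        specimen = ds.sample_meta["specimen_id"]
    out = []
    for i, cell in enumerate(ds.sample_ids):
        k = int(np.argmax(proba[i]))
        label = model.class_labels[k]
        if proba[i, k] < unassigned_floor:
            label = "unassigned"
        out.append(
            CellAnnotation(
                cell_id=cell,
                assigned_label=label,
                probabilities={c: float(p) for c, p in zip(model.class_labels, proba[i])},
                specimen_id=None if specimen is None else str(specimen[cell]),
            )
        )
    return out


def compose_by_specimen(
    annotations: list[CellAnnotation],
    specimen_map: dict[str, str] | None = None,
    class_labels: list[str] | None = None,
    group_metadata: pd.DataFrame | None = None,
) -> CompositionTable:
    """Percentage of each annotated type per specimen.

    ``specimen_map`` (cell id -> specimen) overrides the annotations'
    own specimen ids.  Labels never observed in a specimen appear with
    0; percentages are relative to that specimen's annotated cells.
    """
    if not annotations:
        raise ValidationError("no annotations given")
    rows: dict[str, dict[str, int]] = {}
    labels = set(class_labels or [])
    for a in annotations:
        spec = specimen_map.get(a.cell_id) if specimen_map else a.specimen_id
        if spec is None:
            raise ValidationError(f"cell {a.cell_id!r} has no specimen assignment")
        rows.setdefault(spec, {})
        rows[spec][a.assigned_label] = rows[spec].get(a.assigned_label, 0) + 1
        labels.add(a.assigned_label)
    cols = class_labels or sorted(labels)
    for extra in sorted(labels - set(cols)):
        cols.append(extra)
    table = pd.DataFrame(0.0, index=sorted(rows), columns=cols)
    for spec, counts in rows.items():
        total = sum(counts.values())
        for label, c in counts.items():
            table.loc[spec, label] = 100.0 * c / total
    return CompositionTable(table=table, group_metadata=group_metadata)


@dataclass
class PCAControlResult:
    """PCA with scrambled-data component retention."""

    n_retained: int
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # loadings, rows = components
    scores: np.ndarray  # specimen coordinates
    threshold: float  # max leading scrambled-component EV fraction


def pca_with_scrambled_control(
    comp: CompositionTable, n_scrambles: int = 100, seed: int = 0
) -> PCAControlResult:
    """Centered PCA via SVD, keeping components whose explained-variance
    fraction exceeds the strongest leading component observed across
    ``n_scrambles`` independent column permutations of the data."""
    X = comp.table.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValidationError("PCA control needs at least 3 specimens")
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    evr = var / total if total > 0 else np.zeros_like(var)
    rng = np.random.default_rng(seed)
    threshold = 0.0
    for _ in range(n_scrambles):
        Z = np.empty_like(Xc)
        for j in range(p):
            Z[:, j] = Xc[rng.permutation(n), j]
        Z -= Z.mean(axis=0)
        sz = np.linalg.svd(Z, compute_uv=False)
        vz = sz**2
        if vz.sum() > 0:
            threshold = max(threshold, float(vz[0] / vz.sum()))
    n_retained = int(np.sum(evr > threshold))
    scores = Xc @ vt.T
    return PCAControlResult(
        n_retained=n_retained,
        explained_variance_ratio=evr,
        components=vt,
        scores=scores,
        threshold=threshold,
    )


def cluster_specimens(
    comp: CompositionTable, k: int, method: str = "ward"
) -> pd.Series:
    """Agglomerative clustering of specimens on euclidean distances of
    their percentage rows; labels 1..k in specimen order, deterministic."""
    X = comp.table.to_numpy(dtype=float)
    if k < 1 or k > len(X):
        raise ValidationError(f"k must be in [1, {len(X)}]")
    if method not in ("ward", "average", "complete", "single"):
        raise ValidationError(f"unsupported linkage {method!r}")
    Z = _linkage(X, method=method, metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=comp.table.index, name="cluster")
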