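"""Core in-memory containers for expression data.

The central type is :class:`ExpressionDataset`, a genes x samples matrix
with an explicit missing-value mask, optional per-gene annotation
(GC fraction, transcript length) and optional per-sample metadata
(cell-type label, study of origin).  The mask is carried through every
pipeline stage: a missing value is never silently coerced to zero, and
only the dummy encoding used for model fitting turns masked positions
into the sentinel ``-1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Allowed values of ``ExpressionDataset.value_scale``.
VALUE_SCALES = ("raw_counts", "normalized_counts", "log2")

#: Sentinel written at masked positions by the dummy encoding.
DUMMY_VALUE = -1.0


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with mask and metadata.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifiers for rows and columns of ``values``.
    values
        Non-negative matrix of shape ``(n_genes, n_samples)``.  After the
        dummy encoding used for fitting, masked positions may hold exactly
        ``-1``; everywhere else values stay non-negative.
    missing_mask
        Boolean matrix, ``True`` where the source reported no value.
    gene_annotation
        Optional DataFrame indexed by gene id with columns
        ``gc_fraction`` (in [0, 1]) and ``length_bp`` (positive int).
    sample_meta
        Optional DataFrame indexed by sample id with columns
        ``cell_type`` (may be NA for unlabeled cells) and ``study_id``.
    value_scale
        One of ``raw_counts``, ``normalized_counts``, ``log2``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]
    gene_annotation: pd.DataFrame | None = None
    sample_meta: pd.DataFrame | None = None
    value_scale: str = "raw_counts"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n_g, n_s = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (n_g, n_s):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{n_g} genes x {n_s} samples"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValidationError("missing_mask shape differs from values")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.value_scale not in VALUE_SCALES:
            raise ValidationError(f"unknown value_scale {self.value_scale!r}")
        obs = self.values[~self.missing_mask]
        if obs.size and not np.all(np.isfinite(obs)):
            raise ValidationError("non-finite value at a non-missing position")
        if obs.size and obs.min() < 0:
            i, j = np.argwhere((self.values < 0) & ~self.missing_mask)[0]
            raise ValidationError(
                f"negative value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        # masked positions may hold anything on disk-read (0) or the dummy
        # sentinel after encoding; nothing else to check there.
        if self.gene_annotation is not None:
            ann = self.gene_annotation
            if "gc_fraction" in ann.columns:
                gc = ann["gc_fraction"].dropna()
                if len(gc) and ((gc < 0) | (gc > 1)).any():
                    bad = ann.index[(ann["gc_fraction"] < 0) | (ann["gc_fraction"] > 1)]
                    raise ValidationError(
                        f"gc_fraction outside [0, 1] for gene(s): {list(bad)[:5]}"
                    )
            if "length_bp" in ann.columns:
                ln = ann["length_bp"].dropna()
                if len(ln) and (ln <= 0).any():
                    raise ValidationError("non-positive length_bp in annotation")

    # -- convenience ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def labels(self) -> pd.Series:
        """Per-sample cell-type labels (raises if no metadata)."""
        if self.sample_meta is None or "cell_type" not in self.sample_meta:
            raise ValidationError("dataset has no cell_type labels")
        return self.sample_meta["cell_type"].reindex(self.sample_ids)

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            missing_mask=self.missing_mask.copy(),
            gene_annotation=None if self.gene_annotation is None else self.gene_annotation.copy(),
            sample_meta=None if self.sample_meta is None else self.sample_meta.copy(),
            value_scale=self.value_scale,
        )

    def with_values(self, values: np.ndarray, value_scale: str | None = None) -> "ExpressionDataset":
        """New dataset sharing ids/metadata with replaced values."""
        out = self.copy()
        out.values = np.asarray(values, dtype=float)
        if value_scale is not None:
            out.value_scale = value_scale
        out.validate()
        return out

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        genes = list(genes)
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValidationError(f"genes not in dataset: {missing[:5]}")
        rows = [index[g] for g in genes]
        ann = None
        if self.gene_annotation is not None:
            ann = self.gene_annotation.reindex(genes)
        return ExpressionDataset(
            gene_ids=genes,
            sample_ids=list(self.sample_ids),
            values=self.values[rows],
            missing_mask=self.missing_mask[rows],
            gene_annotation=ann,
            sample_meta=None if self.sample_meta is None else self.sample_meta.copy(),
            value_scale=self.value_scale,
        )

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionDataset":
        samples = list(samples)
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise ValidationError(f"samples not in dataset: {missing[:5]}")
        cols = [index[s] for s in samples]
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.reindex(samples)
        return ExpressionDataset(
            gene_ids=list(self.gene_ids),
            sample_ids=samples,
            values=self.values[:, cols],
            missing_mask=self.missing_mask[:, cols],
            gene_annotation=None if self.gene_annotation is None else self.gene_annotation.copy(),
            sample_meta=meta,
            value_scale=self.value_scale,
        )

    def encoded_matrix(self, dummy: float = DUMMY_VALUE) -> np.ndarray:
        """Samples x genes matrix with masked entries set to ``dummy``.

        This is the orientation model fitting expects.
        """
        x = self.values.T.copy()
        x[self.missing_mask.T] = dummy
        return x

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.missing_mask, other.missing_mask)
            and self.value_scale == other.value_scale
        )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(str(g) for g in self.genes))
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/test sample-id partition.

    Validated against a dataset with :meth:`check`; every cell-type label
    occurring in the dataset must be represented in the training half.
    """

    train_sample_ids: tuple[str, ...]
    test_sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        train, test = set(self.train_sample_ids), set(self.test_sample_ids)
        if len(train) != len(self.train_sample_ids) or len(test) != len(self.test_sample_ids):
            raise ValidationError("split contains duplicated sample ids")
        if train & test:
            raise ValidationError(f"train/test overlap: {sorted(train & test)[:5]}")

    def check(self, ds: ExpressionDataset) -> None:
        known = set(ds.sample_ids)
        extra = (set(self.train_sample_ids) | set(self.test_sample_ids)) - known
        if extra:
            raise ValidationError(f"split references unknown samples: {sorted(extra)[:5]}")
        labels = ds.labels
        train_types = set(labels.reindex(list(self.train_sample_ids)).dropna())
        all_types = set(labels.dropna())
        absent = all_types - train_types
        if absent:
            raise ValidationError(
                f"cell type(s) missing from training split: {sorted(absent)}"
            )
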