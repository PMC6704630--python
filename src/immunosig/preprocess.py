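"""Filtering and normalization chain for merged multi-study RNA-seq counts.

The pipeline order is fixed: low-expression filter, within-lane
GC-content normalization, between-lane full-quantile normalization, a
second filter pass with the same rule, and finally the log2(v+1)
transform.  Each step leaves the missing mask untouched; missing entries
never count toward filter thresholds and are excluded from rank and
smoother computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .dataset import ExpressionDataset
from .errors import ValidationError


@dataclass(frozen=True)
class FilterParams:
    """Low-expression filter: keep genes with >= ``min_count`` in at
    least ``min_samples`` non-missing entries.

    Defaults follow the bulk immune-cell setting (5 counts in 5
    samples); T-helper-sized cohorts use ``min_samples=4``.
    """

    min_count: float = 5.0
    min_samples: int = 5

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValidationError("min_count must be non-negative")
        if self.min_samples < 1:
            raise ValidationError("min_samples must be a positive integer")


@dataclass
class NormalizationReport:
    """Gene counts and diagnostics accumulated across the chain."""

    stages: list[str] = field(default_factory=list)
    genes_before: dict[str, int] = field(default_factory=dict)
    genes_after: dict[str, int] = field(default_factory=dict)
    sample_diagnostics: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, before: int, after: int, **diag) -> None:
        self.stages.append(stage)
        self.genes_before[stage] = int(before)
        self.genes_after[stage] = int(after)
        if diag:
            self.sample_diagnostics[stage] = diag

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "genes_before": self.genes_before,
            "genes_after": self.genes_after,
            "sample_diagnostics": self.sample_diagnostics,
        }


def filter_low_expression(
    ds: ExpressionDataset, params: FilterParams = FilterParams()
) -> ExpressionDataset:
    """Drop genes without ``min_count`` in at least ``min_samples``
    non-missing entries; gene order otherwise preserved."""
    if ds.value_scale == "log2":
        raise ValidationError("filter operates on (normalized) counts, not log2")
    if params.min_samples > ds.n_samples:
        raise ValidationError(
            f"min_samples={params.min_samples} exceeds the {ds.n_samples} samples"
        )
    ok = (ds.values >= params.min_count) & ~ds.missing_mask
    keep = ok.sum(axis=1) >= params.min_samples
    if not keep.any():
        raise ValidationError(
            "low-expression filter removed every gene; lower min_count or "
            "min_samples"
        )
    return ds.subset_genes([g for g, k in zip(ds.gene_ids, keep) if k])


def _gc_fit_loess(gc: np.ndarray, logv: np.ndarray, span: float) -> np.ndarray:
    return lowess(logv, gc, frac=span, return_sorted=False)


def _gc_fit_median_bin(gc: np.ndarray, logv: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Piecewise-constant fallback: per-GC-quantile-bin medians."""
    edges = np.quantile(gc, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, len(edges) - 2)
    fit = np.empty_like(logv)
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.any():
            fit[sel] = np.median(logv[sel])
    return fit


def within_lane_gc_normalize(
    ds: ExpressionDataset,
    annotation: pd.DataFrame | None = None,
    span: float = 0.3,
    method: str = "loess",
) -> ExpressionDataset:
    """Remove each sample's smooth GC-content trend from log counts.

    Per sample, a local-linear smoother (``method="loess"``, span
    configurable) of log(count + 0.5) on GC fraction is fitted over
    non-missing genes; the fitted trend is subtracted and the result is
    re-anchored so the sample's median log count is preserved, then
    mapped back to the count scale (clipped at zero).  ``"median_bin"``
    replaces the smoother with GC-bin medians.
    """
    if ds.value_scale == "log2":
        raise ValidationError("GC normalization operates on counts")
    if method not in ("loess", "median_bin"):
        raise ValidationError(f"unknown GC method {method!r}")
    ann = annotation if annotation is not None else ds.gene_annotation
    if ann is None or "gc_fraction" not in getattr(ann, "columns", []):
        raise ValidationError("GC normalization requires a gc_fraction annotation")
    gc_all = ann["gc_fraction"].reindex(ds.gene_ids)
    absent = [g for g, v in zip(ds.gene_ids, gc_all.values) if not np.isfinite(v)]
    if absent:
        raise ValidationError(
            f"{len(absent)} retained gene(s) lack GC annotation, e.g. {absent[:5]}"
        )
    gc_all = gc_all.to_numpy(dtype=float)
    out = ds.values.copy()
    for j in range(ds.n_samples):
        obs = ~ds.missing_mask[:, j]
        n_obs = int(obs.sum())
        if n_obs < 20:
            raise ValidationError(
                f"sample {ds.sample_ids[j]!r} has only {n_obs} non-missing "
                "genes; the GC smoother needs at least 20"
            )
        logv = np.log(ds.values[obs, j] + 0.5)
        gc = gc_all[obs]
        if method == "loess":
            fit = _gc_fit_loess(gc, logv, span)
        else:
            fit = _gc_fit_median_bin(gc, logv)
        resid = logv - fit
        shift = np.median(logv) - np.median(resid)
        out[obs, j] = np.maximum(np.exp(resid + shift) - 0.5, 0.0)
    res = ds.with_values(out, value_scale="normalized_counts")
    return res


def between_lane_full_quantile(ds: ExpressionDataset) -> ExpressionDataset:
    """Force every sample onto the across-sample mean distribution.

    The reference is the mean of per-sample quantile functions on a
    common grid; each sample's non-missing values are replaced by the
    reference at their (average, for ties) rank.  With no missing values
    this is exactly the mean of order statistics.
    """
    if ds.value_scale == "log2":
        raise ValidationError("quantile normalization operates on counts")
    if ds.n_samples < 2:
        warnings.warn("single sample: full-quantile normalization is the identity")
        return ds.with_values(ds.values.copy(), value_scale="normalized_counts")
    grid = np.linspace(0.0, 1.0, ds.n_genes) if ds.n_genes > 1 else np.array([0.5])
    qfuncs = np.empty((ds.n_samples, grid.size))
    for j in range(ds.n_samples):
        v = ds.values[~ds.missing_mask[:, j], j]
        if v.size == 0:
            raise ValidationError(
                f"sample {ds.sample_ids[j]!r} has no observed values"
            )
        qfuncs[j] = np.quantile(v, grid) if v.size > 1 else float(v[0])
    reference = qfuncs.mean(axis=0)
    out = ds.values.copy()
    for j in range(ds.n_samples):
        obs = ~ds.missing_mask[:, j]
        v = ds.values[obs, j]
        if v.size == 1:
            probs = np.array([0.5])
        else:
            probs = (rankdata(v, method="average") - 1.0) / (v.size - 1.0)
        out[obs, j] = np.interp(probs, grid, reference)
    return ds.with_values(out, value_scale="normalized_counts")


def log2_transform(ds: ExpressionDataset) -> ExpressionDataset:
    """log2(v + 1) on non-missing entries; missing entries untouched."""
    if ds.value_scale == "log2":
        raise ValidationError("dataset is already on the log2 scale")
    obs = ~ds.missing_mask
    if ds.values[obs].size and ds.values[obs].min() < 0:
        raise ValidationError("negative value encountered before log2")
    out = ds.values.copy()
    out[obs] = np.log2(out[obs] + 1.0)
    return ds.with_values(out, value_scale="log2")


def normalize_pipeline(
    ds: ExpressionDataset,
    params: FilterParams = FilterParams(),
    annotation: pd.DataFrame | None = None,
    span: float = 0.3,
    skip_gc: bool = False,
    gc_method: str = "loess",
) -> tuple[ExpressionDataset, NormalizationReport]:
    """Run the full fixed chain and return (log2 dataset, report).

    Normalization is intended to be fit separately per sample group
    (e.g. train vs test); callers pass one group at a time.
    """
    report = NormalizationReport()
    n0 = ds.n_genes
    ds1 = filter_low_expression(ds, params)
    report.record("filter_1", n0, ds1.n_genes)
    if skip_gc:
        ds2 = ds1
        report.record("gc_normalize_skipped", ds1.n_genes, ds1.n_genes)
    else:
        ds2 = within_lane_gc_normalize(ds1, annotation=annotation, span=span, method=gc_method)
        report.record("gc_normalize", ds1.n_genes, ds2.n_genes)
    ds3 = between_lane_full_quantile(ds2)
    med = np.median(ds3.values, axis=0)
    report.record(
        "quantile_normalize", ds2.n_genes, ds3.n_genes,
        per_sample_median={s: float(m) for s, m in zip(ds3.sample_ids, med)},
    )
    ds4 = filter_low_expression(ds3, params)
    report.record("filter_2", ds3.n_genes, ds4.n_genes)
    ds5 = log2_transform(ds4)
    report.record("log2", ds4.n_genes, ds5.n_genes)
    return ds5, report
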