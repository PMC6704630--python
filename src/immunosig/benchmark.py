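"""Gene-set benchmarking by Fisher exact scoring on binarized expression.

A sample is reduced to an expressed/not-expressed bit per gene (strict
``value > threshold`` on the log2 scale, default 2.48; missing entries
count as not expressed).  Each gene set is scored per sample by the
one-sided (enrichment) hypergeometric p-value of the 2x2 table
(in-set vs out-of-set) x (expressed vs not).  The negative class comes
from scrambled datasets resampling expression values with replacement
by gene across patients, which preserves per-gene marginals while
destroying cross-gene structure.  One ROC per bootstrap iteration is
interpolated to a common FPR grid; the mean curve with percentile
confidence bands summarizes performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .classifier import roc_from_scores
from .dataset import ExpressionDataset, GeneSet
from .errors import ValidationError

_FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class BenchmarkConfig:
    binarize_threshold: float = 2.48  # log2 scale
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.binarize_threshold):
            raise ValidationError("binarize_threshold must be finite")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError("ci_level must be in (0, 1)")


@dataclass
class BenchmarkResult:
    """Mean ROC with confidence band for one gene set."""

    name: str
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    lower_tpr: np.ndarray
    upper_tpr: np.ndarray
    mean_auc: float
    auc_values: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    flag: str | None = None

    def __post_init__(self) -> None:
        for arr in (self.mean_tpr, self.lower_tpr, self.upper_tpr):
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValidationError("ROC curves must stay within [0, 1]")
        if np.any(self.lower_tpr > self.mean_tpr + 1e-12) or np.any(
            self.mean_tpr > self.upper_tpr + 1e-12
        ):
            raise ValidationError("CI band must contain the mean curve")


def binarize(ds: ExpressionDataset, threshold: float = 2.48) -> np.ndarray:
    """Expressed = value strictly above threshold; missing = not expressed."""
    if ds.value_scale != "log2":
        raise ValidationError("binarization expects log2-scale expression")
    return (ds.values > threshold) & ~ds.missing_mask


def fisher_score(
    sample_bits: np.ndarray, gene_set: GeneSet, universe: list[str]
) -> float:
    """One-sided enrichment p-value for one sample's expressed bits.

    2x2 table: membership in ``gene_set`` against expressed/not over
    the ``universe``; p = P(overlap >= observed) under the
    hypergeometric null.
    """
    universe_set = set(universe)
    if not gene_set.genes <= universe_set:
        raise ValidationError(
            f"gene set {gene_set.name!r} is not a subset of the universe"
        )
    if len(universe_set - gene_set.genes) == 0:
        raise ValidationError("gene set equals the universe; no complement to test")
    bits = np.asarray(sample_bits, dtype=bool)
    if bits.shape[0] != len(universe):
        raise ValidationError("bit vector length differs from universe size")
    in_set = np.fromiter((g in gene_set.genes for g in universe), bool, len(universe))
    M = len(universe)
    K = int(in_set.sum())
    n_expr = int(bits.sum())
    k = int((bits & in_set).sum())
    return float(hypergeom.sf(k - 1, M, K, n_expr))


def _set_scores(bits: np.ndarray, in_set: np.ndarray) -> np.ndarray:
    """-log10 enrichment p per sample, vectorized (bits: genes x samples)."""
    M = bits.shape[0]
    K = int(in_set.sum())
    n_expr = bits.sum(axis=0)
    k = bits[in_set].sum(axis=0)
    p = hypergeom.sf(k - 1, M, K, n_expr)
    return -np.log10(np.maximum(p, 1e-300))


def scramble_dataset(ds: ExpressionDataset, seed: int = 0) -> ExpressionDataset:
    """Same-shape dataset resampling each gene's values (and their
    missingness) with replacement across samples; deterministic."""
    rng = np.random.default_rng(seed)
    p, n = ds.values.shape
    donor = rng.integers(0, n, size=(p, n))
    rows = np.arange(p)[:, None]
    out = ds.copy()
    out.values = ds.values[rows, donor]
    out.missing_mask = ds.missing_mask[rows, donor]
    out.validate()
    return out


def benchmark_gene_sets(
    ds_labeled: ExpressionDataset,
    gene_sets: list[GeneSet],
    config: BenchmarkConfig = BenchmarkConfig(),
) -> list[BenchmarkResult]:
    """Bootstrap ROC benchmarking of gene sets against scrambled data.

    Per iteration a fresh scrambled dataset provides the negatives; the
    positives for a set are the real samples of the matching cell type
    when the set name matches a label, otherwise all real samples.  Per
    iteration one ROC is computed per set, interpolated to a fixed FPR
    grid, and summarized by the mean curve, percentile confidence band
    and mean AUC across ``n_boot`` iterations.
    """
    if not gene_sets:
        raise ValidationError("no gene sets given")
    if ds_labeled.value_scale != "log2":
        raise ValidationError("benchmark expects a log2-scale dataset")
    if ds_labeled.n_samples < 30:
        warnings.warn(
            f"only {ds_labeled.n_samples} samples; the bootstrap null is "
            "calibrated for N >= 30"
        )
    universe = list(ds_labeled.gene_ids)
    universe_set = set(universe)
    labels = None
    if ds_labeled.sample_meta is not None and "cell_type" in ds_labeled.sample_meta:
        labels = ds_labeled.labels.to_numpy(dtype=object)
    bits_real = binarize(ds_labeled, config.binarize_threshold)

    prepared = []
    for gs in gene_sets:
        inter = gs.genes & universe_set
        if not inter:
            prepared.append((gs, None, None, "no overlap with universe"))
            continue
        flag = None
        if inter != gs.genes:
            flag = f"{len(gs.genes) - len(inter)} gene(s) outside the universe ignored"
        in_set = np.fromiter((g in inter for g in universe), bool, len(universe))
        pos_mask = None
        if labels is not None and gs.name in set(labels):
            pos_mask = labels == gs.name
        prepared.append((gs, in_set, pos_mask, flag))

    alpha = (1.0 - config.ci_level) / 2.0
    tprs = {gs.name: [] for gs, *_ in prepared}
    aucs = {gs.name: [] for gs, *_ in prepared}
    real_scores = {}
    for gs, in_set, pos_mask, _ in prepared:
        if in_set is None:
            continue
        s = _set_scores(bits_real, in_set)
        real_scores[gs.name] = s[pos_mask] if pos_mask is not None else s
    for it in range(config.n_boot):
        scrambled = scramble_dataset(ds_labeled, seed=config.seed + it)
        bits_scr = binarize(scrambled, config.binarize_threshold)
        for gs, in_set, pos_mask, _ in prepared:
            if in_set is None:
                continue
            s_real = real_scores[gs.name]
            s_scr = _set_scores(bits_scr, in_set)
            fpr, tpr, area = roc_from_scores(s_real, s_scr)
            tprs[gs.name].append(np.interp(_FPR_GRID, fpr, tpr))
            aucs[gs.name].append(area)

    results = []
    for gs, in_set, _, flag in prepared:
        if in_set is None:
            results.append(
                BenchmarkResult(
                    name=gs.name, fpr_grid=_FPR_GRID,
                    mean_tpr=np.zeros_like(_FPR_GRID),
                    lower_tpr=np.zeros_like(_FPR_GRID),
                    upper_tpr=np.zeros_like(_FPR_GRID),
                    mean_auc=float("nan"), auc_values=np.array([]), flag=flag,
                )
            )
            continue
        T = np.vstack(tprs[gs.name])
        mean_tpr = T.mean(axis=0)
        # percentile band, widened minimally so it always contains the
        # mean curve (discrete/skewed TPR distributions can otherwise
        # place the mean outside an empirical quantile)
        lower = np.minimum(np.quantile(T, alpha, axis=0), mean_tpr)
        upper = np.maximum(np.quantile(T, 1.0 - alpha, axis=0), mean_tpr)
        results.append(
            BenchmarkResult(
                name=gs.name,
                fpr_grid=_FPR_GRID,
                mean_tpr=mean_tpr,
                lower_tpr=lower,
                upper_tpr=upper,
                mean_auc=float(np.mean(aucs[gs.name])),
                auc_values=np.asarray(aucs[gs.name]),
                flag=flag,
            )
        )
    return results
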