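"""Synthetic multi-study, multi-cell-type count data with planted markers.

The generator emulates the statistical structure the pipeline assumes
when merging heterogeneous public bulk RNA-seq studies: negative-
binomial counts around gene-specific baselines, per-study GC-content
and library-scale biases, missing values, and two styles of planted
marker gene per cell type:

* *over-expressed* markers, multiplied by ``marker_fold_change`` in
  their own type (exercising positive classifier coefficients), and
* *absent-in-type* markers, attenuated to near zero in their own type
  while expressed at baseline everywhere else (exercising negative
  coefficients).

Single-cell profiles are drawn from the same generative model with an
extra dropout process zeroing observed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, SplitSpec
from .errors import ValidationError


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    Defaults give five well-separated cell types profiled across three
    simulated studies: 40 samples per type, 2000 genes with 20
    over-expressed (8-fold) and 10 absent-in-type markers per type,
    negative-binomial dispersion 10, and 5% missing values.
    """

    n_cell_types: int = 5
    samples_per_type: int = 40
    n_genes: int = 2000
    markers_per_type: int = 20
    absent_markers_per_type: int = 10
    marker_fold_change: float = 8.0
    marker_off_attenuation: float = 1.0  # <1 also silences markers outside their type
    absent_attenuation: float = 0.02
    nb_dispersion: float = 10.0
    baseline_mean_log_range: tuple[float, float] = (2.0, 9.0)  # log2 counts
    gc_bias_strength: float = 1.0
    study_scale_spread: float = 1.0  # log2 spread of per-study library scale
    n_studies: int = 3
    missing_rate: float = 0.05
    single_cell_dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        per_type = self.markers_per_type + self.absent_markers_per_type
        if per_type * self.n_cell_types > self.n_genes:
            raise ValidationError(
                f"{per_type} markers x {self.n_cell_types} types exceed "
                f"{self.n_genes} genes"
            )
        if self.marker_fold_change < 1.0:
            raise ValidationError("marker_fold_change must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.single_cell_dropout_rate < 1.0:
            raise ValidationError("single_cell_dropout_rate must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if min(self.n_cell_types, self.samples_per_type, self.n_genes, self.n_studies) < 1:
            raise ValidationError("counts must be positive")


@dataclass
class GroundTruth:
    """Planted structure emitted alongside each simulated dataset."""

    cell_types: list[str]
    up_markers: dict[str, list[str]]
    absent_markers: dict[str, list[str]]
    mean_matrix: np.ndarray = field(repr=False)  # genes x types, pre-bias

    def all_markers(self) -> list[str]:
        out: list[str] = []
        for t in self.cell_types:
            out.extend(self.up_markers[t])
            out.extend(self.absent_markers[t])
        return out


def _base_means(cfg: SimulationConfig, rng: np.random.Generator):
    """Gene baselines, marker assignment and per-type mean matrix."""
    p, K = cfg.n_genes, cfg.n_cell_types
    types = [f"type{t + 1}" for t in range(K)]
    gene_ids = [f"G{g + 1:05d}" for g in range(p)]
    lo, hi = cfg.baseline_mean_log_range
    baseline = 2.0 ** rng.uniform(lo, hi, size=p)
    M = np.tile(baseline[:, None], (1, K))
    up: dict[str, list[str]] = {}
    absent: dict[str, list[str]] = {}
    cursor = 0
    for t, name in enumerate(types):
        up_idx = np.arange(cursor, cursor + cfg.markers_per_type)
        cursor += cfg.markers_per_type
        ab_idx = np.arange(cursor, cursor + cfg.absent_markers_per_type)
        cursor += cfg.absent_markers_per_type
        if cfg.marker_off_attenuation < 1.0:
            others = [k for k in range(K) if k != t]
            M[np.ix_(up_idx, others)] *= cfg.marker_off_attenuation
        M[up_idx, t] *= cfg.marker_fold_change
        M[ab_idx, t] *= cfg.absent_attenuation
        up[name] = [gene_ids[i] for i in up_idx]
        absent[name] = [gene_ids[i] for i in ab_idx]
    return gene_ids, types, baseline, M, up, absent


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-9)
    return rng.negative_binomial(theta, theta / (theta + mean)).astype(float)


def simulate_bulk(cfg: SimulationConfig = SimulationConfig()) -> tuple[ExpressionDataset, GroundTruth]:
    """Labeled bulk count matrix with annotations and planted markers.

    Deterministic given ``cfg.seed``.  Samples are assigned round-robin
    to ``n_studies`` studies, each with its own multiplicative GC bias
    ``exp(b_s (gc - 0.5))`` and library-scale factor.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids, types, _, M, up, absent = _base_means(cfg, rng)
    p, K = cfg.n_genes, cfg.n_cell_types
    gc = rng.uniform(0.25, 0.75, size=p)
    length = np.round(2.0 ** rng.uniform(9.0, 13.3, size=p)).astype(int)

    n = K * cfg.samples_per_type
    sample_ids, labels, studies = [], [], []
    values = np.zeros((p, n))
    if cfg.n_studies > 1:
        b = cfg.gc_bias_strength * np.linspace(-1.0, 1.0, cfg.n_studies)
        scale = 2.0 ** (cfg.study_scale_spread * np.linspace(-0.5, 0.5, cfg.n_studies))
    else:
        b = np.zeros(1)
        scale = np.ones(1)
    col = 0
    for t, name in enumerate(types):
        for r in range(cfg.samples_per_type):
            s = col % cfg.n_studies
            mean = M[:, t] * np.exp(b[s] * (gc - 0.5)) * scale[s]
            values[:, col] = _nb_draw(rng, mean, cfg.nb_dispersion)
            sample_ids.append(f"{name}_rep{r + 1:03d}")
            labels.append(name)
            studies.append(f"study{s + 1}")
            col += 1
    mask = rng.random((p, n)) < cfg.missing_rate
    annotation = pd.DataFrame(
        {"gc_fraction": gc, "length_bp": length}, index=pd.Index(gene_ids, name="gene_id")
    )
    meta = pd.DataFrame(
        {"cell_type": labels, "study_id": studies},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    ds = ExpressionDataset(
        gene_ids=gene_ids, sample_ids=sample_ids, values=values,
        missing_mask=mask, gene_annotation=annotation, sample_meta=meta,
    )
    truth = GroundTruth(cell_types=types, up_markers=up, absent_markers=absent, mean_matrix=M)
    return ds, truth


def simulate_single_cells(
    cfg: SimulationConfig,
    cells_per_specimen: int,
    n_specimens: int,
    composition,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Single-cell profiles drawn from the bulk generative model.

    ``composition`` maps cell type to proportion (one dict for all
    specimens, or a list of dicts per specimen).  Each expressed count
    is zeroed with probability ``single_cell_dropout_rate``.  Cells
    carry their true generating type and specimen id in ``sample_meta``.
    """
    rng = np.random.default_rng(cfg.seed + 7_654_321)
    gene_ids, types, _, M, up, absent = _base_means(
        cfg, np.random.default_rng(cfg.seed)
    )
    if isinstance(composition, dict):
        composition = [composition] * n_specimens
    if len(composition) != n_specimens:
        raise ValidationError("need one composition per specimen")
    p = cfg.n_genes
    n = cells_per_specimen * n_specimens
    values = np.zeros((p, n))
    cell_ids, cell_types, specimens = [], [], []
    col = 0
    for sp in range(n_specimens):
        comp = composition[sp]
        names = list(comp)
        probs = np.array([comp[t] for t in names], dtype=float)
        if probs.sum() <= 0 or (probs < 0).any():
            raise ValidationError("composition proportions must be non-negative")
        probs = probs / probs.sum()
        unknown = [t for t in names if t not in types]
        if unknown:
            raise ValidationError(f"composition references unknown types {unknown}")
        for c in range(cells_per_specimen):
            t = rng.choice(len(names), p=probs)
            tname = names[t]
            mean = M[:, types.index(tname)]
            counts = _nb_draw(rng, mean, cfg.nb_dispersion)
            if cfg.single_cell_dropout_rate > 0:
                counts[rng.random(p) < cfg.single_cell_dropout_rate] = 0.0
            values[:, col] = counts
            cell_ids.append(f"spec{sp + 1:02d}_cell{c + 1:04d}")
            cell_types.append(tname)
            specimens.append(f"spec{sp + 1:02d}")
            col += 1
    meta = pd.DataFrame(
        {"cell_type": cell_types, "specimen_id": specimens},
        index=pd.Index(cell_ids, name="sample_id"),
    )
    ds = ExpressionDataset(
        gene_ids=gene_ids, sample_ids=cell_ids, values=values, sample_meta=meta,
    )
    truth = GroundTruth(cell_types=types, up_markers=up, absent_markers=absent, mean_matrix=M)
    return ds, truth


def stratified_split(
    ds: ExpressionDataset, test_fraction: float = 0.4, seed: int = 0
) -> SplitSpec:
    """Per-cell-type random train/test partition of the samples."""
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must be in (0, 1)")
    labels = ds.labels
    rng = np.random.default_rng(seed)
    train, test = [], []
    for t in sorted(labels.dropna().unique()):
        ids = [s for s in ds.sample_ids if labels[s] == t]
        perm = rng.permutation(len(ids))
        n_test = max(1, int(round(test_fraction * len(ids))))
        n_test = min(n_test, len(ids) - 2)  # keep >= 2 training samples
        test.extend(ids[i] for i in perm[:n_test])
        train.extend(ids[i] for i in perm[n_test:])
    split = SplitSpec(train_sample_ids=tuple(train), test_sample_ids=tuple(test))
    split.check(ds)
    return split
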