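"""Shared fixtures.

``big_workflow`` runs the flagship synthetic study once per session
(five well-separated cell types, 40 samples each, 2000 genes, planted
markers, defaults for augmentation and the lambda grid) through
normalization, classifier training, signature building and single-cell
annotation; several end-to-end tests read from it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from immunosig.annotate import annotate_cells, compose_by_specimen
from immunosig.classifier import AugmentParams, train_classifier
from immunosig.dataset import ExpressionDataset
from immunosig.model import PenaltySpec
from immunosig.preprocess import FilterParams, normalize_pipeline
from immunosig.signatures import build_all_signatures
from immunosig.synthetic import (
    SimulationConfig,
    simulate_bulk,
    simulate_single_cells,
    stratified_split,
)

#: study conditions for the flagship run (generator defaults, fixed seed)
BIG_SEED = 11


def small_sim_config(**overrides) -> SimulationConfig:
    """A fast 3-type configuration for module-level tests."""
    base = dict(
        n_cell_types=3, samples_per_type=12, n_genes=300, markers_per_type=8,
        absent_markers_per_type=4, missing_rate=0.05, seed=1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def tiny_ds() -> ExpressionDataset:
    """3 genes x 4 samples with one missing entry and labels."""
    import pandas as pd

    values = np.array([[5.0, 0.0, 2.0, 7.0], [2.0, 3.0, 0.0, 1.0], [7.0, 1.0, 4.0, 9.0]])
    mask = np.zeros_like(values, dtype=bool)
    mask[1, 1] = True
    meta = pd.DataFrame(
        {"cell_type": ["A", "A", "B", "B"], "study_id": ["s1"] * 4},
        index=pd.Index(["x1", "x2", "x3", "x4"], name="sample_id"),
    )
    return ExpressionDataset(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["x1", "x2", "x3", "x4"],
        values=values,
        missing_mask=mask,
        sample_meta=meta,
    )


@pytest.fixture(scope="session")
def small_workflow():
    """Fast 3-type pipeline shared by signature/annotation tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = small_sim_config()
        ds, truth = simulate_bulk(cfg)
        split = stratified_split(ds, 0.4, seed=2)
        tr = ds.subset_samples(list(split.train_sample_ids))
        te = ds.subset_samples(list(split.test_sample_ids))
        ntr, _ = normalize_pipeline(tr, FilterParams(5, 4))
        nte, _ = normalize_pipeline(te, FilterParams(5, 4))
        shared = [g for g in ntr.gene_ids if g in set(nte.gene_ids)]
        ntr, nte = ntr.subset_genes(shared), nte.subset_genes(shared)
        aug = AugmentParams(duplication_factor=10, dropout_fraction=0.10, seed=3)
        spec = PenaltySpec(max_iter=3000)
        model, evals, chosen = train_classifier(
            ntr, nte, spec=spec, augment_params=aug, seed=3
        )
    return {
        "config": cfg, "truth": truth, "train": ntr, "test": nte,
        "augment": aug, "spec": spec, "model": model, "evals": evals,
        "chosen": chosen,
    }


@pytest.fixture(scope="session")
def big_workflow():
    """Flagship synthetic study: 5 types x 40 samples, 2000 genes,
    20 over-expressed (8-fold) + 10 absent markers per type, duplication
    100 with 10% dropout, the seven-value lambda grid."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = SimulationConfig(seed=BIG_SEED)
        ds, truth = simulate_bulk(cfg)
        split = stratified_split(ds, 0.4, seed=BIG_SEED + 1)
        tr = ds.subset_samples(list(split.train_sample_ids))
        te = ds.subset_samples(list(split.test_sample_ids))
        ntr, _ = normalize_pipeline(tr)
        nte, _ = normalize_pipeline(te)
        shared = [g for g in ntr.gene_ids if g in set(nte.gene_ids)]
        ntr, nte = ntr.subset_genes(shared), nte.subset_genes(shared)
        aug = AugmentParams(seed=BIG_SEED + 2)
        spec = PenaltySpec(max_iter=2000)
        model, evals, chosen = train_classifier(
            ntr, nte, spec=spec, augment_params=aug, seed=BIG_SEED + 2
        )
        sigs = build_all_signatures(
            ntr, nte, model, spec=spec, augment_params=aug, seed=BIG_SEED + 3
        )
        uniform = {t: 1.0 / len(truth.cell_types) for t in truth.cell_types}
        sc, _ = simulate_single_cells(cfg, cells_per_specimen=100, n_specimens=4,
                                      composition=uniform)
        annotations = annotate_cells(model, sc)
        composition = compose_by_specimen(annotations, class_labels=model.class_labels)
    return {
        "config": cfg, "truth": truth, "train": ntr, "test": nte,
        "augment": aug, "spec": spec, "model": model, "evals": evals,
        "chosen": chosen, "signatures": sigs, "single_cells": sc,
        "annotations": annotations, "composition": composition,
        "uniform_composition": uniform,
    }
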