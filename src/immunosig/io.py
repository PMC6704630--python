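"""Readers and writers for the plain-text formats the pipeline consumes.

Counts, annotations, labels and signatures travel as delimited text
(TSV/CSV chosen by extension); single-cell matrices as MatrixMarket
coordinate triplets with companion gene/barcode lists; fitted models as
self-describing JSON; gene sets as GMT or two-column TSV.

Missing values: ``NA``, ``NaN`` and the empty string are accepted on
read (flagged in the missing mask, never silently coerced); the single
canonical token ``NA`` is written.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .dataset import ExpressionDataset, GeneSet
from .errors import DataFormatError, ValidationError
from .model import ClassifierModel, PenaltySpec

MODEL_SCHEMA_VERSION = 1

_NA_TOKENS = {"NA", "NaN", "nan", ""}


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


# ----------------------------------------------------------------------
# counts
# ----------------------------------------------------------------------

def read_counts(
    path: str | Path, orientation: str = "genes_in_rows"
) -> ExpressionDataset:
    """Read a delimited count matrix into an :class:`ExpressionDataset`.

    The first row and first column hold identifiers.  NA tokens set the
    missing mask (the stored value is 0 but masked).  Identifier order
    follows the file.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _sep_for(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    rows = [r for r in rows if r]  # drop fully blank lines
    if not rows:
        raise DataFormatError(f"{path}: empty file")
    header = rows[0]
    col_ids = [c.strip() for c in header[1:]]
    if not col_ids:
        raise DataFormatError(f"{path}: header has no sample/gene columns")
    n_cols = len(col_ids)
    row_ids: list[str] = []
    values = np.zeros((len(rows) - 1, n_cols), dtype=float)
    mask = np.zeros_like(values, dtype=bool)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols + 1:
            raise DataFormatError(
                f"{path}: line {i} has {len(row)} fields, expected {n_cols + 1}"
            )
        row_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            tok = cell.strip()
            if tok in _NA_TOKENS:
                mask[i - 2, j] = True
            else:
                try:
                    v = float(tok)
                except ValueError as exc:
                    raise DataFormatError(
                        f"{path}: line {i}, column {header[j + 1]!r}: "
                        f"non-numeric value {tok!r}"
                    ) from exc
                if v < 0:
                    raise DataFormatError(
                        f"{path}: negative count {v} at row {row[0]!r}, "
                        f"column {header[j + 1]!r}"
                    )
                values[i - 2, j] = v
    if orientation == "genes_in_rows":
        gene_ids, sample_ids = row_ids, col_ids
    else:
        gene_ids, sample_ids = col_ids, row_ids
        values, mask = values.T.copy(), mask.T.copy()
    return ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        missing_mask=mask,
    )


def write_counts(ds: ExpressionDataset, path: str | Path) -> None:
    """Write genes-in-rows delimited text; masked entries become ``NA``."""
    sep = _sep_for(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep, lineterminator="\n")
        w.writerow(["gene_id", *ds.sample_ids])
        for i, g in enumerate(ds.gene_ids):
            row: list[str] = [g]
            for j in range(ds.n_samples):
                row.append("NA" if ds.missing_mask[i, j] else repr(float(ds.values[i, j])))
            w.writerow(row)


# ----------------------------------------------------------------------
# per-gene annotation and per-sample metadata
# ----------------------------------------------------------------------

def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation table (gene_id, gc_fraction, length_bp).

    Returns a DataFrame indexed by gene id.  GC fractions outside [0, 1]
    and non-positive lengths are validation errors.  Annotation may cover
    genes absent from a dataset and vice versa; coverage is checked by
    the normalization step that needs it.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"gene_id", "gc_fraction", "length_bp"}
    if not required.issubset(df.columns):
        raise DataFormatError(
            f"{path}: annotation needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene in annotation: {dup!r}")
    df = df.set_index("gene_id")
    bad_gc = df.index[(df["gc_fraction"] < 0) | (df["gc_fraction"] > 1)]
    if len(bad_gc):
        raise ValidationError(f"gc_fraction outside [0, 1] for: {list(bad_gc)[:5]}")
    if (df["length_bp"] <= 0).any():
        bad = df.index[df["length_bp"] <= 0]
        raise ValidationError(f"non-positive length_bp for: {list(bad)[:5]}")
    df["length_bp"] = df["length_bp"].astype(int)
    return df


def write_gene_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.reset_index().to_csv(path, sep=_sep_for(path), index=False)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (sample_id, cell_type[, study_id])."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if "sample_id" not in df.columns:
        raise DataFormatError(f"{path}: needs a sample_id column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample in metadata: {dup!r}")
    return df.set_index("sample_id")


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        path, sep=_sep_for(path), index=False
    )


# ----------------------------------------------------------------------
# sparse single-cell input
# ----------------------------------------------------------------------

def _read_id_list(path: str | Path, what: str) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    if not ids:
        raise DataFormatError(f"{path}: empty {what} list")
    return ids


def read_sparse_matrix(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> ExpressionDataset:
    """Read an MTX-style coordinate matrix plus gene/barcode lists.

    Sparse zeros are genuine zeros, not missing values.  Duplicate
    coordinates are summed (the common coordinate-file dialect).
    """
    genes = _read_id_list(genes_path, "gene")
    barcodes = _read_id_list(barcodes_path, "barcode")
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:
        raise DataFormatError(f"{matrix_path}: cannot parse MTX file: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise DataFormatError(
            f"{matrix_path}: declared shape {mat.shape} does not match "
            f"{len(genes)} genes x {len(barcodes)} barcodes"
        )
    dense = np.asarray(mat.todense(), dtype=float)  # coo sums duplicates
    if dense.size and dense.min() < 0:
        raise ValidationError(f"{matrix_path}: negative entry in sparse matrix")
    return ExpressionDataset(gene_ids=genes, sample_ids=barcodes, values=dense)


# ----------------------------------------------------------------------
# model JSON
# ----------------------------------------------------------------------

def write_model(model: ClassifierModel, path: str | Path) -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "kind": model.kind,
        "class_labels": model.class_labels,
        "gene_ids": model.gene_ids,
        "intercepts": model.intercepts.tolist(),
        "coefficients": model.coefficients.tolist(),
        "penalty": {
            "alpha": model.penalty.alpha,
            "lam": model.penalty.lam,
            "grouped": model.penalty.grouped,
            "standardize": model.penalty.standardize,
            "tol": model.penalty.tol,
            "max_iter": model.penalty.max_iter,
        },
        "training_provenance": model.training_provenance,
        "converged": model.converged,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_model(path: str | Path) -> ClassifierModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise DataFormatError(f"{path}: invalid JSON: {exc}") from exc
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise DataFormatError(
            f"{path}: unknown model schema version {version!r} "
            f"(this build reads version {MODEL_SCHEMA_VERSION})"
        )
    pen = doc["penalty"]
    p = len(doc["gene_ids"])
    k = 1 if doc["kind"] == "binary" else len(doc["class_labels"])
    coefficients = np.asarray(doc["coefficients"], dtype=float).reshape(p, k)
    return ClassifierModel(
        kind=doc["kind"],
        class_labels=list(doc["class_labels"]),
        gene_ids=list(doc["gene_ids"]),
        intercepts=np.asarray(doc["intercepts"], dtype=float),
        coefficients=coefficients,
        penalty=PenaltySpec(**pen),
        training_provenance=doc.get("training_provenance", {}),
        converged=doc.get("converged", True),
    )


# ----------------------------------------------------------------------
# gene sets
# ----------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (``.gmt``) or two-column TSV/CSV."""
    path = Path(path)
    sets: list[GeneSet] = []
    if path.suffix.lower() == ".gmt":
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    if not line.strip():
                        continue
                    raise DataFormatError(
                        f"{path}: line {i}: GMT rows need name, description "
                        "and at least one gene"
                    )
                sets.append(GeneSet(name=fields[0], genes=frozenset(fields[2:]) - {""}))
    else:
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
        cols = list(df.columns)
        if len(cols) < 2:
            raise DataFormatError(f"{path}: expected two columns (set, gene)")
        for name, grp in df.groupby(cols[0], sort=False):
            sets.append(GeneSet(name=str(name), genes=frozenset(grp[cols[1]])))
    if not sets:
        raise DataFormatError(f"{path}: no gene sets found")
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["set_name", "gene_id"])
        for gs in sets:
            for g in sorted(gs.genes):
                w.writerow([gs.name, g])
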