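"""Reading and writing cohorts in standard single-cell containers.

The primary container is H5AD (an AnnData holding cells × features, with the
sample membership and cell-type annotation as ``obs`` columns and the
per-sample class labels in ``uns``); a plain-text CSV/MTX directory is the
fallback.  Cell-type vocabularies are fixed at load time in sorted order and
class names are label-encoded by sorted name, so loading is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .data import Cohort, Sample

__all__ = ["IOConfig", "load_cohort", "save_cohort", "preprocess_counts"]

SAMPLE_TABLE_KEY = "sample_meta"


@dataclass
class IOConfig:
    input_path: str
    format: str = "h5ad"  # or "csv_mtx"
    sample_key: str = "sample_id"
    celltype_key: str = "cell_type"
    label_key: str = "label"
    layer: str | None = None
    positive_class: str | None = None

    def __post_init__(self) -> None:
        if self.format not in ("h5ad", "csv_mtx"):
            raise ValueError(f"unknown format {self.format!r}")


def save_cohort(cohort: Cohort, path, format: str = "h5ad") -> None:
    """Write a cohort to H5AD or a CSV/MTX directory (float32 matrix)."""
    X = np.vstack([s.X for s in cohort.samples]).astype(np.float32)
    obs = pd.DataFrame({
        "sample_id": np.concatenate([[s.sample_id] * s.n_cells for s in cohort.samples]),
        "cell_type": [cohort.cell_type_names[t]
                      for s in cohort.samples for t in s.cell_types],
    })
    obs.index = [f"cell_{i}" for i in range(len(obs))]
    sample_meta = pd.DataFrame({
        "sample_id": cohort.sample_ids,
        "label": [cohort.class_names[s.label] for s in cohort.samples],
    })
    if format == "h5ad":
        adata = ad.AnnData(X=X, obs=obs)
        adata.uns[SAMPLE_TABLE_KEY] = sample_meta
        adata.write_h5ad(Path(path))
    elif format == "csv_mtx":
        outdir = Path(path)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(outdir / "matrix.mtx"), sp.csr_matrix(X))
        obs.to_csv(outdir / "cells.csv", index=False)
        sample_meta.to_csv(outdir / "samples.csv", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_h5ad(config: IOConfig):
    adata = ad.read_h5ad(config.input_path)
    for key in (config.sample_key, config.celltype_key):
        if key not in adata.obs.columns:
            raise KeyError(f"{config.input_path}: obs column {key!r} not found")
    X = adata.layers[config.layer] if config.layer else adata.X
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    cells = pd.DataFrame({
        "sample_id": adata.obs[config.sample_key].astype(str).to_numpy(),
        "cell_type": adata.obs[config.celltype_key].astype(str).to_numpy(),
    })
    if SAMPLE_TABLE_KEY in adata.uns:
        meta = pd.DataFrame(adata.uns[SAMPLE_TABLE_KEY])
        if config.label_key not in meta.columns:
            raise KeyError(f"{config.input_path}: sample table lacks column {config.label_key!r}")
        labels = dict(zip(meta["sample_id"].astype(str), meta[config.label_key].astype(str)))
    elif config.label_key in adata.obs.columns:
        # per-cell label column: must be constant within each sample
        grp = cells.assign(label=adata.obs[config.label_key].astype(str).to_numpy())
        per_sample = grp.groupby("sample_id")["label"].nunique()
        bad = per_sample[per_sample > 1]
        if len(bad):
            raise ValueError(f"samples with inconsistent labels: {list(bad.index)}")
        labels = grp.groupby("sample_id")["label"].first().to_dict()
    else:
        raise KeyError(f"{config.input_path}: no label column {config.label_key!r} found")
    return X, cells, labels


def _read_csv_mtx(config: IOConfig):
    indir = Path(config.input_path)
    X = np.asarray(mmread(str(indir / "matrix.mtx")).todense(), dtype=float) \
        if (indir / "matrix.mtx").exists() else None
    if X is None:
        raise FileNotFoundError(f"{indir}: matrix.mtx not found")
    cells = pd.read_csv(indir / "cells.csv", dtype=str)
    for key in (config.sample_key, config.celltype_key):
        if key not in cells.columns:
            raise KeyError(f"{indir}/cells.csv: column {key!r} not found")
    cells = cells.rename(columns={config.sample_key: "sample_id",
                                  config.celltype_key: "cell_type"})
    meta = pd.read_csv(indir / "samples.csv", dtype=str)
    if config.label_key not in meta.columns:
        raise KeyError(f"{indir}/samples.csv: column {config.label_key!r} not found")
    labels = dict(zip(meta["sample_id"], meta[config.label_key]))
    return X, cells, labels


def load_cohort(config: IOConfig) -> Cohort:
    """Load a cohort; cells are grouped by sample, vocabularies sorted.

    Every cell must map to a labeled sample; offending samples are listed in
    the error.  Class names are encoded in sorted order; with
    ``positive_class`` set (binary), that class is forced to index 1.
    """
    if config.format == "h5ad":
        X, cells, labels = _read_h5ad(config)
    else:
        X, cells, labels = _read_csv_mtx(config)
    if cells[["sample_id", "cell_type"]].isna().any().any():
        bad = cells.index[cells[["sample_id", "cell_type"]].isna().any(axis=1)].tolist()
        raise ValueError(f"cells with missing sample or cell-type annotation: {bad[:20]}")
    unlabeled = sorted(set(cells["sample_id"]) - set(labels))
    if unlabeled:
        raise ValueError(f"samples without a class label: {unlabeled}")

    type_names = sorted(cells["cell_type"].unique())
    type_index = {t: i for i, t in enumerate(type_names)}
    class_names = sorted(set(labels.values()))
    if config.positive_class is not None:
        if config.positive_class not in class_names:
            raise ValueError(f"positive class {config.positive_class!r} not among {class_names}")
        if len(class_names) != 2:
            raise ValueError("positive_class applies to binary cohorts only")
        class_names = [c for c in class_names if c != config.positive_class]
        class_names.append(config.positive_class)
    class_index = {c: i for i, c in enumerate(class_names)}

    samples = []
    for sid in sorted(cells["sample_id"].unique()):
        mask = (cells["sample_id"] == sid).to_numpy()
        samples.append(Sample(
            X=X[mask],
            cell_types=np.array([type_index[t] for t in cells.loc[mask, "cell_type"]]),
            label=class_index[labels[sid]],
            sample_id=sid,
        ))
    return Cohort(samples, len(type_names), len(class_names), type_names, class_names)


def preprocess_counts(
    cohort: Cohort,
    target_sum: float = 1e4,
    filter_genes_min_cells: int | None = None,
) -> Cohort:
    """Count preprocessing: optional gene filter, per-cell total scaling, log1p.

    Genes with nonzero expression in fewer than ``filter_genes_min_cells``
    cells (counted cohort-wide) are removed first when the filter is enabled.
    Each cell's counts are then scaled to sum to ``target_sum`` and
    log1p-transformed; all-zero cells are left untouched with a warning.
    """
    mats = [s.X for s in cohort.samples]
    if any((M < 0).any() for M in mats):
        raise ValueError("negative entries: preprocess_counts expects raw counts")
    keep = slice(None)
    if filter_genes_min_cells is not None:
        nonzero_cells = sum((M > 0).sum(axis=0) for M in mats)
        keep = np.flatnonzero(nonzero_cells >= filter_genes_min_cells)
    new_samples = []
    for s in cohort.samples:
        M = s.X[:, keep]
        totals = M.sum(axis=1, keepdims=True)
        zero = totals[:, 0] == 0
        if zero.any():
            warnings.warn(
                f"sample {s.sample_id!r}: {int(zero.sum())} all-zero cell(s) left unscaled")
        scaled = np.where(zero[:, None], M, M / np.where(totals == 0, 1.0, totals) * target_sum)
        new_samples.append(Sample(
            X=np.log1p(scaled), cell_types=s.cell_types,
            label=s.label, sample_id=s.sample_id))
    return Cohort(new_samples, cohort.n_cell_types, cohort.n_classes,
                  list(cohort.cell_type_names), list(cohort.class_names))
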