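"""Data-quality robustness experiments.

Three protocols probe how performance degrades with (a) fewer training
samples, (b) fewer cells per sample, and (c) noisier cell-type annotations.
Each perturbs the cohort, re-runs the standard evaluation, and reports mean
AUC per perturbation level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .data import Cohort, Sample
from .model import ModelConfig
from .train import TrainConfig, fit, predict_cohort, evaluate, nested_cv

__all__ = [
    "experiment_train_size",
    "experiment_cell_subsample",
    "experiment_annotation_noise",
]

logger = logging.getLogger(__name__)


def experiment_train_size(
    cohort: Cohort,
    model_config: ModelConfig,
    train_config: TrainConfig,
    fractions=(0.25, 0.5, 0.75),
    n_splits: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean test AUC when training on a fraction of the samples.

    Per fraction, ``n_splits`` stratified random train/test splits are drawn;
    the model is fit on the training fraction and scored by AUC on the rest.
    A split whose training half collapses to one class is redrawn and logged.
    """
    labels = cohort.labels
    rows = []
    for f_idx, frac in enumerate(fractions):
        aucs = []
        sss = StratifiedShuffleSplit(
            n_splits=n_splits, train_size=frac, random_state=int((seed + 101 * f_idx) % 2**31))
        split_seed = np.random.default_rng(seed + 7 * f_idx)
        for tr_idx, te_idx in sss.split(np.zeros(len(cohort)), labels):
            attempt = 0
            while len(np.unique(labels[tr_idx])) < 2:
                logger.warning("single-class train split at fraction %s; resampling", frac)
                redraw = StratifiedShuffleSplit(
                    n_splits=1, train_size=frac,
                    random_state=int(split_seed.integers(2**31)))
                tr_idx, te_idx = next(redraw.split(np.zeros(len(cohort)), labels))
                attempt += 1
                if attempt > 10:
                    raise RuntimeError(f"cannot draw a two-class train split at fraction {frac}")
            tc = replace(train_config, seed=int(split_seed.integers(2**31)))
            params = fit(cohort.subset(tr_idx), model_config, tc)
            test = cohort.subset(te_idx)
            probs = predict_cohort(test, params, model_config)
            aucs.append(evaluate(probs, test.labels)["auc"])
        rows.append({"fraction": frac, "mean_auc": float(np.mean(aucs)),
                     "sd_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                     "n_splits": len(aucs)})
    return pd.DataFrame(rows)


def _subsample_cells(cohort: Cohort, fraction: float, rng: np.random.Generator) -> Cohort:
    """Keep ceil(fraction * N) cells per sample, at least one."""
    new_samples = []
    for s in cohort.samples:
        k = max(1, math.ceil(fraction * s.n_cells))
        keep = np.sort(rng.choice(s.n_cells, size=k, replace=False))
        new_samples.append(Sample(
            X=s.X[keep], cell_types=s.cell_types[keep],
            label=s.label, sample_id=s.sample_id))
    return Cohort(new_samples, cohort.n_cell_types, cohort.n_classes,
                  list(cohort.cell_type_names), list(cohort.class_names))


def experiment_cell_subsample(
    cohort: Cohort,
    model_config: ModelConfig,
    train_config: TrainConfig,
    fractions=(0.25, 0.5, 0.75),
    n_repeats: int = 10,
    seed: int = 0,
    grid=None,
    n_outer: int = 10,
    n_inner: int = 5,
) -> pd.DataFrame:
    """Nested-CV AUC after randomly subsampling cells within each sample.

    Fraction 1.0 leaves the cohort untouched (no random draws), so it
    reproduces the unperturbed CV result under the same seeds.
    """
    rows = []
    for f_idx, frac in enumerate(fractions):
        aucs = []
        for k in range(n_repeats):
            if frac >= 1.0:
                sub = cohort
            else:
                rng = np.random.default_rng(int((seed + 1009 * k + 97 * f_idx) % 2**31))
                sub = _subsample_cells(cohort, frac, rng)
            res = nested_cv(sub, model_config, train_config, grid=grid,
                            n_outer=n_outer, n_inner=n_inner, n_repeats=1,
                            seed=seed + k)
            aucs.append(res.mean_auc())
        rows.append({"fraction": frac, "mean_auc": float(np.mean(aucs)),
                     "sd_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                     "n_repeats": n_repeats})
    return pd.DataFrame(rows)


def _randomize_annotations(cohort: Cohort, fraction: float, rng: np.random.Generator) -> Cohort:
    """Re-label ceil(fraction * N) cells per sample uniformly over all I types."""
    I = cohort.n_cell_types
    new_samples = []
    for s in cohort.samples:
        n_noisy = math.ceil(fraction * s.n_cells)
        idx = rng.choice(s.n_cells, size=n_noisy, replace=False)
        ct = s.cell_types.copy()
        ct[idx] = rng.integers(0, I, size=n_noisy)
        new_samples.append(Sample(X=s.X, cell_types=ct, label=s.label, sample_id=s.sample_id))
    return Cohort(new_samples, I, cohort.n_classes,
                  list(cohort.cell_type_names), list(cohort.class_names))


def experiment_annotation_noise(
    cohort: Cohort,
    model_config: ModelConfig,
    train_config: TrainConfig,
    noise_fracs=(0.0, 0.25, 0.5),
    n_repeats: int = 10,
    seed: int = 0,
    grid=None,
    n_outer: int = 10,
    n_inner: int = 5,
) -> pd.DataFrame:
    """Nested-CV AUC under uniformly randomized cell-type annotations.

    Noise level 0 applies no perturbation and therefore matches the baseline
    CV bitwise under shared seeds.
    """
    rows = []
    for f_idx, frac in enumerate(noise_fracs):
        aucs = []
        for k in range(n_repeats):
            if frac <= 0.0:
                noisy = cohort
            else:
                rng = np.random.default_rng(int((seed + 2003 * k + 89 * f_idx) % 2**31))
                noisy = _randomize_annotations(cohort, frac, rng)
            res = nested_cv(noisy, model_config, train_config, grid=grid,
                            n_outer=n_outer, n_inner=n_inner, n_repeats=1,
                            seed=seed + k)
            aucs.append(res.mean_auc())
        rows.append({"noise_fraction": frac, "mean_auc": float(np.mean(aucs)),
                     "sd_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                     "n_repeats": n_repeats})
    return pd.DataFrame(rows)
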