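"""Exact logit decomposition, cell-type importance scores and permutation test.

Because both pooling stages and the classification head are linear, the
pre-activation prediction of a sample decomposes exactly as

    logit = b + sum_i beta_i (W h_i) = b + sum_i sum_j gamma_ij (W h_ij),

so every cell and every cell type carries an additive contribution to the
prediction.  The importance score of cell type ``i`` contrasts its mean
type-level logit between the two classes,

    kappa_i = mean_{s in S1} l_si - mean_{s in S0} l_si,

and significance is assessed by refitting the model on label permutations to
build a null distribution of kappa per type, with multiple-testing
correction over types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import Cohort, Sample
from .model import ModelConfig, ModelParams, HIERARCHICAL_MODES, forward

__all__ = [
    "LogitDecomposition",
    "ImportanceReport",
    "decompose",
    "cohort_decompositions",
    "importance_scores",
    "importance_scores_multiclass",
    "permutation_test",
    "rank_cell_types",
]

logger = logging.getLogger(__name__)

_CORRECTIONS = {"bh": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}


@dataclass
class LogitDecomposition:
    """Additive contributions of cells and cell types to one sample's logit.

    ``per_cell_logits`` is aligned to the sample's original cell order; each
    entry is gamma_ij * (W h_ij) — a scalar in binary mode, a C-vector with a
    softmax head.  ``per_type_logits`` is aligned to ``present_types``.  For
    ablation modes only the cell-level decomposition exists (``has_types``
    is False and the per-cell weights are the flat attention weights).
    """

    sample_id: str
    cell_types: np.ndarray
    per_cell_logits: np.ndarray
    present_types: np.ndarray
    per_type_logits: np.ndarray
    bias: np.ndarray
    total_logit: np.ndarray
    has_types: bool

    def type_logit(self, i: int):
        """l_si for cell type i; 0 when the type is absent from the sample."""
        pos = np.flatnonzero(self.present_types == i)
        if pos.size == 0:
            return np.zeros_like(np.asarray(self.bias, dtype=float)) * 0.0
        return self.per_type_logits[pos[0]]


def decompose(
    sample: Sample, params: ModelParams, config: ModelConfig,
    n_cell_types: int | None = None,
) -> LogitDecomposition:
    """Exact decomposition of a sample's prediction logit."""
    cache = forward(sample, params, config, n_cell_types=n_cell_types)
    W = params.head_W  # (d,) binary, (C,d) softmax
    cell_proj = cache.H @ W.T if W.ndim == 2 else cache.H @ W  # (N,C) or (N,)
    if config.mode in HIERARCHICAL_MODES:
        rec = cache.record
        gamma = rec.gamma
        type_proj = rec.type_reprs @ W.T if W.ndim == 2 else rec.type_reprs @ W
        per_type = (rec.beta[:, None] * type_proj) if W.ndim == 2 else rec.beta * type_proj
        present = rec.present_types
        has_types = True
    else:
        gamma = cache.flat_att
        per_type = np.zeros((0, W.shape[0]) if W.ndim == 2 else 0)
        present = np.zeros(0, dtype=int)
        has_types = False
    per_cell = (gamma[:, None] * cell_proj) if W.ndim == 2 else gamma * cell_proj
    return LogitDecomposition(
        sample_id=sample.sample_id,
        cell_types=sample.cell_types.copy(),
        per_cell_logits=per_cell,
        present_types=present,
        per_type_logits=per_type,
        bias=np.asarray(params.head_b, dtype=float),
        total_logit=np.asarray(cache.logits, dtype=float),
        has_types=has_types,
    )


def cohort_decompositions(
    cohort: Cohort, params: ModelParams, config: ModelConfig
) -> list[LogitDecomposition]:
    return [decompose(s, params, config, n_cell_types=cohort.n_cell_types)
            for s in cohort.samples]


def _type_logit_matrix(cohort: Cohort, decomps: list[LogitDecomposition]) -> np.ndarray:
    """S×I matrix of scalar type logits; 0 where a type is absent (binary head)."""
    L = np.zeros((len(cohort), cohort.n_cell_types))
    for s_idx, dec in enumerate(decomps):
        if not dec.has_types:
            raise ValueError("importance scores require a hierarchical mode (cta/ha)")
        if dec.per_type_logits.ndim != 1:
            raise ValueError("scalar type logits require the binary head")
        L[s_idx, dec.present_types] = dec.per_type_logits
    return L


def importance_scores(cohort: Cohort, decomps: list[LogitDecomposition]) -> np.ndarray:
    """Binary importance score per cell type.

    kappa_i = mean type-i logit over positive samples minus the mean over
    negative samples; a sample lacking type i contributes l_si = 0 while
    staying in its class average, which preserves sum_i kappa-additivity
    with the forward-pass logits.
    """
    if cohort.n_classes != 2:
        raise ValueError("importance_scores is binary; use importance_scores_multiclass")
    y = cohort.labels
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("both classes must be non-empty")
    L = _type_logit_matrix(cohort, decomps)
    return L[y == 1].mean(axis=0) - L[y == 0].mean(axis=0)


def importance_scores_multiclass(
    cohort: Cohort, decomps: list[LogitDecomposition], target_class: int
) -> np.ndarray:
    """One-vs-rest generalization of the importance score.

    For the target class ``c``, contrasts the class-c component of the
    type-level logits between samples of class c and all other samples.
    With two classes and the positive class as target this reduces exactly
    to :func:`importance_scores`.  The multi-class form is this package's
    own one-vs-rest construction.
    """
    if not 0 <= target_class < cohort.n_classes:
        raise ValueError(f"unknown class {target_class}")
    y = cohort.labels
    if not (np.any(y == target_class) and np.any(y != target_class)):
        raise ValueError("target class and its complement must both be non-empty")
    S, I = len(cohort), cohort.n_cell_types
    L = np.zeros((S, I))
    for s_idx, dec in enumerate(decomps):
        if not dec.has_types:
            raise ValueError("importance scores require a hierarchical mode (cta/ha)")
        if dec.per_type_logits.ndim == 1:
            # binary sigmoid head: the scalar is the class-1 logit component
            comp = dec.per_type_logits if target_class == 1 else -dec.per_type_logits
        else:
            comp = dec.per_type_logits[:, target_class]
        L[s_idx, dec.present_types] = comp
    return L[y == target_class].mean(axis=0) - L[y != target_class].mean(axis=0)


@dataclass
class ImportanceReport:
    """Observed and null importance scores with significance calls."""

    kappa: np.ndarray           # (I,)
    null_kappas: np.ndarray     # (n_perm, I)
    p_raw: np.ndarray
    p_adj: np.ndarray
    critical: np.ndarray
    n_permutations: int
    alpha: float
    correction_method: str
    two_sided: bool
    seed: int
    cell_type_names: list[str]

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa.tolist(),
            "null_kappas": self.null_kappas.tolist(),
            "p_raw": self.p_raw.tolist(),
            "p_adj": self.p_adj.tolist(),
            "critical": self.critical.tolist(),
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "correction_method": self.correction_method,
            "two_sided": self.two_sided,
            "seed": self.seed,
            "cell_type_names": list(self.cell_type_names),
        }


def permutation_test(
    cohort: Cohort,
    config: ModelConfig,
    train_fn,
    n_perm: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
    correction: str = "bh",
    two_sided: bool = True,
) -> ImportanceReport:
    """Label-permutation significance test for the importance scores.

    ``train_fn(cohort, seed) -> ModelParams`` is the training contract; the
    same procedure (and hyperparameters) fits the observed model and every
    permutation refit, each from a fresh seeded initialization.  Empirical
    p-values use the add-one estimator

        p_i = (1 + #{k : |kappa_perm_k,i| >= |kappa_obs_i|}) / (n_perm + 1)

    (one-sided on kappa itself when ``two_sided=False``), followed by the
    selected multiple-testing correction over cell types.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19")
    if correction not in _CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(_CORRECTIONS)}")
    params_obs = train_fn(cohort, seed)
    kappa_obs = importance_scores(cohort, cohort_decompositions(cohort, params_obs, config))

    rng = np.random.default_rng(seed)
    labels = cohort.labels
    nulls = np.zeros((n_perm, cohort.n_cell_types))
    for k in range(n_perm):
        perm_labels = labels[rng.permutation(len(labels))]
        if len(np.unique(perm_labels)) < 2:  # impossible for a permutation, guarded anyway
            perm_labels = labels[rng.permutation(len(labels))]
        perm_cohort = cohort.with_labels(perm_labels)
        fit_seed = int(rng.integers(2**31))
        try:
            params_k = train_fn(perm_cohort, fit_seed)
        except (RuntimeError, FloatingPointError) as exc:
            logger.warning("permutation %d failed to train (%s); re-seeding once", k, exc)
            params_k = train_fn(perm_cohort, int(rng.integers(2**31)))
        nulls[k] = importance_scores(
            perm_cohort, cohort_decompositions(perm_cohort, params_k, config))

    if two_sided:
        exceed = (np.abs(nulls) >= np.abs(kappa_obs)[None, :]).sum(axis=0)
    else:
        exceed = (nulls >= kappa_obs[None, :]).sum(axis=0)
    p_raw = (1.0 + exceed) / (n_perm + 1.0)
    p_adj = multipletests(p_raw, alpha=alpha, method=_CORRECTIONS[correction])[1]
    p_adj = np.minimum(p_adj, 1.0)
    return ImportanceReport(
        kappa=kappa_obs,
        null_kappas=nulls,
        p_raw=p_raw,
        p_adj=p_adj,
        critical=p_adj <= alpha,
        n_permutations=n_perm,
        alpha=alpha,
        correction_method=correction,
        two_sided=two_sided,
        seed=seed,
        cell_type_names=list(cohort.cell_type_names),
    )


def rank_cell_types(report: ImportanceReport) -> pd.DataFrame:
    """Importance table sorted by kappa descending, ties broken by name."""
    df = pd.DataFrame({
        "cell_type": report.cell_type_names,
        "kappa": report.kappa,
        "p_raw": report.p_raw,
        "p_adj": report.p_adj,
        "critical": report.critical,
    })
    return df.sort_values(
        ["kappa", "cell_type"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
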