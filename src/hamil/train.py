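"""Fitting, metrics and the repeated nested cross-validation protocol.

Gradients of the cross-entropy objective with respect to every parameter are
derived analytically (backpropagation through the linear head, the two softmax
attention stages and the ReLU encoder) and checked against finite differences
in the test suite.  Optimization is mini-batch Adam over samples; bags are
ragged, so each sample is processed individually and gradients are averaged
over the batch.

Evaluation follows a repeated, stratified, nested k-fold protocol: inner folds
score each hyperparameter combination by the AUC of its stacked inner-fold
predictions, the winner is refit on the full outer-train split, and one set of
metrics per repeat is computed on the stacked out-of-fold predictions of all
outer folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, fields as dc_fields

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .data import Cohort, Sample
from .model import (
    ModelConfig,
    ModelParams,
    HIERARCHICAL_MODES,
    cross_entropy_loss,
    forward,
    init_params,
)

__all__ = ["TrainConfig", "CVResult", "fit", "predict_cohort", "evaluate", "nested_cv"]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    n_epochs: int = 100
    batch_size: int = 8
    weight_decay: float = 0.0
    early_stop_patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.n_epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")


# -- gradients ---------------------------------------------------------------

def _zero_grads(params: ModelParams) -> dict:
    return {
        "enc_W": [np.zeros_like(W) for W in params.enc_W],
        "enc_b": [np.zeros_like(b) for b in params.enc_b],
        "att_w": np.zeros_like(params.att_w),
        "att_b": 0.0,
        "type_v": np.zeros_like(params.type_v),
        "type_b": 0.0,
        "head_W": np.zeros_like(params.head_W),
        "head_b": np.zeros_like(np.asarray(params.head_b, dtype=float)),
    }


def _segment_softmax(e: np.ndarray, starts: np.ndarray, rep: np.ndarray) -> np.ndarray:
    """Softmax within contiguous segments; ``rep`` maps cells to segment ids."""
    seg_max = np.maximum.reduceat(e, starts)
    z = np.exp(e - seg_max[rep])
    denom = np.add.reduceat(z, starts)
    return z / denom[rep]


def loss_and_grads(
    samples: list[Sample],
    params: ModelParams,
    config: ModelConfig,
    n_cell_types: int,
) -> tuple[float, dict]:
    """Summed cross-entropy over the batch and its parameter gradients.

    The whole batch is processed as one concatenated cell matrix with
    segment reductions over (sample, cell type) groups, so the cost per step
    is a handful of matrix products regardless of the number of bags.
    """
    g = _zero_grads(params)
    B = len(samples)
    y = np.array([s.label for s in samples], dtype=int)
    X = np.vstack([s.X for s in samples])
    n_cells = np.array([s.n_cells for s in samples])
    cell_sample = np.repeat(np.arange(B), n_cells)
    cell_type = np.concatenate([s.cell_types for s in samples])

    # order cells so that (sample, type) groups are contiguous
    if config.mode in HIERARCHICAL_MODES:
        seg_key = cell_sample * n_cell_types + cell_type
    else:
        seg_key = cell_sample
    order = np.argsort(seg_key, kind="stable")
    X, seg_key, cell_sample = X[order], seg_key[order], cell_sample[order]
    uniq, starts, counts = np.unique(seg_key, return_index=True, return_counts=True)
    n_seg = len(uniq)
    cell_seg = np.repeat(np.arange(n_seg), counts)            # segment id per cell
    seg_sample = cell_sample[starts]                          # sample id per segment
    samp_starts = np.unique(seg_sample, return_index=True)[1]  # first segment per sample
    seg_per_sample = np.bincount(seg_sample, minlength=B)
    if np.any(seg_per_sample == 0):
        raise ValueError("sample with no present cell types")
    seg_samp_rep = np.repeat(np.arange(B), seg_per_sample)

    # encoder forward
    layer_inputs, preacts = [], []
    H = X
    for W, b in zip(params.enc_W, params.enc_b):
        layer_inputs.append(H)
        Z = H @ W.T + b
        preacts.append(Z)
        H = np.maximum(Z, 0.0)

    # within-segment weights alpha (uniform for cta/mean_pool)
    if config.mode in ("ha", "cell_att"):
        e = H @ params.att_w + params.att_b
        alpha = _segment_softmax(e, starts, cell_seg)
    else:
        alpha = 1.0 / counts[cell_seg]

    seg_repr = np.add.reduceat(alpha[:, None] * H, starts, axis=0)  # (n_seg, d)

    # across-segment weights beta (trivial single segment for flat modes)
    if config.mode in HIERARCHICAL_MODES:
        f = seg_repr @ params.type_v + params.type_b
        beta = _segment_softmax(f, samp_starts, seg_samp_rep)
        h = np.add.reduceat(beta[:, None] * seg_repr, samp_starts, axis=0)  # (B, d)
    else:
        beta = np.ones(n_seg)
        h = seg_repr

    # head + loss
    if config.binary_head:
        z = h @ params.head_W + float(params.head_b)
        p = 1.0 / (1.0 + np.exp(-z))
        probs = np.column_stack([1.0 - p, p])
    else:
        logits = h @ params.head_W.T + np.asarray(params.head_b, dtype=float)
        lmax = logits.max(axis=1, keepdims=True)
        ez = np.exp(logits - lmax)
        probs = ez / ez.sum(axis=1, keepdims=True)
    total_loss = cross_entropy_loss(probs, y)

    # head backward
    if config.binary_head:
        dz = p - y.astype(float)                       # (B,)
        g["head_W"] += dz @ h
        g["head_b"] += dz.sum()
        dh = dz[:, None] * params.head_W[None, :]      # (B, d)
    else:
        dz = probs.copy()
        dz[np.arange(B), y] -= 1.0                     # (B, C)
        g["head_W"] += dz.T @ h
        g["head_b"] += dz.sum(axis=0)
        dh = dz @ params.head_W                        # (B, d)

    # across-segment backward
    if config.mode in HIERARCHICAL_MODES:
        dh_seg_parent = dh[seg_samp_rep]               # (n_seg, d)
        dbeta = np.einsum("sd,sd->s", seg_repr, dh_seg_parent)
        dseg = beta[:, None] * dh_seg_parent
        inner = np.add.reduceat(beta * dbeta, samp_starts)
        df = beta * (dbeta - inner[seg_samp_rep])
        g["type_v"] += seg_repr.T @ df
        g["type_b"] += df.sum()
        dseg += df[:, None] * params.type_v[None, :]
    else:
        dseg = dh

    # within-segment backward
    dseg_cell = dseg[cell_seg]                         # (N, d)
    dH = alpha[:, None] * dseg_cell
    if config.mode in ("ha", "cell_att"):
        dalpha = np.einsum("nd,nd->n", H, dseg_cell)
        inner = np.add.reduceat(alpha * dalpha, starts)
        de = alpha * (dalpha - inner[cell_seg])
        g["att_w"] += H.T @ de
        g["att_b"] += de.sum()
        dH += de[:, None] * params.att_w[None, :]

    # encoder backward
    dcur = dH
    for l in reversed(range(len(params.enc_W))):
        dZ = dcur * (preacts[l] > 0)
        g["enc_W"][l] += dZ.T @ layer_inputs[l]
        g["enc_b"][l] += dZ.sum(axis=0)
        dcur = dZ @ params.enc_W[l]

    return total_loss, g


def loss_and_grads_persample(
    samples: list[Sample],
    params: ModelParams,
    config: ModelConfig,
    n_cell_types: int,
) -> tuple[float, dict]:
    """Reference per-sample implementation of :func:`loss_and_grads`.

    Follows the forward cache bag by bag; kept as the slow cross-check for
    the vectorized batch path.
    """
    g = _zero_grads(params)
    total_loss = 0.0
    for sample in samples:
        cache = forward(sample, params, config, n_cell_types=n_cell_types)
        y = sample.label
        total_loss += cross_entropy_loss(cache.probs[None, :], [y])

        # head: d loss / d logits for sigmoid-BCE and softmax-CE share one form
        if config.binary_head:
            dz = cache.probs[1] - float(y)
            g["head_W"] += dz * cache.h
            g["head_b"] += dz
            dh = dz * params.head_W
        else:
            dz = cache.probs.copy()
            dz[y] -= 1.0
            g["head_W"] += np.outer(dz, cache.h)
            g["head_b"] += dz
            dh = params.head_W.T @ dz

        H = cache.H
        dH = np.zeros_like(H)
        if config.mode in HIERARCHICAL_MODES:
            rec = cache.record
            reprs, beta = rec.type_reprs, rec.beta
            # h = sum_i beta_i h_i
            dbeta = reprs @ dh
            drepr = beta[:, None] * dh[None, :]
            # softmax over types
            df = beta * (dbeta - beta @ dbeta)
            g["type_v"] += reprs.T @ df
            g["type_b"] += df.sum()
            drepr += np.outer(df, params.type_v)
            for p, (idx, alpha_i) in enumerate(zip(rec.type_cell_idx, rec.alpha)):
                dh_i = drepr[p]
                H_i = H[idx]
                dH[idx] += alpha_i[:, None] * dh_i[None, :]
                if config.mode == "ha":  # CTA alphas are constants
                    dalpha = H_i @ dh_i
                    de = alpha_i * (dalpha - alpha_i @ dalpha)
                    g["att_w"] += H_i.T @ de
                    g["att_b"] += de.sum()
                    dH[idx] += np.outer(de, params.att_w)
        elif config.mode == "mean_pool":
            dH += dh[None, :] / H.shape[0]
        else:  # cell_att
            a = cache.flat_att
            dH += a[:, None] * dh[None, :]
            dalpha = H @ dh
            de = a * (dalpha - a @ dalpha)
            g["att_w"] += H.T @ de
            g["att_b"] += de.sum()
            dH += np.outer(de, params.att_w)

        # encoder
        dcur = dH
        for l in reversed(range(len(params.enc_W))):
            dZ = dcur * (cache.preacts[l] > 0)
            g["enc_W"][l] += dZ.T @ cache.layer_inputs[l]
            g["enc_b"][l] += dZ.sum(axis=0)
            dcur = dZ @ params.enc_W[l]

    return total_loss, g


# -- Adam --------------------------------------------------------------------

class _Adam:
    def __init__(self, params: ModelParams, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = _zero_grads(params)
        self.v = _zero_grads(params)

    def _step_one(self, value, grad, m, v, decay):
        if decay and self.wd:
            grad = grad + self.wd * value
        m_new = self.b1 * m + (1 - self.b1) * grad
        v_new = self.b2 * v + (1 - self.b2) * grad**2 if isinstance(grad, np.ndarray) \
            else self.b2 * v + (1 - self.b2) * grad * grad
        m_hat = m_new / (1 - self.b1**self.t)
        v_hat = v_new / (1 - self.b2**self.t)
        value_new = value - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
        return value_new, m_new, v_new

    def step(self, params: ModelParams, grads: dict) -> None:
        self.t += 1
        for l in range(len(params.enc_W)):
            params.enc_W[l], self.m["enc_W"][l], self.v["enc_W"][l] = self._step_one(
                params.enc_W[l], grads["enc_W"][l], self.m["enc_W"][l], self.v["enc_W"][l], True)
            params.enc_b[l], self.m["enc_b"][l], self.v["enc_b"][l] = self._step_one(
                params.enc_b[l], grads["enc_b"][l], self.m["enc_b"][l], self.v["enc_b"][l], False)
        params.att_w, self.m["att_w"], self.v["att_w"] = self._step_one(
            params.att_w, grads["att_w"], self.m["att_w"], self.v["att_w"], True)
        params.att_b, self.m["att_b"], self.v["att_b"] = self._step_one(
            params.att_b, grads["att_b"], self.m["att_b"], self.v["att_b"], False)
        params.type_v, self.m["type_v"], self.v["type_v"] = self._step_one(
            params.type_v, grads["type_v"], self.m["type_v"], self.v["type_v"], True)
        params.type_b, self.m["type_b"], self.v["type_b"] = self._step_one(
            params.type_b, grads["type_b"], self.m["type_b"], self.v["type_b"], False)
        params.head_W, self.m["head_W"], self.v["head_W"] = self._step_one(
            params.head_W, grads["head_W"], self.m["head_W"], self.v["head_W"], True)
        hb, mb, vb = self._step_one(
            np.asarray(params.head_b, dtype=float), grads["head_b"],
            self.m["head_b"], self.v["head_b"], False)
        params.head_b, self.m["head_b"], self.v["head_b"] = hb, mb, vb


# -- fitting -----------------------------------------------------------------

def fit(cohort: Cohort, model_config: ModelConfig, train_config: TrainConfig) -> ModelParams:
    """Minimize the cross-entropy objective by mini-batch Adam.

    Deterministic given ``train_config.seed``: the seed drives parameter
    initialization and the per-epoch shuffling and nothing else.
    """
    if len(cohort) < 2 or len(np.unique(cohort.labels)) < 2:
        raise ValueError("fit requires at least two samples from at least two classes")
    rng = np.random.default_rng(train_config.seed)
    params = init_params(model_config, rng)
    opt = _Adam(params, train_config.learning_rate, train_config.weight_decay)
    S = len(cohort)
    best_loss, stall = np.inf, 0
    for epoch in range(train_config.n_epochs):
        order = rng.permutation(S)
        epoch_loss = 0.0
        for start in range(0, S, train_config.batch_size):
            batch_idx = order[start:start + train_config.batch_size]
            batch = [cohort.samples[i] for i in batch_idx]
            loss, grads = loss_and_grads(batch, params, model_config, cohort.n_cell_types)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={train_config.learning_rate}, mode={model_config.mode})")
            n = len(batch)
            scaled = {
                "enc_W": [G / n for G in grads["enc_W"]],
                "enc_b": [G / n for G in grads["enc_b"]],
                "att_w": grads["att_w"] / n,
                "att_b": grads["att_b"] / n,
                "type_v": grads["type_v"] / n,
                "type_b": grads["type_b"] / n,
                "head_W": grads["head_W"] / n,
                "head_b": grads["head_b"] / n,
            }
            opt.step(params, scaled)
            epoch_loss += loss
        epoch_loss /= S
        if train_config.early_stop_patience is not None:
            if epoch_loss < best_loss - 1e-6:
                best_loss, stall = epoch_loss, 0
            else:
                stall += 1
                if stall >= train_config.early_stop_patience:
                    break
    return params


def predict_cohort(cohort: Cohort, params: ModelParams, config: ModelConfig) -> np.ndarray:
    """Per-sample class probabilities, shape (S, C)."""
    return np.array([
        forward(s, params, config, n_cell_types=cohort.n_cell_types).probs
        for s in cohort.samples
    ])


def training_loss(cohort: Cohort, params: ModelParams, config: ModelConfig) -> float:
    probs = predict_cohort(cohort, params, config)
    return cross_entropy_loss(probs, cohort.labels)


# -- metrics -----------------------------------------------------------------

def evaluate(probs: np.ndarray, labels: np.ndarray) -> dict:
    """AUC, F1, accuracy, precision and recall from stacked predictions.

    Binary tasks use the positive class at threshold 0.5; multi-class tasks
    use argmax predictions, macro averaging, and one-vs-rest macro AUC.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    C = probs.shape[1]
    if C == 2:
        preds = (probs[:, 1] >= 0.5).astype(int)
        auc = roc_auc_score(labels, probs[:, 1])
        avg = "binary"
    else:
        preds = probs.argmax(axis=1)
        auc = roc_auc_score(labels, probs, multi_class="ovr", average="macro")
        avg = "macro"
    return {
        "auc": float(auc),
        "f1": float(f1_score(labels, preds, average=avg, zero_division=0)),
        "accuracy": float(accuracy_score(labels, preds)),
        "precision": float(precision_score(labels, preds, average=avg, zero_division=0)),
        "recall": float(recall_score(labels, preds, average=avg, zero_division=0)),
    }


def _stacked_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    if probs.shape[1] == 2:
        return float(roc_auc_score(labels, probs[:, 1]))
    return float(roc_auc_score(labels, probs, multi_class="ovr", average="macro"))


# -- nested cross-validation -------------------------------------------------

_MODEL_FIELDS = {f.name for f in dc_fields(ModelConfig)}
_TRAIN_FIELDS = {f.name for f in dc_fields(TrainConfig)}


def _apply_grid_point(model_config: ModelConfig, train_config: TrainConfig, point: dict):
    mc_over = {k: v for k, v in point.items() if k in _MODEL_FIELDS}
    tc_over = {k: v for k, v in point.items() if k in _TRAIN_FIELDS}
    unknown = set(point) - _MODEL_FIELDS - _TRAIN_FIELDS
    if unknown:
        raise ValueError(f"unknown hyperparameters in grid point: {sorted(unknown)}")
    return replace(model_config, **mc_over), replace(train_config, **tc_over)


@dataclass
class CVResult:
    """Outcome of a repeated nested CV run."""

    repeat_metrics: list[dict]
    chosen_hyperparams: list[list[dict]]   # per repeat, per outer fold
    fold_assignments: list[np.ndarray]     # per repeat: outer-fold id per sample
    stacked_probs: list[np.ndarray]        # per repeat: (S, C)
    seeds: list[int]

    def summary(self) -> dict:
        keys = self.repeat_metrics[0].keys()
        return {
            k: {
                "mean": float(np.mean([m[k] for m in self.repeat_metrics])),
                "sd": float(np.std([m[k] for m in self.repeat_metrics], ddof=1))
                if len(self.repeat_metrics) > 1 else 0.0,
            }
            for k in keys
        }

    def mean_auc(self) -> float:
        return float(np.mean([m["auc"] for m in self.repeat_metrics]))


def nested_cv(
    cohort: Cohort,
    model_config: ModelConfig,
    train_config: TrainConfig,
    grid: list[dict] | None = None,
    n_outer: int = 10,
    n_inner: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified nested k-fold CV with inner-loop model selection.

    Per outer fold, every grid point is scored by the AUC of its stacked
    inner-fold predictions on the outer-train split only; the best point is
    refit on the full outer-train split and used to predict the held-out
    fold.  Metrics are computed once per repeat on the S stacked out-of-fold
    predictions.  A grid point that fails to train scores AUC 0.5 and is
    logged.  Fully deterministic given ``seed``.
    """
    if grid is None or len(grid) == 0:
        grid = [{}]
    S = len(cohort)
    if S < n_outer:
        raise ValueError(f"cohort of {S} samples cannot be split into {n_outer} folds")
    labels = cohort.labels
    C = cohort.n_classes

    repeat_metrics, chosen_all, fold_maps, stacked_all, seeds = [], [], [], [], []
    for r in range(n_repeats):
        rs = int((seed + 9973 * r) % (2**31))
        seeds.append(rs)
        seed_stream = np.random.default_rng(rs)
        outer = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=rs)
        stacked = np.zeros((S, C))
        fold_map = np.full(S, -1)
        chosen_folds = []
        for fold_id, (tr_idx, te_idx) in enumerate(outer.split(np.zeros(S), labels)):
            fold_map[te_idx] = fold_id
            train_cohort = cohort.subset(tr_idx)
            if len(grid) > 1:
                best_point, _ = _inner_select(
                    train_cohort, model_config, train_config, grid, n_inner, seed_stream)
            else:
                best_point = grid[0]
            mc, tc = _apply_grid_point(model_config, train_config, best_point)
            tc = replace(tc, seed=int(seed_stream.integers(2**31)))
            params = fit(train_cohort, mc, tc)
            for i in te_idx:
                stacked[i] = forward(
                    cohort.samples[i], params, mc, n_cell_types=cohort.n_cell_types).probs
            chosen_folds.append(best_point)
        repeat_metrics.append(evaluate(stacked, labels))
        chosen_all.append(chosen_folds)
        fold_maps.append(fold_map)
        stacked_all.append(stacked)
    return CVResult(repeat_metrics, chosen_all, fold_maps, stacked_all, seeds)


def _inner_select(train_cohort, model_config, train_config, grid, n_inner, seed_stream):
    """Score each grid point by stacked inner-fold AUC; ties go to the first."""
    y = train_cohort.labels
    S = len(train_cohort)
    inner_seed = int(seed_stream.integers(2**31))
    inner = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=inner_seed)
    splits = list(inner.split(np.zeros(S), y))
    best_auc, best_point = -np.inf, grid[0]
    for point in grid:
        mc, tc = _apply_grid_point(model_config, train_config, point)
        stacked = np.zeros((S, train_cohort.n_classes))
        try:
            for tr, te in splits:
                tc_fold = replace(tc, seed=int(seed_stream.integers(2**31)))
                params = fit(train_cohort.subset(tr), mc, tc_fold)
                for i in te:
                    stacked[i] = forward(
                        train_cohort.samples[i], params, mc,
                        n_cell_types=train_cohort.n_cell_types).probs
            auc = _stacked_auc(stacked, y)
        except (RuntimeError, FloatingPointError, ValueError) as exc:
            logger.warning("grid point %r failed to train (%s); scored as AUC 0.5", point, exc)
            auc = 0.5
        if auc > best_auc:
            best_auc, best_point = auc, point
    return best_point, best_auc
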