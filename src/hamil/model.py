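"""Hierarchical attention-based MIL models (CTA, HA) and ablation variants.

The model maps a bag of annotated cells to a class probability in three
stages.  An encoder (one or two dense ReLU layers) maps each cell's feature
vector ``x_ij`` to a representation ``h_ij``.  Cells are then pooled within
each cell type — by attention in the HA model, by the arithmetic mean in the
CTA model — giving one representation ``h_i`` per present cell type, and a
second softmax attention pools the cell types into the sample representation
``h = sum_i beta_i h_i``.  A linear head (sigmoid for binary, softmax for
multi-class) turns ``h`` into probabilities.  Because both pooling steps and
the head are linear, the prediction logit decomposes exactly into per-cell
and per-type contributions (see :mod:`hamil.interpret`).

Two ablation variants drop the hierarchy: ``mean_pool`` averages all cells,
``cell_att`` applies a single softmax attention over all cells ignoring
types.

This module is a pure forward/parameter layer; optimization lives in
:mod:`hamil.train`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import Sample

__all__ = [
    "ModelConfig",
    "ModelParams",
    "AttentionRecord",
    "init_params",
    "encode_cells",
    "cell_attention",
    "aggregate_cells",
    "cell_type_attention",
    "sample_representation",
    "ablation_representation",
    "predict_proba",
    "forward",
    "cross_entropy_loss",
    "save_checkpoint",
    "load_checkpoint",
]

MODES = ("cta", "ha", "mean_pool", "cell_att")
HIERARCHICAL_MODES = ("cta", "ha")


@dataclass
class ModelConfig:
    """Architecture of a CTA/HA model.

    ``mode`` selects the aggregation: ``"cta"`` (mean-pool cells, attend over
    types), ``"ha"`` (attend over cells, then types), or the ablations
    ``"mean_pool"`` / ``"cell_att"``.  ``force_softmax_head`` uses the
    multi-class softmax head even when ``n_classes == 2`` (the default binary
    head is a single sigmoid unit).
    """

    input_dim: int
    n_classes: int = 2
    mode: str = "cta"
    hidden_dim: int = 32
    n_hidden_layers: int = 1
    nonlinearity: str = "relu"
    force_softmax_head: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.n_hidden_layers not in (1, 2):
            raise ValueError("n_hidden_layers must be 1 or 2")
        if self.hidden_dim < 1 or self.input_dim < 1 or self.n_classes < 2:
            raise ValueError("invalid dimensions")
        if self.nonlinearity != "relu":
            raise ValueError("only the relu nonlinearity is supported")

    @property
    def binary_head(self) -> bool:
        return self.n_classes == 2 and not self.force_softmax_head


@dataclass
class ModelParams:
    """All trainable tensors.

    ``enc_W[l]`` / ``enc_b[l]`` are the encoder layers; ``att_w``, ``att_b``
    the cell-level attention (shared across types); ``type_v``, ``type_b`` the
    type-level attention; the head is either ``head_W`` (C×d) with vector
    ``head_b`` or, in binary mode, vector ``head_w`` with scalar ``head_b``.
    """

    enc_W: list[np.ndarray]
    enc_b: list[np.ndarray]
    att_w: np.ndarray
    att_b: float
    type_v: np.ndarray
    type_b: float
    head_W: np.ndarray  # (C, d) multi-class, (d,) binary
    head_b: np.ndarray  # (C,) multi-class, scalar ndarray binary

    def copy(self) -> "ModelParams":
        return ModelParams(
            enc_W=[W.copy() for W in self.enc_W],
            enc_b=[b.copy() for b in self.enc_b],
            att_w=self.att_w.copy(),
            att_b=float(self.att_b),
            type_v=self.type_v.copy(),
            type_b=float(self.type_b),
            head_W=self.head_W.copy(),
            head_b=np.array(self.head_b, dtype=float),
        )

    def check(self, config: ModelConfig) -> None:
        d, m = config.hidden_dim, config.input_dim
        if len(self.enc_W) != config.n_hidden_layers:
            raise ValueError("encoder depth does not match config")
        expect_in = m
        for W, b in zip(self.enc_W, self.enc_b):
            if W.shape != (d, expect_in) or b.shape != (d,):
                raise ValueError("encoder weight shapes do not match config")
            expect_in = d
        if self.att_w.shape != (d,) or self.type_v.shape != (d,):
            raise ValueError("attention vector shapes do not match config")
        if config.binary_head:
            if self.head_W.shape != (d,):
                raise ValueError("binary head expects a d-vector")
        elif self.head_W.shape != (config.n_classes, d):
            raise ValueError("softmax head expects a C×d matrix")


def init_params(config: ModelConfig, rng: np.random.Generator | None = None) -> ModelParams:
    """Seeded initialization: fan-in-scaled encoder/head, small attention vectors.

    Attention vectors start near zero so the initial model is close to mean
    pooling; the first optimization steps then decide where attention is
    warranted.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d, m, C = config.hidden_dim, config.input_dim, config.n_classes
    dims = [m] + [d] * config.n_hidden_layers
    enc_W = [rng.normal(0.0, np.sqrt(2.0 / dims[l]), size=(d, dims[l]))
             for l in range(config.n_hidden_layers)]
    enc_b = [np.zeros(d) for _ in range(config.n_hidden_layers)]
    att_scale = 0.01
    params = ModelParams(
        enc_W=enc_W,
        enc_b=enc_b,
        att_w=rng.normal(0.0, att_scale, size=d),
        att_b=0.0,
        type_v=rng.normal(0.0, att_scale, size=d),
        type_b=0.0,
        head_W=(rng.normal(0.0, np.sqrt(1.0 / d), size=d) if config.binary_head
                else rng.normal(0.0, np.sqrt(1.0 / d), size=(C, d))),
        head_b=(np.zeros(()) if config.binary_head else np.zeros(C)),
    )
    return params


def _softmax(e: np.ndarray) -> np.ndarray:
    # max-shifted for overflow safety; shift invariance is a tested property
    e = np.asarray(e, dtype=float)
    z = np.exp(e - e.max())
    return z / z.sum()


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def encode_cells(X: np.ndarray, params: ModelParams, config: ModelConfig) -> np.ndarray:
    """Per-cell encoder h_ij = phi(W_x x_ij + b_x), composed for two layers."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != config.input_dim:
        raise ValueError(f"expected cells × {config.input_dim} matrix, got {X.shape}")
    params.check(config)
    H = X
    for W, b in zip(params.enc_W, params.enc_b):
        H = _relu(H @ W.T + b)
    return H


def cell_attention(H_i: np.ndarray, w: np.ndarray, b: float) -> np.ndarray:
    """Within-type softmax attention weights alpha_ij over the cells of one type."""
    H_i = np.atleast_2d(np.asarray(H_i, dtype=float))
    if H_i.shape[0] < 1:
        raise ValueError("cell_attention requires at least one cell")
    return _softmax(H_i @ np.asarray(w, dtype=float) + b)


def aggregate_cells(H_i: np.ndarray, alpha_i: np.ndarray) -> np.ndarray:
    """Attention-weighted cell-type representation h_i = sum_j alpha_ij h_ij."""
    H_i = np.atleast_2d(np.asarray(H_i, dtype=float))
    alpha_i = np.asarray(alpha_i, dtype=float)
    if alpha_i.shape != (H_i.shape[0],):
        raise ValueError("one attention weight per cell required")
    return alpha_i @ H_i


def cell_type_attention(type_reprs: np.ndarray, v: np.ndarray, b: float) -> np.ndarray:
    """Softmax attention weights beta_i over the present cell types of a sample."""
    R = np.atleast_2d(np.asarray(type_reprs, dtype=float))
    if R.shape[0] < 1:
        raise ValueError("sample has no present cell types")
    return _softmax(R @ np.asarray(v, dtype=float) + b)


@dataclass
class AttentionRecord:
    """Per-sample attention weights and intermediate representations.

    ``present_types`` lists the cell-type indices with at least one cell;
    ``alpha``, ``type_reprs`` and ``beta`` are aligned to it.  ``gamma`` holds
    the combined weights gamma_ij = beta_i * alpha_ij in the original cell
    order, so it sums to one over the whole bag.
    """

    present_types: np.ndarray
    type_cell_idx: list[np.ndarray]
    alpha: list[np.ndarray]
    beta: np.ndarray
    type_reprs: np.ndarray
    sample_repr: np.ndarray
    gamma: np.ndarray


@dataclass
class ForwardCache:
    """Everything the backward pass and the interpretability layer need."""

    layer_inputs: list[np.ndarray]   # inputs to each encoder layer (first is X)
    preacts: list[np.ndarray]        # pre-activation of each encoder layer
    H: np.ndarray                    # final cell representations, N×d
    record: AttentionRecord | None   # hierarchical modes only
    flat_att: np.ndarray | None      # ablation modes: per-cell weights over all N
    h: np.ndarray                    # sample representation
    logits: np.ndarray               # scalar (binary) or (C,)
    probs: np.ndarray                # always length C


def _encode_with_cache(X, params, config):
    H = np.asarray(X, dtype=float)
    layer_inputs, preacts = [], []
    for W, b in zip(params.enc_W, params.enc_b):
        layer_inputs.append(H)
        Z = H @ W.T + b
        preacts.append(Z)
        H = _relu(Z)
    return layer_inputs, preacts, H


def sample_representation(
    sample: Sample, params: ModelParams, config: ModelConfig, n_cell_types: int | None = None
) -> tuple[np.ndarray, AttentionRecord]:
    """Hierarchical sample representation h = sum_i beta_i h_i (CTA/HA modes)."""
    if config.mode not in HIERARCHICAL_MODES:
        raise ValueError(f"mode {config.mode!r} is not hierarchical; use ablation_representation")
    cache = forward(sample, params, config, n_cell_types=n_cell_types)
    return cache.h, cache.record


def ablation_representation(
    sample: Sample, params: ModelParams, config: ModelConfig
) -> np.ndarray:
    """Flat sample representation: mean pooling or one softmax over all cells."""
    if config.mode not in ("mean_pool", "cell_att"):
        raise ValueError(f"mode {config.mode!r} is not an ablation mode")
    return forward(sample, params, config).h


def forward(
    sample: Sample,
    params: ModelParams,
    config: ModelConfig,
    n_cell_types: int | None = None,
) -> ForwardCache:
    """Full forward pass for any mode, returning all intermediates.

    Absent cell types (``n_si = 0``) are excluded from the type softmax; the
    softmax runs only over the types present in this sample.
    """
    params.check(config)
    layer_inputs, preacts, H = _encode_with_cache(sample.X, params, config)
    N = H.shape[0]

    if config.mode in HIERARCHICAL_MODES:
        I = n_cell_types if n_cell_types is not None else int(sample.cell_types.max()) + 1
        counts = np.bincount(sample.cell_types, minlength=I)
        present = np.flatnonzero(counts)
        if present.size == 0:
            raise ValueError(f"sample {sample.sample_id!r} has no present cell types")
        type_cell_idx, alphas, reprs = [], [], []
        for i in present:
            idx = np.flatnonzero(sample.cell_types == i)
            H_i = H[idx]
            if config.mode == "ha":
                alpha_i = cell_attention(H_i, params.att_w, params.att_b)
            else:  # cta: exact mean pooling
                alpha_i = np.full(idx.size, 1.0 / idx.size)
            type_cell_idx.append(idx)
            alphas.append(alpha_i)
            reprs.append(aggregate_cells(H_i, alpha_i))
        reprs = np.array(reprs)
        beta = cell_type_attention(reprs, params.type_v, params.type_b)
        h = beta @ reprs
        gamma = np.zeros(N)
        for b_i, idx, alpha_i in zip(beta, type_cell_idx, alphas):
            gamma[idx] = b_i * alpha_i
        record = AttentionRecord(
            present_types=present,
            type_cell_idx=type_cell_idx,
            alpha=alphas,
            beta=beta,
            type_reprs=reprs,
            sample_repr=h,
            gamma=gamma,
        )
        flat_att = None
    elif config.mode == "mean_pool":
        flat_att = np.full(N, 1.0 / N)
        h = flat_att @ H
        record = None
    else:  # cell_att: single softmax over all cells, types ignored
        flat_att = _softmax(H @ params.att_w + params.att_b)
        h = flat_att @ H
        record = None

    logits, probs = predict_proba(h, params, config, return_logits=True)
    return ForwardCache(
        layer_inputs=layer_inputs,
        preacts=preacts,
        H=H,
        record=record,
        flat_att=flat_att,
        h=h,
        logits=logits,
        probs=probs,
    )


def predict_proba(
    h: np.ndarray, params: ModelParams, config: ModelConfig, return_logits: bool = False
):
    """Class probabilities from a sample representation.

    Binary head: p = sigmoid(w̄·h + b̄), returned as ``[1-p, p]``.  Otherwise
    softmax(W h + b).
    """
    h = np.asarray(h, dtype=float)
    if config.binary_head:
        logit = float(params.head_W @ h + params.head_b)
        p = 1.0 / (1.0 + np.exp(-logit))
        probs = np.array([1.0 - p, p])
        logits = np.array(logit)
    else:
        logits = params.head_W @ h + np.asarray(params.head_b, dtype=float)
        probs = _softmax(logits)
    return (logits, probs) if return_logits else probs


def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Summed cross-entropy L = -sum_s log p_{s, y_s} over samples."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("label out of range")
    p_correct = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.log(p_correct).sum())


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(
    path,
    params: ModelParams,
    config: ModelConfig,
    cell_type_names: list[str] | None = None,
    class_names: list[str] | None = None,
) -> None:
    """Write config + weights + vocabularies to a single JSON file.

    JSON float literals round-trip float64 exactly, so the save/load cycle is
    lossless for weights and bit-stable for the config.
    """
    blob = {
        "format": "hamil-checkpoint-v1",
        "config": asdict(config),
        "params": {
            "enc_W": [W.tolist() for W in params.enc_W],
            "enc_b": [b.tolist() for b in params.enc_b],
            "att_w": params.att_w.tolist(),
            "att_b": float(params.att_b),
            "type_v": params.type_v.tolist(),
            "type_b": float(params.type_b),
            "head_W": params.head_W.tolist(),
            "head_b": np.asarray(params.head_b).tolist(),
        },
        "cell_type_names": cell_type_names,
        "class_names": class_names,
    }
    Path(path).write_text(json.dumps(blob))


def load_checkpoint(path):
    """Load a checkpoint; returns (params, config, cell_type_names, class_names)."""
    blob = json.loads(Path(path).read_text())
    if blob.get("format") != "hamil-checkpoint-v1":
        raise ValueError(f"{path}: not a hamil checkpoint")
    config = ModelConfig(**blob["config"])
    p = blob["params"]
    params = ModelParams(
        enc_W=[np.array(W, dtype=float) for W in p["enc_W"]],
        enc_b=[np.array(b, dtype=float) for b in p["enc_b"]],
        att_w=np.array(p["att_w"], dtype=float),
        att_b=float(p["att_b"]),
        type_v=np.array(p["type_v"], dtype=float),
        type_b=float(p["type_b"]),
        head_W=np.array(p["head_W"], dtype=float),
        head_b=np.array(p["head_b"], dtype=float),
    )
    return params, config, blob.get("cell_type_names"), blob.get("class_names")
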