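"""Seeded synthetic cohorts with hierarchical cell-type structure.

The generator emulates the statistical shape of an annotated single-cell
cohort: per sample, a cell count drawn uniformly from a range, cell-type
proportions drawn from a Dirichlet (with random type absence), and cell
features drawn around type-specific Gaussian centroids.  The class signal is
injected through designated *driver* cell types, either as an additive mean
shift of driver cells in positive samples (expression channel) or as a tilt
of the driver type's proportion (composition channel); the two channels are
separately switchable.  Feature values live in the log-normalized /
embedding space the models consume; an optional negative-binomial count mode
feeds the count-preprocessing path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data import Cohort, Sample

__all__ = [
    "SimConfig",
    "simulate_cohort",
    "simulate_rare_driver",
    "fixture_micro_cohort",
    "hierarchical_signal_config",
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``samples_per_class`` has one entry per class; ``effect_size`` is the
    additive shift delta applied to every feature of (a fraction of) driver-
    type cells in samples of class >= 1 (scaled by the class index when
    C > 2); ``composition_effect`` is added to the driver types' Dirichlet
    proportions in positive samples before renormalization.
    """

    samples_per_class: tuple = (30, 30)
    n_cell_types: int = 5
    n_features: int = 50
    cells_per_sample: tuple = (50, 150)
    dirichlet_concentration: float = 5.0
    driver_types: tuple = (0,)
    effect_size: float = 2.0
    driver_cell_fraction: float = 1.0
    composition_effect: float = 0.0
    within_type_sd: float = 1.0
    between_type_sd: float = 1.0
    dropout_rate: float = 0.1
    annotation_noise: float = 0.0
    count_mode: bool = False
    nb_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.samples_per_class) or len(self.samples_per_class) < 2:
            raise ValueError("need at least two classes with at least one sample each")
        if self.n_cell_types < 1 or self.n_features < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.cells_per_sample
        if lo < 1 or hi < lo:
            raise ValueError("invalid cells_per_sample range")
        for r, name in [(self.dropout_rate, "dropout_rate"),
                        (self.annotation_noise, "annotation_noise"),
                        (self.driver_cell_fraction, "driver_cell_fraction")]:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dropout_rate >= 1.0:
            raise ValueError("dropout_rate 1 would leave samples without cells")
        if not set(self.driver_types) <= set(range(self.n_cell_types)):
            raise ValueError("driver_types must be valid cell-type indices")


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw one cohort; byte-identical for identical configs (seed included)."""
    rng = np.random.default_rng(config.seed)
    I, m = config.n_cell_types, config.n_features
    C = len(config.samples_per_class)
    # type centroids, fixed for the cohort
    centroids = rng.normal(0.0, config.between_type_sd, size=(I, m))
    driver = np.array(sorted(config.driver_types), dtype=int)

    samples = []
    s_id = 0
    for label, n_samples in enumerate(config.samples_per_class):
        for _ in range(n_samples):
            samples.append(_draw_sample(
                rng, config, centroids, driver, label, C, f"S{s_id:03d}"))
            s_id += 1
    return Cohort(
        samples=samples,
        n_cell_types=I,
        n_classes=C,
        cell_type_names=[f"type_{i}" for i in range(I)],
        class_names=[f"class_{c}" for c in range(C)],
    )


def _draw_sample(rng, config, centroids, driver, label, n_classes, sample_id) -> Sample:
    I, m = config.n_cell_types, config.n_features
    lo, hi = config.cells_per_sample
    N = int(rng.integers(lo, hi + 1))
    props = rng.dirichlet(np.full(I, config.dirichlet_concentration))
    # random type absence; keep at least the most abundant type
    drop = rng.random(I) < config.dropout_rate
    if drop.all():
        drop[np.argmax(props)] = False
    props = np.where(drop, 0.0, props)
    if label >= 1 and config.composition_effect != 0.0:
        tilt = np.zeros(I)
        tilt[driver] = config.composition_effect
        props = np.where(props > 0, props + tilt, 0.0)
        props = np.clip(props, 0.0, None)
    props = props / props.sum()
    counts = rng.multinomial(N, props)
    if counts.sum() == 0:  # degenerate multinomial cannot happen, but stay safe
        counts[np.argmax(props)] = N

    cell_types = np.repeat(np.arange(I), counts)
    X = centroids[cell_types] + rng.normal(0.0, config.within_type_sd, size=(counts.sum(), m))

    if label >= 1:
        # per-class magnitude: class c >= 1 carries c * delta / (C - 1); the
        # subset selection is drawn regardless of delta so that signal and
        # null cohorts with equal seeds share the same noise stream
        delta = config.effect_size * label / max(n_classes - 1, 1)
        for t in driver:
            idx = np.flatnonzero(cell_types == t)
            if idx.size == 0:
                continue
            k = math.ceil(config.driver_cell_fraction * idx.size)
            if k == 0:
                continue
            chosen = rng.choice(idx, size=k, replace=False)
            X[chosen] += delta

    if config.count_mode:
        # map to non-negative counts: NB with log-link around the Gaussian field
        mu = np.exp(X - X.mean())
        r = config.nb_dispersion
        X = rng.negative_binomial(r, r / (r + mu)).astype(float)

    if config.annotation_noise > 0.0:
        n_noisy = math.ceil(config.annotation_noise * len(cell_types))
        noisy = rng.choice(len(cell_types), size=n_noisy, replace=False)
        cell_types = cell_types.copy()
        cell_types[noisy] = rng.integers(0, I, size=n_noisy)

    return Sample(X=X, cell_types=cell_types, label=label, sample_id=sample_id)


def simulate_rare_driver(config: SimConfig, driver_cell_fraction: float = 0.1) -> Cohort:
    """Cohort whose class signal sits in a small subpopulation of the driver type.

    Equivalent to :func:`simulate_cohort` with ``driver_cell_fraction``
    overridden; at fraction 1.0 it reproduces the plain cohort for the same
    config, at fraction 0.0 the cohort carries no expression signal.
    """
    if driver_cell_fraction == 0.0:
        return simulate_cohort(replace(config, effect_size=0.0, driver_cell_fraction=0.0))
    return simulate_cohort(replace(config, driver_cell_fraction=driver_cell_fraction))


def hierarchical_signal_config(seed: int = 0) -> SimConfig:
    """Cohort where the cell-type annotation is the efficient route to the label.

    A weak shift (delta = 0.5, half the within-type noise scale) is spread
    over every driver-type cell, so no single cell is individually
    informative; the signal emerges only in the driver type's average.
    Pooling within the annotated type before attending across types matches
    this structure directly, whereas a flat softmax over all cells must
    recover the type grouping from the centroids on its own, and global mean
    pooling dilutes the driver average with the other types.
    """
    return SimConfig(
        samples_per_class=(30, 30),
        n_cell_types=5,
        n_features=30,
        cells_per_sample=(40, 80),
        effect_size=0.5,
        within_type_sd=1.0,
        between_type_sd=1.5,
        dropout_rate=0.1,
        seed=seed,
    )


def fixture_micro_cohort() -> Cohort:
    """Hard-coded 4-sample, 2-type, 3-feature cohort for hand-oracle tests.

    Sample S2 lacks cell type 1 entirely (exercises the absent-type masking);
    bag sizes range from 2 to 4 cells.
    """
    samples = [
        Sample(
            X=np.array([[0.5, -1.0, 2.0],
                        [1.5, 0.0, -0.5],
                        [-0.5, 1.0, 0.5]]),
            cell_types=np.array([0, 0, 1]),
            label=0,
            sample_id="S0",
        ),
        Sample(
            X=np.array([[2.0, 1.0, 0.0],
                        [0.0, -0.5, 1.0],
                        [1.0, 1.5, -1.0],
                        [-1.0, 0.5, 0.5]]),
            cell_types=np.array([0, 1, 1, 0]),
            label=1,
            sample_id="S1",
        ),
        Sample(
            X=np.array([[0.25, 0.75, -0.25],
                        [-0.75, 0.25, 1.25]]),
            cell_types=np.array([0, 0]),
            label=0,
            sample_id="S2",
        ),
        Sample(
            X=np.array([[1.0, -1.5, 0.5],
                        [0.5, 2.0, 1.0],
                        [-0.25, 0.0, -1.0]]),
            cell_types=np.array([1, 0, 1]),
            label=1,
            sample_id="S3",
        ),
    ]
    return Cohort(
        samples=samples,
        n_cell_types=2,
        n_classes=2,
        cell_type_names=["type_A", "type_B"],
        class_names=["control", "case"],
    )
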