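"""Bag-structured single-cell data containers.

A :class:`Sample` is one MIL bag: the cells of one patient sample, each cell a
feature vector (log-normalized expression or a precomputed embedding) with a
cell-type annotation, plus a single class label for the whole bag.  A
:class:`Cohort` is a list of samples sharing a cell-type vocabulary and class
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Sample", "Cohort"]


@dataclass
class Sample:
    """One labeled bag of annotated cells.

    Parameters
    ----------
    X
        Cell feature matrix, shape (n_cells, n_features).
    cell_types
        Integer cell-type index per cell, values in ``{0..I-1}``.
    label
        Class index of the sample, in ``{0..C-1}``.
    sample_id
        Unique identifier.
    """

    X: np.ndarray
    cell_types: np.ndarray
    label: int
    sample_id: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.cell_types = np.asarray(self.cell_types, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] < 1:
            raise ValueError(f"sample {self.sample_id!r}: X must be a non-empty 2-D matrix")
        if self.cell_types.shape != (self.X.shape[0],):
            raise ValueError(f"sample {self.sample_id!r}: one cell-type index per cell required")
        if not np.all(np.isfinite(self.X)):
            raise ValueError(f"sample {self.sample_id!r}: X contains non-finite entries")
        if self.cell_types.min() < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative cell-type index")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def type_counts(self, n_cell_types: int) -> np.ndarray:
        """Per-type cell counts n_i (length I); zero for absent types."""
        return np.bincount(self.cell_types, minlength=n_cell_types)

    def present_types(self, n_cell_types: int) -> np.ndarray:
        """Sorted indices of cell types with at least one cell."""
        return np.flatnonzero(self.type_counts(n_cell_types))


@dataclass
class Cohort:
    """Collection of samples sharing a cell-type vocabulary and class set."""

    samples: list[Sample]
    n_cell_types: int
    n_classes: int
    cell_type_names: list[str] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("cohort has no samples")
        if not self.cell_type_names:
            self.cell_type_names = [f"type_{i}" for i in range(self.n_cell_types)]
        if not self.class_names:
            self.class_names = [f"class_{c}" for c in range(self.n_classes)]
        if len(self.cell_type_names) != self.n_cell_types:
            raise ValueError("cell_type_names length does not match n_cell_types")
        if len(self.class_names) != self.n_classes:
            raise ValueError("class_names length does not match n_classes")
        m = self.samples[0].n_features
        for s in self.samples:
            if s.n_features != m:
                raise ValueError(f"sample {s.sample_id!r}: feature dimension mismatch")
            if s.cell_types.max() >= self.n_cell_types:
                raise ValueError(f"sample {s.sample_id!r}: cell-type index out of range")
            if not 0 <= s.label < self.n_classes:
                raise ValueError(f"sample {s.sample_id!r}: label {s.label} out of range")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def n_features(self) -> int:
        return self.samples[0].n_features

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset(self, indices) -> "Cohort":
        """Cohort restricted to the given sample indices (vocabularies kept)."""
        idx = np.asarray(indices, dtype=int)
        return Cohort(
            samples=[self.samples[i] for i in idx],
            n_cell_types=self.n_cell_types,
            n_classes=self.n_classes,
            cell_type_names=list(self.cell_type_names),
            class_names=list(self.class_names),
        )

    def with_labels(self, labels) -> "Cohort":
        """Same data with the sample labels replaced (used by permutation tests)."""
        labels = np.asarray(labels, dtype=int)
        if labels.shape != (len(self.samples),):
            raise ValueError("one label per sample required")
        return Cohort(
            samples=[replace(s, label=int(l)) for s, l in zip(self.samples, labels)],
            n_cell_types=self.n_cell_types,
            n_classes=self.n_classes,
            cell_type_names=list(self.cell_type_names),
            class_names=list(self.class_names),
        )
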