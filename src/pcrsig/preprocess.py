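"""Log transformation and quantile normalization.

Quantile normalization forces every sample (column) onto a common empirical
distribution by rank replacement. Two variants are provided:

* :func:`quantile_normalize` — classic joint normalization where the target
  distribution is the across-sample mean of sorted columns;
* :func:`align_to_reference` — reference-anchored normalization, where the
  target distribution (:class:`ReferenceQuantiles`) was frozen from a
  training cohort and each new sample is mapped onto it independently.
  This is the step that lets a classifier trained on one cohort be applied,
  without retraining, to batch-shifted external cohorts or even to a single
  new patient profile.

Ties within a column receive the mean of the reference values over the tied
rank positions (the standard convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import ExpressionMatrix

__all__ = [
    "ReferenceQuantiles",
    "log2_transform",
    "quantile_normalize",
    "reference_quantiles",
    "align_to_reference",
]


@dataclass
class ReferenceQuantiles:
    """A frozen target distribution: sorted vector, one entry per transcript."""

    values: np.ndarray
    n_source_samples: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("reference quantiles must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reference quantiles must be finite")
        if np.any(np.diff(self.values) < 0):
            raise ValueError("reference quantiles must be non-decreasing")

    def to_dict(self) -> dict:
        return {"values": self.values.tolist(), "n_source_samples": self.n_source_samples}

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceQuantiles":
        return cls(np.asarray(d["values"], dtype=float), int(d["n_source_samples"]))


def log2_transform(matrix: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Elementwise ``log2(value + offset)``; errors with coordinates if any
    argument is non-positive."""
    shifted = matrix.values + offset
    if np.any(shifted <= 0):
        r, c = np.argwhere(shifted <= 0)[0]
        raise ValueError(
            f"log2 of non-positive value at probe {matrix.probe_ids[r]!r}, "
            f"sample {matrix.sample_ids[c]!r}: {matrix.values[r, c]} + {offset}"
        )
    return matrix.with_values(np.log2(shifted))


def _replace_by_rank(column: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map a column onto ``reference`` by rank, averaging over ties."""
    order = np.argsort(column, kind="mergesort")
    sorted_vals = column[order]
    # runs of tied values share the mean of their reference positions
    is_start = np.empty(len(column), dtype=bool)
    is_start[0] = True
    is_start[1:] = sorted_vals[1:] != sorted_vals[:-1]
    starts = np.flatnonzero(is_start)
    counts = np.diff(np.append(starts, len(column)))
    run_means = np.add.reduceat(reference, starts) / counts
    assigned_sorted = np.repeat(run_means, counts)
    out = np.empty_like(column, dtype=float)
    out[order] = assigned_sorted
    return out


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Joint quantile normalization of all columns.

    After the transform every column's sorted values equal the across-column
    mean of sorted values; within-column rank order is preserved. A single
    column is returned unchanged (the mean of one sample is itself).
    """
    v = matrix.values
    ref = np.sort(v, axis=0).mean(axis=1)
    out = np.column_stack([_replace_by_rank(v[:, j], ref) for j in range(v.shape[1])])
    return matrix.with_values(out)


def reference_quantiles(matrix: ExpressionMatrix) -> ReferenceQuantiles:
    """Freeze the across-column mean of sorted values as a reference."""
    ref = np.sort(matrix.values, axis=0).mean(axis=1)
    return ReferenceQuantiles(ref, matrix.n_samples)


def align_to_reference(
    matrix: ExpressionMatrix, reference: ReferenceQuantiles
) -> ExpressionMatrix:
    """Map every column of ``matrix`` onto the frozen reference distribution.

    Each column is handled independently (per-sample rank replacement), so a
    single patient's profile can be aligned without access to the rest of the
    cohort.
    """
    ref = reference.values
    if len(ref) != matrix.n_probes:
        raise ValueError(
            f"reference length {len(ref)} != transcript count {matrix.n_probes}"
        )
    v = matrix.values
    out = np.column_stack([_replace_by_rank(v[:, j], ref) for j in range(v.shape[1])])
    return matrix.with_values(out)
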