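"""NODF nestedness of a binary incidence matrix.

NODF (nestedness metric based on overlap and decreasing fill) scores every
pair of rows and every pair of columns: if the better-filled member of the
pair strictly exceeds the other's fill (and the latter is non-empty), the
pair contributes 100 x (shared ones) / (fill of the sparser member);
otherwise it contributes 0. The matrix value is the mean contribution over
all n(n-1)/2 row pairs and m(m-1)/2 column pairs, on a 0-100 scale. Because
the decreasing-fill condition compares fills rather than positions, NODF is
invariant under row/column permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix_core import IncidenceMatrix

__all__ = ["NestednessResult", "nodf", "sort_by_marginals"]


@dataclass(frozen=True)
class NestednessResult:
    nodf_rows: float
    nodf_cols: float
    nodf_total: float
    n_row_pairs: int
    n_col_pairs: int


def _axis_scores(a: np.ndarray) -> tuple[float, int]:
    """Sum of paired NODF scores over all unordered row pairs of ``a``."""
    fills = a.sum(axis=1)
    shared = a @ a.T
    n = a.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    fi, fj = fills[iu], fills[ju]
    fmin = np.minimum(fi, fj)
    valid = (fi != fj) & (fmin > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(valid, 100.0 * shared[iu, ju] / np.maximum(fmin, 1), 0.0)
    return float(scores.sum()), len(iu)


def nodf(m: IncidenceMatrix | np.ndarray) -> NestednessResult:
    """Compute NODF for a binary matrix.

    Accepts an :class:`IncidenceMatrix` or a plain 0/1 array. A degenerate
    all-zero matrix scores 0 with a warning.
    """
    a = m.entries if isinstance(m, IncidenceMatrix) else np.asarray(m)
    a = (a > 0).astype(np.int64)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("NODF requires a 2-D matrix with >=2 rows and columns")
    if a.sum() == 0:
        warnings.warn("all-zero matrix: NODF defined as 0", stacklevel=2)
    row_sum, n_row_pairs = _axis_scores(a)
    col_sum, n_col_pairs = _axis_scores(a.T)
    return NestednessResult(
        nodf_rows=row_sum / n_row_pairs,
        nodf_cols=col_sum / n_col_pairs,
        nodf_total=(row_sum + col_sum) / (n_row_pairs + n_col_pairs),
        n_row_pairs=n_row_pairs,
        n_col_pairs=n_col_pairs,
    )


def nodf_total(m: IncidenceMatrix | np.ndarray) -> float:
    """Convenience scalar statistic (e.g. for null-model testing)."""
    return nodf(m).nodf_total


def sort_by_marginals(m: IncidenceMatrix) -> IncidenceMatrix:
    """Reorder rows and columns by decreasing fill (ties keep original
    order). Purely cosmetic: NODF is permutation-invariant."""
    row_order = np.argsort(-m.entries.sum(axis=1), kind="stable")
    col_order = np.argsort(-m.entries.sum(axis=0), kind="stable")
    return IncidenceMatrix(
        m.entries[np.ix_(row_order, col_order)],
        [m.host_ids[i] for i in row_order],
        [m.phage_ids[j] for j in col_order],
    )
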