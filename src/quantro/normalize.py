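"""Global-adjustment normalizers and the test-guided selector.

Quantile normalization forces every sample onto one reference distribution
(the rank-wise mean of the per-sample order statistics); median
normalization removes per-sample location shifts; spike-in scaling divides
each sample by the mean of its spike-in control probes on the log2 scale.
``quantro_guided_normalize`` runs the distribution test first and applies
quantile normalization only when the test does not detect global
between-group differences (otherwise the data pass through unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import DataError, FeatureMatrix
from .permtest import QuantroResults, QuantroTest

__all__ = [
    "NormalizedMatrix",
    "quantile_normalize",
    "median_normalize",
    "spike_in_normalize",
    "quantro_guided_normalize",
]


@dataclass
class NormalizedMatrix:
    """Normalized values plus the method and (for QN) the reference used."""

    matrix: FeatureMatrix
    method: str  # "quantile" | "median" | "spike_in" | "none"
    reference: np.ndarray | None = None

    @property
    def values(self) -> np.ndarray:
        return self.matrix.values


def quantile_normalize(matrix: FeatureMatrix, tie_mode: str = "stable") -> NormalizedMatrix:
    """Quantile-normalize all samples to the rank-wise mean reference.

    (1) order values within each sample, (2) average across samples at each
    rank, (3) substitute each value with the average at its rank, (4) restore
    the original row order. ``tie_mode="stable"`` (default) breaks ties by
    original row order via a stable sort, so every column's multiset equals
    the reference exactly; ``tie_mode="average"`` assigns tied raw values the
    mean of the reference values spanning their tied ranks (parity with
    common implementations, at the cost of the multiset invariant when ties
    exist).
    """
    if tie_mode not in ("stable", "average"):
        raise DataError(f"unknown tie_mode {tie_mode!r}; use 'stable' or 'average'")
    if matrix.n_samples < 2:
        raise DataError("quantile normalization needs >= 2 samples to average across")
    X = matrix.values
    order = np.argsort(X, axis=0, kind="stable")
    sorted_cols = np.take_along_axis(X, order, axis=0)
    if np.all(sorted_cols[:, 1:] == sorted_cols[:, :1]):
        # already a common distribution: averaging identical columns would
        # perturb the last bit, so take the shared column as the reference
        # (makes repeated normalization an exact fixed point)
        reference = sorted_cols[:, 0].copy()
    else:
        reference = sorted_cols.mean(axis=1)
    out = np.empty_like(X)
    np.put_along_axis(out, order, reference[:, None], axis=0)
    if tie_mode == "average":
        for j in range(X.shape[1]):
            _, inv = np.unique(X[:, j], return_inverse=True)
            sums = np.bincount(inv, weights=out[:, j])
            counts = np.bincount(inv)
            out[:, j] = (sums / counts)[inv]
    return NormalizedMatrix(matrix.with_values(out), "quantile", reference=reference)


def median_normalize(matrix: FeatureMatrix) -> NormalizedMatrix:
    """Shift each sample so its median equals the mean of the original
    per-sample medians (keeps the data on their original scale)."""
    X = matrix.values
    med = np.median(X, axis=0)
    target = med.mean()
    return NormalizedMatrix(matrix.with_values(X + (target - med)), "median")


def spike_in_normalize(matrix: FeatureMatrix, spike_in_rows: Sequence) -> NormalizedMatrix:
    """Scale each sample by its spike-in controls on the log2 scale.

    ``spike_in_rows`` may be feature ids or integer row indices. All raw
    values must be positive. Each column's log2 values have the column mean
    of the spike-in rows subtracted (equivalently, raw values are divided by
    a geometric-mean-based spike-in factor); output stays on the log2 scale.
    """
    rows = list(spike_in_rows)
    if len(rows) == 0:
        raise DataError("spike_in_rows must be non-empty")
    if all(isinstance(r, (int, np.integer)) for r in rows):
        idx = np.asarray(rows, dtype=np.intp)
        if idx.min() < 0 or idx.max() >= matrix.n_features:
            raise DataError("spike-in row index out of range")
    else:
        lookup = {fid: i for i, fid in enumerate(matrix.feature_ids)}
        missing = [str(r) for r in rows if str(r) not in lookup]
        if missing:
            raise DataError(f"unknown spike-in feature ids: {missing[:5]}")
        idx = np.asarray([lookup[str(r)] for r in rows], dtype=np.intp)
    X = matrix.values
    if np.any(X <= 0):
        raise DataError("spike-in scaling requires strictly positive raw values")
    L = np.log2(X)
    factors = L[idx, :].mean(axis=0)
    return NormalizedMatrix(matrix.with_values(L - factors), "spike_in")


def quantro_guided_normalize(
    matrix: FeatureMatrix,
    n_permutations: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[NormalizedMatrix, QuantroResults]:
    """Run the distribution test, then quantile-normalize only if safe.

    If the permutation p-value is >= ``alpha`` (no global between-group
    differences detected) the matrix is quantile normalized; otherwise the
    values pass through unchanged (method ``"none"``) -- compose
    :func:`median_normalize` explicitly if a location-only adjustment is
    still wanted. Both the chosen matrix and the test result are returned.
    """
    result = QuantroTest(matrix).fit(
        n_permutations=n_permutations, seed=seed, alpha=alpha, **fit_kwargs
    )
    if result.perm_p >= alpha:
        return quantile_normalize(matrix), result
    return NormalizedMatrix(matrix.with_values(matrix.values.copy()), "none"), result
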