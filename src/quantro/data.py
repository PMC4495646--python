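"""Grouped feature-matrix container shared by the test, the normalizers and
the simulator.

A :class:`FeatureMatrix` holds a features x samples array of raw measurements
(intensities, PM values, beta values -- the units are arbitrary) together
with feature/sample identifiers and an optional group factor. The group
factor is what the distribution test operates on; normalizers that act
per-sample (quantile, median, spike-in) do not require it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["DataError", "FeatureMatrix"]


class DataError(ValueError):
    """Raised when an input matrix or group assignment is malformed."""


def _as_str_list(ids: Sequence, n: int, what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(ids) != n:
        raise DataError(f"expected {n} {what}, got {len(ids)}")
    seen = set()
    for x in ids:
        if x in seen:
            raise DataError(f"duplicate {what.rstrip('s')} id: {x!r}")
        seen.add(x)
    return ids


@dataclass
class FeatureMatrix:
    """Features x samples numeric matrix with identifiers and a group factor.

    Parameters
    ----------
    values : ndarray, shape (n_features, n_samples)
        Raw measurements. Must be finite after ingest (see ``drop_na``).
    feature_ids, sample_ids : sequence of str
        Unique row / column identifiers.
    groups : sequence, optional
        One categorical label per sample. Required by the distribution test
        and the evaluation harness; optional for per-sample normalizers.
    drop_na : bool
        If True, rows containing non-finite values are dropped (with a
        logged count) instead of raising.
    """

    values: np.ndarray
    feature_ids: list[str] = field(default=None)  # type: ignore[assignment]
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    groups: np.ndarray | None = None
    drop_na: bool = False

    def __post_init__(self) -> None:
        X = np.asarray(self.values, dtype=float)
        if X.ndim != 2:
            raise DataError(f"values must be 2-D (features x samples), got ndim={X.ndim}")
        n, m = X.shape
        if self.feature_ids is None:
            self.feature_ids = [f"feature_{i + 1}" for i in range(n)]
        if self.sample_ids is None:
            self.sample_ids = [f"sample_{j + 1}" for j in range(m)]
        self.feature_ids = _as_str_list(self.feature_ids, n, "features")
        self.sample_ids = _as_str_list(self.sample_ids, m, "samples")

        bad = ~np.isfinite(X)
        if bad.any():
            if self.drop_na:
                bad_rows = bad.any(axis=1)
                logger.info("dropping %d rows with non-finite values", int(bad_rows.sum()))
                X = X[~bad_rows]
                self.feature_ids = [f for f, b in zip(self.feature_ids, bad_rows) if not b]
            else:
                i, j = np.argwhere(bad)[0]
                raise DataError(
                    "non-finite value at feature "
                    f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r} "
                    "(pass drop_na=True to drop such rows)"
                )
        if X.shape[0] < 2:
            raise DataError(f"need at least 2 features, got {X.shape[0]}")
        self.values = X

        if self.groups is not None:
            g = np.asarray(self.groups, dtype=object)
            if g.shape != (m,):
                raise DataError(
                    f"groups must assign one label per sample ({m}), got shape {g.shape}"
                )
            self.groups = g
            codes, levels = pd.factorize(g)  # level order = order of appearance
            self._codes = codes.astype(np.intp)
            self._levels = list(levels)
        else:
            self._codes = None
            self._levels = None

    # ------------------------------------------------------------------ #
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def group_levels(self) -> list:
        """Distinct group labels in order of first appearance."""
        self.require_groups(min_levels=1)
        return list(self._levels)

    @property
    def group_codes(self) -> np.ndarray:
        """Integer code per sample into :attr:`group_levels`."""
        self.require_groups(min_levels=1)
        return self._codes

    @property
    def n_groups(self) -> int:
        return len(self.group_levels)

    @property
    def group_sizes(self) -> np.ndarray:
        """Samples per group, ordered as :attr:`group_levels`."""
        return np.bincount(self.group_codes, minlength=self.n_groups)

    def group_columns(self) -> list[np.ndarray]:
        """Column-index arrays, one per group level."""
        codes = self.group_codes
        return [np.flatnonzero(codes == k) for k in range(self.n_groups)]

    # ------------------------------------------------------------------ #
    def require_groups(self, min_levels: int = 2) -> None:
        if self.groups is None:
            raise DataError("this operation requires a group assignment")
        if len(self._levels) < min_levels:
            raise DataError(
                f"K >= {min_levels} groups required, got {len(self._levels)}"
            )

    def with_values(self, new_values: np.ndarray) -> "FeatureMatrix":
        """Copy of this matrix with ``values`` replaced (same ids/groups)."""
        return FeatureMatrix(
            np.asarray(new_values, dtype=float),
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            groups=None if self.groups is None else self.groups.copy(),
        )

    def with_groups(self, groups: Sequence) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(),
            feature_ids=list(self.feature_ids),
            sample_ids=list(self.sample_ids),
            groups=np.asarray(list(groups), dtype=object),
        )

    # ------------------------------------------------------------------ #
    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, groups: Sequence | None = None, drop_na: bool = False
    ) -> "FeatureMatrix":
        """Build from a features x samples DataFrame (index = feature ids)."""
        return cls(
            df.to_numpy(dtype=float),
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            groups=None if groups is None else np.asarray(list(groups), dtype=object),
            drop_na=drop_na,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g = "ungrouped" if self.groups is None else f"{self.n_groups} groups"
        return f"<FeatureMatrix {self.n_features} features x {self.n_samples} samples, {g}>"
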