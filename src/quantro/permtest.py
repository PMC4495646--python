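"""Permutation F-test for global differences in distributions between groups.

The null hypothesis is that every group shares one distribution; the
alternative is that at least one group's distribution differs globally
(shape or spread -- pure location shifts are absorbed by per-sample median
centering and reported separately via an ANOVA on sample medians). The test
statistic is

    F = MS_between / MS_within
      = (SS_between / (K - 1)) / (SS_within / (n_T - K))

where the sums of squares are Mallows-distance dispersions of the sample
quantile functions (see :mod:`quantro.quantiles`). Significance is assessed
by permuting group labels: either B uniform random relabelings with the
add-one p-value (1 + #{F_b >= F_obs}) / (B + 1), or exhaustively over all
distinct label assignments (identity included, raw proportion).

A small p-value indicates global distributional differences between groups,
in which case global-adjustment normalization (e.g. quantile normalization)
would remove signal along with technical variation and may be inappropriate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError, FeatureMatrix
from .quantiles import QuantileSet, empirical_quantile_set, ss_decompose

__all__ = ["MedianAnovaResult", "QuantroResults", "QuantroTest", "f_quantro", "median_anova"]


# --------------------------------------------------------------------------- #
# median ANOVA diagnostic
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class MedianAnovaResult:
    """One-way fixed-effects ANOVA on the per-sample medians.

    ``degenerate`` flags zero within-group variance of the medians, where
    the F statistic is +inf (between-variance > 0) or 0 (all medians equal).
    """

    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False


def median_anova(matrix: FeatureMatrix) -> MedianAnovaResult:
    """Test whether the average of the per-sample medians differs across
    groups (location diagnostic accompanying the distribution test)."""
    matrix.require_groups()
    K = matrix.n_groups
    n_t = matrix.n_samples
    if n_t <= K:
        raise DataError(f"median ANOVA needs n_T > K (got n_T={n_t}, K={K})")
    med = np.median(matrix.values, axis=0)
    grand = med.mean()
    ssb = 0.0
    ssw = 0.0
    for cols in matrix.group_columns():
        m = med[cols]
        ssb += m.size * (m.mean() - grand) ** 2
        ssw += float(((m - m.mean()) ** 2).sum())
    dfb, dfw = K - 1, n_t - K
    if ssw == 0.0:
        if ssb > 0.0:
            return MedianAnovaResult(np.inf, 0.0, dfb, dfw, degenerate=True)
        return MedianAnovaResult(0.0, 1.0, dfb, dfw, degenerate=True)
    f = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return MedianAnovaResult(float(f), p, dfb, dfw)


# --------------------------------------------------------------------------- #
# results container
# --------------------------------------------------------------------------- #
@dataclass
class QuantroResults:
    """Fitted results of the distribution test.

    Carries the ANOVA-style decomposition of the quantile-function
    dispersion (squared measurement units), the F statistic, the median
    ANOVA diagnostic, and -- when a permutation test was run -- the
    permutation p-value and null draws.
    """

    ss_total: float
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    f_quantro: float
    median_anova: MedianAnovaResult
    n_features: int
    n_samples: int
    group_levels: list
    group_sizes: np.ndarray
    alpha: float = 0.05
    perm_p: float | None = None
    n_permutations: int | None = None
    perm_stats: np.ndarray | None = None
    exhaustive: bool = False
    seed: int | None = None
    quantile_set: QuantileSet | None = field(default=None, repr=False)

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within

    @property
    def n_groups(self) -> int:
        return len(self.group_levels)

    @property
    def global_differences(self) -> bool | None:
        """Whether the test rejects at ``alpha`` (None without permutations)."""
        if self.perm_p is None:
            return None
        return bool(self.perm_p < self.alpha)

    # ------------------------------------------------------------------ #
    def summary(self) -> str:
        k_desc = ", ".join(
            f"{lvl}: {n}" for lvl, n in zip(self.group_levels, self.group_sizes)
        )
        lines = [
            "          Test for global differences in distributions",
            "=" * 64,
            f"No. features: {self.n_features}   No. samples: {self.n_samples}   "
            f"Groups: {self.n_groups} ({k_desc})",
            "-" * 64,
            f"{'':<14}{'SS':>14}{'df':>6}{'MS':>14}",
            f"{'Between':<14}{self.ss_between:>14.6g}{self.df_between:>6}{self.ms_between:>14.6g}",
            f"{'Within':<14}{self.ss_within:>14.6g}{self.df_within:>6}{self.ms_within:>14.6g}",
            f"{'Total':<14}{self.ss_total:>14.6g}",
            "-" * 64,
            f"F_quantro: {self.f_quantro:.6g}",
            f"ANOVA on sample medians: F = {self.median_anova.f_stat:.6g}, "
            f"p = {self.median_anova.p_value:.4g}"
            + ("  [degenerate]" if self.median_anova.degenerate else ""),
        ]
        if self.perm_p is not None:
            mode = "exhaustive" if self.exhaustive else "random"
            lines += [
                f"Permutation test ({mode}, B = {self.n_permutations}): "
                f"p = {self.perm_p:.4g}  (alpha = {self.alpha:g})",
                "Global differences detected: "
                + ("yes -- global-adjustment normalization may be inappropriate"
                   if self.global_differences else "no"),
            ]
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_dict(self, include_perm_stats: bool = False) -> dict:
        d = {
            "ss_total": self.ss_total,
            "ss_between": self.ss_between,
            "ss_within": self.ss_within,
            "ms_between": self.ms_between,
            "ms_within": self.ms_within,
            "f_quantro": self.f_quantro,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "median_anova": {
                "f_stat": self.median_anova.f_stat,
                "p_value": self.median_anova.p_value,
                "degenerate": self.median_anova.degenerate,
            },
            "n_features": self.n_features,
            "n_samples": self.n_samples,
            "group_levels": [str(x) for x in self.group_levels],
            "group_sizes": [int(x) for x in self.group_sizes],
            "alpha": self.alpha,
            "perm_p": self.perm_p,
            "n_permutations": self.n_permutations,
            "exhaustive": self.exhaustive,
            "seed": self.seed,
            "global_differences": self.global_differences,
        }
        if include_perm_stats and self.perm_stats is not None:
            d["perm_stats"] = [float(x) for x in self.perm_stats]
        return d

    def plot_permutations(self, ax=None, bins: int = 30):
        """Histogram of the permutation null with the observed F marked."""
        if self.perm_stats is None:
            raise DataError("no permutation draws stored; run fit() first")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        finite = self.perm_stats[np.isfinite(self.perm_stats)]
        ax.hist(finite, bins=bins, color="0.7", edgecolor="0.4")
        if np.isfinite(self.f_quantro):
            ax.axvline(self.f_quantro, color="crimson", lw=2, label="observed F")
            ax.legend()
        ax.set_xlabel("permutation F")
        ax.set_ylabel("count")
        ax.set_title(f"permutation null (p = {self.perm_p:.3g})")
        return ax


# --------------------------------------------------------------------------- #
# internal machinery
# --------------------------------------------------------------------------- #
def _f_ratio(ssb: float, ssw: float, dfb: int, dfw: int) -> float:
    # Degenerate conventions: no within-variance with between-variance ->
    # +inf (counted >= any permuted F); no variance at all -> 0.
    msb = ssb / dfb
    msw = ssw / dfw
    if msw == 0.0:
        return np.inf if msb > 0.0 else 0.0
    return msb / msw


def _ss_noise_floor(S: np.ndarray) -> float:
    # Averaging identical columns perturbs the last bit, leaving SS terms of
    # order eps^2 * scale; anything below this floor is numerically zero.
    eps = np.finfo(float).eps
    return 16.0 * eps**2 * float(np.mean(S * S)) * S.shape[1]


def _f_for_column_groups(S: np.ndarray, col_groups: list[np.ndarray], dfb: int, dfw: int) -> float:
    """F statistic for sorted-centered matrix S under a column partition."""
    g = S.mean(axis=1)
    ssb = 0.0
    ssw = 0.0
    for cols in col_groups:
        block = S[:, cols]
        gm = block.mean(axis=1)
        ssb += cols.size * float(np.mean((gm - g) ** 2))
        ssw += float(np.mean((block - gm[:, None]) ** 2, axis=0).sum())
    floor = _ss_noise_floor(S)
    if ssb < floor:
        ssb = 0.0
    if ssw < floor:
        ssw = 0.0
    return _f_ratio(ssb, ssw, dfb, dfw)


def _distinct_permutations(codes: Sequence[int]):
    """Yield all distinct orderings of a label multiset (lexicographic)."""
    a = sorted(codes)
    n = len(a)
    while True:
        yield tuple(a)
        i = n - 2
        while i >= 0 and a[i] >= a[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while a[j] <= a[i]:
            j -= 1
        a[i], a[j] = a[j], a[i]
        a[i + 1:] = a[i + 1:][::-1]


def _n_distinct_assignments(sizes: np.ndarray) -> int:
    total = int(sizes.sum())
    n = 1
    for s in sizes:
        n *= comb(total, int(s))
        total -= int(s)
    return n


def _codes_to_column_groups(codes: np.ndarray, K: int) -> list[np.ndarray]:
    return [np.flatnonzero(codes == k) for k in range(K)]


# --------------------------------------------------------------------------- #
# the model
# --------------------------------------------------------------------------- #
class QuantroTest:
    """Model object for the grouped distribution test.

    Parameters
    ----------
    data : FeatureMatrix, DataFrame or ndarray
        Features x samples measurements. A :class:`FeatureMatrix` carries its
        own group factor; otherwise pass ``groups``.
    groups : sequence, optional
        One label per sample (K >= 2 levels).
    median_center : bool
        Subtract each sample's median before computing quantile functions
        (default True; makes the statistic location-invariant, with the
        median ANOVA reported as the location diagnostic).

    Examples
    --------
    >>> test = QuantroTest(values, groups=["A"] * 5 + ["B"] * 5)
    >>> res = test.fit(n_permutations=100, seed=1)
    >>> print(res.summary())
    """

    def __init__(self, data, groups: Sequence | None = None, *, median_center: bool = True):
        if isinstance(data, FeatureMatrix):
            fm = data if groups is None else data.with_groups(groups)
        elif isinstance(data, pd.DataFrame):
            fm = FeatureMatrix.from_dataframe(data, groups=groups)
        else:
            fm = FeatureMatrix(np.asarray(data, dtype=float),
                               groups=None if groups is None else np.asarray(list(groups), dtype=object))
        fm.require_groups()
        if fm.n_samples <= fm.n_groups:
            raise DataError(
                f"n_T > K required for within-group degrees of freedom "
                f"(n_T={fm.n_samples}, K={fm.n_groups})"
            )
        self.data = fm
        self.median_center = median_center
        self._qs: QuantileSet | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, groups: Sequence, **kwargs) -> "QuantroTest":
        return cls(df, groups=groups, **kwargs)

    # ------------------------------------------------------------------ #
    @property
    def quantile_set(self) -> QuantileSet:
        if self._qs is None:
            self._qs = empirical_quantile_set(self.data, median_center=self.median_center)
        return self._qs

    def statistic(self, alpha: float = 0.05) -> QuantroResults:
        """Observed statistic and decomposition, without a permutation test."""
        qs = self.quantile_set
        sst, ssb, ssw = ss_decompose(qs)
        floor = _ss_noise_floor(qs.sample_qfs)
        sst, ssb, ssw = (0.0 if x < floor else x for x in (sst, ssb, ssw))
        dfb = self.data.n_groups - 1
        dfw = self.data.n_samples - self.data.n_groups
        return QuantroResults(
            ss_total=sst,
            ss_between=ssb,
            ss_within=ssw,
            df_between=dfb,
            df_within=dfw,
            f_quantro=_f_ratio(ssb, ssw, dfb, dfw),
            median_anova=median_anova(self.data),
            n_features=self.data.n_features,
            n_samples=self.data.n_samples,
            group_levels=self.data.group_levels,
            group_sizes=self.data.group_sizes,
            alpha=alpha,
            quantile_set=qs,
        )

    def fit(
        self,
        n_permutations: int = 1000,
        seed: int | None = None,
        *,
        alpha: float = 0.05,
        exhaustive: bool = False,
        n_workers: int = 1,
        max_exhaustive: int = 100_000,
        keep_perm_stats: bool = True,
    ) -> QuantroResults:
        """Run the permutation test and return fitted results.

        Random mode draws ``n_permutations`` uniform relabelings preserving
        group sizes (duplicates allowed) and uses the add-one p-value;
        exhaustive mode enumerates every distinct assignment (identity
        included) and uses the exact proportion. Permutations are
        pre-generated from ``seed`` before any parallel dispatch, so the
        p-value is identical for any ``n_workers``.
        """
        fm = self.data
        sizes = fm.group_sizes
        if np.sum(sizes >= 2) < 2:
            raise DataError(
                "permutation test requires at least two groups with n_k >= 2"
            )
        if n_permutations < 1:
            raise DataError("n_permutations must be >= 1")

        res = self.statistic(alpha=alpha)
        f_obs = res.f_quantro
        S = self.quantile_set.sample_qfs
        K = fm.n_groups
        dfb, dfw = res.df_between, res.df_within
        codes = fm.group_codes

        if exhaustive:
            n_assign = _n_distinct_assignments(sizes)
            if n_assign > max_exhaustive:
                raise DataError(
                    f"{n_assign} distinct assignments exceed the exhaustive cap "
                    f"({max_exhaustive}); use random permutations instead"
                )
            partitions = [
                _codes_to_column_groups(np.asarray(perm, dtype=np.intp), K)
                for perm in _distinct_permutations(codes.tolist())
            ]
        else:
            rng = np.random.default_rng(seed)
            partitions = [
                _codes_to_column_groups(rng.permutation(codes), K)
                for _ in range(n_permutations)
            ]

        if n_workers > 1:
            from joblib import Parallel, delayed

            chunks = np.array_split(np.arange(len(partitions)), n_workers)
            parts = Parallel(n_jobs=n_workers)(
                delayed(_eval_chunk)(S, [partitions[i] for i in idx], dfb, dfw)
                for idx in chunks if idx.size
            )
            perm_stats = np.concatenate(parts)
        else:
            perm_stats = _eval_chunk(S, partitions, dfb, dfw)

        exceed = int(np.sum(perm_stats >= f_obs))  # ties count as exceedances
        if exhaustive:
            perm_p = exceed / len(perm_stats)
            n_perm = len(perm_stats)
        else:
            perm_p = (1 + exceed) / (n_permutations + 1)
            n_perm = n_permutations

        res.perm_p = float(perm_p)
        res.n_permutations = n_perm
        res.perm_stats = perm_stats if keep_perm_stats else None
        res.exhaustive = exhaustive
        res.seed = seed
        return res


def _eval_chunk(S: np.ndarray, partitions, dfb: int, dfw: int) -> np.ndarray:
    return np.array([_f_for_column_groups(S, p, dfb, dfw) for p in partitions])


def f_quantro(data, groups: Sequence | None = None, median_center: bool = True) -> QuantroResults:
    """Convenience: observed F statistic (no permutation test)."""
    return QuantroTest(data, groups=groups, median_center=median_center).statistic()
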