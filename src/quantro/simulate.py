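"""Simulator for two-group DNA methylation microarray experiments.

Ground truth is a methylation proportion per CpG per group, with a
configurable fraction of differentially methylated (DM) CpGs. Observation
passes the per-sample methylated / unmethylated target concentrations
through a Langmuir adsorption model of probe hybridization (optical
background + saturating specific binding), multiplies in per-sample
per-channel scale factors (scanner/dye gain -- the "technical variation"
knob) and multiplicative log-normal probe noise, and forms observed beta
values as meth / (meth + unmeth + offset) with the platform-default
offset of 100.

Truth distribution defaults (three-mode hypo/hemi/hyper baseline mixture,
uniform |effect| in [0.2, 0.4] with random sign, clipping to (0.02, 0.98))
are exposed in the function signatures and the YAML config; see
docs/methods.md for the rationale behind each default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

import numpy as np

from .data import DataError, FeatureMatrix

__all__ = [
    "LangmuirParams",
    "MethylTruth",
    "SimulatedArraySet",
    "simulate_truth",
    "langmuir_intensity",
    "simulate_arrays",
]


@dataclass(frozen=True)
class LangmuirParams:
    """Hybridization model parameters.

    baseline
        Optical background intensity at zero target concentration
        (fluorescence units).
    saturation
        Maximum specific-hybridization intensity above baseline.
    affinity
        Half-saturation concentration (same units as concentration): the
        specific signal is saturation * c / (c + affinity).
    noise_sd
        Log-scale sd of multiplicative log-normal probe-level noise.
    sample_scale_sd
        Log-scale sd of the per-sample, per-channel scale factors; this is
        the level of technical variation between arrays.
    """

    baseline: float = 500.0
    saturation: float = 10_000.0
    affinity: float = 10_000.0
    noise_sd: float = 0.05
    sample_scale_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("baseline", "saturation", "noise_sd", "sample_scale_sd"):
            if getattr(self, name) < 0:
                raise DataError(f"LangmuirParams.{name} must be >= 0")
        if self.affinity <= 0:
            raise DataError("LangmuirParams.affinity must be > 0")


@dataclass(frozen=True)
class MethylTruth:
    """Ground-truth methylation proportions for a two-group design."""

    true_beta: np.ndarray  # (n_cpgs, 2) in (0, 1)
    dm_mask: np.ndarray  # bool, (n_cpgs,)
    dm_delta: np.ndarray  # signed group2 - group1 difference; 0 off-mask
    pi_dm: float
    cpg_ids: list[str] = field(default_factory=list)

    @property
    def n_cpgs(self) -> int:
        return self.true_beta.shape[0]


def simulate_truth(
    n_cpgs: int,
    pi_dm: float,
    effect_size: tuple[float, float] = (0.2, 0.4),
    seed: int | None = None,
    *,
    mode_means: Sequence[float] = (0.1, 0.5, 0.9),
    mode_weights: Sequence[float] = (0.4, 0.2, 0.4),
    mode_sd: float = 0.05,
    clip: tuple[float, float] = (0.02, 0.98),
) -> MethylTruth:
    """Draw ground-truth group methylation proportions.

    Baseline (shared) proportions come from a three-component mixture of
    hypo-, hemi- and hyper-methylated modes with Gaussian within-mode
    jitter, clipped into ``clip``. A uniformly chosen ``ceil(pi_dm *
    n_cpgs)`` subset of CpGs is differentially methylated: group 2's
    proportion is shifted by ``|delta| ~ U(effect_size)`` with random sign
    (sign flipped deterministically if clipping would annihilate the
    effect). Exactly reproducible per ``seed``.
    """
    if n_cpgs < 1:
        raise DataError("n_cpgs must be >= 1")
    if not (0.0 <= pi_dm <= 1.0):
        raise DataError(f"pi_dm must lie in [0, 1], got {pi_dm}")
    lo, hi = clip
    if not (0.0 < lo < hi < 1.0):
        raise DataError("clip bounds must satisfy 0 < lo < hi < 1")
    rng = np.random.default_rng(seed)

    comp = rng.choice(len(mode_means), size=n_cpgs, p=np.asarray(mode_weights, float))
    base = np.asarray(mode_means, float)[comp] + rng.normal(0.0, mode_sd, n_cpgs)
    base = np.clip(base, lo, hi)

    n_dm = ceil(pi_dm * n_cpgs)
    dm_mask = np.zeros(n_cpgs, dtype=bool)
    g2 = base.copy()
    if n_dm > 0:
        dm_idx = rng.choice(n_cpgs, size=n_dm, replace=False)
        dm_mask[dm_idx] = True
        mag = rng.uniform(effect_size[0], effect_size[1], n_dm)
        sign = rng.choice([-1.0, 1.0], size=n_dm)
        shifted = np.clip(base[dm_idx] + sign * mag, lo, hi)
        # a clip against the boundary can erase the effect; flip the sign
        # toward the interior so every masked CpG keeps a nonzero delta
        dead = np.abs(shifted - base[dm_idx]) < 1e-9
        if dead.any():
            shifted[dead] = np.clip(base[dm_idx][dead] - sign[dead] * mag[dead], lo, hi)
        g2[dm_idx] = shifted

    dm_delta = g2 - base
    return MethylTruth(
        true_beta=np.column_stack([base, g2]),
        dm_mask=dm_mask,
        dm_delta=dm_delta,
        pi_dm=float(pi_dm),
        cpg_ids=[f"cpg_{i + 1}" for i in range(n_cpgs)],
    )


def langmuir_intensity(concentration, params: LangmuirParams, noise_draw=0.0) -> np.ndarray:
    """Hybridization intensity for a target concentration.

    The noiseless mean is ``baseline + saturation * c / (c + affinity)``
    (monotone, saturating); the returned value is ``mean * exp(noise_draw)``.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise DataError("concentration must be >= 0")
    mean = params.baseline + params.saturation * c / (c + params.affinity)
    return mean * np.exp(noise_draw)


@dataclass(frozen=True)
class SimulatedArraySet:
    """Simulated channel intensities and observed betas for one experiment."""

    meth: np.ndarray  # (n_cpgs, n_T), fluorescence units
    unmeth: np.ndarray
    beta_observed: np.ndarray  # in [0, 1)
    groups: np.ndarray  # label per sample
    sample_ids: list[str]
    truth: MethylTruth
    seed: int | None
    offset: float = 100.0

    def to_feature_matrix(self, channel: str = "beta") -> FeatureMatrix:
        """Package one channel as a grouped :class:`FeatureMatrix`."""
        values = {"beta": self.beta_observed, "meth": self.meth, "unmeth": self.unmeth}
        if channel not in values:
            raise DataError(f"unknown channel {channel!r}")
        return FeatureMatrix(
            values[channel].copy(),
            feature_ids=list(self.truth.cpg_ids),
            sample_ids=list(self.sample_ids),
            groups=self.groups.copy(),
        )


def simulate_arrays(
    truth: MethylTruth,
    n_per_group: int = 5,
    total_molecules: float = 10_000.0,
    params: LangmuirParams | None = None,
    seed: int | None = None,
    *,
    bio_jitter_sd: float = 0.01,
    offset: float = 100.0,
    group_labels: tuple[str, str] = ("A", "B"),
) -> SimulatedArraySet:
    """Hybridize ground truth into observed two-channel array data.

    Per sample, the methylated target concentration is ``total_molecules *
    beta`` and the unmethylated one ``total_molecules * (1 - beta)``, where
    ``beta`` adds per-sample biological jitter (sd ``bio_jitter_sd`` on the
    proportion scale) around the group mean. Both channels pass through the
    Langmuir model with independent per-sample per-channel scale factors
    (log-normal, sd ``params.sample_scale_sd``) and probe-level log-normal
    noise (sd ``params.noise_sd``). Observed betas use the given offset.
    Fully seed-reproducible.
    """
    if n_per_group < 2:
        raise DataError("n_per_group must be >= 2")
    params = params or LangmuirParams()
    rng = np.random.default_rng(seed)
    n = truth.n_cpgs
    n_t = 2 * n_per_group
    group_idx = np.repeat([0, 1], n_per_group)
    groups = np.asarray([group_labels[g] for g in group_idx], dtype=object)
    sample_ids = [f"{group_labels[g]}{i % n_per_group + 1}" for i, g in enumerate(group_idx)]

    beta_s = truth.true_beta[:, group_idx]
    if bio_jitter_sd > 0:
        beta_s = beta_s + rng.normal(0.0, bio_jitter_sd, size=(n, n_t))
    beta_s = np.clip(beta_s, 1e-4, 1 - 1e-4)

    conc_m = total_molecules * beta_s
    conc_u = total_molecules * (1.0 - beta_s)

    scale_m = np.exp(rng.normal(0.0, params.sample_scale_sd, n_t))
    scale_u = np.exp(rng.normal(0.0, params.sample_scale_sd, n_t))
    noise_m = rng.normal(0.0, params.noise_sd, size=(n, n_t))
    noise_u = rng.normal(0.0, params.noise_sd, size=(n, n_t))

    meth = langmuir_intensity(conc_m, params, noise_m) * scale_m[None, :]
    unmeth = langmuir_intensity(conc_u, params, noise_u) * scale_u[None, :]
    beta_obs = meth / (meth + unmeth + offset)

    return SimulatedArraySet(
        meth=meth,
        unmeth=unmeth,
        beta_observed=beta_obs,
        groups=groups,
        sample_ids=sample_ids,
        truth=truth,
        seed=seed,
        offset=offset,
    )
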