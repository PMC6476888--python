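"""Seeded generators emulating the statistical structure of the pipeline.

Three families cover every stage: (a) descriptor matrices with a low-rank
latent block driving a subset of informative columns and a known linear
response, (b) lognormal IC50 draws with right-censoring at the assay
ceiling, mirroring the ">25 uM" pattern of the activity table, and
(c) Gaussian absorption bands with prescribed hypochromism and band shift.
All generators are pure functions of their parameters and seed, and every
stage of the pipeline recovers its generator's ground truth in the
noiseless limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from naphqsar.datasets import ActivityValue
from naphqsar.spectra import Spectrum


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the latent-regression generator."""

    n: int = 60
    p: int = 100
    n_informative: int = 10
    rank: int = 3
    effect_size: float = 1.0
    noise: float = 0.2  # SD of the Gaussian noise added to y
    x_noise: float = 0.0  # SD of elementwise noise on the informative block
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_informative <= self.p:
            raise ValueError("need 0 <= n_informative <= p")
        if self.noise < 0 or self.x_noise < 0:
            raise ValueError("noise levels must be >= 0")


class LatentRegression(NamedTuple):
    X: np.ndarray
    y: np.ndarray
    informative: np.ndarray  # column indices carrying signal
    coef: np.ndarray  # true b over all p columns


def gen_latent_regression(spec: SyntheticSpec) -> LatentRegression:
    """Rank-``rank`` informative block + pure-noise columns + linear response.

    X[:, informative] = T P' (+ x_noise E), each informative column rescaled
    to unit variance so effect sizes are commensurate with the iid
    standard-normal noise columns filling the rest of X;
    y = X[:, informative] @ b + noise * eps with |b_j| = effect_size and
    random signs.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_informative
    T = rng.standard_normal((spec.n, spec.rank))
    P = rng.standard_normal((k, spec.rank))
    X = rng.standard_normal((spec.n, spec.p))
    informative = np.arange(k)
    if k:
        block = T @ P.T
        if spec.x_noise:
            block = block + spec.x_noise * rng.standard_normal(block.shape)
        sd = block.std(axis=0)
        block = block / np.where(sd > 0, sd, 1.0)
        X[:, informative] = block
    coef = np.zeros(spec.p)
    coef[informative] = spec.effect_size * rng.choice([-1.0, 1.0], size=k)
    y = X @ coef + spec.noise * rng.standard_normal(spec.n)
    return LatentRegression(X, y, informative, coef)


def gen_censored_activities(
    n: int,
    censor_fraction: float,
    threshold_um: float = 25.0,
    scale_log: float = 1.0,
    seed: int = 0,
) -> list[ActivityValue]:
    """Lognormal IC50 draws censored at the assay ceiling.

    The lognormal location is set so the probability of exceeding the
    threshold equals ``censor_fraction`` (the realized fraction then lies
    within binomial error of the request).  At fraction 0 the distribution
    is anchored at a 1.5 uM median — the spread of the measured table —
    and above-threshold draws are rejected so no entry is censored.
    """
    if not 0.0 <= censor_fraction <= 1.0:
        raise ValueError("censor_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if censor_fraction == 1.0:
        return [ActivityValue(censored=True) for _ in range(n)]
    if censor_fraction == 0.0:
        mu = np.log(1.5)
        out = []
        while len(out) < n:
            v = float(np.exp(mu + scale_log * rng.standard_normal()))
            if v <= threshold_um:
                out.append(ActivityValue(ic50=v))
        return out
    mu = np.log(threshold_um) - scale_log * stats.norm.ppf(1.0 - censor_fraction)
    values = np.exp(mu + scale_log * rng.standard_normal(n))
    return [
        ActivityValue(censored=True) if v > threshold_um else ActivityValue(ic50=float(v))
        for v in values
    ]


def gen_spectra(
    peak_nm: float = 380.0,
    width_nm: float = 20.0,
    amplitude: float = 1.0,
    hypochromism_pct: float = 14.09,
    shift_nm: float = 2.0,
    noise: float = 0.0,
    seed: int = 0,
    grid: tuple[float, float] = (200.0, 500.0),
    concentration_m: float | None = None,
) -> tuple[Spectrum, Spectrum]:
    """Free/bound Gaussian-band pair with known hypochromism and band shift.

    The bound band is the free band scaled by (1 - H/100) and moved by
    ``shift_nm`` (positive = red); optional iid Gaussian noise [AU] is
    added to both.
    """
    if not grid[0] <= peak_nm <= grid[1]:
        raise ValueError("peak must lie within the wavelength grid")
    if width_nm <= 0:
        raise ValueError("band width must be positive")
    rng = np.random.default_rng(seed)
    wl = np.arange(grid[0], grid[1] + 1.0)
    band = lambda center: amplitude * np.exp(-((wl - center) ** 2) / (2.0 * width_nm**2))
    free = band(peak_nm)
    bound = (1.0 - hypochromism_pct / 100.0) * band(peak_nm + shift_nm)
    if noise:
        free = free + noise * rng.standard_normal(wl.shape)
        bound = bound + noise * rng.standard_normal(wl.shape)
    return (
        Spectrum(wl, free, concentration_m=concentration_m),
        Spectrum(wl, bound, concentration_m=concentration_m),
    )
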