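"""Overdispersed photon-count model of the CCD imaging system.

The camera's count statistics are overdispersed relative to Poisson:
variance = g * mean with gain factor g (g = 3 for the reference system,
determined from repeated exposures of a static scene).  Counts are modeled
as negative binomial with that mean/variance pair; error propagation turns
the count variance into the variance of the normalized intensities used as
inverse weights in the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseModel", "nb_parameters", "sample_intensity", "normalized_variance"]

logger = logging.getLogger(__name__)


@dataclass
class NoiseModel:
    """Gain factor and RNG seed of the count-noise model.

    g = 1 is the Poisson limit and is handled as a special case; g < 1
    (underdispersion) is outside the model.
    """

    gain: float = 3.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.gain < 1.0:
            raise ValueError(f"gain must be >= 1, got {self.gain}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def nb_parameters(mu, g):
    """Negative-binomial (size r, success probability p) for mean mu, variance g*mu.

    r = mu^2 / (sigma^2 - mu) = mu / (g - 1),  p = mu / sigma^2 = 1 / g.
    Requires mu > 0 and g > 1 (otherwise the NB parameterization degenerates).
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("expected counts must be positive")
    if g <= 1.0:
        raise ValueError("negative-binomial parameterization needs g > 1")
    return mu / (g - 1.0), 1.0 / g


def sample_counts(mu, g, rng: np.random.Generator) -> np.ndarray:
    """Draw one noisy count per element of ``mu`` (mean mu, variance g*mu).

    Sampled through the Gamma-Poisson mixture, which realizes the negative
    binomial for any real size parameter r > 0: lambda ~ Gamma(r, g-1),
    I ~ Poisson(lambda).  g = 1 falls back to pure Poisson.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("expected counts must be positive")
    if g == 1.0:
        return rng.poisson(mu)
    r, _ = nb_parameters(mu, g)
    return rng.poisson(rng.gamma(shape=r, scale=g - 1.0))


def sample_intensity(mu: float, model: NoiseModel, n: int) -> np.ndarray:
    """n noisy counts for expected intensity mu under ``model``."""
    return sample_counts(np.full(n, float(mu)), model.gain, model.rng())


def normalized_variance(I_ji, I_jT, g, n_p):
    """Variance of the normalized intensity I_N = 2 I / I_T - 1.

    Error propagation of the count variance g*I through the normalization,
    including the uncertainty of the transmittance itself (estimated from
    the n_p-point profile mean):

        sigma_N^2 = g I / I_T^2 + g I^2 / (n_p I_T^3)

    Non-positive counts are floored at 1 so the weights stay finite.
    """
    I_jT = np.asarray(I_jT, dtype=float)
    if np.any(I_jT <= 0):
        raise ValueError("transmittance must be positive")
    I = np.asarray(I_ji, dtype=float)
    if np.any(I <= 0):
        logger.warning("non-positive counts floored at 1 for variance evaluation")
        I = np.maximum(I, 1.0)
    return g * I / I_jT**2 + g * I**2 / (n_p * I_jT**3)
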