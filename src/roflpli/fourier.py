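"""Harmonic analysis of a polarizer-rotation profile.

The noise-free signal contains only a DC term and the second harmonic in
rho, so a single harmonic projection recovers the three standard 3D-PLI
modalities exactly: transmittance I_T (twice the profile mean), direction
phi (the phase) and retardation |sin delta| (the relative amplitude).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["Modalities", "extract_modalities"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Modalities:
    """Transmittance, direction and retardation of one profile (or stack).

    Fields are scalars for a single profile and arrays for stacked input.
    """

    transmittance: np.ndarray
    phi: np.ndarray
    retardation: np.ndarray


def extract_modalities(profile, rho) -> Modalities:
    """Extract (I_T, phi, |sin delta|) from intensities over rotation angles.

    Works on any shape ``(..., n_p)`` with the rotation axis last.  The
    angles must sample the 2*rho frequency uniformly (n_p >= 5 equally
    spaced steps covering [0, pi) suffice).  phi is returned in [0, pi);
    retardation is clamped to [0, 1] (noise can push the raw amplitude
    ratio slightly above 1).
    """
    profile = np.asarray(profile, dtype=float)
    rho = np.asarray(rho, dtype=float)
    n_p = rho.size
    if n_p < 5 or profile.shape[-1] != n_p:
        raise ValueError("need >= 5 samples and matching rho/profile lengths")
    a0 = profile.mean(axis=-1)
    if np.all(profile == 0):
        raise ValueError("all-zero profile has no modalities")
    c = 2.0 / n_p * (profile * np.sin(2 * rho)).sum(axis=-1)
    s = 2.0 / n_p * (profile * np.cos(2 * rho)).sum(axis=-1)
    amp = np.hypot(c, s)
    with np.errstate(invalid="ignore", divide="ignore"):
        ret = np.where(a0 > 0, amp / np.where(a0 > 0, a0, 1.0), 0.0)
    if np.any(ret > 1.0):
        logger.warning("retardation amplitude ratio above 1 clamped (noise)")
        ret = np.minimum(ret, 1.0)
    phi = np.mod(0.5 * np.arctan2(-s, c), np.pi)
    # for a numerically DC profile the phase is undefined: convention phi = 0
    phi = np.where(amp <= 1e-12 * np.maximum(a0, 1e-300), 0.0, phi)
    if phi.ndim == 0:
        phi = phi[()]
    return Modalities(2.0 * a0, phi, ret)
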