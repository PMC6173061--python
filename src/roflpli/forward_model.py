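"""Noise-free 3D-PLI signal model.

A myelinated fiber behaves as a negative uniaxial birefringent crystal.
With crossed polarizers rotated by ``rho`` the transmitted intensity is

    I(rho) = I_T/2 * (1 + sin(2(rho - phi)) * sin(delta)),

with the retardation

    delta = pi/2 * d * cos^2(alpha),

where ``d`` (relative thickness) lumps section thickness, birefringence
and wavelength into a single dimensionless parameter.  For a tilted stage
position the same law applies to the rotated orientation (phi_j, alpha_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .geometry import FiberOrientation, TiltState

__all__ = [
    "PixelParams",
    "AcquisitionConfig",
    "retardation",
    "intensity_profile",
    "simulate_series",
    "normalized_model",
    "normalize_measured",
]

#: Stage tilt of the standard measurement protocol (before refraction).
STAGE_TILT = np.deg2rad(8.0)
#: Refractive index assumed for formalin-fixed human brain tissue.
N_TISSUE = 1.45


@dataclass(frozen=True)
class PixelParams:
    """The per-pixel fit target (phi, alpha, d) plus the fit residual.

    ``d`` is the relative thickness: the dimensionless combination
    4 t_s dn / lambda of section thickness t_s, birefringence dn and
    wavelength lambda.  It is kept as one free parameter; its physical
    constituents are never estimated separately.  ``chi2`` is set by the
    fitter (weighted residual sum) and None before fitting.
    """

    phi: float
    alpha: float
    d: float
    chi2: float | None = None

    def orientation(self) -> FiberOrientation:
        return FiberOrientation(self.phi, self.alpha)

    def vector(self) -> np.ndarray:
        return geometry.orientation_to_vector(self.orientation())


def _default_tilt_states() -> list[TiltState]:
    tau_int = geometry.snell_internal_angle(STAGE_TILT, N_TISSUE)
    return geometry.standard_tilt_states(tau_int)


@dataclass
class AcquisitionConfig:
    """Geometry and gain of one measurement (or simulation) protocol.

    Defaults reproduce the standard protocol: 18 polarizer steps of
    10 deg, planar + 4 cardinal tilts at the internal tilt angle
    arcsin(sin 8deg / 1.45) = 5.51 deg, transmittance 2500 counts and
    camera gain 3.  ``transmittance`` is the *mean* transmitted intensity
    over a rotation (the typical count level of a brain section).  ``path_length_correction`` optionally scales the
    per-tilt thickness by 1/cos(tau) for sensitivity studies; by default
    tilting changes only the orientation.
    """

    n_polarizer_steps: int = 18
    rho_step: float = np.deg2rad(10.0)
    tilt_states: list[TiltState] = field(default_factory=_default_tilt_states)
    transmittance: float = 2500.0
    gain: float = 3.0
    n_tissue: float = N_TISSUE
    path_length_correction: bool = False

    def __post_init__(self) -> None:
        if self.n_polarizer_steps < 3:
            raise ValueError("need at least 3 polarizer steps")
        n_planar = sum(1 for t in self.tilt_states if t.tau == 0.0)
        if n_planar != 1:
            raise ValueError("exactly one tilt state must be planar (tau = 0)")

    @property
    def rho(self) -> np.ndarray:
        """Polarizer rotation angles rho_i = i * rho_step."""
        return np.arange(self.n_polarizer_steps) * self.rho_step

    @property
    def n_tilts(self) -> int:
        return len(self.tilt_states)


def retardation(alpha, d):
    """sin(delta) = sin(pi/2 * d * cos^2 alpha); broadcasts over arrays."""
    return np.sin(np.pi / 2 * np.asarray(d) * np.cos(alpha) ** 2)


def _effective_params(p: PixelParams, t: TiltState, cfg: AcquisitionConfig):
    """(phi_j, alpha_j, d_j) seen in stage position ``t``."""
    tilted = geometry.tilt_orientation(p.orientation(), t)
    d_j = p.d / np.cos(t.tau) if cfg.path_length_correction else p.d
    return tilted.phi, tilted.alpha, d_j


def intensity_profile(p: PixelParams, t: TiltState, cfg: AcquisitionConfig) -> np.ndarray:
    """Expected intensities over one polarizer rotation at stage position ``t``.

    ``cfg.transmittance`` is the mean transmitted intensity (the I_T/2
    prefactor of the signal law), so the profile oscillates about it with
    relative amplitude sin(delta).
    """
    phi_j, alpha_j, d_j = _effective_params(p, t, cfg)
    sin_delta = retardation(alpha_j, d_j)
    return cfg.transmittance * (1.0 + np.sin(2 * (cfg.rho - phi_j)) * sin_delta)


def simulate_series(p: PixelParams, cfg: AcquisitionConfig) -> np.ndarray:
    """Noise-free intensity matrix of shape (n_tilts, n_polarizer_steps)."""
    return np.stack([intensity_profile(p, t, cfg) for t in cfg.tilt_states])


def normalized_model(p: PixelParams, t: TiltState, rho_i, cfg: AcquisitionConfig | None = None) -> np.ndarray:
    """Model prediction f_ji in [-1, 1] for the normalized intensity.

    f = sin(2(rho_i - phi_j)) * sin(pi/2 * d_j * cos^2 alpha_j), with
    (phi_j, alpha_j) the tilted orientation.  Odd in d: f(phi, alpha, -d)
    = -f(phi, alpha, d).
    """
    cfg = cfg or AcquisitionConfig()
    sign = np.sign(p.d) if p.d != 0 else 1.0
    phi_j, alpha_j, d_j = _effective_params(
        PixelParams(p.phi, p.alpha, abs(p.d)), t, cfg
    )
    return sign * np.sin(2 * (np.asarray(rho_i) - phi_j)) * retardation(alpha_j, d_j)


def normalize_measured(I_ji, I_jT):
    """Map measured counts into [-1, 1] about the per-tilt transmittance.

    I_N = 2 I / I_T - 1, removing absorption differences between stage
    positions.  I_T must be positive.
    """
    I_jT = np.asarray(I_jT, dtype=float)
    if np.any(I_jT <= 0):
        raise ValueError("transmittance must be positive for normalization")
    return 2.0 * np.asarray(I_ji, dtype=float) / I_jT - 1.0
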