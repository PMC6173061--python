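"""Orientation geometry for tilted polarimetric imaging.

3D-PLI parameterises a fiber axis by the in-plane direction angle ``phi``
(range [0, pi)) and the out-of-plane inclination ``alpha`` (range
[-pi/2, pi/2]).  Because a fiber is an axis, not a vector, the parameter
space is a half sphere: ``v`` and ``-v`` denote the same fiber.  This module
provides the conversions between the angular and Cartesian representations,
the rotation describing the tiltable specimen stage, the Snell correction
for refraction inside the tissue, the symmetrization that folds an
unbounded (phi_u, alpha_u) pair back onto the half sphere, and the acute
angle used as the orientation-error metric.

All angles are radians; degrees appear only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FiberOrientation",
    "TiltState",
    "UnboundedOrientation",
    "TILT_LABELS",
    "orientation_to_vector",
    "vector_to_orientation",
    "rotation_matrix",
    "snell_internal_angle",
    "tilt_orientation",
    "standard_tilt_states",
    "symmetrize",
    "symmetrize_angles",
    "acute_angle",
]

#: Stage-position labels in index order (j = 0 is the planar measurement).
TILT_LABELS = ("planar", "N", "E", "S", "W")

# Below this in-plane norm a vector counts as the pole (+-z), where the
# azimuth is undefined and a fixed convention (phi = 0) is returned.
_POLE_EPS = 1e-9


@dataclass(frozen=True)
class FiberOrientation:
    """A fiber axis on the half-sphere parameter space.

    Attributes
    ----------
    phi : float
        Direction angle (in-plane), radians in [0, pi).
    alpha : float
        Inclination angle (out-of-plane), radians in [-pi/2, pi/2].
    """

    phi: float
    alpha: float

    def vector(self) -> np.ndarray:
        return orientation_to_vector(self)


@dataclass(frozen=True)
class UnboundedOrientation:
    """An orientation before folding onto the half sphere; no invariants."""

    phi_u: float
    alpha_u: float


@dataclass(frozen=True)
class TiltState:
    """One position of the tiltable specimen stage.

    ``psi`` is the azimuth of the tilt axis, ``tau`` the tilt magnitude
    (for fitting, the *internal* angle after Snell correction).  Index 0
    is reserved for the planar (untilted) measurement.
    """

    index: int
    psi: float
    tau: float
    label: str = ""

    def __post_init__(self) -> None:
        if (self.index == 0) != (self.tau == 0.0):
            raise ValueError(
                "index 0 is reserved for the planar state (tau = 0); got "
                f"index={self.index}, tau={self.tau}"
            )


def standard_tilt_states(tau: float, n_tilt: int = 4) -> list[TiltState]:
    """Planar position plus ``n_tilt`` equidistant tilt directions.

    The tilt azimuths are psi_j = 2 pi (j - 1) / n_tilt for j = 1..n_tilt.
    With the default n_tilt = 4 the labels follow the cardinal scheme
    N (psi=0), E (psi=90 deg), S (180 deg), W (270 deg).
    """
    states = [TiltState(0, 0.0, 0.0, "planar")]
    for j in range(1, n_tilt + 1):
        psi = 2.0 * np.pi * (j - 1) / n_tilt
        label = TILT_LABELS[j] if n_tilt == 4 else f"t{j}"
        states.append(TiltState(j, psi, float(tau), label))
    return states


def orientation_to_vector(o: FiberOrientation) -> np.ndarray:
    """Unit vector (cos a cos p, cos a sin p, sin a) of an orientation."""
    ca = np.cos(o.alpha)
    return np.array([ca * np.cos(o.phi), ca * np.sin(o.phi), np.sin(o.alpha)])


def unit_vectors(phi: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Vectorized orientation-to-vector; returns shape ``phi.shape + (3,)``."""
    phi = np.asarray(phi, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    ca = np.cos(alpha)
    return np.stack([ca * np.cos(phi), ca * np.sin(phi), np.sin(alpha)], axis=-1)


def vector_to_orientation(v: np.ndarray) -> FiberOrientation:
    """Fold a Cartesian axis into the half-sphere parameter space.

    ``v`` and ``-v`` map to the same orientation.  Vectors within 1e-9 of
    the poles +-z return the convention (phi=0, alpha=+-pi/2).
    """
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0.0 or not np.isfinite(norm):
        raise ValueError("cannot orient a zero or non-finite vector")
    x, y, z = v / norm
    if np.hypot(x, y) < _POLE_EPS:
        return FiberOrientation(0.0, float(np.copysign(np.pi / 2, z)))
    phi_u = np.arctan2(y, x)
    alpha_u = np.arcsin(np.clip(z, -1.0, 1.0))
    phi, alpha = symmetrize_angles(phi_u, alpha_u)
    return FiberOrientation(float(phi), float(alpha))


def rotation_matrix(psi: float, tau: float) -> np.ndarray:
    """Stage rotation R(psi, tau) = Rz(psi) Ry(tau) Rz(-psi).

    Tilts the specimen by ``tau`` about an axis whose azimuth is set by
    ``psi``: first rotate the tilt axis onto y (Rz(-psi)), tilt about y,
    rotate back.
    """
    cp, sp = np.cos(psi), np.sin(psi)
    ct, st = np.cos(tau), np.sin(tau)
    rz = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[ct, 0.0, st], [0.0, 1.0, 0.0], [-st, 0.0, ct]])
    return rz @ ry @ rz.T


def snell_internal_angle(tau_stage: float, n_tissue: float) -> float:
    """Tilt angle of the light path inside the tissue.

    Refraction at the tissue surface reduces the stage tilt ``tau_stage``
    to arcsin(sin(tau_stage) / n_tissue).  For the standard 8 deg stage
    tilt and n = 1.45 this gives approximately 5.51 deg.
    """
    if n_tissue < 1.0:
        raise ValueError(f"refractive index must be >= 1, got {n_tissue}")
    if abs(tau_stage) >= np.pi / 2:
        raise ValueError("stage tilt must satisfy |tau| < pi/2")
    return float(np.arcsin(np.sin(tau_stage) / n_tissue))


def tilt_orientation(o: FiberOrientation, t: TiltState) -> FiberOrientation:
    """Orientation of the fiber as seen in stage position ``t``."""
    vt = rotation_matrix(t.psi, t.tau) @ orientation_to_vector(o)
    return vector_to_orientation(vt)


def symmetrize_angles(phi_u, alpha_u):
    """Fold unbounded angles (phi_u, alpha_u) onto the half sphere.

    Returns (phi, alpha) with phi in [0, pi) and alpha in [-pi/2, pi/2]
    describing the same fiber axis:

        phi   = phi_u mod pi
        alpha = ((alpha_u + pi/2) mod pi - pi/2) * sgn(1/2 - floor((phi_u/pi) mod 2))

    Accepts scalars or broadcasting arrays.  The degenerate pole case where
    the mapping would yield alpha = +pi/2 is canonicalised to -pi/2 (the
    same axis) so the mapping is exactly idempotent.
    """
    phi_u = np.asarray(phi_u, dtype=float)
    alpha_u = np.asarray(alpha_u, dtype=float)
    phi = np.mod(phi_u, np.pi)
    sign = np.where(np.floor(np.mod(phi_u / np.pi, 2.0)) < 0.5, 1.0, -1.0)
    alpha = (np.mod(alpha_u + np.pi / 2, np.pi) - np.pi / 2) * sign
    alpha = np.where(alpha == np.pi / 2, -np.pi / 2, alpha)
    # np.mod can round a tiny negative phi_u up to exactly pi; (pi, a) and
    # (0, -a) are the same axis, so fold once more to keep phi in [0, pi)
    alpha = np.where(phi >= np.pi, -alpha, alpha)
    phi = np.where(phi >= np.pi, phi - np.pi, phi)
    if phi.ndim == 0:
        return float(phi), float(alpha)
    return phi, alpha


def symmetrize(u: UnboundedOrientation, d: float) -> tuple[FiberOrientation, float]:
    """Map an unbounded (orientation, thickness) onto the parameter space.

    The relative thickness may be negative during unbounded optimization;
    because the normalized signal is odd in ``d``, taking |d| together with
    the angle folding leaves the model value unchanged.
    """
    phi, alpha = symmetrize_angles(u.phi_u, u.alpha_u)
    return FiberOrientation(phi, alpha), abs(d)


def acute_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Acute angle between two fiber axes, radians in [0, pi/2].

    Uses |v1 . v2| so that antipodal vectors (the same axis) give 0;
    evaluated as atan2(|cross|, |dot|), which keeps full precision near 0
    where arccos alone would lose half the significant digits.
    """
    d = abs(float(np.dot(v1, v2)))
    c = float(np.linalg.norm(np.cross(v1, v2)))
    return float(np.arctan2(c, d))
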