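"""Robust Orientation Fitting via Least Squares (ROFL).

Per-pixel weighted least-squares estimation of the fiber direction phi,
inclination alpha and relative thickness d from the full set of tilting
measurements.  The planar measurement alone cannot separate alpha from d
(both enter only through the retardation); the oblique views break that
degeneracy.  The fit minimizes

    chi^2 = sum_ji ((f_ji(phi, alpha, d) - I_N,ji) * w_ji)^2

over all stage positions j (including the planar one) and rotation angles
i, with weights w = 1/sigma_N from the propagated count-noise variance.
The optimization runs unbounded: the direction from the planar harmonic
analysis plus a coarse 6 x 6 grid over (alpha, d) provides the starting
point, Levenberg-Marquardt refines it, and the half-sphere symmetry of the
problem folds the unbounded solution back into phi in [0, pi), alpha in
[-pi/2, pi/2], d >= 0.  d is deliberately *not* capped at 1: fitted d > 1
signals that the single-fiber model does not describe the pixel (e.g.
crossing fibers), as does an elevated chi^2.

The module exposes a statsmodels-style ``ROFLModel`` / ``ROFLResult`` pair
for single series plus functional wrappers (``fit_pixel``, ``fit_image``)
for bulk use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import fourier, geometry, noise as noise_mod
from .forward_model import PixelParams
from .geometry import TiltState

__all__ = [
    "FitConfig",
    "MeasurementSeries",
    "ROFLModel",
    "ROFLResult",
    "build_weights",
    "chi_squared",
    "grid_init",
    "fit_pixel",
    "fit_image",
    "InclinationSolver",
]

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Tuning knobs of the ROFL optimizer.

    The initialization grid places ``n_alpha_init x n_d_init`` nodes at the
    centers of equal bins over alpha in [-pi/2, pi/2] and d in
    (0, d_grid_max], avoiding the degenerate edges alpha = +-90 deg and
    d = 0.  LM tolerances are tight because each fit is tiny (3 parameters,
    <= 90 residuals).
    """

    n_alpha_init: int = 6
    n_d_init: int = 6
    d_grid_max: float = 1.0
    lm_max_iter: int = 200
    lm_tolerance: float = 1e-10
    weight_floor: float = 1.0
    background_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_alpha_init < 2 or self.n_d_init < 2:
            raise ValueError("initialization grid needs >= 2 nodes per axis")
        if self.lm_tolerance <= 0:
            raise ValueError("lm_tolerance must be positive")


@dataclass
class MeasurementSeries:
    """Per-pixel intensity matrix over stage positions x rotation angles."""

    intensities: np.ndarray  # (n_tilts, n_polarizer_steps)
    tilt_states: list[TiltState]
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        n_t, n_p = self.intensities.shape
        if n_t != len(self.tilt_states) or n_p != self.rho.size:
            raise ValueError("intensity matrix inconsistent with tilt/rho axes")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def transmittances(self) -> np.ndarray:
        """Per-tilt transmittance I_jT = 2 x profile mean."""
        return 2.0 * self.intensities.mean(axis=1)

    def normalized(self) -> np.ndarray:
        I_T = self.transmittances()
        if np.any(I_T <= 0):
            raise ValueError("degenerate (non-positive) transmittance")
        return 2.0 * self.intensities / I_T[:, None] - 1.0


def build_weights(series: MeasurementSeries, g: float) -> np.ndarray:
    """Inverse-sigma weights w_ji = 1/sigma_N from the propagated noise.

    Variances are evaluated at the *measured* intensities so the weights
    are fixed before optimization; counts below 1 are floored.
    """
    I_T = series.transmittances()
    if np.any(I_T <= 0):
        raise ValueError("degenerate (non-positive) transmittance")
    I = np.maximum(series.intensities, 1.0)
    var = noise_mod.normalized_variance(I, I_T[:, None], g, series.rho.size)
    return 1.0 / np.sqrt(var)


class _FitContext:
    """Precomputed geometry shared by every pixel of one acquisition.

    Holds the stage rotation matrices, the 2*rho harmonics, and the
    (alpha, d) initialization nodes, so per-pixel work reduces to a few
    small vectorized array operations.
    """

    def __init__(self, tilt_states, rho, config: FitConfig | None = None, gain: float = 3.0):
        self.tilt_states = list(tilt_states)
        self.rho = np.asarray(rho, dtype=float)
        self.config = config or FitConfig()
        self.gain = float(gain)
        self.R = np.stack(
            [geometry.rotation_matrix(t.psi, t.tau) for t in self.tilt_states]
        )
        self.sin2rho = np.sin(2 * self.rho)
        self.cos2rho = np.cos(2 * self.rho)
        self.planar_index = next(
            i for i, t in enumerate(self.tilt_states) if t.tau == 0.0
        )
        na, nd = self.config.n_alpha_init, self.config.n_d_init
        alpha_nodes = -np.pi / 2 + (np.arange(na) + 0.5) * np.pi / na
        d_nodes = (np.arange(nd) + 0.5) / nd * self.config.d_grid_max
        aa, dd = np.meshgrid(alpha_nodes, d_nodes, indexing="ij")
        self.alpha_nodes = alpha_nodes
        self.d_nodes = d_nodes
        self.grid_alpha = aa.ravel()
        self.grid_d = dd.ravel()

    def model(self, v: np.ndarray, d) -> np.ndarray:
        """Normalized model f for axis vector(s) v and thickness(es) d.

        Works on v of shape (..., 3) and broadcasting d, returning
        (..., n_tilts, n_p).  Evaluating through the axis vector is the
        symmetrized model: f depends only on the fiber axis and |d|.
        """
        d = np.abs(np.asarray(d, dtype=float))
        vt = np.einsum("tij,...j->...ti", self.R, v)
        x, y = vt[..., 0], vt[..., 1]
        x2, y2 = x * x, y * y
        cos2_alpha = x2 + y2
        denom = np.maximum(cos2_alpha, 1e-300)
        cos2phi = (x2 - y2) / denom
        sin2phi = 2.0 * x * y / denom
        amp = np.sin(np.pi / 2 * d[..., None] * cos2_alpha)
        return amp[..., None] * (
            cos2phi[..., None] * self.sin2rho - sin2phi[..., None] * self.cos2rho
        )

    def planar_phi(self, intensities: np.ndarray) -> float:
        """Direction angle from the planar profile's second harmonic."""
        prof = intensities[self.planar_index]
        n_p = self.rho.size
        c = 2.0 / n_p * (prof * self.sin2rho).sum()
        s = 2.0 / n_p * (prof * self.cos2rho).sum()
        return float(np.mod(0.5 * np.arctan2(-s, c), np.pi))

    def fit(self, intensities: np.ndarray) -> dict:
        """Full ROFL fit of one (n_tilts, n_p) count matrix."""
        cfg = self.config
        I = np.asarray(intensities, dtype=float)
        I_T = 2.0 * I.mean(axis=1)
        if np.any(I_T <= 0):
            raise ValueError("degenerate (non-positive) transmittance")
        I_N = 2.0 * I / I_T[:, None] - 1.0
        I_w = np.maximum(I, cfg.weight_floor)
        var = self.gain * I_w / I_T[:, None] ** 2 + self.gain * I_w**2 / (
            self.rho.size * I_T[:, None] ** 3
        )
        w = 1.0 / np.sqrt(var)

        phi0 = self.planar_phi(I)
        v_grid = geometry.unit_vectors(
            np.full_like(self.grid_alpha, phi0), self.grid_alpha
        )
        f_grid = self.model(v_grid, self.grid_d)
        chi2_grid = (((f_grid - I_N) * w) ** 2).sum(axis=(1, 2))
        k0 = int(np.argmin(chi2_grid))
        chi2_init = float(chi2_grid[k0])
        x0 = np.array([phi0, self.grid_alpha[k0], self.grid_d[k0]])

        def residuals(x):
            ca = np.cos(x[1])
            v = np.array([ca * np.cos(x[0]), ca * np.sin(x[0]), np.sin(x[1])])
            return ((self.model(v, x[2]) - I_N) * w).ravel()

        res = least_squares(
            residuals,
            x0,
            method="lm",
            ftol=cfg.lm_tolerance,
            xtol=cfg.lm_tolerance,
            gtol=cfg.lm_tolerance,
            max_nfev=cfg.lm_max_iter * (len(x0) + 1),
        )
        chi2 = 2.0 * float(res.cost)
        converged = res.status > 0
        if chi2 > chi2_init:  # LM must never end above its start
            x, chi2, jac = x0, chi2_init, None
            converged = False
        else:
            x, jac = res.x, res.jac
        phi, alpha = geometry.symmetrize_angles(x[0], x[1])
        return {
            "phi": float(phi),
            "alpha": float(alpha),
            "d": abs(float(x[2])),
            "chi2": chi2,
            "chi2_init": chi2_init,
            "converged": converged,
            "nfev": int(res.nfev),
            "jac": jac,
            "ss_data": float(((I_N * w) ** 2).sum()),
        }


def chi_squared(p: PixelParams, series: MeasurementSeries, weights: np.ndarray) -> float:
    """Weighted residual sum for parameters ``p`` against a series.

    ``p`` may be unbounded (any angles, negative d); the model is always
    evaluated after folding onto the parameter space, so the value is
    invariant under symmetrization.
    """
    ctx = _FitContext(series.tilt_states, series.rho)
    v = geometry.unit_vectors(p.phi, p.alpha)
    f = ctx.model(v, abs(p.d))
    return float((((f - series.normalized()) * weights) ** 2).sum())


def grid_init(
    series: MeasurementSeries,
    weights: np.ndarray,
    phi0: float,
    config: FitConfig | None = None,
) -> PixelParams:
    """Best (phi0, alpha_l, d_k) node of the brute-force starting grid."""
    ctx = _FitContext(series.tilt_states, series.rho, config)
    v_grid = geometry.unit_vectors(np.full_like(ctx.grid_alpha, phi0), ctx.grid_alpha)
    f = ctx.model(v_grid, ctx.grid_d)
    chi2 = (((f - series.normalized()) * weights) ** 2).sum(axis=(1, 2))
    k = int(np.argmin(chi2))
    return PixelParams(phi0, float(ctx.grid_alpha[k]), float(ctx.grid_d[k]), float(chi2[k]))


class ROFLModel:
    """One pixel's tilting measurement, ready to fit.

    Parameters
    ----------
    series : MeasurementSeries
        Count matrix over stage positions and rotation angles, with its
        tilt geometry.  Tilt angles must already be the internal
        (Snell-corrected) angles.
    gain : float
        Camera gain factor g (variance = g x mean).
    config : FitConfig, optional
        Optimizer settings.
    """

    def __init__(self, series: MeasurementSeries, gain: float = 3.0,
                 config: FitConfig | None = None):
        self.series = series
        self.gain = float(gain)
        self.config = config or FitConfig()
        self._ctx = _FitContext(series.tilt_states, series.rho, self.config, self.gain)

    @classmethod
    def from_arrays(cls, intensities, tilt_states, rho, gain: float = 3.0,
                    config: FitConfig | None = None) -> "ROFLModel":
        return cls(MeasurementSeries(intensities, tilt_states, rho), gain, config)

    def fit(self) -> "ROFLResult":
        raw = self._ctx.fit(self.series.intensities)
        return ROFLResult(self, raw)


class ROFLResult:
    """Estimates, uncertainties and diagnostics of one ROFL fit."""

    def __init__(self, model: ROFLModel, raw: dict):
        self.model = model
        self.params = PixelParams(raw["phi"], raw["alpha"], raw["d"], raw["chi2"])
        self.chi2 = raw["chi2"]
        self.chi2_init = raw["chi2_init"]
        self.converged = raw["converged"]
        self.nfev = raw["nfev"]
        self._jac = raw["jac"]
        self._ss_data = raw["ss_data"]
        n_t, n_p = model.series.intensities.shape
        self.df_resid = n_t * n_p - 3

    @property
    def phi(self) -> float:
        return self.params.phi

    @property
    def alpha(self) -> float:
        return self.params.alpha

    @property
    def d(self) -> float:
        return self.params.d

    @property
    def r_squared(self) -> float:
        """1 - chi2 / sum((w I_N)^2): weighted goodness of fit."""
        return 1.0 - self.chi2 / self._ss_data if self._ss_data > 0 else np.nan

    def cov_params(self) -> np.ndarray:
        """Covariance of (phi, alpha, d) from the weighted Jacobian.

        Residuals are already scaled by 1/sigma, so cov = (J^T J)^-1.
        NaN if the Jacobian is unavailable or singular (e.g. at the pole,
        where phi is unidentifiable).
        """
        if self._jac is None:
            return np.full((3, 3), np.nan)
        jtj = self._jac.T @ self._jac
        try:
            return np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            return np.full((3, 3), np.nan)

    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params()), 0, None))

    def summary(self) -> str:
        se = self.bse()
        se_deg = np.rad2deg(se[:2])
        lines = [
            "ROFL fit",
            "=" * 46,
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}",
            "-" * 46,
            f"{'phi [deg]':<14}{np.rad2deg(self.phi):>12.3f}{se_deg[0]:>12.3f}",
            f"{'alpha [deg]':<14}{np.rad2deg(self.alpha):>12.3f}{se_deg[1]:>12.3f}",
            f"{'d':<14}{self.d:>12.4f}{se[2]:>12.4f}",
            "-" * 46,
            f"chi2 = {self.chi2:.4f}   R^2 = {self.r_squared:.4f}   "
            f"converged = {self.converged}   nfev = {self.nfev}",
        ]
        return "\n".join(lines)


def fit_pixel(
    series: MeasurementSeries,
    cfg: FitConfig | None = None,
    noise: noise_mod.NoiseModel | None = None,
) -> PixelParams:
    """Fit one pixel; returns the symmetrized (phi, alpha, d) with chi2."""
    gain = noise.gain if noise is not None else 3.0
    return ROFLModel(series, gain, cfg).fit().params


def fit_image(
    stack,
    cfg: FitConfig | None = None,
    noise: noise_mod.NoiseModel | None = None,
    n_workers: int = 1,
):
    """Per-pixel ROFL over an image stack.

    Parameters
    ----------
    stack
        Object with ``intensities`` of shape (n_tilts, n_p, H, W),
        ``tilt_states`` and ``rho`` (e.g. ``roflpli.io.Stack``).
    n_workers : int
        Process count for the optional local pool.  The fit is
        deterministic, so maps are identical for any worker count.

    Returns
    -------
    dict of 2-D float arrays: ``direction`` and ``inclination`` (radians),
    ``thickness``, ``chi2``, ``r_squared``.  Background pixels (planar
    transmittance below ``background_fraction`` of the robust stack
    maximum) are NaN.
    """
    cfg = cfg or FitConfig()
    gain = noise.gain if noise is not None else 3.0
    I = np.asarray(stack.intensities, dtype=float)
    n_t, n_p, h, w_ = I.shape
    ctx = _FitContext(stack.tilt_states, stack.rho, cfg, gain)
    planar_it = 2.0 * I[ctx.planar_index].mean(axis=0)
    robust_max = np.percentile(planar_it, 99)
    mask = planar_it >= cfg.background_fraction * robust_max

    maps = {k: np.full((h, w_), np.nan) for k in
            ("direction", "inclination", "thickness", "chi2", "r_squared")}
    idx = np.argwhere(mask)

    def _run(rows):
        out = np.empty((len(rows), 5))
        for k, (r, c) in enumerate(rows):
            raw = ctx.fit(I[:, :, r, c])
            rsq = 1.0 - raw["chi2"] / raw["ss_data"] if raw["ss_data"] > 0 else np.nan
            out[k] = (raw["phi"], raw["alpha"], raw["d"], raw["chi2"], rsq)
        return out

    if n_workers > 1 and len(idx) > 1:
        from joblib import Parallel, delayed

        chunks = np.array_split(idx, n_workers * 4)
        chunks = [c for c in chunks if len(c)]
        results = Parallel(n_jobs=n_workers)(delayed(_run)(c) for c in chunks)
        values = np.concatenate(results)
        idx = np.concatenate(chunks)
    else:
        values = _run(idx)

    n_fail = 0
    for (r, c), row in zip(idx, values):
        for k, key in enumerate(maps):
            maps[key][r, c] = row[k]
    n_fail = int(np.sum(~np.isfinite(values[:, 3]))) if len(values) else 0
    logger.info(
        "fit_image: %d pixels fitted, %d background, %d failures",
        len(idx), h * w_ - len(idx), n_fail,
    )
    return maps


class InclinationSolver:
    """Adapter contract for alternative per-pixel solvers.

    Any callable mapping a MeasurementSeries to PixelParams (for instance
    a discrete-Fourier-transform analytical solver) can be benchmarked
    against ROFL through this interface; no implementation is bundled.
    """

    def __call__(self, series: MeasurementSeries) -> PixelParams:  # pragma: no cover
        raise NotImplementedError
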