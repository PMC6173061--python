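"""Synthetic image phantoms for end-to-end pipeline tests.

A phantom is a small image divided into regions of homogeneous fiber
parameters — emulating, say, dense white matter (high d), cortex-like
tissue (low d) and a steep fiber tract — over a transmittance-only
background (no birefringent signal, d = 0).  Simulating the tilting
measurement of a phantom and fitting it with ROFL exercises the whole
stack pipeline against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import noise as noise_mod
from .forward_model import AcquisitionConfig, PixelParams, simulate_series
from .io import Stack
from .noise import NoiseModel

__all__ = ["PhantomRegion", "PhantomSpec", "generate_phantom"]


@dataclass
class PhantomRegion:
    """One homogeneous region: a boolean mask plus its fiber parameters."""

    mask: np.ndarray
    params: PixelParams

    @classmethod
    def rectangle(cls, shape, rows: slice, cols: slice, params: PixelParams):
        mask = np.zeros(shape, dtype=bool)
        mask[rows, cols] = True
        return cls(mask, params)

    @classmethod
    def disk(cls, shape, center, radius: float, params: PixelParams):
        rr, cc = np.indices(shape)
        mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
        return cls(mask, params)


@dataclass
class PhantomSpec:
    """Layout of a phantom image: disjoint regions over a background."""

    height: int
    width: int
    regions: list[PhantomRegion] = field(default_factory=list)
    background_transmittance: float = 2500.0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be >= 1")
        cover = np.zeros((self.height, self.width), dtype=int)
        for r in self.regions:
            if r.mask.shape != (self.height, self.width):
                raise ValueError("region mask shape does not match phantom")
            cover += r.mask
        if np.any(cover > 1):
            raise ValueError("phantom regions overlap")


def generate_phantom(
    spec: PhantomSpec,
    acq: AcquisitionConfig | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Stack, dict]:
    """Simulate the tilting measurement of a phantom.

    Returns the measurement :class:`Stack` and ground-truth maps
    (``direction``/``inclination`` in radians, ``thickness``; NaN on the
    background).  ``noise=None`` or gain exactly 1 with no model yields a
    noise-free stack for exact-recovery tests.
    """
    acq = acq or AcquisitionConfig()
    n_t, n_p = acq.n_tilts, acq.n_polarizer_steps
    shape = (spec.height, spec.width)
    stack = np.empty((n_t, n_p) + shape)
    # background: constant transmittance, no modulation
    stack[...] = spec.background_transmittance
    truth = {k: np.full(shape, np.nan) for k in ("direction", "inclination", "thickness")}
    for region in spec.regions:
        clean = simulate_series(region.params, acq)
        stack[:, :, region.mask] = clean[:, :, None]
        truth["direction"][region.mask] = region.params.phi
        truth["inclination"][region.mask] = region.params.alpha
        truth["thickness"][region.mask] = region.params.d
    if noise is not None:
        rng = rng if rng is not None else noise.rng()
        stack = noise_mod.sample_counts(stack, noise.gain, rng).astype(float)
    return Stack(stack, acq.tilt_states, acq.rho, acq.n_tissue), truth
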