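# Methods

## Signal model

A myelinated fiber bundle behaves as a negative uniaxial birefringent
crystal.  Between crossed polarizers rotated by ρ the transmitted intensity
in a pixel is sinusoidal in 2ρ:

    I(ρ) = I_mean · (1 + sin(2(ρ − φ)) · sin δ),     δ = (π/2) · d · cos²α.

`I_mean` (the transmittance) is the mean transmitted intensity over one
rotation; φ ∈ [0°, 180°) is the in-plane direction, α ∈ [−90°, 90°] the
inclination out of the sectioning plane, and d ≥ 0 the relative thickness.
The profile mean, phase and relative amplitude therefore carry the three
standard modalities (transmittance, direction, retardation |sin δ|); they
are extracted exactly by a single-harmonic projection (`fourier`), since
the noise-free signal contains only DC and 2ρ terms.

Because α and d enter only through δ, one planar view cannot separate
them, and the separation is bijective only for d ∈ (0, 1].  Tilting the
specimen by τ about azimuth ψ rotates the fiber axis by
R(ψ, τ) = R_z(ψ) R_y(τ) R_z(−ψ); refraction reduces the 8° stage tilt to
an internal arcsin(sin 8°/1.45) ≈ 5.51° inside tissue of refractive index
1.45.  The five views (planar + N/E/S/W) see different effective
inclinations α_j, which breaks the α–d entanglement.

Per stage position, tilting is assumed to change only the orientation, not
the optical path length; an `AcquisitionConfig.path_length_correction`
flag optionally scales the per-view thickness by 1/cos τ for sensitivity
studies.

## Noise model

CCD counts are overdispersed: variance = g · mean with gain g = 3 for the
reference system (determined from repeated exposures of a static scene;
here g is a configuration input, not re-estimated).  Counts are modeled as
negative binomial with size r = μ/(g−1) and success probability 1/g, and
sampled through the Gamma–Poisson mixture, which is valid for real-valued
r and reduces to Poisson at g = 1.

The fit operates on normalized intensities I_N = 2I/I_T − 1 with the
per-view transmittance I_T taken as twice the measured profile mean (this
removes view-dependent absorption).  Error propagation of the count
variance through the normalization, including the uncertainty of the
N_P-point mean itself, gives

    σ_N² = g·I/I_T² + g·I²/(N_P·I_T³),

and the fit weights are w = 1/σ_N, evaluated at the measured counts
(floored at 1 count) so they are fixed before optimization.

## The ROFL fit

Objective: χ² = Σ_j Σ_i ((f_ji(φ, α, d) − I_N,ji) · w_ji)², summed over all
stage positions including the planar one, with
f_ji = sin(2(ρ_i − φ_j)) sin(π/2 · d · cos²α_j) evaluated at the tilted
orientation (φ_j, α_j).

* **Initialization.**  φ starts at the planar harmonic phase φ₀.  (α, d)
  start at the best of a 6 × 6 grid at φ₀; the nodes sit at the centers of
  six equal bins over α ∈ [−90°, 90°] and d ∈ (0, 1], avoiding the
  degenerate edges α = ±90° and d = 0.
* **Unbounded optimization.**  Levenberg-Marquardt
  (`scipy.optimize.least_squares`, method `lm`, ftol = xtol = gtol = 1e−10,
  ≤ 200 iterations — the fits are 3-parameter on ≤ 90 points, so tight
  tolerances are cheap) runs over unbounded (φ_u, α_u, d).  The model is
  evaluated through the unit axis vector
  v = (cos α cos φ, cos α sin φ, sin α) and |d|; since f depends only on
  the fiber *axis* (v and −v are the same fiber) and is odd in d, this is
  identical to folding (φ_u, α_u, d) onto the half sphere before every
  evaluation (property-tested), and avoids hard parameter bounds entirely.
* **Symmetrization.**  The solution is folded into φ ∈ [0, π),
  α ∈ [−π/2, π/2], d ≥ 0 via φ = φ_u mod π and
  α = ((α_u + π/2) mod π − π/2) · sgn(½ − ⌊(φ_u/π) mod 2⌋).  The degenerate
  pole output α = +π/2 arising from the sign factor is canonicalised to
  −π/2 (the same axis) so the mapping is exactly idempotent; vectors within
  1e−9 of ±z report (φ = 0, α = ±π/2) since the azimuth is undefined there.
* **Diagnostics.**  The result carries χ² (never above its initialization
  value — if LM cannot improve, the grid point is returned with a
  convergence flag rather than an exception), R² = 1 − χ²/Σ(w·I_N)², and
  parameter covariances (JᵀJ)⁻¹ from the weighted Jacobian.  d is *not*
  constrained to ≤ 1: fitted d > 1 and elevated χ² flag pixels the
  single-fiber model does not describe (crossing fibers, artifacts).

Image stacks are fitted pixelwise (`fit_image`), deterministically for any
worker count; pixels whose planar transmittance falls below 10% of the
stack's 99th-percentile value are masked as background (NaN).

## Monte-Carlo validation

The simulator generates exactly the measurement the fitter expects: the
ground-truth axis is rotated into the planar + N/E/S/W views with
τ = 5.51° applied directly (the internal angle; no Snell conversion in
simulation), noise-free profiles are computed at mean transmittance 2500
counts, and every count is replaced by a negative-binomial draw with
variance 3× the mean.  Note that "transmittance 2500" is the *profile
mean*; this convention reproduces the package's reference error surface,
whereas treating 2500 as twice the mean does not.

* **Accuracy study** (`run_accuracy_study`): ground truths on an (α, d)
  grid at fixed φ = 45° — the worst case relative to the four tilt
  azimuths — with per-configuration means of the acute axis error
  γ = arccos |v̂·v| (≤ 90° by the half-sphere symmetry, so no wrap-around
  handling is needed for φ) and of σ_d = |d̂ − d|/d.  Full-design defaults
  are α ∈ {0, 1, …, 90}°, d ∈ {0.01, …, 0.9}, 100,000 replicates per cell;
  the bundled studies and `scripts/acceptance.py` use a coarse grid
  (α step 10°, d step 0.1) with 300–2000 replicates per configuration,
  which resolves the surface's shape while keeping single-CPU runtimes in
  the minutes.
* **Bias study** (`run_uniform_study`): orientations drawn uniformly on
  the sphere (normalized Gaussian triples) at d = 0.5; true and fitted
  inclinations are binned into density-normalized 0.25° bins.  The truth
  histogram follows p(α) ∝ cos α; the least-squares amplitude of
  a·cos α in per-degree units is π/360 ≈ 0.008727 analytically, and
  ≈ 0.0087 from 500,000 samples.  A biased estimator distorts this
  histogram (the classical analytical DFT solver depletes α ≈ 0°); the
  ROFL histogram is compared to the truth by a total-variation distance
  after aggregating to 3° bins, so that sampling noise at desk-scale
  sample counts does not drown the bias signal.

What the synthetic studies do *not* emulate: spatial structure
(every pixel is independent), crossing fibers and partial-volume mixing,
view misregistration, illumination calibration drift, and wavelength
dependence.  Passing them shows estimator correctness and efficiency under
the stated noise model, not robustness to those experimental effects; the
phantom module adds spatial regions but inherits the same signal model.

## Accuracy figures and a known discrepancy

At the reference conditions the fit is statistically efficient: its
parameter scatter matches the Cramér-Rao bound of the count-noise model
(e.g. σ_α 2.29° observed vs 2.26° bound at α = 40°, d = 0.5).  The
resulting surfaces: minimal ⟨γ⟩ ≈ 1°, ≈ 2.3° on average over
d ∈ [0.2, 0.9] × α ∈ [0°, 80°] with a worst case ≈ 10° at (80°, 0.2), and
⟨σ_d⟩ ≈ 42% for a perpendicular fiber at d = 0.9.  Thin sections
(d < 0.05) leave almost no birefringent signal and orientations become
essentially random.

One caveat: the α–d ridge (only d·cos²α is strongly constrained; the
split comes from the weak tilt signal) makes σ_d grow steeply with
inclination — already at the Cramér-Rao bound, the *region average* of
⟨σ_d⟩ over d ∈ [0.2, 0.9] × α ∈ [20°, 90°] is ≈ 20% on the coarse grid,
dominated by α ≥ 80°.  A much smaller region average sometimes quoted for
this setting (≈ 5%) is not attainable by any unbiased estimator consistent
with the other figures above, and the corresponding acceptance test is
expected to fail; the per-configuration values away from steep fibers
(≈ 2–10% for α ≤ 60°) are the meaningful summary.

## Numerical and design notes

* Angles are radians internally, degrees at every I/O boundary (TIFF/CSV/
  CLI); direction maps are written in [0°, 180°), inclination in
  [−90°, 90°].
* Cartesian convention v = (cos α cos φ, cos α sin φ, sin α): α is the
  elevation out of the sectioning plane.
* Tilt labels map N→ψ=0°, E→90°, S→180°, W→270° (ψ_j = 2π(j−1)/N_tilt);
  simulation statistics are invariant to this labeling.
* The acute angle is evaluated as atan2(‖v₁×v₂‖, |v₁·v₂|), which keeps
  full precision near 0 where arccos loses half the significant digits.
* Retardation ratios pushed above 1 by noise are clamped to 1 with a
  warning (the fitter refits raw profiles anyway); numerically constant
  profiles report the φ = 0 convention.
* Degenerate inputs: zero vectors, non-positive transmittance and
  overlapping phantom regions raise; non-positive counts are floored at
  1 for variance evaluation; LM non-convergence returns the best point
  with a flag, never an exception.
* An `InclinationSolver` adapter (MeasurementSeries → PixelParams) lets a
  third-party analytical solver be benchmarked through the same studies;
  none is bundled.
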