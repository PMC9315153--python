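# Methods

This note records the mathematical conventions and modelling choices
behind `polarscope`, in the order of the processing chain.

## Stokes/Mueller conventions

Stokes vectors are `(s0, s1, s2, s3)` with `s1` the horizontal–vertical
linear component, `s2` the ±45° linear component and `s3` the circular
component. Frame rotations by `α` act on `(s1, s2)` through the usual
`2α` rotation. A quarter-wave plate with horizontal fast axis maps
+45° linear light to circular with `s3 = −1` under this sign
convention; all modules share it, so only relative signs matter.
`is_physical_mueller` checks the standard necessary conditions
(passivity of the first row/column, `|M_ij| ≤ M11`, and output-DOP
bounds over a probe set).

## Dual-rotating-retarder polarimetry

The polarization state generator is a horizontal polarizer followed by
a quarter-wave plate at `θ`; the analyzer is a quarter-wave plate at
`5θ` followed by a horizontal polarizer. One measurement is 30 steps of
6°, spanning 180°. The detected intensity is a trigonometric polynomial
in `ψ = 2θ` containing harmonics up to `12ψ` (25 real coefficients).

Two reconstruction routes are provided and agree to machine precision:

- **lstsq** — least squares on the 30×16 polarimetric measurement
  matrix whose rows are `a_k ⊗ s_k` (analyzer row vector, generator
  Stokes vector at step `k`).
- **fourier** — the trace is reduced to its harmonic coefficients
  `α₀, αₙ, βₙ` by discrete Fourier analysis, and the linear map from
  the 16 Mueller elements to the 25 harmonics is inverted. This is the
  classical harmonic (Azzam-type) reconstruction, realized as a
  numerical solve instead of a transcribed coefficient table.

Noiseless simulated traces of ideal standards (air, polarizers,
quarter-wave plates) reconstruct to ≈10⁻¹³ % error, comfortably inside
the 1 % calibration bound typical of real instruments.

## Lu–Chipman polar decomposition

`M = M_Δ · M_R · M_D` (depolarizer · retarder · diattenuator), computed
on the M11-normalized matrix:

- Diattenuation `D = sqrt(M12² + M13² + M14²) / M11`. (Some published
  summaries omit the `1/M11`; the normalized form is used so `D` is
  dimensionless and scale-invariant.)
- `M_D` is assembled from the diattenuation vector; `M' = M · M_D⁻¹`,
  and `m_Δ = sign(det m') · (m' m'ᵀ)^{1/2}` via a batched symmetric
  eigendecomposition; `M_R = M_Δ⁻¹ M'`.
- Linear retardance
  `δ = arccos{ sqrt[(M_R22 + M_R33)² + (M_R32 − M_R23)²] − 1 }`.
  A widely cited variant misprints the indices inside the first square
  (summing `M_R(2,2) + M_R(3,2)`), which fails even for the identity
  retarder; the standard form above is implemented.
- Depolarization `Δ = 1 − |tr(M_Δ) − 1| / 3`.

Near-singular diattenuators (`D → 1`) are clamped for invertibility and
the affected pixels are flagged in the validity mask. Forward-composed
random products recover `(D, δ, Δ)` to better than 10⁻⁸.

## Texture quantification

Parameter maps are normalized to 8-bit gray by an affine map of the
image's own min/max to [0, 255] (round half-up). Mean and Entropy are
first-order histogram moments on the 256-level image. The GLCM is
computed after uniform re-quantization to `Ng = 64` levels, at an
inter-pixel displacement `d` chosen per magnification
(1, 3, 5, 11, 15 for 4×…60×), pooled symmetrically over the directions
0°, 45°, 90°, 135° and normalized. Diagonal neighbors at displacement
`d` are the `(d, d)` offsets (Haralick's Chebyshev convention).
Features use 1-based level indices:
Contrast `Σ (i−j)² p`, Correlation `(Σ ij·p − μxμy)/(σxσy)`,
Energy `Σ p²` (the angular second moment; some libraries report its
square root), Homogeneity `Σ p / (1 + (i−j)²)`. Correlation is NaN for
constant images. An independent brute-force pair-enumeration oracle in
the test suite pins the counting.

## Infinite-cylinder scattering

The exact series solution for an infinite circular cylinder at oblique
incidence (zenith angle ζ between the propagation direction and the
cylinder axis) is evaluated from Bessel/Hankel functions with the
classical truncation order `ceil(x + 4x^{1/3} + 2)` plus a safety
margin, and a convergence check on the trailing coefficients. The 2×2
amplitude matrix `[[T1, T4], [T3, T2]]` over the scattering-cone
azimuth Θ is converted to Mueller form through the coherency
transformation `M = A (J ⊗ J*) A⁻¹`.

Validation: at normal incidence the cross-polarized coefficients vanish;
single-scattering Mueller matrices have Gil–Bernabeu purity 1; the
sub-wavelength limit reproduces the Rayleigh-wire closed form (parallel
mode uniform in Θ, perpendicular mode ∝ cos²Θ) to better than 1 %.
Forward fractions within ±15° increase monotonically across radii
100 nm → 1.5 µm, the mechanism that couples fiber caliber to the
fraction of scattered light an objective accepts
(`acceptance_half_angle(NA) = arcsin(NA/n)`, 14.5° at NA 0.25, 53.1°
at NA 0.80).

## Polarized Monte Carlo (oriented-cylinder slab)

Photons traverse a 6 µm slab of cylinders aligned on average with the
lab x axis; each interaction draws a fresh axis with independent
in-plane and out-of-plane Gaussian tilts (σ = 30°). Scattering from an
infinite cylinder is confined to the specular cone around the axis, so
the deflection is parametrized by the cone azimuth Θ alone, sampled by
inverse CDF from the *unpolarized* (M11) density at the current
axis–direction angle ζ. Because the sampled geometry is
polarization-independent, all six input basis states (H, V, ±45°, R, L)
share identical photon paths (common random numbers), and polarization
enters through per-event Mueller factors `M(Θ)/M11(Θ)` (times the
relative unpolarized scattering rate) carried in the Stokes vectors.
Transverse reference frames are tracked explicitly and Stokes vectors
are rotated between the cylinder frame and the detection frame. Exit
photons are binned by polar angle; each bin's Mueller matrix is the
least-squares solve of the six input/output Stokes pairs.

**Dichroic extinction.** Fine cylinders scatter axis-parallel light
about twice as strongly as perpendicular light (channel cross sections
`q∥/q⊥ ≈ 1.97` at 100 nm radius vs 1.007 at 1.5 µm, from the exact
series). A model with a single polarization-independent extinction
coefficient therefore gets the diattenuation-vs-collection-angle trend
*backwards* in thin slabs: the dominant ballistic beam would carry
`D = 0` while wide-angle scattered light carries all the diattenuation.
The transport consequently applies a per-segment differential
extinction — a diattenuator `exp(−(µ∥−µ₀)l)`, `exp(−(µ⊥−µ₀)l)` in the
frame of an ensemble axis draw, with `µ₀ = 200 cm⁻¹` the unpolarized
coefficient — while keeping path geometry polarization-independent.
With it, transmission at small acceptance angles is dominated by the
strongly diattenuated quasi-ballistic beam, and `D` decreases as the
collection cone widens for fine fibers while staying near zero for
coarse ones. The analogous *retarding* beam birefringence is not
modelled. The trends hold for the cumulative (acceptance-cone) reading
of `D` vs angle; annular differential readings instead increase with
angle, because per-event diattenuation grows with Θ.

Invariants: zero scattering yields the exact identity Mueller matrix,
and transmitted + reflected photon counts equal the launched count
exactly.

## Synthetic fibrous regions and resolution degradation

Regions are correlated-random-walk fiber strokes with Gaussian
cross-profiles on a 360×360 native canvas at 0.0575 µm pitch (the 60×
sample-plane pixel of a 3.45 µm camera; 20.7 µm field of view — a
desk-scale problem size chosen so a 27-region × 5-magnification study
runs in minutes). Each pixel carries a fiber density (softly saturating
with overlap), a doubled-angle-averaged axial orientation, and a radius
from a thin (100–200 nm) / coarse (1–1.5 µm) mixture. The optical model
composes, per pixel, `M = M_Δ · M_R(δ, axis) · M_D(D, axis)` with
`δ ∝ density`, `Δ = Δ₀ + c·density` (the planted δ–Δ coupling;
a decoupled variant draws constant per-region floors), and `D` tied to
the radius-dependent cylinder dichroism — so Lu–Chipman decomposition
of a native image recovers the planted maps exactly (≤10⁻¹³).

Each objective rendering applies a Gaussian PSF of sample-plane sigma
`0.21 λ/NA` to all 16 element maps, then resamples to the camera pitch
divided by the magnification (anti-aliased linear resize). Both steps
are convex pixel combinations, so degraded images remain physical
Mueller images; this generalizes integer-factor box averaging to
non-integer pitch ratios.

## The resolution study

For every region × magnification, the pipeline decomposes the rendered
image and summarizes each of the D/δ/Δ maps with the six texture
statistics, producing a tidy feature table, per-feature Pearson
correlation matrices across magnifications, quartile (box-plot) tables,
and the across-region δ–Δ correlation per magnification. With the
coupled generator the planted δ–Δ correlation is recovered
(r ≈ 0.95–1.0 across magnifications); the decoupled generator yields
|r| < 0.4. Per-region mean δ is nearly invariant under the degradation
model (adjacent-magnification r ≥ 0.99), while high-order texture
statistics (Contrast, Correlation) decorrelate between the extreme
magnifications — the resolution-dependence the study quantifies.

## Limitations

- The polarimeter model is noiseless and ideal (no retardance error,
  axis misalignment or detector noise); the 1 % bound is a ceiling
  check, not an error model.
- The Monte Carlo omits beam birefringence, finite-cylinder end
  effects, cylinder–cylinder correlation, and refractive-index
  mismatch at the slab boundaries.
- Synthetic regions plant retardance and diattenuation aligned to one
  local axis per pixel and use a diagonal depolarizer; real tissue
  exhibits axis dispersion within a pixel and anisotropic
  depolarization.
- Degradation treats the PSF as Gaussian and ignores objective
  aberrations, depth sectioning and photon noise.
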