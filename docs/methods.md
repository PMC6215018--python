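# Methods

## The reconstruction

HiLo optical sectioning fuses two co-registered widefield fluorescence
images of the same field: a uniform-illumination image `i_u` (rotating
diffuser) and a stationary laser-speckle image `i_s`. Out-of-focus signal
is identified by the local contrast of the imaged speckle, which decays
with defocus; in-focus high spatial frequencies are taken directly from
`i_u`, which is diffraction-limited.

The pipeline, in order:

1. **Difference image** `i_d = i_s − i_u`. Subtracting the uniform image
   removes specimen structure, leaving only the illumination modulation
   (signed, near zero-mean).
2. **Band-pass** of `i_d`:
   `BP(k) = exp(−k²/4σ_bp²) − exp(−k²/2σ_bp²)`, a difference of two
   Gaussian low-passes (zero at DC, peak gain 1/4 at `k = 2σ_bp√ln2`).
   Restricting contrast evaluation to a band accelerates its decay with
   defocus and couples the sectioning strength to `σ_bp`.
3. **Local contrast** `C = sd/µ` in a sliding `Λ×Λ` window: `sd` is the
   population standard deviation of the band-passed difference, `µ` the
   local mean of `i_u`. Using `i_u` for the denominator is deliberate:
   `i_d` is zero-mean by construction, so the literal quotient on the
   difference image would be singular; normalising by the local specimen
   brightness is what makes `C` a contrast. Windows whose `i_u` mean
   falls below 1e−6 of the global mean return `C = 0` (background).
   Edges are reflect-padded.
4. **Weighting**: `i_su = i_u · C`, then `i_LP = LP(i_su)` where
   `LP = 1 − HP` and `HP` is a Gaussian high-pass with half gain at the
   cut-off `k_c` (`HP(k) = 1 − exp(−k² ln2 / k_c²)` — the simplest form
   satisfying `HP(k_c) = 1/2` exactly).
5. **Hi component**: `i_HP = HP(i_u)`.
6. **Seam factor** `η = |Î_HP|(k_c) / |Î_LP|(k_c)`, estimated as the mean
   spectral magnitude over a one-bin-wide annulus at `k_c` (a single-bin
   point evaluation is noise-dominated; the azimuthal average is the
   stable estimator of the radial spectrum). If the Lo spectrum is
   degenerate (e.g. `i_s = i_u`), `η` falls back to 1 with a warning and
   the pipeline collapses to a pure high-pass of `i_u`.
7. **Fusion**: `i_HiLo = i_HP + η·i_LP`. Negative values are kept by
   default so the linear identity is exactly testable; clamping to 0 is
   optional.

## The sigma calibration

A single user parameter `σ ≥ 1` controls the section thickness through

    σ_bp = 0.1/σ  cycles/pixel,   k_c = 0.18·σ_bp,   Λ = 1/(2 k_c)
    (Λ rounded to the nearest odd integer so windows are centred).

`σ = 1` anchors the band at 0.1 cycles/pixel (k_c = 0.018, Λ = 27), the
highest band frequency at which thickness still responds linearly to σ.
The *inverse* mapping of σ onto frequency is forced by two observations
about the method itself:

- defocused speckle contrast decays at a rate roughly proportional to
  the band frequency, so section thickness scales like 1/k_band; a
  thickness that grows (near-linearly) with σ therefore requires
  k_band ∝ 1/σ;
- speckle-leakage artifacts arise when the contrast window holds too few
  imaged grains and are observed to vanish at larger σ, which requires
  Λ to grow with σ.

Under this calibration Λ ≈ 27.8·σ pixels, so the window always spans
≥ 9 grains of a 3-pixel speckle pattern and leakage is confined to
explicit window overrides or very coarse speckle.

## The synthetic imaging model

The simulator emulates a 0.47-NA mesoscope detection path: 0.7 µm
lateral and 7 µm axial FWHM at a 224 nm pixel pitch (defaults of
`ImagingModel`).

**Illumination.** Fully developed speckle is generated by the
pupil-phase method: unit amplitudes with uniform random phases on a
centred frequency-plane disk of radius `0.5145/grain_px`, intensity =
|inverse FFT|², normalised to mean 1. The intensity autocovariance FWHM
then equals `grain_px` (verified by round-trip estimation within ±20%
for grains 3–20 px). Rotating-diffuser illumination is the mean of `n`
independent patterns (residual contrast `1/√n`; the default 100
realizations leave ~10% residual modulation in `i_u`). Illumination is
treated as z-invariant: sectioning in the simulation arises from
detection-side defocus only. Real speckle also decorrelates axially and
the physical section thickness depends on the illumination NA; this
simplification is why simulated thickness targets carry ±20–25%
tolerances rather than printed precision.

**Detection.** Each specimen slice is multiplied by the illumination,
filtered by a defocus-dependent MTF, and summed — a widefield camera
performs no axial rejection, so the DC gain is 1 at every defocus and
total energy is conserved. Two defocus laws are provided:

- `"otf"` (default): diffraction-limited in-focus MTF (pupil
  autocorrelation, cut-off `1.029/lateral_fwhm`) times the Hopkins
  defocus factor `2J1(a)/a`, `a = (4π·1.772/axial_fwhm)·|dz|·k̃(1−k̃)`
  with `k̃ = k/k_cut`. Both constants follow from scalar diffraction
  (axial PSF FWHM ≈ 1.772 λ/NA², cut-off 2NA/λ) expressed through the
  two stated FWHMs. The essential feature is that mid-band frequencies
  defocus fastest while near-cutoff frequencies decay slowly — the
  behaviour that makes the measured section *thicken* as σ lowers the
  band frequency, and the reason this is the default.
- `"gaussian"`: a Gaussian blur with
  `FWHM(dz) = lateral_fwhm·√(1+(dz/z_R)²)`, `z_R = axial_fwhm/2`. A
  smooth, parameter-light stand-in whose axial decay is monotone in
  frequency; useful for quick tests but incapable of reproducing the
  thickness-vs-σ growth, so it is not the default.

**Noise.** Poisson photon noise (exact below 20 expected counts,
scaled-variance Gaussian above — correct variance structure at a
fraction of the cost), additive Gaussian read noise, constant offset.
Rendered fixtures default to ~2000 expected counts per unit emission,
3-count read noise and a 0.05 pedestal. All randomness derives from one
seed via `SeedSequence` spawning; fixtures are bit-reproducible.

**Phantoms.** The tilted-layer phantom places a Gaussian axial profile
(default FWHM 0.8 µm, thin relative to the 7 µm axial response) at
`z(x) = (x − focus_column)·pixel·tilt`, uniform along rows, with unit
integrated density per column. The bilayer phantom pairs an in-focus
plane of isolated bright bands with a uniform plane defocused by more
than the axial FWHM, giving line profiles with well-defined peaks and
out-of-focus background minima.

## Measurements

**Section thickness** is measured as on the physical instrument: five
one-pixel-thick horizontal line profiles, evenly spaced within the
central 50% of rows, each fitted with `A·exp(−(x−x₀)²/2w²) + baseline`;
the lateral FWHM `2√(2ln2)·w` converts to axial microns via the tilt
(`pixel·height/base`). Fits are initialised from moments of a 5-pixel
smoothed copy (raw profiles carry speckle residue) and bounded to keep
the solver away from single-pixel artefacts; a peak must rise 3 noise
standard deviations above the baseline.

On the standard fixture (2048×512, grain 3 px, ±30 µm axial span,
seeded), thickness at σ = 1…10 rises from ≈ 5.8 µm to ≈ 23 µm, monotone
and near-linear (R² > 0.99), with σ = 1/2/3 at ≈ 5.8/7.8/10.1 µm —
within the stated tolerances of the reference system's 6.8/8.7/~10 µm.
The σ = 1 value approximates the simulated 7 µm axial response (within
20%), i.e. the measurement pipeline recovers the known ground truth.

**Contrast** is the peak/minimum ratio of a one-pixel vertical line
profile. The minimum must be positive: either subtract the camera offset
upstream, or (as the bilayer study does) keep the same pedestal in both
profiles being compared. On the bilayer fixture the HiLo contrast
exceeds the widefield contrast by well over the 2× floor asserted in
tests; the absolute improvement is specimen-dependent and not a claim
about real tissue.

**Speckle leakage** is scored as the Pearson correlation between the
reconstruction and the raw speckle pattern, both high-pass filtered at
the grain frequency `1/grain_px`. The warning threshold of 0.2, and the
3-grains-per-window-side rule, operationalise the qualitative guidance
that several imaged grains must fit in the sampling window; on fixtures
the window rule is the binding criterion (an undersampled window
corrupts the contrast map through its *envelope*, which this linear
score does not fully capture — a known limitation).

## Large frames and tiling

Mesoscope frames reach 259.5 Mpx; whole-frame FFTs at that size are
memory-hostile. `tiled_reconstruct` processes halo-padded tiles and
stitches the cores. The halo must cover the contrast window plus three
standard deviations of the widest spatial filter kernel
(`1/(2π·min(k_c/√(2ln2), σ_bp))` pixels); below that bound the call
fails with the required minimum. η is computed once per frame — on a
block-averaged pass when the longest side exceeds 1024 px — never per
tile, because per-tile values would create visible brightness steps.
Interior pixels agree with the full-frame reconstruction to ~1e−8
relative on 512² fixtures (tolerance asserted: 1e−3).

## Numerical conventions and degenerate inputs

- Frequencies are in cycles/pixel everywhere; the DFT is numpy's
  unnormalised-forward convention (filters are pure gains, so the
  convention cancels).
- FFT filtering assumes periodic boundaries; no padding or apodization
  inside `apply_filter` (tiling handles edge effects at scale); the
  sliding window uses reflective padding.
- `i_s = i_u` collapses the pipeline to a pure high-pass of `i_u`
  (η → 1 with a degenerate-spectrum warning).
- Joint rescaling of both inputs rescales the output by the same factor
  (η and C are scale-invariant).
- Zero tilt makes the thickness conversion factor 0; reported as 0 with
  a degenerate-geometry warning.
- 32-bit float TIFF output with no rescaling is the default so the
  `i_HP + η·i_LP` identity survives a write/read cycle; 16-bit export
  applies a documented global min–max normalization.

## Known limitations

- Detection-only sectioning: no illumination-side axial decorrelation,
  no scattering/turbidity, so the inhomogeneous-brightness effects seen
  in thick turbid specimens are out of scope.
- The Hopkins factor is an approximation to the true defocused OTF
  (it ignores the oscillatory fine structure's phase interplay with
  apodization), and the in-focus MTF assumes an unaberrated pupil.
- Absolute contrast-improvement factors on real tissue are not
  reproduced — only the direction and a conservative floor.
- The leakage score is a linear correlation and underestimates envelope
  -type leakage; the window rule is the reliable detector.
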