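# Methods

`fntdose` implements LET-based estimation of out-of-field neutron dose with
fluorescent nuclear track detectors (FNTDs, Al2O3:C,Mg) read out by confocal
fluorescence microscopy. This note describes the models, the defaults and
the reasoning behind the open design choices.

## Measurement model

A detector readout is a stack of 11 optical sections, 512 x 512 px covering
100 um x 100 um, at nominal depths 2, 4, ..., 22 um. Every charged particle
crossing the polished surface leaves one fluorescent spot per section,
laterally displaced between sections by `dz * tan(theta)` along its azimuth,
where `theta` is the polar angle against the surface normal. Depths are
treated as nominal stage depths; no refractive-index rescaling is applied,
and the synthetic generator uses the same convention, so the two sides are
consistent by construction.

The analysis chain is:

1. **Spot detection** — per-section background is the median; the detection
   threshold is `median + max(k * MAD, floor)` with `k = 5` and a 30 a.u.
   absolute floor (the floor matters only for near-noiseless synthetic
   images, where the MAD collapses to zero). Connected components of at
   least 4 px become spots. Each spot carries an intensity-weighted
   centroid and a background-subtracted peak intensity refined by separable
   log-parabola interpolation through the brightest pixel and its
   neighbours (exact for a sampled Gaussian; the refinement is clamped at
   a factor 2 to stay robust under shot noise).
2. **3D linking** — greedy nearest-neighbour association between
   consecutive sections within a slope-limited radius
   `r0 + dz * tan(theta_max)` (defaults `r0 = 1 um`, `theta_max = 75 deg`).
   Where two chains contend for the same spot (crossing tracks, merged
   spots) secondary links are recorded and chains are walked with a
   directional-consistency rule (successive displacement vectors must agree
   within 30 degrees). A spot used by two chains, or two chains approaching
   within 1.5 um in the same section, marks all involved chains as
   `rejected_overlap`; their intensities are considered corrupted and they
   are excluded downstream. No gaps are allowed: chains occupy consecutive
   sections only.
3. **Geometry** — total-least-squares line fit (principal axis of the 3D
   centroid cloud) gives `theta`, azimuth, and depth extent. On noiseless
   synthetic tracks the recovered angle is exact to well below a degree for
   `theta <= 60 deg`.
4. **Track intensity** — mean of the per-section peak intensities from the
   second to the penultimate occupied section; undefined for chains
   spanning fewer than 3 sections (such stubs are classified as delta
   electrons anyway).
5. **Classification** — out-of-field chains spanning at most 4 sections are
   delta-electron stubs; in the alpha-reference region, chains whose
   deepest spot stays within 16 um (the alpha range in alumina) are
   alpha-reference tracks and anything deeper is an out-of-field ion
   leaking into the region.

## Calibration

**Angular intensity correction.** Track-spot intensity falls with polar
angle. The relative intensity is modelled by the logistic

    y(theta) = a / (1 + exp(b (theta - c))) + 1 - a / (1 + exp(-b c)),

whose offset guarantees `y(0) = 1`. With the fitted parameters
`a = 0.79`, `b = 0.15 /deg`, `c = 15 deg`, the curve predicts 36% of the
normal-incidence intensity at 30 degrees, saturates near 0.28 at large
angles, and hence corrects intensities by at most a factor ~3.5. Measured
intensities are divided by `y(theta)` before the LET conversion. The model
is fitted by nonlinear least squares (inverse-variance weighted when
intensity uncertainties are supplied, bounded to `a in (0,1]`,
`b in (0,1]`, `c in [0,90]`, initialised at `(0.7, 0.1, 20)`); the fit
reports 95% confidence intervals, R^2 and a 95% prediction band.

Calibration exposures at several nominal angles are reduced with a sum of
Gaussians fitted to the 1-degree-binned angle histogram ("fourth-order
Gaussian" is read as four components, one per exposure angle, initialised
at the four largest histogram maxima and fitted on raw counts), and a
single Gaussian fitted to the 100-a.u.-binned intensity histogram of the
tracks within one sigma of each angle peak.

In a simulation study with intensity scatter of 0.03 (consistent with the
residual scatter implied by the reported R^2 = 0.991 at nine angle points)
the fit recovers each parameter within the reported 95% confidence
half-widths in >= 90% of replicates. The simulated intensity is evaluated
at the realised (jittered) angle of each point, because in the measurement
protocol the angle mean and the intensity mean are estimated from the same
track population and are therefore self-consistent.

**Sensitivity.** Inter-detector sensitivity (reported to vary by factors
0.6–2.5) is corrected with an alpha-reference irradiation of constant
radiation quality: the per-detector alpha intensity peak, divided by a
fleet reference, gives a factor `s` by which all intensities of that
detector are divided. The fleet reference defaults to the median of the
per-detector peak means (absolute anchoring is not required, only relative
consistency); at least 200 alpha tracks are required.

**LET conversion.** The intensity-to-LET curve is pluggable: log-linear
(`ln LET = p0 + p1 ln I`), power law, or a monotone knot table interpolated
log-log. The shipped default is `I = 1000 * sqrt(LET)` (a.u., keV/um),
an invertible stand-in with realistic spot amplitudes shared by the
synthetic renderer so that rendered stacks round-trip through the analysis.
Intensities outside the calibration validity range are clamped to its edge
and flagged per track rather than silently extrapolated.

## Dosimetry

For N tracks with mean LET in water `L_i` (keV/um) and polar angle
`theta_i` crossing area `A` (cm^2),

    D = k / (rho A) * sum_i L_i / cos(theta_i),      k = 1.602e-9,

with `rho` in g/cm^3; `k` is derived in code from the elementary charge by
dimensional analysis (keV -> J, /um -> /cm, J/g -> Gy). The dose equivalent
weights each term by the ICRP-60 quality factor

    Q(L) = 1                 L < 10
    Q(L) = 0.32 L - 2.2      10 <= L <= 100
    Q(L) = 300 / sqrt(L)     L > 100,

evaluated in water (so `rho` is water density when computing H). The
published piecewise form has a small step at L = 100 (29.8 vs 30.0); it is
kept verbatim, without smoothing.

Filters follow the measurement protocol: only particles able to reach
10 um depth along their slant path are scored (image tracks must be
identifiable over at least 5 sections; phase-space records must satisfy
`range(E) >= 10 um / cos(theta)` via a Bragg–Kleeman range table for
alumina, `R = alpha E^p` with `p = 1.735` and `alpha` anchored so a
~1.9 MeV proton — LET in water near 25 keV/um — has a 10 um range, scaled
to other ions as `(a/z^2) R_p(E/a)`). The LET split threshold is 25 keV/um
with the boundary assigned to the low-LET class. Fluence counts crossing
tracks per area without angle weighting, after delta and overlap removal
but before the 10-um range filter (switchable).

Uncertainties: Poisson on counts for fluence; a seeded per-track bootstrap
(default 1000 resamples) for experimental D and H; batch statistics
(k = 10 batches) for simulated, weighted records.

Spectra are density-normalised with linear 1 keV/um bins up to the
threshold and 10 logarithmic bins per decade above it, together with the
relative cumulative dose equivalent versus LET (non-decreasing, ending at
1). Angle summaries report median, interquartile range and the mode of the
1-degree-binned histogram.

## Synthetic data generator

The generator defines the study conditions used throughout the tests:

* Areal track density 5e4 per cm^2 per Gy of target dose (Poisson), the
  order of magnitude of the measured out-of-field fluences.
* Polar angles from a scaled Beta(2.2, 5.2) on [0, 90) deg: mode at
  20 deg, right-skewed, ~7% of tracks beyond 50 deg.
* LET: 99% low-LET bulk from a lognormal (median 2 keV/um, sigma 0.6,
  truncated to [0.5, 25]) and a 1% high-LET admixture drawn log-uniformly
  on [25, 500] keV/um. The admixture exercises the quality-factor
  amplification — a ~1% fluence fraction carrying more than half of H —
  without claiming a physical spectrum.
* Delta-electron stubs (0.15 per ion) with residual depths of 6–8.9 um,
  visible in 3–4 consecutive sections; alpha-reference tracks at
  near-normal incidence with constant nominal LET (100 keV/um) and a
  15 um residual depth, vanishing before the 16 um classification bound.
* Rendering: one anisotropic Gaussian spot per section, peak amplitude
  `intensity_model(LET) * s * y(theta)`; the in-plane elongation grows
  with the per-section track segment `dz tan(theta)` (added in quadrature
  to the 0.4 um lateral PSF), reproducing the circular -> elliptical ->
  line-like spot morphology. Beyond a track's residual depth the amplitude
  falls off with a 0.4 um axial sigma. Noise is additive Gaussian
  background (mean 100, sd 8 a.u.) plus Poisson shot noise on the spot
  signal. The detector sensitivity `s` enters only as the amplitude scale.
* Per-stack sampling uses a 30 um stationary margin around the field of
  view so tracks can also enter the imaged volume sideways, as in a real
  extended field; the manifest flags which tracks enter the surface inside
  the scanned area.

Every rendered spot is recorded in a manifest keyed to its source track
(only spots whose centre lies inside the field of view are listed as
countable), so recovery can be validated exactly. What the generator does
**not** emulate: depth-dependent signal attenuation, optical aberrations
and a non-Gaussian PSF, detector-intrinsic spatial sensitivity variation,
track curvature, and physically consistent neutron secondary spectra.
Passing the recovery tests therefore demonstrates the correctness of the
analysis chain under the stated noise model, not detector physics.

The phase-space generator emulates event-by-event scoring of charged
particles crossing a plane: species mix of ~88.5% recoil protons, 10%
deuterons and <1% heavier fragments; per-species log-uniform energy bands;
LET tied to energy through the rough stopping-power scaling
`L = 27 z^2 (E/A)^-0.77 keV/um` so records are internally consistent.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.Generator`; fixed seeds give
  bit-identical outputs.
* Linking ties are broken by distance, then lowest spot index; spots are
  canonically ordered by position, making linking invariant to input
  permutation.
* Two identical centroids at different depths give `theta = 0` exactly;
  an all-constant section yields no spots (not an error); an all-equal
  intensity sample returns a zero-width peak with a warning; a flat
  intensity-versus-angle set raises a degenerate-fit error.
* The dose sums are plain vectorised summations; they agree with an
  independent per-track `math.fsum` oracle to 1e-12 relative.

## Problem sizes

The end-to-end validation renders 110 stacks (~550 countable ion tracks,
about 0.011 cm^2 of scanned area) per condition, which resolves the
recovery tolerances (5% fluence, 10% D, 15% H) well above counting noise
while keeping the suite quick. The parameter-recovery study uses 200
replicates at nine angle points.

## Known limitations

* Tracks steeper than ~75 degrees exceed the default linking radius and
  elongate into faint streaks; both the real measurement and this
  implementation under-detect them (they are <2% of out-of-field tracks
  at distal positions).
* The overlap-rejection rate grows quadratically with track density; at
  the default density it removes ~2% of tracks, but crowded alpha-region
  exposures lose noticeably more, which is why the alpha peak is fitted on
  the surviving population.
* The default LET calibration is a stand-in, not a measured curve; all
  absolute dose numbers from synthetic data are internally consistent but
  not detector-calibrated.
* The sub-pixel peak refinement is exact for Gaussian spots but only
  approximate for strongly elongated ones at non-axis-aligned azimuths;
  the residual intensity bias is at the percent level and enters LET
  quadratically through the default square-root calibration.
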