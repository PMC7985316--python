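# Methods

This note records the models implemented in `tddos`, the assumptions they
rest on, the parameter choices that were genuinely open, and what the
synthetic-data tests do and do not demonstrate about real measurements.

## Photon transport

**White Monte Carlo.** Reference temporal point spread functions (TPSFs)
are simulated at *null absorption* only; absorption of any strength is
added afterwards by multiplying each bin by the Beer–Lambert factor
exp(−μa·v·t), v = c/n_sample, evaluated at bin centers. This is exact for
a homogeneous medium because a photon arriving at time t has travelled
exactly the path length v·t, regardless of its geometry — one simulation
therefore serves the entire absorption axis, and the factorization holds
bin-wise to machine precision by construction.

**Similarity relation.** The kernel simulates isotropic scattering with
μs = μs′. Only the reduced scattering coefficient is identifiable from
diffuse transmittance at these optical thicknesses, so the anisotropy
factor is deliberately not a model parameter.

**Boundaries.** A pencil beam enters normally at the entry-face centre;
unpolarized Fresnel reflection/refraction is applied at both faces using
n_sample = 1.41 (soft tissue) against n_external = 1.5 (the PVC holder
panels); internally reflected photons continue propagating. Launch
weight is deposited fully inside the medium (source fibre in contact).
Photons exiting the far face within `detector_radius` (default 0.5 cm)
of the axis are scored by arrival time. At 1 cm slab thickness the
curve *shape* depends only weakly on the detection radius; the value is
configurable and the fibre numerical aperture is not modelled.

**Time grid.** Default 4096 bins of 2.5 ps (0–10.24 ns); the test and
acceptance configurations use 2048 × 5 ps, which spans the same range at
half the cost and still oversamples a < 90 ps instrument response.
Photons whose path exceeds the grid span are tallied as truncated, so
the energy bookkeeping transmitted + reflected + truncated = launched
closes exactly at null absorption.

**Scaling relation.** The radiative transfer equation is invariant under
lengths ×k, μs′ ×1/k, t → k·t; `scale_tpsf` implements exactly this
(bin contents unchanged, time axis stretched). The test suite verifies
that a rescaled simulation is statistically indistinguishable from a
fresh one at the scaled geometry (chi-square homogeneity on pooled bins,
α = 0.01).

**Library and interpolation.** A library holds one null-absorption curve
per node of a geometric μs′ grid (default 25 nodes over 1–70 /cm; the
tests use 10 nodes over 3–28 /cm, covering the synthetic trajectories).
A query between nodes area-normalizes the two bracketing curves,
time-rescales each to the geometrically interpolated mean transit time,
and mixes the shapes linearly in log μs′; total transmittance is
interpolated log-linearly. This is exact at nodes, monotone in mean
transit time, and reproduces a direct simulation at the interval
midpoint to better than 3% over the fit window. The interpolant is only
piecewise smooth across nodes — which matters for the inversion (below).
Queries outside the grid raise; there is no extrapolation.

**Diffusion oracle.** The extrapolated-boundary image-source solution
for a slab, with D = 1/(3μs′), z0 = 1/μs′, and the internal-reflection
coefficient A computed from the Fresnel angular integrals. The
coaxial-disk acceptance multiplies the plane-integrated flux by the
enclosed fraction 1 − exp(−ρ²/4Dvt) of the lateral Gaussian spread.
Absorption enters only through the same separable Beer–Lambert factor,
so the oracle factorizes identically to the Monte Carlo path. At
μs′ = 10 /cm, L = 1 cm the two agree within 10% (relative, on
area-normalized curves over the 80%→1% fit window, 40 ps comparison
bins); the residual is real diffusion-approximation error at ~14
transport mean free paths, which is precisely why the inversion fits
Monte Carlo curves rather than the closed form.

## Instrument model

The IRF is synthetic (Gaussian by default; exponentially modified
Gaussian with a configurable tail constant for SiPM-like responses),
normalized to unit sum, with the width parameter solved numerically so
the FWHM measured off the sampled curve lands within one bin of the
request. Model curves are convolved with the IRF *after* absorption is
applied — convolution and the Beer–Lambert factor do not commute, and
the suite asserts the negative. Convolution is FFT-based but contracted
to agree with direct discrete convolution to 1e-10 relative. Counting
noise is an independent Poisson draw per bin around the expected shape
scaled to the requested total, plus a uniform background; the dispersion
index across replicates is ~1 by test. Afterpulsing, pile-up and
differential nonlinearity are out of scope.

## Inversion

Per wavelength, the fit minimizes the Poisson deviance (weighted least
squares available) between the measured histogram and
amplitude · (library(μs′) · exp(−μa·v·t)) ⊛ IRF, evaluated only between
the first bin ≥ 80% of the peak on the rising edge and the last bin
≥ 1% of the peak on the falling edge. The amplitude is always free and
has a closed form at each (μa, μs′), reducing the search to two
dimensions — the estimate uses the temporal shape only, which the suite
verifies (rescaling counts changes nothing but the amplitude). The
background is estimated from the first 5% of bins by default, or fixed;
a fitted IRF/data time shift exists but is off by default since the
synthesis is shift-free by construction.

Because the library interpolant is only piecewise smooth, the deviance
is multi-modal in μs′ with kinks at the nodes. Initialization therefore
scans a dense μs′ grid (three subdivisions per node interval) and
minimizes over μa *at each scan point* (the μa profile at 1e6 counts is
far too sharp for any fixed seed list), then runs Nelder–Mead from the
best basin and from its two neighbours, keeping the lowest optimum.
One fit takes ~0.2–0.5 s on one CPU with a prebuilt library.

Measured performance on self-generated data (the acceptance script
recomputes these): noiseless round trips are exact to optimizer
tolerance; at 1e6 counts the median absolute error of both parameters
is well under 5%; varying true μa at fixed μs′ across a 3×3 grid moves
the other recovered parameter by under 3% (the time-domain
disentangling claim); parameter RMSE falls monotonically with total
counts.

## Spectral features

* **Power law:** μs′(λ) = a(λ/λ0)^−b, λ0 = 650 nm, fitted linearly in
  log–log; a tracks scatterer density, b effective size. Exact on
  noiseless input; |bias(b)| ≤ 0.02 under 5% multiplicative noise.
* **Peaks:** natural cubic spline through the 10 nm samples, extremum
  located on a 0.1 nm evaluation grid. Localization error is ≤ 1 nm for
  smooth single-peaked bands — which is what makes 4–15 nm shifts
  quantifiable from 10 nm sampling. An extremum on a band edge is
  flagged, not reported as a peak. FWHM is measured at half prominence
  above the higher band-edge minimum. Default bands: hemoglobin
  720–800 nm, emerging peak 810–870 nm (the literature quotes both
  "830 nm" and "840 nm"; the band covers both), 910 nm valley
  880–940 nm, water 940–1010 nm; all configurable.
* **Significance:** two-sided paired t-test per wavelength, pairing by
  sample index, no multiple-testing correction (a Benjamini–Hochberg
  option exists but is off by default, matching common practice in
  small-sample tissue studies). Zero-variance differences are flagged
  degenerate. Type-I error is calibrated: 0.05 ± 0.01 at n = 3 pairs
  over 1e4 null replicates.
* **Signatures:** `detect_signatures` reports presence and a signed
  magnitude for: (1) μa decrease beyond 900 nm, (2) global μs′ change,
  (3) 840 nm peak emergence (interior spline maximum present in treated,
  absent in native; magnitude = prominence gain over the band chord),
  (4) 760 nm redshift, (5) 970 nm blueshift *with* narrowing,
  (6) short-wavelength (650–800 nm) μa rise, (7) μs′ decline from its
  intra-treatment maximum. Magnitudes of (1), (2), (6) use the
  symmetric relative difference so swapping native/treated negates them
  exactly. Signature (7) is a kinetic feature — a decline from the peak
  reached during treatment — and therefore takes the normalized
  scattering time course as an optional input; comparing only the two
  end-state spectra cannot distinguish "rose less" from "rose and fell
  back", and under the canonical plateau magnitudes (×2 at 70 °C, ×3 at
  105 °C) the overtreated end state always remains above the critical
  one even after its charring-driven decline.

## Synthetic tissue generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Chromophore basis.** Packaged parametric band approximations (sums of
Gaussian bands over exponential backgrounds), not tabulated literature
spectra, so nothing external is downloaded: deoxyhemoglobin with its
760 nm band; a flat oxyhemoglobin curve; methemoglobin dominating both
heme species over 780–900 nm with the band that surfaces near 840 nm on
conversion, and retaining a (thermally shifted) 760 nm band so partial
conversion does not erase the observable peak; water with its main band
at 975 nm (shiftable by δ, width-scalable by w) plus a minor 840 nm
sub-band whose amplitude grows as the main band narrows; and an
exponentially decaying charring term (decay constant 180 nm). Native
composition defaults are heart-like: c_Hb = 0.10, c_HbO2 = 0.03, water
fraction 0.75, a = 6.9 /cm, b = 1.2 — giving μa(760) ≈ 0.22 /cm and a
realistic μs′ range of ~3.7–23 /cm across the protocols.

**Protocols.** Linear ramp from 23 °C over 180 s to the set point (70 or
105 °C), 600 s hold, optional exponential passive cooling (τ = 300 s).
Broadband mode: 46 wavelengths (650–1100 nm, 10 nm steps), one spectrum
per minute, 13 spectra over ramp + hold. Kinetic mode: 5 wavelengths
(770/840/910/980/1060 nm) every 10 s for 600 s.

**Trajectories.** All kinetic forms are the package's own choices — the
phenomenology they reproduce is documented, the rate laws are not
measured quantities:

* Hb → metHb: first order (k = 1e-3 /s) in time spent above the 75 °C
  threshold; ~49% conversion by the end of the 105 °C hold, exactly zero
  at 70 °C. A slow first-order Hb pool loss above 60 °C (2.5e-4 /s)
  models chromophore destruction.
* Water: first-order loss gated by a logistic activation above ~60 °C
  and accelerated above 100 °C (dehydration); the band blueshift
  saturates at −5 nm and the width factor at 0.78 via a logistic
  temperature response that is renormalized to vanish at 23 °C.
* Hemoglobin redshift: δ = 15 nm · ((T−23)/82)^2.4, giving ~4 nm at
  70 °C and 15 nm at 105 °C.
* Scattering: a two-stage logistic rise in temperature reaching ×2 at
  70 °C and ×3.3 at 105 °C, a slow additional rise during sub-100 °C
  holds, and a charring-driven decline (up to 15%, τ = 300 s of time
  above 100 °C). b decreases by up to 0.15 under charring.
* Charring absorption amplitude grows only with time above 100 °C,
  saturating at 0.30 /cm (at 650 nm).
* Cooling: the configured fractions of the water-band shift (40%) and
  narrowing (50%) recover; conversion, charring, water loss and the
  redshift do not; μs′ drops a further 5%.
* Threshold ordering (scattering onset 50 °C < metHb 75 °C < charring
  100 °C) is enforced at construction.

Replicate "samples" perturb the native composition log-normally (3%
spread, keeping inter-sample deviation under ~5%). Every record is
synthesized through the same forward model the inversion uses
(library → Beer–Lambert → IRF → Poisson), with per-record seeds spawned
from the dataset seed, so runs are bit-reproducible.

**What the synthetic data does not emulate:** spatial heterogeneity of
the ablation zone, vessel heat sinks, microbubbles, needle artefacts,
wavelength-dependent IRF drift, detector afterpulsing, and the
rapid-transition spectral distortion of minute-long broadband scans.
Passing the end-to-end tests shows the *pipeline* is correct and
self-consistent at realistic count levels; it does not validate the
trajectory rate laws against tissue.

## Numerical choices and degenerate inputs

Seeds are explicit arguments everywhere randomness exists; library node
seeds and dataset record seeds are spawned from the user seed via
`SeedSequence` (kept below 2^31). Empty Monte Carlo curves (no photon
detected) are flagged, never silently zero. Flat or all-zero histograms
are rejected by the window finder. Interpolated library curves are
clipped to zero before the ballistic time. Fit results at the library
boundary are flagged. Failed wavelengths in a spectrum stay NaN and are
never interpolated over. Library persistence is plain text at %.17g, so
save/load round trips are bit-exact.

## Problem sizes

The test and acceptance runs use 2048 × 5 ps grids; 1e6 photons for
causality/scaling checks, 4–6e6 for the diffusion-oracle comparison
(with 40–80 ps comparison bins to keep counting noise below the
tolerance being asserted), 2e5 photons per library node (sufficient
because synthesis and inversion share the library, so node-level noise
cancels in round trips), 1e6 counts per synthesized DTOF, 20–50 noisy
fits per error estimate, and 4000–10000 replicates for the t-test
calibration. These sizes are the package's defaults for its own
validation; all are parameters.

## Known limitations

* Transmittance slab geometry only; no reflectance mode, layered media,
  or polarization.
* The diffusion oracle degrades at low μs′·L; it is a shape oracle in
  the diffusive regime, not a general reference.
* Library interpolation accuracy degrades below μs′ ≈ 3/cm at 1 cm
  thickness (barely diffusive curves change shape quickly); the default
  grids keep node ratios ≤ 1.3 there.
* The chromophore basis is a phenomenological stand-in with the correct
  band positions, orderings and responses, not literature extinction
  data; a file loader accepts real tabulated spectra.
* Single-wavelength independent fits only; no spectrally constrained
  simultaneous inversion.
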