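# tddos — time-domain diffuse optical spectroscopy of thermally treated tissue

Radiofrequency ablation (RFA) destroys tumours and aberrant cardiac
pathways by Joule heating, but incomplete ablation is common and hard to
detect in real time. Time-domain diffuse optical spectroscopy (TD-DOS)
probes the treated tissue with picosecond laser pulses and records the
distribution of photon times of flight (DTOF): because absorption and
scattering deform the temporal shape of the DTOF in distinct ways, a
single measurement disentangles the broadband absorption coefficient
μa(λ) from the reduced scattering coefficient μs′(λ) — no amplitude
calibration needed. The recovered spectra carry well-defined thermal
signatures: dehydration depresses μa beyond 900 nm, coagulation raises
μs′ severalfold, a new absorption peak surfaces near 840 nm as hemoglobin
converts to methemoglobin above 75 °C, the 760 nm deoxyhemoglobin peak
redshifts by 4–15 nm, the ~970 nm water peak blueshifts by 3–9 nm and
narrows, and charring above 100 °C raises short-wavelength absorption
while μs′ falls back from its peak.

This package implements the full computation behind such measurements,
for instrument builders and analysts who have DTOF histograms and want
optical-property spectra and treatment signatures out:

* **Forward model** (`tddos.photon_transport`) — "white" Monte Carlo
  photon transport through a slab in transmittance at null absorption,
  with absorption added analytically via the Beer–Lambert factor
  exp(−μa·v·t); a precomputed library over μs′ queried continuously by
  shape interpolation; the radiative-transfer scaling relation
  (lengths ×k, μs′/k, t → k·t); and the diffusion-approximation
  closed form (extrapolated-boundary image sources) as an analytic oracle.
* **Instrument model** (`tddos.instrument`) — IRF synthesis and
  convolution, Poisson photon-counting noise.
* **Inversion** (`tddos.inversion`) — per-wavelength fits of
  amplitude · (model ⊛ IRF) to the measured DTOF over the window from
  80% of the peak on the rising edge to 1% on the falling edge,
  minimizing the Poisson deviance over (μa, μs′) with a free amplitude.
* **Spectral features** (`tddos.features`) — Mie power-law fit
  μs′(λ) = a(λ/λ0)^−b with λ0 = 650 nm, cubic-spline sub-grid peak
  localization (shifts of a few nm are recoverable from 10 nm sampling),
  paired per-wavelength t-tests, normalized kinetics, and a composite
  treatment-signature report.
* **Synthetic tissue** (`tddos.synthetic`) — a parametric chromophore
  basis (Hb, HbO2, metHb, water, charring) and deterministic
  heating-trajectory models for critical treatment (70 °C) and
  overtreatment (105 °C), so the whole pipeline is testable end to end
  without instrument data.

## Worked example

```python
import numpy as np
import tddos as td

geometry = td.SlabGeometry(thickness=1.0, n_sample=1.41, n_external=1.5)
grid = td.TimeGrid(0.0, 5.0, 2048)              # 5 ps bins out to 10.24 ns
library = td.build_library(geometry, np.geomspace(3, 28, 10), grid,
                           n_photons=200_000, seed=42)
irf = td.synthesize_irf(80.0, "gaussian", grid, peak_position=300.0)

# synthesize one DTOF at mua = 0.20 /cm, mus' = 10 /cm, 1e6 counts ...
model = td.convolve_irf(td.apply_absorption(
    td.interpolate_library(library, 10.0), 0.20), irf)
record = td.add_counting_noise(model, 1e6, 0.0, 1.0, grid, 800.0, seed=7)

# ... and invert it
result = td.fit_optical_properties(record, irf, library,
                                   td.FitConfig(background="none"))
print(f"mua = {result.mua:.4f} /cm, mus' = {result.mus_prime:.3f} /cm")
```

prints

```
mua = 0.1988 /cm, mus' = 9.972 /cm
```

i.e. both coefficients recovered to well under 1% from a single noisy
histogram — the fit used only the temporal shape, never the amplitude.
A spectrum is just this fit repeated per wavelength
(`td.fit_spectrum`), after which

```python
pl = td.fit_power_law(spectrum)        # a (1/cm at 650 nm), b
report = td.detect_signatures(native_spectrum, treated_spectrum)
```

quantifies the scattering power law and the treatment signatures.

A command-line interface wraps the same stages:

```sh
tddos build-library --config run.yaml --out library/
tddos simulate --config run.yaml --library library/ --out data/
tddos fit --dtof-dir data/ --irf data/irf.tsv --library library/ --out spectra/
tddos features --native spectra/spectrum_t0000.csv \
               --treated spectra/spectrum_t0780.csv --out report.json
```

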