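# saxsizer

Nanoparticle size-distribution analysis for small-angle X-ray scattering
(SAXS), built around the question a metrologist asks: *how reproducibly can
different laboratories determine the size distribution and concentration of
the same nanoparticle dispersion?* The package implements the full analysis
chain for an inter-laboratory ("round robin") comparison of dilute sphere
dispersions — curve post-processing, three independent size-distribution
inversions, absolute-intensity concentration determination, q-uncertainty
sensitivity, and ensemble statistics — plus a synthetic round-robin generator
so the entire chain is testable without any external data.

It is aimed at SAXS practitioners and nanometrology researchers who work with
background-subtracted 1-D curves of dilute, spherical, polydisperse particles
(the reference case: poly(acrylic acid)-stabilized silver nanoparticles,
number-weighted mean radius ≈ 2.8 nm).

## The model

All three analysis branches assume dilute, non-interacting homogeneous
spheres. The measured intensity is

    I(q) = n ∫ D_n(R) [Δρ V(R)]² P(qR) dR + B,

with number density *n* [m⁻³], number-weighted size distribution *D_n*,
contrast Δρ (scattering-length-density difference, Å⁻²; 6.8 × 10⁻⁵ Å⁻² for
silver in water at 8 keV), sphere volume V(R) = (4π/3)R³, flat background
*B*, and the sphere form factor P(x) = [3(sin x − x cos x)/x³]², x = qR.

The parametric size distribution is the lognormal of the radii,

    D(R) = A / (√(2π) w R) · exp(−ln²(R/R₀) / (2w²)),

with area *A*, median radius *R₀* and log-space width *w*; its mean is
R₀ e^{w²/2} and its standard deviation R₀ e^{w²/2} √(e^{w²} − 1).

Three inversions recover the distribution from a curve:

* **`fit_lsq`** — classical weighted least squares of the lognormal-sphere
  model; with absolute units the fitted scale is the particle number density,
  hence the molar concentration c_n.
* **`ift`** — regularized indirect-transform inversion: a non-negative
  histogram distribution with a second-difference smoothness penalty, the
  regularization weight chosen on the χ² stability plateau; lognormal fits to
  the gridded result give number- and volume-weighted measurands.
* **`fit_mc`** — form-free Monte Carlo population fit: sphere contributions
  evolve by replacement moves accepted only when χ² decreases, repetitions
  give spread-based uncertainties, and the fitted scale gives the volume
  fraction, hence the mass concentration c_v.

Curves are first clipped to 0.1 ≤ q ≤ 3.0 nm⁻¹, rebinned to ≤ 100
logarithmic bins (uncertainty = max of propagated and standard-error
estimates), and floored at 1% relative uncertainty.

## Worked example

```sh
python examples/02_least_squares_fit.py
```

```
median radius R0 = 2.724 nm (truth 2.73)
width w          = 0.230   (truth 0.229)
mean radius      = 2.798 nm, sd = 0.653 nm
number density   = 2.507e+21 m^-3
c_n              = 4.163e-06 mol/l
reduced chi^2    = 0.292
```

One simulated laboratory's curve (1% noise) is rebinned and fitted; the
number-weighted mean radius (2.80 nm), width (0.65 nm) and number
concentration (4.2 × 10⁻⁶ mol l⁻¹) are the measurands a lab would report for
this silver dispersion. The other scripts in `examples/` demonstrate the
ensemble band comparison, the Monte Carlo and indirect-transform inversions,
q-uncertainty propagation, and the full 45-laboratory study.

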