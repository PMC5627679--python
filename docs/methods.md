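# Methods

## Scope and model assumptions

The package analyzes background-subtracted 1-D SAXS curves of dilute,
non-interacting, homogeneous spherical particles of non-uniform size. No
structure factor is included (the dilute limit is assumed throughout), no
smearing/de-smearing is modelled, and only the sphere form factor is
provided. Intensities may be absolutely calibrated (dΣ/dΩ in m⁻¹ sr⁻¹) or in
arbitrary units; concentrations are only available for the former.

## Post-processing chain

1. **Unit harmonization** — q to nm⁻¹ (Å⁻¹ × 10), absolute intensities to
   m⁻¹ (cm⁻¹ × 100). Idempotent. Negative intensities are retained:
   background subtraction legitimately produces them.
2. **q-window clipping** — closed interval 0.1 ≤ q ≤ 3.0 nm⁻¹ by default,
   which is sufficient to constrain particles in the few-nanometre range; a
   curve with fewer than 20 surviving points is rejected.
3. **Logarithmic rebinning** — at most 100 log-spaced bins between the
   curve's extreme q values. Bin q is the arithmetic mean of member q (at
   this bin density the geometric mean differs negligibly); bin intensity is
   the mean of members. The bin uncertainty is the larger of the propagated
   uncertainty of the mean, √(Σσᵢ²)/n, and the standard error of the mean of
   the member intensities; points lacking a supplied σ contribute only to the
   standard-error branch. The result is floored at 1% of |I|: experience with
   laboratory SAXS shows smaller claimed uncertainties are unrealistic and
   distort fit weighting. The floored fraction is reported per curve.
4. **Scale matching / ensemble bands** — curves are interpolated onto a
   common grid (linear in log I vs log q, no extrapolation) and matched to
   their pointwise median by the uncertainty-weighted closed form
   s = Σ(I·I_ref/σ²)/Σ(I²/σ²); percentile bands (median ±34.1% ≙ two
   standard deviations total, ±45% ≙ 90% of the data) summarize ensemble
   agreement.

## The three inversions

**Least squares (`fit_lsq`).** Damped least squares (Levenberg–Marquardt) on
(scale, R₀, w, B), with scale and R₀ fitted as logarithms to enforce
positivity without bound constraints. Initialization: R from a Guinier fit to
the 10 lowest-q points (R = √(5/3)·R_g), w = 0.2, B from the 10 highest-q
intensities, scale from the lowest-q intensity. On a poor fit (reduced
χ² > 10) the fit restarts from R₀ ∈ {1, 2, 3, 5} nm and keeps the best; an
unconverged result is flagged, never silent. Parameter uncertainties come
from the covariance at the optimum scaled by the reduced χ². When χ² = 1 is
unreachable the achieved value is reported rather than failing. The forward
quadrature uses a 200-point log-spaced radius grid spanning ±5 log-widths
around the median (> 99.999% of lognormal mass); trapezoid integration.

**Indirect transform (`ift`).** A linear inversion onto 60 log-spaced
histogram bins spanning the observability window of the q range,
[π/(2 q_max), π/q_min] ≈ [0.5, 31] nm for the default window. The inversion
is parameterized in the *number*-weighted density with kernel Δρ²V²(R)P(qR):
with a volume-weighted basis the data cannot forbid a flat pedestal at small
R (its kernel vanishes as V²) and the derived number weighting explodes;
parameterizing in number space puts the penalty directly on the
measurand-carrying density, and the volume weighting (× R³) stays clean. The
solution minimizes ‖(Ax − I)/σ‖² + λ‖Lx‖² subject to x ≥ 0 (NNLS), where L
is the second-difference operator with implicit zero boundaries (the
distribution vanishes outside the window). A flat background enters as a
free-sign column pair. λ is chosen by a stability-plateau rule — the largest
λ whose reduced χ² stays within 5% of the minimum over a 14-point log grid —
refined by log-bisection to the plateau edge so the effective smoothing is
not quantized by the grid (without the refinement the extracted width
jitters by the grid spacing). Measurands come from least-squares lognormal
fits to the gridded result in each weighting; a fit whose parameters leave
the grid (or w > 2) falls back to direct grid moments and is flagged.

**Monte Carlo (`fit_mc`).** N = 200 sphere contributions with radii drawn
log-uniformly (via a 400-point log grid) in the observability window; each
iteration proposes replacing one random contribution with a new log-uniform
radius, re-solves scale and background analytically (2-parameter weighted
linear least squares, scale constrained non-negative), and accepts iff the
reduced χ² decreases — so χ² is non-increasing by construction. The walk
stops at χ² ≤ 1 or 10⁵ iterations. If the pilot repetition cannot reach the
target, the criterion is raised to the pilot minimum × 1.02 and recorded
(a data-quality signal: it indicates under-reported uncertainties). Ten
repetitions with independent seeds give a volume-weighted histogram (50 log
bins) with 1-σ spread per bin and spread-based measurand uncertainties. Each
contribution carries equal number density, so volume weights are ∝ R³;
number-weighted statistics of the accepted set are reported but are
intrinsically noisy, because contributions too small to scatter measurably
(V² → 0) sit wherever the walk left them. The inner loop is compiled with
numba (pure-NumPy fallback with identical arithmetic); all randomness is
pre-generated from seeded numpy Generators, making results bit-reproducible
per (curve, config, seed).

## Contrast and concentrations

X-ray scattering-length densities use non-anomalous electron counts from a
built-in table of atomic numbers and weights: ρ_e = (ρ_m/M)·N_A·ΣZ, SLD =
r_e·ρ_e. For silver (10.49 g cm⁻³) against water (0.997 g cm⁻³, ambient)
this gives Δρ = 6.82 × 10⁻⁵ Å⁻² at 8 keV, matching the standard value to two
figures; dispersion corrections are not implemented (at 8 keV they are
negligible for this system). Conversions: c_n = n/(N_A·10³) mol l⁻¹;
φ = c_n·N_A·10³·⟨V⟩_n with ⟨V⟩_n = (4π/3)⟨R³⟩_n; c_v = φ·ρ_m·10³ g l⁻¹.
Volume→number conversion requires an explicit small-R cutoff because
dividing a gridded distribution by R³ diverges — the reason this direction
is discouraged for reporting.

## q-uncertainty

A pure relative q-scale error ε rescales every fitted length by 1/(1+ε)
exactly (reciprocal space); a fixed q shift distorts the curve non-uniformly
and perturbs mainly the width. `sensitivity_study` quantifies both by
refitting perturbed curves, seeding refits from the baseline to isolate the
q effect from optimizer variance. `resolution_budget` combines first-order
geometric contributions (divergence, beam width/height, bin width) and the
energy spread in quadrature at a reference q; it is a generic small-angle
budget taking user geometry, not a model of any specific instrument.

## Synthetic round robin

The generator emulates a multi-laboratory study of one dispersion. Defaults
(the study conditions): number-weighted lognormal with R₀ = 2.73 nm,
w = 0.229 (mean 2.80 nm, sd 0.65 nm, relative width ≈ 23%), volume fraction
2.7 × 10⁻⁴, Ag/water contrast at 8 keV, 1 m⁻¹ residual flat background —
implying n = 2.50 × 10²¹ m⁻³, c_n = 4.2 × 10⁻⁶ mol l⁻¹, c_v = 2.86 g l⁻¹.
Per-lab variability: lognormal intensity-scale bias with σ = 5%;
multiplicative Gaussian noise, lognormal around 1% at mid-q (clipped to
0.3–3%) and inflated by (1 + q/q_max) toward high q as counting statistics
degrade; 80–400 points on a log or linear grid spanning roughly
0.08–0.1 → 3.0–3.6 nm⁻¹; a q-axis shift ~ N(0, 0.01 nm⁻¹); absolute units
with probability 28/45; 15% of labs report no uncertainties and 40%
under-report them by 2–10× (exercising the 1% floor); two labs are flagged
outliers and measure a 30% oversized population. Everything is reproducible
from (TruthSpec, master_seed).

What the generator does **not** emulate: instrumental smearing and
resolution differences, background-subtraction shape errors, container
scattering, or interparticle interference. Consequently the scale-matched
ensemble band of synthetic curves (~1–2% at 2 SD) is narrower than the 5–10%
a real heterogeneous instrument pool shows — the synthetic 5–10% band
appears in the *unmatched* absolute-unit overlay, driven by the scale
jitter. Passing ensemble tests therefore demonstrate correct statistical
transfer of noise, scale and q-calibration variability, not robustness to
shape-level instrument systematics.

## Ensemble statistics

Measurand records (per dataset × method) aggregate to mean, sample SD
(ddof = 1), median, quartiles by linear interpolation between order
statistics, and 5/95% whiskers — the usual box-plot conventions. Outlier
datasets are excluded on request. Method comparison uses classical one-way
ANOVA at α = 0.05 (degenerate zero-within-variance groups handled
explicitly). The distribution check for a measurand across laboratories is a
Kolmogorov–Smirnov test against a maximum-likelihood-fitted location-scale
Student-t; with fitted parameters the KS p-value is conservative, which
suits a "not rejected" statement.

The study-level reproducibility statistic is the 2-SD relative spread
(200·sd/mean, %) of a recovered measurand across non-outlier laboratories.
The accuracy claim it supports is a capability statement, so the bound is
taken over the best-performing method per measurand; per-method spreads are
always reported alongside. On the default ensemble the parametric fit
determines the mean radius to ≲ 0.7% (2 SD), the indirect transform the
volume-weighted width to ≲ 3%; the form-free Monte Carlo spreads are a few
times wider — the cost of making no shape assumption. Absolute-scale
quantities (volume fraction, concentrations) inherit the labs' intensity
scale jitter: with 5% (1 σ) jitter their 2-SD spread cannot fall below 10%,
which is why concentration reproducibility is quoted at the ~10% (1 σ)
level.

## Numerical choices and degenerate inputs

* Sphere form factor uses a series expansion below x = 10⁻² to avoid
  cancellation; the branch agrees with the closed form to 10⁻¹⁰.
* w = 0 lognormals are handled by closed-form moments (the pdf is a delta);
  fits clamp w ≥ 10⁻⁶ internally.
* Empty rebin bins are dropped; single-member bins pass through; a curve
  with no more points than bins passes through unchanged apart from the
  uncertainty floor.
* Zero-intensity floor cases fall back to the smallest positive float so σ
  stays positive.
* Problem sizes in the shipped tests and the acceptance study (45 labs, 100
  q bins, 200 MC contributions × 10 repetitions, 60 IFT bins × 14 λ values)
  were chosen so a full study completes in well under a minute on one core
  while leaving measurand noise far below the tolerances being tested.

## Known limitations

* Spheres only; no structure factor, no smearing.
* The IFT branch is this package's own regularized inversion — it mirrors
  the class of classical indirect-transform programs but not any specific
  implementation's smoothing norm or interactive λ choice; agreement at the
  ensemble level, not per-dataset equality, is the design target.
* Number-weighted Monte Carlo statistics are noisy by construction (see
  above); volume-weighted quantities are the reliable MC output.
* Anomalous dispersion corrections to the contrast are not implemented.
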