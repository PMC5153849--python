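# Methods

## Scope and model chain

`odcal` converts plate-reader optical density readings into microbial
cell concentrations. The chain is: single-particle scattering cross
sections → suspension turbidity and multiple-scattering correction →
robust calibration-curve fitting and inversion → growth-curve metrics.
A synthetic-data layer generates every input with known ground truth, so
the whole chain can be validated end to end without instrument data.

## Single-particle optics

Scatterers are homogeneous spheres with a real refractive index; cells
and filaments are represented by equivalent-volume spheres. This is the
central optical simplification of the package: polystyrene beads are
genuinely spherical and non-absorbing at 600 nm, unpigmented bacteria
and yeast nearly so, but elongated filaments are not spheres and their
true phase function differs. Conventions: size parameter
x = πD·n_m/λ_vac, relative index m = n_p/n_m.

* **Mie series.** Coefficients aₙ, bₙ are computed with the logarithmic
  derivative Dₙ(mx) by downward recurrence and Riccati–Bessel functions
  by upward recurrence. The series is truncated at
  max(⌈x + 4x^{1/3} + 2⌉, ⌈m·x⌉ + 10); the second term matters for
  optically soft but large spheres, where partial waves up to n ≈ m·x
  still contribute (without it the x = 500, m = 1.19 efficiency is wrong
  by 7·10⁻⁵ relative). The downward recurrence starts 15 orders above
  the cutoff. Supported range x ≤ 10⁴. The test suite pins the
  implementation to an independent extended-precision direct-summation
  oracle (mpmath, 50 digits; generator committed next to the frozen
  values) at ≤ 10⁻⁶ relative error on a 20-point (x, m) grid.
* **Limits.** Rayleigh Q_sca = (8/3)x⁴|(m²−1)/(m²+2)|² for x ≲ 0.3; the
  van de Hulst anomalous-diffraction efficiency
  Q = 2 − (4/ρ)sin ρ + (4/ρ²)(1 − cos ρ), ρ = 2x(m−1), for soft
  particles; and the small-phase-shift cross-section
  σ = (ρ²/2)πr², which is exactly ∝ r⁴ at fixed indices and wavelength.
  The r⁴ form is adopted as the package's reading of the classic
  soft-particle (Jöbst) approximation — it is the expression that yields
  the r⁴ proportionality quoted for spherical bacteria — not as a
  reproduction of any particular historical formula. `jobst_sigma` warns
  when ρ > 0.5.
* **Detector acceptance.** A real instrument with aperture radius R at
  distance d accepts scattered light within θ_acc = arctan(R/d); the
  effective extinction efficiency is q_ext minus the phase-function
  integral over [0, θ_acc] (Gauss–Legendre, 64 nodes, node-doubling
  convergence check at 10⁻⁶). The default geometry is ideal (θ_acc = 0)
  because instrument-specific R and d are generally unpublished;
  geometry is a config option.
* **Polydispersity.** For size_cv > 0, cross-sections are averaged over
  a lognormal diameter distribution by 11-point Gauss–Hermite
  quadrature. The reference bead set has CVs of 2–9%, which shifts σ by
  well under 10%.

## Forward model

Decadic turbidity τ = σCL/ln 10 (σ in cm², C in ml⁻¹, L in cm). In the
single-scattering regime OD = τ (Beer–Lambert). At higher density OD is
parabolic in concentration; the correction factor is modeled with a
single dimensionless coefficient q:

    OD = τ − qτ²,   valid for τ ≤ 1/(2q)

q defaults to 0.1 and is conceptually fit per instrument and scatterer.
This is the minimal model reproducing the parabolic OD(N) dependence
while reducing exactly to Beer–Lambert as q → 0 or C → 0; the true
multiple-scattering correction depends on the path coordinate and
geometry in ways that require knowing N anyway, which is precisely why
empirical calibration is the practical route. Beyond the monotone
branch (the photon-diffusion limit) the model refuses to evaluate.

Fill-volume corrections are instrument configuration, defaulting to the
published BMG factors (×1.0560 for 300 µl, ×1.5848 for 200 µl, ×6.3694
for 100 µl). They are deliberately not derived from well geometry: the
100 µl factor is far from naive path-length scaling (meniscus and
condensation optics dominate), so only the measured table is trusted.
The single/multiple regime boundary is OD 0.2, inclusive on the single
side, configurable.

## Calibration

* **Orientation.** OD is fitted as a quadratic function of known
  concentration, OD(C) = p₀ + p₁C + p₂C², and converting OD readings
  solves the quadratic — matching how bead calibrations are constructed
  (fit, then solve the polynomial at chosen ODs). The intercept is
  retained so blank offsets are visible rather than hidden.
* **Trimming.** Points whose replicate-mean OD reaches the instrument
  saturation level (default 3.5, configurable) are removed first; at
  least 4 distinct concentrations must survive.
* **Robust fit.** Tukey-bisquare IRLS with tuning constant 4.685 and
  MAD residual scale, via statsmodels RLM (max 50 iterations,
  tolerance 10⁻⁸). Replicates enter as individual observations; the
  robust loss handles their weighting. Concentrations are rescaled by
  their maximum internally for conditioning (raw C² spans ~10²⁰).
* **Degree selection.** Sequential nested-model F-tests on OLS fits:
  the lowest degree for which the next-order term is not significant at
  α = 0.01. On forward-model data (exactly quadratic in C) with 2%
  noise, degree 2 is modal across seeds.
* **Inversion.** The root of p₂C² + p₁C + (p₀ − od) on the increasing
  branch, computed in the cancellation-free form 2(od − p₀)/(p₁ + √disc);
  round trips are exact to ≤ 10⁻⁹ relative. ODs outside the fitted OD
  span raise, distinguishing "saturated" from "below_blank";
  extrapolation is an explicit opt-in. Curve monotonicity is verified by
  derivative sign on a grid, not assumed.
* **Transfer.** Cross-instrument calibration defaults to proportional,
  scale = Σod_A·od_B / Σod_A² (an offset can be freed); OD-vs-count
  alignment likewise estimates the single ratio c minimizing
  Σ(od − c·C)², with counts linearly interpolated onto OD timepoints.
  A single shared factor is the package's interpretation of two-axis
  scaling: with both series in arbitrary units only the relative scale
  is identifiable from that objective.

## Growth analysis

Specific growth rate is the slope of an ordinary least-squares line
through ln(value) vs time in a sliding window (default 5 points — 37.5
min at the default 7.5 min sampling), assigned to the window center, in
hr⁻¹. Windows containing non-positive values are skipped with a
warning. μ_max is the peak of this series; the estimator is exact on
noiseless exponentials. Note that the maximum of a noisy rate series is
biased upward, which is why curve comparisons default to the
replicate-averaged trace (below). Lag time is where the tangent at the
μ_max point (in log space) meets the initial baseline, defined as the
mean log of the first three samples, clipped to [0, t_μmax]; on a pure
exponential this construction returns the mean time of those baseline
points (≈ one sampling interval), not exactly zero. Traces with
μ_max ≤ 10⁻⁶ hr⁻¹ are treated as non-growing and get an undefined
(NaN) lag. Metrics are computed per replicate and summarized as
mean ± SEM; `compare_rate_estimates` instead averages replicates first,
the convention used for published plate-reader traces, to suppress the
max-statistic bias when comparing OD-based and count-based rates.

OD→concentration conversion inverts the calibration pointwise and flags
each point ok / saturated / below_blank; out-of-range points become NaN
rather than extrapolated values. Early-growth points below the
calibrated OD range are expected and simply unresolvable by that curve.

## Synthetic data

The generators emulate the reference experimental design:

* **Bead series** — diameters {0.51, 0.96, 3.00, 10.0, 15.7} µm,
  n_p = 1.59, water (n_m = 1.333, λ = 600 nm); default grid of 24
  concentrations spanning true OD 0.05–2.4; multiplicative Gaussian
  readout noise with CV 2% (a plate-reader-typical figure; no noise
  model is prescribed by the underlying study). Ground truth, including
  the exact forward-model polynomial, is returned with every series.
* **Growth curves** — exponential or logistic biomass growth (defaults:
  μ = 0.7 hr⁻¹, N₀ = 5·10⁶ ml⁻¹, K = 2·10⁹ baseline-cell equivalents —
  enteric-bacteria-like values), sampled every 7.5 min; readout is the
  mean of 5 noisy forward-model evaluations per timepoint, 10 replicate
  wells. The logistic capacity caps biomass, not cell number, so size
  trajectories repartition biomass into count × per-cell volume.
* **Size trajectories** — `constant` (minimal-medium growth: OD ∝ N
  throughout by construction); `stationary_shrink` (per-cell volume
  falls by 30% approaching stationary phase); `filamentation`
  (β-lactam-like: from the time the culture reaches OD ≈ 0.2 — 5.5 h at
  the defaults — cell number is frozen while per-cell volume tracks
  continuing biomass growth up to 10×, then filaments divide back with
  an 8 h relaxation). The pulse parameters are free knobs chosen once
  to produce the qualitative filamentation signature: an interval of
  flat N with rising OD, an OD-based μ_max above and later than the
  count-based one, and an OD dip from its peak as filaments divide.
  Filament optics use the equivalent-volume sphere, the package's main
  modeling simplification; real filament phase functions would modify
  the quantitative (not the qualitative) picture. Cell index defaults
  to n_p = 1.40 (E. coli protoplasm at 600 nm).
* **Counting** — per-field counts are Poisson(C·V) in a
  55.6 × 55.6 × 100 µm field (V = 3.091·10⁻⁷ ml), default 30 fields
  (within the usual 20–50); the estimator mean/V is unbiased and its
  SEM is reported.

What passing tests on these generators show — and what they do not: the
pipeline recovers its own forward model under realistic noise,
sampling, and size-change scenarios, with correct statistics; they do
not certify any particular instrument's q, saturation level, or
geometry, nor filament scattering, all of which need the per-instrument
calibration the package exists to perform.

## Numerical choices and degenerate inputs

Decadic (log₁₀) OD convention throughout. Time is stored in seconds,
rates reported in hr⁻¹. Mie series: cutoffs as above; acceptance
quadrature errors out rather than returning unconverged values.
Calibration fitting raises on fewer than degree + 2 distinct
concentrations; all-saturated series raise; inversion at the blank level
returns C = 0; negative measured ODs smaller than −10⁻³ are rejected,
larger ones clipped to zero with a warning. File writers emit sorted
rows, ≥ 9 significant digits, LF endings; calibration JSON is
schema-versioned and unknown versions are rejected. CLI exit codes:
0 success, 1 data/validation error, 2 usage error.

## Known limitations

Real refractive indices only (no absorbing scatterers); spheres only
(equivalent-volume mapping for rods/filaments); quadratic
multiple-scattering correction with a single q (no photon-diffusion
regime); proportional-only default for cross-calibration; no CFU-based
calibration (systematically biased under antibiotics, where cells can
be dead but not lysed); no parametric (Gompertz/Baranyi) growth fits;
no plate edge-effect correction.
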