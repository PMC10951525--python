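# Methods

## Scope

`uvact` covers the desk side of a UV-LED sensitivity evaluation: dose
accounting and validity factors for a collimated exposure, plate-count
survival statistics, dose-response model fits, the four wavelength-
sensitivity ratio methods, and a synthetic generator that stands in for the
bench. Device physics that requires unpublished hardware geometry — ray
tracing of the LED board and aperture stack, LED junction-temperature
modelling, radiometer cosine-response calibration — is out of scope; the
emitter model below is parametric, not a reproduction of any instrument.

## Dosimetry

Dose is irradiance × time (mJ/cm² = mW/cm² × s). Two timing corrections
refine the time base:

* **Power-supply lag.** DC supplies take a current-dependent time to reach
  the setpoint; the lag at the LED's drive current (piecewise-linear in a
  measured current→lag table; extrapolation outside the table is refused)
  is added to the timer setting.
* **Startup overshoot.** The transient current excess at switch-on is
  modelled as a fixed per-exposure energy surplus calibrated at a reference
  interval (a fraction of the dose delivered over that interval at the
  exposure's dose rate). Because the transient happens once, the surplus
  does not grow with exposure time; at a typical 3 % measured over 2 s it
  is negligible for exposures of a few seconds.

The five validity factors:

* **WF = (1 − 10^(−a·l)) / (a·l·ln 10)** — the depth average of decadic
  transmission 10^(−a·z) over the liquid column (a: decadic absorbance per
  cm at the evaluation wavelength, l: depth in cm). The absorbance input is
  the single-wavelength value at the LED peak, usually converted from a
  measured percent transmittance over a 1 mm path; an emission-spectrum-
  weighted variant (`water_factor_weighted`) exists but is not the default
  reporting convention.
* **DF = L/(L+l)** — beam divergence between the surface and the bottom of
  the column, L the working distance.
* **PF** — mean/center and mean/max irradiance over the dish area. Both are
  reported because a multi-LED surface source need not peak at the dish
  center. The center node of an even-sized grid is the node nearest the
  geometric center, ties broken toward smaller coordinates.
* **RF = 1 − Σ f(θ)·R(θ)** — unpolarized Fresnel reflectance at the
  air/suspension interface averaged over the beam's incidence-angle
  distribution (suspension index defaults to water's 1.33; any wavelength
  dependence of the index is the caller's responsibility).
* **CV = 100·SD/mean** of the masked irradiance field, with the *sample* SD
  (n−1): measured grids are small, and the conservative convention is the
  explicit default so results citing a population-SD convention can be
  reconciled.

Gates are inclusive — WF ≥ 0.9, DF ≥ 0.94, CV ≤ 6.7 % — and gate validity
only; the default workflow never rescales dose by the factors. A
`corrected_dose` mode (dose × WF × DF × PF_max × RF) exists for comparing
against protocols that fold them in. Depth may be given nominally (0.1 cm
for 1 mL in a φ35 mm dish) or computed from volume (0.104 cm); both
conventions are accepted side by side since published tables round.

## Survival kinetics

Log survival is log₁₀(Nt/N0) per replicate, each replicate paired with its
own unirradiated (dose-0) control — replicates are assumed to be
independent assay days. Zero-colony plates are censored at 0.5 colonies and
the affected curve points flagged `censored_at_detection_limit`; this keeps
the transform finite while marking the detection floor. Points are
aggregated as mean ± SEM (sample SD/√n); a single replicate yields SEM 0
with a `single_replicate` flag.

Fits are constrained through the origin because log survival at dose 0 is
identically 0 by construction:

* **First-order**: k_F0 = Σ F·y / Σ F² on the linear portion, y = −log₁₀ S.
  "Reading the linear portion by eye" is replaced by an explicit rule —
  all nonzero doses with mean log survival ≥ −4 (≥ 2 points), overridable
  via `dose_range`. r² uses the uncentered total sum of squares, the
  appropriate convention for a through-origin model.
* **Quadratic**: least squares for −log₁₀ S = b₁F + b₂F²; a design with
  fewer than two distinct nonzero doses is rejected as unidentifiable.

Dose-for-log-reduction inverts the mean curve by monotone piecewise-linear
interpolation (fit objects are inverted analytically). Targets beyond the
measured range raise unless `extrapolate=True`, which inverts the quadratic
fit instead. Interpolation is on the mean curve, not per replicate;
replicate-level uncertainty is propagated by resampling replicates and
refitting (as the bootstrap in the test suite does).

Condition comparisons use the two-sided pooled-variance (Student's)
two-sample t-test with 0.05/0.01 significance flags; two constant, equal
groups are reported as a degenerate p = 1 rather than an error.

## Wavelength-sensitivity ratios

GF₁, GF₂, GF₃, GF₄ as defined in the README. Numerical choices:

* GF₃'s objective is evaluated at the test curve's measured doses (a
  discrete sum, not a continuous integral): the discrete form mirrors the
  data actually available. The scale search runs over [0.01, 100]; because
  noisy quadratic fits can turn concave and make the objective multimodal,
  the global minimum is bracketed on a 400-point log-spaced grid before
  bounded refinement, and the test suite checks agreement with a brute-force
  grid search to 1e-6. A solution pinned at a bound is an error — the
  curves do not admit a dose-axis mapping.
* GF₄ is oriented so values > 1 mean the test wavelength is more effective
  than the reference ("ratio of required dose" is direction-ambiguous
  otherwise). d₀ defaults to 4 mJ/cm², the standard comparison dose. The
  reference dose for the observed log survival is read from the mean
  reference curve by interpolation, without extrapolation unless requested.
* Reference-wavelength entries are set to exactly 1: a curve's ratio to
  itself is identically 1, and this must not depend on optimizer
  convergence.
* Table cells that cannot be established — a log-reduction target
  unreachable on either curve, or no admissible GF₃ mapping — degrade to
  NaN with a per-row flag instead of failing the whole table; the action
  spectrum drops NaN rows and flags the omission. GF₂ targets default to
  1, 2 and 3 logs and are recorded per level, so curvature shows up as
  level dependence.

The action spectrum orders GF₄ by wavelength; tied maxima are all reported
(lowest returned as the peak, flagged), and a peak at the first or last
wavelength is flagged as a boundary.

## Synthetic data

The generator emulates a 13-LED (250–365 nm) assay on *E. coli* ATCC
25922 at 1 mW/cm² surface irradiance:

* **Kinetics.** The reference (280 nm) coefficients (b₁, b₂) are solved at
  run time from two anchors: 0.95 logs at 4 mJ/cm² at 280 nm, and 5.96
  logs at 10 mJ/cm² at 254 nm with ε₂₅₄ = 1.25 — giving b₁ ≈ 0.1249,
  b₂ ≈ 0.0282. Dose scales at 254/267/270 nm are 1.25/1.56/1.52; the
  remaining nine wavelengths are PCHIP-interpolated in log₁₀ ε through
  shape knots peaked at 267 nm (≈1.12 at 250 nm, falling to 0.40 at
  290 nm, 0.08 at 300 nm, 0.02 at 308 nm and 10⁻³ at 365 nm). The knot
  values away from the four anchors are plausible-shape choices consistent
  with known germicidal spectra — steep fall-off above 290 nm, near-flat
  UVA tail — and are explicitly non-normative.
* **Counts.** Per (wavelength, dose, replicate): the model's log survival
  plus a Normal(0, 0.2) replicate effect in log₁₀ space sets the true
  concentration from N₀ = 10⁷ CFU/mL; a decimal auto-dilution targets the
  30–300 colony countable window (dilution 1 when even the neat plate is
  sparse); the plate count is Poisson. Doses default to 0–10 mJ/cm² in
  2 mJ/cm² steps with four replicates. The 0.2 log SD reproduces SEMs of
  roughly 0.05–0.15 at n = 4, the magnitude typical of replicated CFU
  assays, without attempting to separate variance components the data
  cannot identify. Deterministic mode switches off both noise sources and
  emits expectation-valued (fractional) counts so the analysis recovers the
  model exactly — which is why `colony_count` admits floats.
* **Irradiance fields.** LEDs are point emitters with intensity
  ∝ cosᵐθ/d² on a configurable board layout (default: centered 6 mm-pitch
  grid trimmed toward a disc); arriving power over the dish is binned by
  incidence angle into the AngularDistribution the reflection factor and
  beam-fraction operations consume. This reproduces the qualitative bench
  behaviours — fields flatten and beams collimate as working distance
  grows — but no published uniformity or within-cone percentage, since the
  real device's optics are not public.
* **LED spectra.** Unit-area Gaussians on a 0.5 nm grid, 10 nm FWHM.

What passing tests on this generator do *not* show: real assays have
shoulders and tails from repair and subpopulation effects, day-to-day N₀
drift, and counting biases that a Poisson-plus-lognormal model does not
produce. The generator validates the pipeline's statistics, not the biology.

## Problem sizes

The stochastic recovery suites use 100 seeded assays for rate-constant CI
coverage and 50 assays × 60 bootstrap resamples for the GF₄/dose-scale
check — sizes at which the pass thresholds (≥ 90 % coverage) are stable
binomial statements while the whole suite stays interactive-fast.

## Known limitations

* Printed water factors for dense suspensions in the source protocols are
  not always reproducible from printed transmittances with the standard WF
  formula; `uvact` reports the standard formula and leaves reconciliation
  to the user.
* GF₃'s published antecedent is under-specified; the discrete least-squares
  form here is a declared choice, exact for curves that are true dose-scaled
  quadratics of each other.
* The t-test assumes equal variances per the protocol convention; pass
  `welch=True` to `compare_conditions` to drop the assumption. Likewise the
  first-order fit is through-origin by definition of log survival; a
  `free_intercept=True` variant exposes shoulders as nonzero intercepts.
* No multi-hit/series-event survival models, photoreactivation or dark-
  repair corrections.
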