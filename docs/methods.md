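# Methods

## The problem

Cereal aphids (*Sitobion avenae* on winter wheat being the canonical case)
build up and collapse within a single spring season.  Their instantaneous
relative growth rate

    RGR(t) = d ln n / dt        [aphid · aphid⁻¹ · day⁻¹]

integrates reproduction, development, mortality and migration, and responds
primarily to two drivers that are both observable in routine field
campaigns: ambient temperature θ (°C) and the phenological stage s of the
host wheat (Zadoks decimal code, 0–99).  This package estimates the RGR
series from noisy weekly counts, fits a parametric response surface
f(θ, s; φ) to the pooled estimates, and validates the fitted surface on
held-out field-years.  Because the historical survey tables this style of
analysis was developed on are not publicly deposited, a synthetic survey
generator with the same statistical structure stands in for them; every
stage of the method is exercised and checked against a known ground truth.

## RGR estimation from counts (smoothing-spline log-derivative)

Weekly counts are transformed to ln(n+1) (defined at zero counts, which are
kept — the transform exists precisely to retain them), smoothed with a
penalized natural cubic smoothing spline, and differentiated analytically
at the observation times.  The spline minimizes

    Σᵢ (yᵢ − g(xᵢ))² + λ ∫ g″(x)² dx ,

solved by Reinsch's algorithm in the Green–Silverman banded form; the
solution is the natural cubic interpolant of its own fitted values, so
evaluation and differentiation go through an ordinary natural cubic spline.
The implementation is cross-checked in the test suite against scipy's
`make_smoothing_spline` at matched λ (agreement ≈ 1e-10); it is implemented
directly rather than delegated because the fit must (a) accept series as
short as 4 points and (b) expose the exact hat matrix.

λ is selected by ordinary leave-one-out cross-validation, computed exactly
from the smoother's hat matrix (eᵢ/(1−Aᵢᵢ)), minimized over a log-spaced
grid of 50 values spanning near-interpolation to the linear limit (anchored
at h̄³ for mean spacing h̄, since λ carries units of time³), then refined by
a bounded golden-section search between the grid neighbours of the optimum.
A boundary optimum raises a warning rather than an error.  Criteria written
as scores to be *maximized* are the same selection up to sign; this package
standardizes on minimizing prediction squared error.  Leave-one-out rather
than generalized cross-validation is a documented choice, not a claim about
what any particular historical analysis used.

Each field-year is smoothed independently; nothing is pooled before the
regression stage.  Derivatives are reported at observation times only.
Totals over the sampled tillers (rather than per-tiller means) enter the
transform by default: with tens-to-thousands of aphids per sample the +1
shift is negligible, whereas per-tiller means below 1 would be swamped by
it.  Both options are exposed.

Known bias at the season edges: at single-digit counts the +1 shift
depresses the log-derivative (d ln(n+1)/dt = f·n/(n+1)), and the natural
boundary conditions flatten the spline.  Interior estimates (two or more
weeks from either end) are accurate to a few percent on noiseless
exponential benchmarks; tests and benchmarks therefore evaluate interior
points.

## The response surface

    f(θ, s) = a θᵇ (θ_max − θ)/θ_max
              · [1 + e^{−k (s − s_m)}]⁻¹
              · [1 − e^{−(s_max − s)/τ}]

* θ_max = 30 °C — lethal maximum temperature, fixed.
* s_max = 92 — latest Zadoks stage allowing aphid feeding (grain ripening),
  fixed.
* τ = 2 Zadoks units — decay scale of the terminal collapse, fixed rather
  than fitted to preserve the four-parameter count.
* s_m — left inflexion of the phenological sigmoid (free).
* a ≥ 0 — overall scale, in day⁻¹ per temperature-response unit (free).
* b — temperature-shape exponent; the thermal optimum sits at
  θ* = b θ_max/(b+1) (free).
* k > 0 — steepness of the phenological sigmoid, per Zadoks unit (free).

The temperature branch rises like θᵇ and is pulled down linearly to zero at
θ_max, giving a single interior maximum; the phenology branch rises
sigmoidally through stem extension (inflexion at s_m) and collapses within
a few Zadoks units of s_max.  Outside the viable domain (θ ≤ 0, θ ≥ θ_max,
s ≥ s_max) the surface is defined as 0, not negative: the boundary value is
a modelling convention, and a flat population is the conservative choice.
A consequence worth stating: this surface is nonnegative everywhere, so
negative *predicted* RGR never occurs; negative *observed* RGR arises from
sampling noise (and in real data, from mortality and emigration the surface
does not resolve).  The declining branch above ~22 °C is implemented but
untestable against realistic data, since spring/summer daily means in the
emulated regions do not exceed 22 °C.

An optional natural-enemy extension adds linear terms c_E·E + c_M·M for
counts of fungus-killed aphids (Entomophthorales) and parasitoid mummies.

## Fitting

Records pool all field-years of a region: response = spline-estimated RGR,
regressors = weekly mean of mean daily temperatures (trailing 7-day window
ending at the sampling date, inclusive) and recorded Zadoks stage.  The
free parameters minimize the residual sum of squares by Gauss–Newton with
step halving (each step solves the linearized normal equations via
least-squares, halving until the objective decreases; convergence at
relative decrease < 1e-8 or 200 iterations, reported as a flag, never an
exception).  Bounds (0 < s_m < s_max, a ≥ 0, k > 0) are enforced by
projection; the Jacobian is a central finite difference, degrading to
one-sided at an active bound.  A trust-region least-squares fallback
(`method="lm"`) is available for stubborn starts and agrees with
Gauss–Newton on the benchmarks.

Default initialization: s_m at the midpoint of observed stages, k = 0.3,
b = 1, and a scaled so the surface maximum matches the 95th percentile of
|observed RGR|.

Asymptotic standard errors and parameter correlations come from
σ̂²(JᵀJ)⁻¹ at the solution.  The a–b pair is structurally near-collinear
(a θᵇ trades ln a against b ln θ); with field-confounded designs the
correlation reaches −0.998 and a is essentially unidentifiable — an
intrinsic property of the model, reported via the correlation table and a
singularity warning, not suppressed.  Records are treated as independent in
the objective even though residuals are serially correlated within fields;
the Durbin–Watson statistic quantifies that violation as a caution, exactly
the role it plays in this literature, and no GLS correction is attempted.

## Diagnostics and validation

* **ANOVA partition**: SS_total = Σ(y−ȳ)² (df n−1), SS_model = Σ(ŷ−ȳ)²
  (df p), SS_error = Σ(y−ŷ)² (df n−p); F = MS_model/MS_error on (p, n−p).
  For nonlinear fits the three SS need not be additive; they are reported
  as computed.  Model R² = SS_model/SS_total, as a percentage.
* **Durbin–Watson**: Σ(eᵢ−eᵢ₋₁)²/Σeᵢ² with differences taken within fields
  only (a field boundary contributes no difference term).  The one-sided
  p-value for positive autocorrelation uses the normal approximation
  DW ≈ N(2, 4/n) and is flagged approximate; the exact Pan/beta algorithm
  is out of scope.
* **Bisector R²**: 1 − [Σ(yᵢ−ŷᵢ)²/(N−1)] / [Σ(yᵢ−ȳ)²/(N−1)], residuals
  taken from the line predicted = observed with no refitting.  The (N−1)
  corrections cancel deliberately: with ŷ fixed at the bisector no
  parameters are estimated, and this convention makes perfect prediction
  score exactly 1.  The index can be negative.
* **Origin-constrained regression**: slope Σyŷ/Σŷ² (bias check; 1 = no
  average bias) with its R² against the observed mean.
* **Sign-error matrix**: 2×2 counts of observed vs predicted RGR sign.
  Exact zeros classify as positive — a flat population is not a decline —
  and the rule is configurable.
* **Residual summary**: mean, median, adjusted Fisher–Pearson skewness (G1).

## The synthetic survey generator

What it emulates, per field-year:

* **Weather**: daily mean = seasonal sinusoid (level 12 °C, amplitude 6 °C,
  peak at day-of-year 200) + a per-season climatic offset (sd 2.5 °C, the
  cold-vs-warm springs that make weekly means span roughly 6–22 °C across
  years) + AR(1) daily noise (sd 1.5 °C, ρ = 0.5), clipped at 22 °C so the
  spring/summer ceiling of the emulated regions holds for every seed;
  t_min/t_max sit ±4 °C around the mean.
* **Phenology**: degree-day accumulation above 0 °C at 20 °C·day per Zadoks
  unit from stage 30 on 1 May; the noise-free season ends at stage ≈ 91.7
  (grain ripening) on 15 July, and warm/cold years ripen earlier/later.
  Driving phenology with temperature deliberately reproduces the field
  confounding of the two regressors (each (θ, s) pair lives on a diagonal
  band).
* **Population**: daily Euler integration N_{t+1} = N_t (1 + f(θ_t, s_t)),
  from 0.05 aphids/tiller.  The latent log-derivative is therefore
  ln(1 + f) rather than f — a ≤ 1% distinction at f ≤ 0.15/day that the
  noise-free chain test accounts for.  Immigration and emigration are not
  modelled separately; they are absorbed into the surface.
* **Observation**: weekly counts on 200 tillers, negative-binomial around
  latent density × tillers with size k = 3 (variance μ + μ²/3; log-scale
  noise sd ≈ 0.5, the "strong sampling noise" regime).  Optional enemy
  counts are negative-binomial with means proportional to the aphid mean.
  Ground-truth surface: s_m = 45, a = 0.012, b = 1.2, k = 0.35, giving a
  peak RGR ≈ 0.15/day and peak densities of a few tens per tiller.

The dispersion default was calibrated once so the fitted model explains
roughly 25–50% of the variance — the regime reported for real regional
fits — and then frozen; measured mean fit R² ≈ 45%, expected held-out
bisector R² ≈ 38%.

What it does **not** emulate, hence what passing tests do not show about
real data: latent population *decline* (the nonnegative surface cannot
produce it, so observed negative RGR is pure noise here, while real crashes
are driven by emigration and natural enemies); region-to-region parameter
differences; observer effects, missed fields, variable sampling effort
within a season; and any spatial structure.

## Study-scale benchmarks and problem sizes

* **Parameter recovery** is benchmarked at n = 160 records with Gaussian
  RGR noise σ = 0.03 over 50 noise seeds, on a deterministic space-filling
  (unscrambled Halton) design over θ ∈ [6, 26] × s ∈ [35, 80] — the region
  where the response carries signal.  Median relative errors ≈ 0.5% (s_m),
  11% (a), 4% (b), 12% (k); at σ = 0 recovery is exact to < 1e-4.  On
  field-confounded designs a's error is bounded below by its Cramér–Rao
  limit (~27% median) — the design, not the optimizer, is the constraint.
* **End-to-end studies** use 17 training field-years (~187 records, the
  scale of a long regional campaign).  A single 9-field validation set
  puts a ±15-point spread on the bisector R², so expected validation
  quality is summarized as the median over 5 replicated studies, each
  validated on 36 held-out field-years.
* All defaults keep the full test suite under ~10 s and the acceptance
  script under ~5 s on one core.

## Numerical conventions

* Internal time is days since the first sampling date of each field; dates
  are ISO-8601 calendar dates in all files.
* CSV: comma-separated UTF-8, '.' decimal, mandatory header; outputs carry
  the configuration hash and seed in '#' comment lines.
* Seeds: a single master seed derives all per-field and per-stage streams
  via `numpy.random.SeedSequence`; fixing it makes every artifact
  bit-reproducible, including serialized JSON.
* Degenerate inputs fail loudly with row-numbered messages (count < 0,
  tillers outside [50, 1000], decreasing stage, t_min > t_max); interior
  weather gaps are linearly interpolated with a logged warning; a weekly
  temperature window with 1–6 of its 7 days present averages what is there
  with a warning, and an empty window drops the record with a logged count.
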