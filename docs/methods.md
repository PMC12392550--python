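# Methods

This note documents the models and procedures `coda24` implements, the
choices made where the design was genuinely open, and what the synthetic
cohort generator does and does not emulate.

## The compositional model

Daily minutes of physical activity (PA), sedentary behavior (SB) and sleep
are a three-part composition: only their relative sizes are informative,
since they are constrained to the day length. All compositions are *closed*
to a common total (default 1440 min/day, configurable) so that minute-based
statements — "move 10 minutes from SB to PA" — mean the same thing for every
child regardless of recorded day length.

Modelling uses isometric log-ratio (ilr) **pivot coordinates**. For a
reference behavior $x_r$ and the remaining pair $(x_a, x_b)$:

$$z_1 = \sqrt{\tfrac{2}{3}}\,\ln\frac{x_r}{\sqrt{x_a x_b}},\qquad
  z_2 = \sqrt{\tfrac{1}{2}}\,\ln\frac{x_a}{x_b}.$$

Conventions, fixed once and used everywhere:

- the reference part sits in the numerator of $z_1$, so "more of the
  reference behavior" always means larger $z_1$ and coefficient signs read
  naturally;
- the remaining pair order follows the cycle PA → SB → sleep → PA with the
  reference removed (reference SB leaves (sleep, PA)). Any fixed order gives
  the same fits; this one is simply deterministic and documented;
- three *rotations* (reference = PA, SB, sleep) are orthonormal
  re-coordinatizations of the same two-dimensional geometry. Log-likelihood,
  R², test statistics, fitted values and residuals are identical across
  rotations (verified to 1e-6 in tests); only the $(z_1, z_2)$ coefficient
  values change meaning. Coefficient signs/magnitudes are therefore
  convention-dependent and comparable across software only after mapping
  bases.

Only three-part compositions are supported, and zero parts are rejected
rather than imputed: the ilr map is undefined on the simplex boundary, and
zero-replacement strategies are deliberately out of scope.

## Diary preprocessing

Events from an 11-category time-use diary are mapped to
{PA, SB, SLEEP, EXCLUDED} by a configuration file; the three non-informative
categories ('other activity', 'I don't know', 'my child was with someone
else') are always EXCLUDED. The mapping that ships with the package
implements only the uncontroversial assignments (sleeping → sleep; screen
use, passive transport, calm sitting/lying, eating/drinking, personal care →
SB; active play, active transport → PA) and is a documented stand-in — the
authoritative intensity/posture classification for this instrument is
published separately, so users should supply their own file for real data.

Validity rules: a day is valid when its informative coverage is at least
23 h (1380 min); a child enters analysis with at least two valid days
(configurable); the mean over valid days is closed to the common total.
Days are index-based; start/end-time parsing and overlap resolution are out
of scope.

Outlier screening flags values with z-scores strictly outside [−3, 3],
using the sample SD (n−1). Screening is applied per timepoint to both ilr
coordinates and each outcome, before modelling; a record is dropped when any
screened variable is flagged. Boundary values (|z| exactly 3) are kept. The
screen uses the PA-pivot coordinates; whether pooled or per-timepoint
screening is "correct" is not determinable from the source analyses, and the
per-timepoint choice is recorded in the artifact log.

## Association models

**Cross-sectional**: OLS of the outcome on $(z_1, z_2, \mathrm{age},
\mathrm{sex})$ with intercept, one record per child (first timepoint when
available, otherwise the second). Sex is coded {0, 1}; age enters linearly
in months; no interactions.

**Longitudinal**: a random-intercept linear mixed model on all records with
complete data (children contribute one or two timepoints), estimated by
**maximum likelihood, not REML**, so that full-vs-null likelihood-ratio
tests on the fixed effects are valid. Children observed once are retained;
if no child repeats, the intercept variance sits at the boundary (0) with a
warning and the fit collapses to pooled OLS.

**Composition test**: the full model is compared with the covariates-only
null refit on exactly the same rows. Linear fits use the partial *F* test
with 2 numerator df (for this design — the ilr block added last — Type I/II/
III ANOVA coincide); mixed fits use the 2-df χ² LRT on ML log-likelihoods.
Explained variance: linear R²Δ is $R^2_{full} - R^2_{null}$; for mixed fits
the marginal and conditional R² follow the Nakagawa–Schielzeth variance
partition ($\mathrm{var}(X\hat\beta)$ over total, and fixed-plus-random over
total) and R²Δ is the change in marginal R². Labels follow Cohen's bands —
very small [0, .02), small [.02, .13), medium [.13, .26], large (> .26) —
with boundary values assigned to the upper class.

**Influence exclusion** is a single pass, not iterated: observations with
Cook's distance > 4/n *and* |studentized residual| > 2 are removed and the
model refit once; both fits are reported for sensitivity. For OLS the
standard formulas are used (externally studentized residuals). For mixed
models no canonical definition exists; here the fixed-effects analogues are
computed on the GLS-whitened problem (whiten X and y by the estimated
marginal covariance $\hat\sigma^2 I + \hat\tau^2 J$ per child, then apply
OLS influence formulas), which measures influence on the fixed effects and
is exact when the variance components are known.

Inference conventions: linear CIs/p-values use t with residual df; mixed
fixed effects use the normal approximation (±1.96·SE). α = .05 throughout,
with no multiple-testing correction — faithful to common practice in this
literature but liberal, and flagged as such.

## Isotemporal reallocation

Applied to the cross-sectional linear fit only (a mixed-model analogue is
not established methodology and is out of scope). Around a reference
composition, a reallocation produces a new composition; the predicted
outcome change is the ilr-coordinate contrast $d = z(\text{new}) -
z(\text{base})$ applied to the fitted ilr coefficients, with
$\mathrm{SE} = \sqrt{d^\top \hat\Sigma d}$ from the coefficient covariance
block and a t-based CI (residual df). Covariate terms cancel in the
difference, so the change is covariate-free; this equals the brute-force
difference of full linear predictions to 1e-10 (property-tested). A change
is "significant" when the 95% CI excludes zero. The zero-minute point is
exactly zero with a zero-width CI.

Choices the source conventions leave open, fixed here:

- **Reference composition**: the closed *arithmetic* mean of the analysis
  sample's compositions, with the geometric (Aitchison) mean available as an
  option; the choice is recorded in output metadata.
- **Proportional split**: "proportionally distributed" is ambiguous — the
  worked convention in this literature splits equally between the two
  non-focal behaviors, so EQUAL is the default, with proportional-to-base
  and explicit weights available.
- **Grid**: 10-min steps over ±60 min. Each proportional curve (3 focal
  behaviors) and each one-by-one curve (6 ordered pairs) has 13 points
  including 0; negative one-by-one deltas duplicate the reversed pair but
  keep curves plot-symmetric. Infeasible points (a behavior driven ≤ 0) are
  reported as gaps, not errors.

## The synthetic cohort generator

The generator exists so every stage can be tested and calibrated without
cohort data. It draws ilr coordinates from a bivariate normal and inverts —
a logistic-normal law on the simplex — because the downstream models are
linear in ilr coordinates, making them correctly specified on generated data
and parameter recovery meaningful. Defaults are anchored to printed
summaries of a real infant/toddler cohort:

- mean composition (224.3, 401.0, 807.0) min/day closed to 1440. The normal
  location is *mean-matched* by a deterministic Gauss–Hermite fixed point so
  that arithmetic part means equal this target despite the log-scale
  convexity (verified within 2% at n = 10,000);
- ilr covariance [[0.045, −0.012], [−0.012, 0.130]] under the sleep-pivot
  generator rotation, calibrated so minute-scale SDs are ≈ (77, 98, 91) —
  approximate, since the anchor tables mix means/SDs with medians/IQRs;
- first-visit ages drawn uniformly within four yearly bins (0–48 months)
  weighted (47, 52, 43, 19); 45.5% girls; follow-up gap 8.7 ± 1.1 months
  (uniform jitter); no second visit past 48 months of age, plus 13%
  independent dropout;
- outcomes: `gm_raw` mimics a 0–72 raw motor score (β_age = 1.1/month,
  sleep-pivot β_ilr1 = +8.5, β_ilr2 = +6.0 — chosen so the implied SB-pivot
  coefficient is ≈ −9.4 and the PA-pivot one ≈ +1, the sign/magnitude
  pattern of reported motor associations; τ = 4.5, σ = 4); `zbmi` a BMI
  z-score near +0.7 with a weaker effect (β_ilr1 = 1.3); `se_raw` a null
  outcome (no composition effect) for calibration. An optional age slope on
  the ilr coordinates defaults to off, as the age–composition joint
  distribution is not quantified in the anchor material.

What it does **not** emulate: item-level test structure or norm-referenced
scaling of developmental scores, WHO growth-curve computation, informative
(outcome-dependent) dropout, within-child correlation of compositions over
time, or reporting error in diaries. Passing tests therefore demonstrate
statistical correctness of the machinery under the assumed data-generating
process, not robustness to the measurement quirks of real diary data.

## Numerical choices and verification

- Closure renormalizes exactly so part sums equal the total at float
  precision; compositions reject non-finite or non-positive parts.
- The ilr inverse exponentiates with a row-max shift for overflow safety.
- Mixed models are fit with statsmodels' MixedLM; on the rare singular-
  Hessian failure the optimizer falls back (default → Powell → CG).
- LRT statistics are floored at 0 (boundary round-off can give tiny
  negatives).
- Simulation sizes in the test suite: type-I error is checked with 2,000
  replicates at n = 100 children (observed rates ≈ 0.04–0.05 for both the
  F and χ² tests, band [0.03, 0.07]); parameter recovery with 500 replicates
  at n = 300 children (median bias < 5%, CI coverage in [0.93, 0.97]). The
  acceptance script uses 400/150 replicates for the same quantities to keep
  a single run short.
- Determinism: everything randomized flows through a single integer seed;
  rerunning a pipeline config with the same seed produces byte-identical
  artifacts (tested).

## Known limitations

- The default diary mapping is provisional (see above); qualifier-level
  rules for real instruments must be supplied by the user.
- Mixed-model influence diagnostics are a reasoned analogue, not a
  standard; alternative definitions (case deletion, conditional Cook's
  distance) would exclude slightly different sets.
- Marginal/conditional R² definitions for mixed models are themselves a
  convention (Nakagawa–Schielzeth); other variance-partition choices exist.
- Reallocation predictions are conditional on the fitted linear model and
  the chosen reference composition; they are descriptive re-expressions of
  the regression, not causal estimates.
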