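# Methods

## Scope and data model

`toxmix` analyses acute lethality bioassays: groups of animals exposed
to one toxicant (a concentration series) or to a fixed-ratio binary
mixture (a dilution series), with deaths counted at census times. The
unit record is one exposure group (component(s), concentration(s) in
mg/L, exposure time, animals exposed, deaths, replicate index).
Concentrations are stored as dosed (e.g. salt mass for metal salts);
conversion to elemental concentrations is deliberately left to the user.

A published 96-hour Cr/Ni assay on the ostracod *Heterocypris* sp.
ships with the package (`toxmix.datasets`): design concentrations,
replicate-mean mortality at 24/48/72/96 h, the reported best-fit curve
parameters per metal and time, the published mixture-design ratios and
the measured mixture LC50s. These tables serve as reference fixtures
and as realistic defaults for the simulator.

## Concentration–response fitting

Three sigmoid families map concentration x > 0 to expected mortality
fraction: Weibull `1 − exp(−exp(α + β·lg x))`, Box–Cox–Weibull
`1 − exp(−exp(α + β·(x^γ − 1)/γ))` and generalised logit
`(1 + exp(−α − β·lg x))^(−γ)`. Inverses are closed forms derived
algebraically from the forward equations. Two modelling notes:

- BCW with γ = 0 is rejected rather than silently replaced: its γ→0
  limit is a natural-log Weibull, a different curve from the lg-based
  Weibull family.
- BCW with γ > 0 has a positive zero-dose baseline and with γ < 0 a
  ceiling below 1; effect levels outside `[f(0+), f(∞))` have no
  inverse and raise a no-solution error. Downstream report writers
  treat this as a blank cell, not a failure.

Fitting is unweighted least squares on the pooled mortality proportion
(replicates averaged per concentration). This choice is validated by
the bundled study: refitting the chromium 96-h series reproduces the
reported parameters (α −0.40, β 1.21), R² (0.96) and MAE (0.05).
Weighted or binomial-likelihood (probit/logit GLM) fitting is out of
scope.

Numerical choices:

- **Multi-start.** Initial values come from a coarse grid (α over
  [−12, 2], β over [0.5, 12], γ ∈ {−0.5…0.5} for BCW, {0.05…2} for GL);
  the best 8 starts by initial SSR are polished with
  `scipy.optimize.least_squares` using analytic Jacobians. The
  three-parameter families are ill-conditioned; single starts are not
  reliable.
- **Box constraints and degeneracy.** Parameters are bounded to
  α ∈ [−30, 10], β ∈ (0, 30], γ ∈ [0.01, 5] (GL) / [−2, 2] (BCW). The
  GL family has a degenerate ridge (γ → 0 with |α|, |β| → ∞) that
  improves SSR indefinitely while driving tail quantities like the LC10
  to zero; without bounds the optimizer follows it. An optimum pinned
  to the box is reported as non-convergence for that family. β is
  restricted positive because mortality increases with dose throughout
  the supported designs.
- **Covariance.** Gauss–Newton: C = (JᵀJ)⁻¹·s² with s² = SSR/(n − m),
  n the pooled concentration count and m the parameter count
  (pseudo-inverse for near-singular JᵀJ).

Family selection (`family="auto"`) returns the highest-R² fit, ties
broken by fewer parameters, then lower MSE. On five pooled points a
three-parameter family usually edges out a two-parameter one by raw R²,
so auto-selection frequently prefers GL/BCW where an analyst might keep
the Weibull; the reported family choices of the reference study are not
reproducible by any single deterministic criterion we tried (raw or
adjusted R²), presumably because they were made on raw replicate data
and/or with analyst judgment. Fix the family explicitly when comparing
against reported parameter sets.

Fit quality is R² = 1 − SSR/SStot, MSE = mean squared error and MAE =
mean absolute error, all on the proportion scale.

## Observation band and LCx confidence intervals

The observation confidence band at concentration x is

    ŷ(x) ± t_{n−m, (1−level)/2} · sqrt(s² + v C vᵀ),

v the parameter gradient of the curve at x. Because the band carries
the residual variance term it is a prediction-style band: it reflects
where new observations fall, not just curve uncertainty.

The LCx point estimate inverts the fitted curve in closed form. Its
interval inverts the band: the concentration where the upper band edge
reaches the level p is the lower bound, where the lower edge reaches p
the upper bound, both found by Brent bisection on the bracket
[LCx/1000, LCx·1000] at 10⁻⁶ relative tolerance. Consequences worth
knowing:

- The band's half-width never drops below t·s, so effect levels smaller
  than that floor (e.g. the LC10 of a noisy series) may never intersect
  the upper edge; the bound is then reported one-sided (0 or ∞) with a
  warning.
- Coverage is conservative: in simulation at the bench design size the
  nominal 95% interval covers the true LC50 in ≈98% of simulated datasets.
- A delta-method interval (parameter covariance propagated through the
  closed-form inverse) is available via `method="delta"` for users who
  want curve-only uncertainty.

How the reference study computed its printed intervals is not
documented; band inversion reproduces their asymmetry qualitatively but
exact agreement is not claimed.

## Hazard summaries

GHS-style acute banding uses the 96-h LC50: strictly between 1 and
10 mg/L is "highly toxic"; at or below 1 "very highly toxic"; at or
above 10 "moderately to slightly toxic". Only the middle band's strict
inequalities are load-bearing for the bundled study. The toxicity
factor is the ratio of LC50s (less toxic over more toxic), convention-
ally rounded to an integer for reporting ("4 times more toxic").

## Mixture designs

- **EECR p**: mass fractions proportional to the components' common
  effect concentration (LCp); the ray's defining top concentration is
  the LCp sum.
- **EquRay i of n**: the segment between the two components' LC50 axis
  intercepts divided into n equidistant points; ray i combines
  (n+1−i)/(n+1) of component a's LC50 with i/(n+1) of component b's.
  The published design table follows this indexing (all five printed
  ratios reproduce to 2 d.p.); the opposite convention appears in some
  prose descriptions and is available via `text_indexing=True`.
- **FRRD**: geometric dilution top/f^k, k = 0…n−1, ratio preserved
  exactly at every level. The reference study used 12 levels; its
  dilution factor is not stated, so the default is 2 (serial halving),
  configurable. A headroom multiplier above the defining top is
  available (`top_multiplier`); with the default of 1 an EECR-10 series
  tops out near 10% expected mortality, which is faithful to the design
  definition but leaves an LC50 beyond the observed range.

Two published EECR ratios (EECR 30: 0.08, EECR 50: 0.11) do not follow
from the published LC30/LC50 values (which give 0.11 and 0.185); only
the EECR 10 ratio is used as an exact reference.

## Mixture reference models and interaction

- **Concentration addition** (Loewe): mixture LCp =
  1/Σᵢ(fᵢ/LCpᵢ), the fraction-weighted harmonic mean; equivalently the
  mixture effect at concentrations cᵢ is the level p where the toxic
  units Σ cᵢ/LCpᵢ(p) equal 1 (unique root; solved by Brent). The
  toxic-unit sum is only defined over the effect range all components
  can attain; outside it the attainable bound is returned. A published
  formulation that sums Cᵢ·LC50ᵢ products is dimensionally inconsistent
  with the CA concept and is treated as a typesetting error.
- **Independent action**: E = 1 − Π(1 − fᵢ(cᵢ)); the mixture LCp along
  a ray is found by bracketed bisection on the total concentration.
- **Synergistic ratio**: SR = single LC50 / mixture LC50. The strict
  rule labels SR > 1 synergistic, < 1 antagonistic, = 1 additive; the
  default adds a ±0.05 additive band around 1 (ε = 0 restores the
  strict rule). "Observed" mixture LC50s come from fitting the same CRC
  machinery to total concentration along a ray.

## Regression surrogate of the mixture surface

Observed mixture mortality is regressed on composition variables —
each component's concentration, the total and the first component's
mass fraction — the only inputs a fixed-ratio design varies. Four
families are compared on a fixed-seed 80:20 split (optionally
stratified by ray): ridge (penalty by internal CV), gradient-boosted
trees (200 rounds, depth 3, learning rate 0.1), a one-hidden-layer
32-unit perceptron, and ordinary multilinear regression. Inside every
model pipeline the three concentration columns are log10-transformed
(mortality responds to log dose — the same axis the CRCs use) and, for
the scale-sensitive ridge and MLP, standardized; the MLP uses the
lbfgs solver, the standard recommendation at these sample sizes. The
family with the highest test R² is selected.

Surrogate LCx values are read off by evaluating the selected model
along a ray on a log-spaced grid of totals, clipping predictions to
[0, 1], monotonizing with a running maximum (tree ensembles produce
piecewise-constant, occasionally non-monotone slices) and inverting by
interpolation. On a noise-free CA-truth surface over the full 8-ray ×
12-level design the selected surrogate reaches test R² ≥ 0.97 and
recovers a ray's LC50 within a few percent.

## Synthetic data

The simulator draws deaths per replicate as Binomial(n_exposed, f) with
f from a known true curve (singles) or from the CA/IA truth model
applied to the true component curves (mixtures). Defaults mirror the
reference bench design: 10 animals per group, 3 replicates, the
published 5-level single series, 12 mixture dilutions, and the
published fitted curves as truth. All randomness flows through
`numpy.random.SeedSequence` keyed by (seed, component-or-ray tag,
time), so datasets are fully reproducible and independent across
components.

What it emulates: sampling noise of the bench design, including the
pooled-proportion pipeline downstream. What it does not: overdispersion
between replicates (no beta-binomial by default), water-chemistry
covariates, time-course dependence between census times, or dosing
error in the concentration series. Passing recovery tests therefore
show the estimators are correct and adequately powered for binomial
noise at this design size, not that real assays are free of extra
variance.

Recoverability at the bench design size depends strongly on curve
steepness: across 200 simulated studies the median |relative error| of
the refit LC50 is ≈13% for the steep nickel-like curve (GL, β ≈ 8.9)
but ≈17% for the shallow chromium-like curve (Weibull, β ≈ 1.2), whose
five levels span only 25–94% expected mortality. Single-study LC50s
from such designs carry meaningful uncertainty, which is why the
confidence-interval machinery matters.

The CA-versus-IA model comparison is likewise a pooled-design question:
on any single ray the two predictions differ by at most ~0.07 effect
units — below binomial noise at 30 animals per level — so truth-model
identification is only reliable when observations are pooled across the
full 8-ray design (where the CA truth wins the R² comparison in ~97% of
simulated studies).

## Pipeline

`run_pipeline` strings the stages together: fit single-agent curves
(best of three families) per component and census time → tabulate
LC10/30/50 with intervals → build the 3 EECR + 5 EquRay design from the
96-h fits → load measured mixture records or simulate them from the
fitted curves → fit mixture CRCs on total concentration → compare
CA/IA/surrogate predictions against pooled observations → classify SR
interactions. Every output table is CSV and re-parseable by the
package's own readers; a run log records the package version, seed,
config hash and per-stage status. Stage failures are logged and
dependent stages skipped rather than aborting the run.

## Known limitations

- No control-mortality (Abbott) correction: the reference study's
  blank controls had zero mortality. Assays with control deaths need
  pre-correction.
- Proportion-scale least squares ignores the binomial mean–variance
  relation; it matches the reference analysis but a GLM would be more
  efficient at extreme effects.
- Auto family selection by raw R² favours three-parameter families on
  short series (see above).
- The surrogate regression interpolates within the dosed composition
  space; extrapolated LCx values beyond the trained concentration range
  are unreliable, and the running-maximum monotonization makes tree
  model inversions step-like.
- Only binary mixtures are supported; no ternary designs, isobolograms
  or combination-index analysis.
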