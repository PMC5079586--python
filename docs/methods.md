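# Methods

This note documents the models behind `lenassess`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical choices that affect results.

## The per-recruit world

Every model in the package lives in an equilibrium per-recruit population:
recruitment is constant (one recruit per unit time, no stock–recruit
feedback), growth follows von Bertalanffy
`L(a) = L∞ (1 − e^{−k (a − t0)})`, natural mortality `M` is constant over
age, and fishing mortality acts on length through an asymptotic logistic
selectivity ogive. Total mortality at age is `Z_a = M + F · S(L_a)`. This
is the standard setting in which the Spawning Potential Ratio is defined:
SPR compares lifetime egg production per recruit with and without fishing,
deliberately excluding any density-dependent compensation.

Ages run from 0 to `tmax` in annual steps by default (the per-recruit sums
are annual; a finer `age_step` is available on every function that
discretises age). At the default parameters the biomass surviving past
`tmax` = 21 yr is < 0.3% of a cohort, so the truncation is immaterial.

## Ogives

Maturity and selectivity both use the two-anchor logistic

`f(l) = 1 / (1 + exp(−ln 19 · (l − l50)/(l95 − l50)))`,

which passes exactly through 0.5 at `l50` and 0.95 at `l95`. Only the 50%
maturity length is usually estimated in the field; `lm95` defaults to
`1.1 × lm50` (a moderately steep ogive) and is configurable.

Egg production at age is `E_a = Mat(L_a) · L_a^b` with the
fecundity–length exponent `b = 3` by default: fecundity in groupers scales
roughly with body weight, and weight scales with the cube of length. `b`
is configurable; SPR is fairly insensitive to it because it affects
numerator and denominator symmetrically.

## Growth-type groups

Individual variability in asymptotic length is propagated with `G = 13`
growth-type groups spanning ±2.5 sd of `N(L∞, CV L∞ · L∞)` at equally
spaced points, weighted by the normal density (conventional LB-SPR
defaults; both configurable). Each group follows its own growth curve, so
large-L∞ groups become selectable earlier and are fished down harder —
the mechanism by which fishing truncates not just the age structure but
the growth composition of survivors.

Within each group, length-at-age is normal around the group curve. If the
within-group CV were the full `CV L∞` the marginal length spread would be
double-counted (the groups already carry between-group variance), so the
within-group CV is reduced to `CV L∞ · sqrt(1 − Var_w(x))`, where
`Var_w(x)` is the weighted variance of the standardised group offsets.
The marginal length-at-age CV therefore equals `CV L∞` for any `G`, and
`G = 1` reduces exactly to the classic single-curve model with the full
CV at age. `CV L∞` defaults to 0.10 — a typical teleost value — and, being
rarely published, is the first knob to sweep in any sensitivity analysis
(the acceptance script reports SPR at 0.05/0.10/0.15).

## Expected composition and the likelihood

The expected catch length composition accumulates, over groups and ages,
`weight_g × N_{g,a} × S(μ_{g,a})` spread across the half-open length grid
by each cell's normal distribution (truncated and renormalised to the
grid). Selectivity and mortality are evaluated at the cell mean length.
Age classes with mean length ≤ 0 (age 0 when `t0 = 0`) are unobservable
by a length-measuring protocol and carry no catch mass.

`fit_lbspr` maximises the multinomial log-likelihood
`Σ_bins n_bin log p_bin(F/M, SL50, SL95)` over the transformed parameters
`(log F/M, SL50, log(SL95 − SL50))`, which enforce positivity and
ordering without constraints. The search is Nelder–Mead (derivative-free;
the likelihood surface is smooth but the binning makes finite-difference
gradients unreliable at coarse grids) from three deterministic starts
anchored on observed length quantiles, keeping the best converged
optimum; convergence tolerance 1e-6 on the log-likelihood. Estimates with
F/M < 0.01 are flagged `at_boundary`. Uncertainty comes from a
nonparametric bootstrap over individual fish (multinomial resampling of
the observed bins, default B = 100, seeded), refit from the point
estimate. Default grid: 2-cm bins from 0 to 1.3 L∞.

## Catch curve

Lengths are converted to ages by inverting the growth curve,
`a = t0 − log(1 − tl/L∞)/k`, floored to integers (ages are right-open
annual classes, consistent with the half-open length bins) and capped at
`tmax` for fish at or above L∞, where the inversion diverges. The
inversion compresses old ages into a narrow length band, so the resulting
Z is sensitive to `t0`, `k` and the flooring rule; every
`MortalityEstimate` echoes the configuration it was computed under, and
assessments should report a `t0` sweep rather than a single Z. The
descending limb starts at the modal age by default ("peak"), with a
"peak_plus_one" option since both conventions are in use. Standard
errors: `se(S) = sqrt(S (S − (T−1)/(n+T−2)))` (the estimator's exact
variance) and `se(Z) = (1 − S)/sqrt(n S)`.

## Trends

Indicator trends are binomial GLMs (logit link) of per-year counts on
calendar year, fit by IRLS (statsmodels) with years centred for
conditioning; significance is the likelihood-ratio chi-square against the
intercept-only model (1 df). When only a published summary table is
available, counts are reconstructed as `round(pct × n / 100)`; this is
approximate because printed percentages are rounded.

The mean-length trend uses the normal random-intercept model
`TL ~ year + (1 | source)`: the source intercepts absorb systematic level
differences between collection programmes so the year slope is not
confounded with which programme sampled which years. The model is fit by
maximum likelihood with the variance ratio `λ = σ²_source/σ²_resid`
profiled out — given λ, the fixed effects and residual variance are
closed-form GLS quantities computable from per-source sums, leaving a
one-dimensional bounded optimisation over log λ (with the λ = 0 boundary
checked explicitly). This implementation matches statsmodels MixedLM (ML)
to ~1e-5 on slope and SE (verified in the test suite) and is ~100× faster
per fit, which matters because the hypothesis test refits both models
inside a parametric bootstrap: the observed statistic is
`2(ℓ_full − ℓ_null)`, the null distribution comes from `n_boot` datasets
simulated from the fitted null (new source intercepts and residuals each
draw), and `p = (1 + #{boot ≥ obs})/(n_boot + 1)`, never exactly zero.

## The simulator

`synthetic_data` inverts the estimation model exactly: equilibrium
numbers per (growth-type group, age) cell, catch weight proportional to
abundance × selectivity at the cell mean length, lengths drawn from the
cell's zero-truncated normal. With `n_gtg = 1` it is the classic
single-curve simulator. Because generator and estimator share one
observation model, parameter-recovery tests measure estimator quality,
not model mismatch; the measured median errors (20 replicates, n = 5000
at F/M = 2) are ~2% for F/M and < 1% for SL50/SL95.

What the simulator does **not** emulate about real landing data: ageing
and measurement error, dome-shaped or time-varying selectivity,
recruitment variability and transient (non-equilibrium) dynamics,
spatial/seasonal structure such as spawning aggregations, sex change, and
market-driven sorting of the catch. Passing recovery tests therefore
demonstrates internal consistency of the estimators under their own
assumptions — it does not certify the assumptions for any particular
fishery.

## Degenerate inputs and tie-breaks

* Per-year summaries report sd as NaN (undefined) for n = 1, never 0;
  empty years are carried and reported, not dropped.
* The catch curve requires ≥ 2 age classes and ≥ 3 fish on the limb;
  `T = 0` (all limb fish at the peak age) returns the flagged degenerate
  S = 0 rather than raising.
* The modal age ties break to the youngest age (`argmax` convention).
* Indicator boundaries: mature is inclusive (`tl ≥ lm50`), the optimum
  interval is closed, mega-spawner is strict (`tl > 1.1 L_opt`), so
  boundary fish are counted exactly once per definition.
* Record validation rejects non-positive lengths, lengths above a 200-cm
  hard cap (data-entry guard, configurable), and years outside
  [1900, 2100]; every rejection is tallied by reason.

## Known limitations

* SPR point values depend on unpublished-in-practice inputs (CV L∞, bin
  width, age discretisation); at the default bacalao parameters the
  plausible range spans roughly 0.03–0.05. Report sweeps, not points.
* Chapman–Robson Z from length-assigned ages inherits the age-assignment
  configuration; it is a consistency indicator here, not an absolute rate.
* The binomial GLMs treat per-year counts as independent binomials;
  overdispersion from within-trip correlation is not modelled.
* Asymptotic (flat-topped) selectivity only; a dome-shaped gear would
  bias F/M upward in this framework.
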