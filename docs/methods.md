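# Methods

## The model

Players are genotypes in an aggregation; a player's relatedness to the
group equals its frequency `r` (all strains assumed mutually unrelated
and mutually distinguishable). Investing a fraction `x ∈ [0, 1]` of the
cell budget in stalk costs `c` per unit of direct fitness and yields a
group benefit `r·b` per unit to the investor, multiplicatively:
`ω = (1 + r·b·x)(1 − c·x)`. The interior maximiser is
`x̂(r) = ½(1/c − 1/(b·r))`, floored at 0; investment switches off below
`r = c/b`. The group optimum (clonal strategy) is
`θ = (b − c)/(2bc) = ½(1/c − 1/b)`; for the canonical rates `b = 12`,
`c = 1` used throughout the examples, `θ = 11/24 ≈ 0.458`.

Collective investment is the frequency-weighted sum
`x_G = Σ r_i x̂(r_i)`; a strain's frequency appears both as its
relatedness (inside `x̂`) and as its weight in the sum.

### Imperfect information

Cells estimate their relatedness with Gaussian error centred on the true
value with SD `e · 4^t [r(1−r)]^t`. The weight equals 1 at `r = ½`, so
`e` is the SD at intermediate relatedness; `t = 0` gives flat noise and
`t > 0` concentrates it at intermediate relatedness, where signals are
plausibly hardest to discriminate. The exponent is called `t`
throughout (one parameter, even where a different letter might be used
for the same role in fitting contexts). A strain's expected investment
is E[x̂(ρ)] under the perceived distribution.

The perceived relatedness is **truncated to [0, 1] and renormalised**:
relatedness is only defined there, and truncation (rather than
reflection or an unbounded support) keeps the distribution a proper
density without inventing mass at impossible values. The alternative
readings would change expected investment near the boundaries; the
truncation choice is local to `truncated_gaussian_weights` if a variant
is ever needed.

### Transdifferentiation enforcement

A developmental negative feedback — prespore cells produce
stalk-inducing factors that prestalk cells degrade — is modelled as a
pressure `D(θ − A_G)` applied to every strain's initial allocation:
`x_i = A_i + D(θ − A_G)`, clipped to [0, 1]. The feedback is at
equilibrium when the group allocates `θ`, reflecting its presumed origin
as a buffer for clonal proportioning errors. Anticipating the feedback
(with nonfocal strains allocating 0, the many-strain evolutionary
scenario), the optimal initial allocation is
`Â(r) = ½((1−D)/(c(1−D·r)) − 1/(b·r))`, floored at 0. Algebraically,
whenever `Â > 0` the realised investment equals the no-feedback optimum
`x̂(r)` — enforcement only binds below the (slightly lowered) threshold
`r < c/(b(1−D) + cD)`, where it pins group investment at the plateau
`D·θ`. The two-strain variant of `Â` has no closed form here and is
covered only by the numerical-maximisation oracle in the tests.
Clipping to [0, 1] never triggers for fitted parameter ranges (asserted
in tests with allocations in [0, 0.8]).

## The empirical investment scale

Stalk cells cannot be counted directly, so investment is inferred from
spore totals. With clonal totals `T_i` and chimeric total `T_G`:
`E_G = Σ r_i T_i`, `S_G = E_G/T_G`, and `I_G = 1 − (1−θ)/S_G`
(`S_G = 1 ↦ θ`, `S_G = 1−θ ↦ 0`). Negative inferred investments
(`S_G < 1−θ`) are reported with a warning, not clipped: they carry the
noise information an unbiased least-squares fit needs.

Model predictions are mapped to the `S` scale by the linear rescaling
`X_G = 1 − θ(1 − x̂_G/θ)` (the form used for fitting), although the
exact inverse of the inference formula is hyperbolic,
`S = (1−θ)/(1 − I)`. The two agree at both endpoints and differ by up
to ≈0.07 at mid-scale for θ ≈ 0.46. Both are implemented
(`model_to_empirical(..., exact=True)`); the linear form is the default
because it is the procedure the assay analysis prescribes, and the
discrepancy is deliberately left visible rather than "fixed".
**Consequence for recovery tests:** the synthetic generator inverts the
exact (hyperbolic) chain, so parameter-recovery tests fit with
`prediction_scale="exact"` — only there is the generating grid point the
exact optimum of the objective (RSS = 0). Fits of real-style data use
the default linear scale.

## Fitting

`grid_search_fit` minimises `Σ (S_obs − X_pred)²` over a Cartesian grid,
by default 20 values per parameter with `b ∈ [2, 15]`, `c ∈ [1, 2)`,
`e ∈ [0, 1]`, `t ∈ (0, 1]`. The `b` upper bound is set above the
canonical best fit (b = 12) so the default grid can contain it; all
bounds are configurable. Ties (within 1e−12) are broken by ascending
`(b, c, e, t)` and all tied points are reported.

The engine precomputes each `(b, c)` strategy on a 2001-point perceived
-relatedness grid, applies each `(e, t)` truncated-Gaussian weight
matrix as one matrix product to get expected-investment curves on a
201-point true-relatedness grid, and linearly interpolates those curves
at each composition's frequencies. This reproduces the direct
per-composition quadrature to ~1e−4 (the final reported RSS is
recomputed on the exact quadrature path) and keeps the full 20⁴ grid at
a few seconds on one core. An independent brute-force loop reproduces
the engine's objective and argmin in the tests.

`fit_D` holds `(b, c, e, t)` fixed and scans `D ∈ {0, 0.01, …, 0.25}`.
`bootstrap_ci` resamples each composition mean from Gaussian(mean, SE)
— reading "resampling from distributions corresponding to the data" as
the sampling distribution of the mean; nonparametric resampling of
replicates is available via `method="replicates"` — refits (100
iterations by default), and takes 5th–95th percentiles of the
deviations, widened to contain the point estimate. A conservative
combined band picks the CI-corner parameter combination that maximises
the deviation of predicted investment. `model_compare_F` uses
`Δp = 2` by default: the perfect-information model drops both error
parameters (`e` and `t`), not just `e`; `Δp` is an argument for the
stricter reading. Per-composition means are unweighted across
replicates.

## smFISH classification

Cells are censored when **both** *ecmA* and *pspA* have fewer than 17
dots. The stricter reading — censor when *either* gene is below 17 —
would discard essentially every committed cell (a committed prespore
cell legitimately has ~0 *ecmA* transcripts), so the both-genes-low
reading is the default and the strict one sits behind
`mode="either"`. Censoring precedes normalisation. *pspA* counts are
rescaled per replicate by `mean(ecmA)/mean(pspA)` over retained cells
(each replicate independently, absorbing hybridisation-efficiency
differences), the index is `pspA_norm/(ecmA + pspA_norm)`, and fates
are `≤0.3` prestalk, `≥0.7` prespore, in between transdifferentiated
(both thresholds inclusive). Chi-square tests use no continuity
correction (counts are large); a flag restores it.

## Group-level statistics

The collapse analysis reports the plain OLS of collapse proportion on
relatedness, with F(1, n−2), as the headline number, and fits the
mixed model (composition random intercept, maximum likelihood)
alongside — both appear in the output. A relatedness-cubed OLS is
provided purely as a plotting aid. The two- vs twenty-strain contrast
fits a mixed model (group type fixed, replicate group random) and
**overrides** the default degrees of freedom with the minimal
`(number of replicate groups − 1)`, a deliberately conservative hard
rule. Pair frequencies are bias-adjusted from the 50:50-mix share `s`
by odds scaling, `f' = f·β/(f·β + 1 − f)` with `β = s/(1−s)` — one
concrete reading of a loosely specified step; it preserves the pair sum
at 1 and reduces to identity at `s = ½`.

## Synthetic data

The generators reproduce the study's designs and noise structure:

* **Designs** — three-strain transects (each strain fixed at 0.2 or 0.8,
  remaining mass split `k/11 : (11−k)/11`, `k = 1…10`; 60 unique
  labelled compositions — the split grid is a stand-in chosen so no
  value collides with the fixed levels, and the readers accept arbitrary
  composition tables) and equal-frequency N-strain groups
  (N ∈ {4…10, 15, 20}).
* **Spore assay** — clonal totals log-normal around 5×10⁶ spores
  (10⁷ cells plated, near-θ allocated to stalk) with among-strain
  CV 0.3; chimeric totals invert the inference chain at the
  model-predicted investment, `T_G = E_G(1 − x_G)/(1 − θ)`, times
  multiplicative log-normal noise of CV 0.15. Replication defaults to
  20 (three-strain) / 22 (N-strain) per composition. The CV was set
  from what hemocytometer spore totals realistically show and is
  consistent with the variance-explained structure such experiments
  report; strain-level variation in *investment strategy* is not
  simulated (only clonal productivity varies).
* **smFISH** — negative-binomial dot counts with class-dependent means
  (prestalk 200/5, prespore 2/200, transdifferentiated 90/115;
  dispersion 15), plus a censorable low-signal fraction. Classes are
  well separated on the index, so classification error is negligible
  against binomial sampling noise.
* **Collapse** — a decreasing logistic link from investment
  (proportion of θ) to collapse probability, binomial per well.

All generators are pure functions of (spec, seed). What they do *not*
emulate: allorecognition/segregation, spatial slug structure,
developmental-timing differences, strain-specific strategy variation,
and any systematic bias of spore counts not caused by stalk allocation.
Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness
to violations of them.

## Numerical choices

* Quadrature: fixed 2001-point trapezoid grid on [0, 1]; the strategy
  has a single kink, and this density keeps quadrature error below 1e−6
  (checked against 10⁶-draw Monte Carlo). When the perception SD falls
  below ten grid steps the integration window is refined locally to
  ±8 SD around the mean so tiny noise levels remain resolved.
* `r = 0` is treated as the limit `x̂ = 0`; divisions are guarded.
* Grid-search ties break by ascending `(b, c, e, t)`; `D` ties by
  ascending `D`.
* All Monte-Carlo and bootstrap paths take explicit seeds and record
  them in their outputs.

## Problem sizes in the test suite

The suite favours small deterministic problems: grid searches use 3–4
values per parameter (the engine is verified against a brute-force loop
at that size, and full-grid behaviour differs only in coverage), the
oracle comparisons use 1000 random parameter draws and 10⁶-draw Monte
Carlo on 20 configurations, D-recovery uses 50 seeded simulated
experiments at the study's replication, and the smFISH recovery check
uses 10,000 cells.

## Known limitations

* **D identifiability.** At realistic measurement noise (CV ≈ 0.15,
  22 replicates per composition, nine group sizes) the least-squares
  objective for `D` is shallow: predictions at `D = 0.13` and `D = 0.17`
  differ by under 0.01 on the `S` scale, below the standard error of a
  composition mean. The sampling SD of the fitted `D` is roughly
  0.04–0.05, so single experiments localise `D` only to about ±0.1 at
  95% confidence; the corresponding strict recovery check in the
  acceptance tests documents this by failing. Noise-free data recover
  `D` exactly.
* The three-strain `(b, c, e, t)` fit shows strong ridge structure
  (benefit rate vs error SD trade-off) at realistic noise; bootstrap
  CIs, not point estimates, are the meaningful summary.
* The Eq-5/Eq-6 scale discrepancy (above) means the default fitting
  objective is not exactly minimised at the generating parameters of
  the synthetic generator; recovery tests use the exact scale.
* Mixed models with very few groups rely on the enforced minimal df;
  their variance components are not reliably estimated at that size.
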