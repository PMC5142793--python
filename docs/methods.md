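# Methods

`rdcapture` implements a complete robust-design capture–recapture
analysis for photo-identification studies: estimation of abundance,
apparent survival and temporary emigration from binary capture
matrices, scaling of marked abundance to total abundance, and a
trend-detection power analysis. This note records the model, the
conventions chosen where several were defensible, and what the
synthetic-data generator does and does not emulate.

## The robust-design model

Sampling is organised in *primary occasions* (field seasons) split into
*secondary occasions* (months or days). The population is treated as
closed within a primary and open between primaries.

**Latent dynamics.** Each marked animal follows a three-state chain
across primaries — *inside* the study area, *outside* (temporary
emigrant), or *dead/permanently gone*:

- inside → inside: `S (1 − γ″)`; inside → outside: `S γ″`;
- outside → inside: `S (1 − γ′)`; outside → outside: `S γ′`;
- any live state → dead: `1 − S`.

`S` is apparent survival (true survival × fidelity); `γ″` is the
probability of leaving given presence, `γ′` the probability of staying
out given absence. Three emigration structures are supported: *none*
(`γ″ = γ′ = 0`), *random* (`γ″ = γ′`, one parameter) and *Markovian*
(two parameters).

**Detection.** While inside, an animal is detected at secondary `s` of
primary `t` with probability `p_ts`; outside or dead it cannot be
detected. `p*_t = 1 − Π_s (1 − p_ts)` is the derived probability of at
least one detection within primary `t`. Detection may be constant,
vary by secondary index (shared across primaries), by primary, or
fully (`primary × secondary`); two-class finite mixtures (Mh, and Mth
with secondary-index variation) add a second detection class with
mixing proportion `π`.

**Likelihood.** The objective is the composite likelihood used by
robust-design software: a product of

1. one full closed-population component per primary, in the f0
   parameterization `N_t = n_t + f0_t` (`n_t` animals detected in
   primary `t`, `f0_t` the expected number of marked animals inside
   but never detected there):
   `Γ(N_t+1)/Γ(f0_t+1) · Π_s p_ts^{x_ts} (1−p_ts)^{N_t−x_ts}`,
   with mixtures replacing the product by π-weighted per-history sums;
2. an open component over primary-level (collapsed) histories,
   conditional on first detection, evaluated by the forward algorithm
   of the three-state chain with emission `p*_t` when inside. Animals
   enter at their first detected primary in state *inside*.

Detection parameters are shared between the two factors. Each factor
is a proper marginal likelihood, so the summed score is unbiased at the
truth and the maximizer is consistent; simulation (50 replicates,
400 animals, the study design) shows apparent survival recovered
without bias and with accurate standard errors (empirical coverage of
±2 SE ≈ 95–98%). Multinomial constants over observed histories are
dropped throughout: absolute log-likelihood and (Q)AICc values are not
comparable across software, but likelihood ratios, Δ(Q)AICc, rankings
and weights are unaffected.

With a single primary the open component is empty and the model
reduces to closed-population Mt; with one secondary per primary and no
emigration the open component reduces to the Cormack–Jolly–Seber
likelihood (both reductions are tested against independent oracles).

**Fitting.** Optimization runs on the unconstrained link scale (logit
for probabilities, log for f0) with L-BFGS-B from 5 overdispersed
random starts by default (logit-uniform draws; deterministic under the
supplied seed; objective tolerance 1e-10). Standard errors come from
the inverse observed information (central-difference Hessian on the
link scale); probability CIs are computed on the logit scale and
back-transformed, and the marked-abundance interval is log-normal on
f0, so the lower bound never falls below the observed count. Estimates
near the link-scale boundary (|link| > 9) and fits where no start
reports clean convergence are flagged, never silently accepted.

## Model selection and averaging

`AICc = −2ℓ/ĉ + 2K + 2K(K+1)/(n_eff − K − 1)` with ĉ = 1, QAICc
otherwise. The effective sample size is `individuals × primaries` by
default (configurable; Δ values and weights are insensitive to this
choice for fixed data). The default grid holds 30 structures:
{none, random, Markovian} × {S(.), S(year)} × {p(.), p(month),
p(year), p(year.month)} plus the six S(.) mixture variants (Mh, Mth).
Time-varying emigration is deliberately excluded from the default grid
(a single shared γ per structure keeps all printed parameter counts
consistent); custom grids can include any spec.

Averaging uses Akaike weights renormalized over the kept subset —
either models within Δ ≤ 2 of the best (default) or a fixed top-k —
with the Burnham–Anderson unconditional standard error
`SE = Σ w_i sqrt(var_i + (θ_i − θ̄)²)`. Parameters a simpler structure
fixes (γ = 0 under no emigration) enter as structural constants.

## Goodness of fit

The TEST2/TEST3 contingency components are computed on the
primary-pooled histories: TEST3.SR (new vs old × ever re-seen;
transience), TEST3.Sm (new vs old × occasion of next encounter),
TEST2.CT (seen at t vs not × seen at t+1 vs not, among animals known
alive across the interval; trap dependence) and TEST2.CL (seen at t vs
not × occasion of next encounter beyond t+1). Cells with expected
counts below 2 are pooled — re-encounter-time categories merged first,
then rows — and tables that cannot be pooled into shape are dropped
with zero degrees of freedom; exact reproduction of another program's
pooling (and hence its χ² to the second decimal) is not claimed.
Signed z statistics report the direction of TEST3.SR and TEST2.CT
effects. The global statistic is the sum over components;
`ĉ = χ²/df` is clamped at 1 for QAICc use (no variance deflation).
Under a null CJS simulation (150 animals, 6 occasions, φ = 0.85,
p = 0.4, 500 replicates) the global test rejects at 4–5% at nominal
α = 0.05.

## Scaling to total abundance

Only well-marked animals enter capture histories, so `Ntot = Nm/θ`
with θ the mark ratio estimated from `n` classified animals, and

    Var(Ntot) = Ntot² ( Var(Nm)/Nm² + (1 − θ)/(n θ) ).

θ is taken per primary occasion (a pooled-θ workflow is possible by
passing the same value for every year). Confidence intervals are
log-normal: `(Ntot/C, Ntot·C)`, `C = exp(1.96 √ln(1 + CV²))`.

For mixed-species groups the pooled estimate is partitioned by species
proportions. The combined CV is the root sum of squares
`√(CV_species² + CV_distinctiveness² + CV_N²)` — the standard
combination of independent relative errors; sources that typeset this
formula sometimes lose the radical, and the root-sum-of-squares
reading is the only one under which the combined CV dominates each
component. Species proportions and their CVs are inputs (estimated
upstream from classified photos); how their intervals are obtained is
left to the caller.

## Trend-detection power

The power analysis asks whether a linear regression of yearly
abundance estimates on time would detect a trend. Following
Gerrodette's approach with the small-sample refinements that followed
it, abundance follows a linear (default) or exponential trajectory
parameterized by the overall fractional change R across the series;
estimate errors have `sd_i = CV_i · A_i`; the error variance is pooled
along the trajectory (`σ² = mean(sd_i²)`); and the one-tailed slope
test's power is the upper tail of a noncentral t with `n − 2` degrees
of freedom and noncentrality `|slope| / √(σ²/S_tt)`. Power at R = 0
equals α exactly. A 10,000-replicate Monte-Carlo simulation of the
slope t-test reproduces the analytic power within ±0.03 at the design
points used in the acceptance checks.

For capture-recapture estimates the CV is expected to scale with the
square root of abundance, so `proportional_to_sqrt_abundance`
(anchored at the first estimate) is the default; `constant` and
`inverse_sqrt_abundance` are provided because the choice moves the
thresholds by a few percentage points.

Two inversions are exposed. `min_detectable_change` bisects the
continuous power curve to 1e-4 (round-trip consistent with
`trend_power`). `min_detectable_decline_percent` reports on the scale
used in practice: it walks the integer-percent grid and compares power
with the target at the two-decimal precision at which power tables are
printed (a power of 0.7989 reads as 0.80). The continuous and grid
answers never differ by more than one percentage point.
`samples_required` returns the smallest series length (≥ 3) whose
power reaches the target.

## The synthetic-data generator

The simulator draws exactly the generative process the estimator
assumes: per-animal three-state trajectories, Bernoulli secondary
detections while inside, one latent mixture class per animal, binomial
marked-photo counts and multinomial species labels. Defaults mirror
the study regime (400 marked animals, five primaries with 3–4
secondaries, S = 0.94, p ≈ 0.1–0.4, θ ≈ 0.25). All animals start
inside by default (populations defined by use of the study area;
configurable), and there is no recruitment unless requested — a
recruitment option exists to give discovery curves a realistic shape.

What it does not emulate: misidentification, mark change, photo
quality variation (θ enters only as a proportion), behavioral
responses to capture, social/spatial structure, or within-primary
mortality. Passing the recovery tests therefore shows the estimator is
correct under the model's own assumptions, not that field data satisfy
them — that is what the goodness-of-fit battery is for.

## Problem sizes in the test suite

The suite exercises: exhaustive likelihood-vs-enumeration equivalence
on all ≈3,900 micro-matrices (≤4 animals, ≤2 primaries, ≤2 secondaries
each, tolerance 1e-10); a dense grid-search oracle for the closed Mt
fit; 50-replicate parameter recovery at the study scale; 500-replicate
GOF null calibration; and a 10,000-replicate Monte-Carlo check of the
power formula. These sizes keep the full suite under a minute while
leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The composite likelihood's information matrix slightly overstates
  precision for detection parameters (they appear in both factors);
  simulation shows the effect is negligible for S, γ and Nm at the
  study's sample sizes.
- f0 is continuous (expected-value parameterization); reported Nm is
  rounded only for display.
- No behavioral-response (trap-happy/shy) models, individual
  covariates, or multi-state extensions beyond inside/outside/dead.
- Identifiability at the series ends (last S, confounded terminal
  parameters) is handled by boundary flagging, not by formal rank
  diagnostics.
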