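# Methods

This note documents the statistical models, the numerical choices
behind them, and what the synthetic-data generator does and does not
emulate. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute at run time.

## Dose–response model and benchmark concentration

Morphology endpoints are binary per embryo; per treatment group they
are binomial counts. The dose–response model is the three-parameter
log-logistic for dichotomous data,

    p(d) = g + (1 − g) · F(a + b·ln d),      F = logistic CDF,

with background rate `g ∈ [0, 1]`, intercept `a`, and slope `b > 0`.
The dose-effect term is *defined* to be zero at d = 0, so p(0) = g
exactly and no log(0) is ever evaluated. "Unrestricted" means the slope
has no lower bound of 1 (the restricted variant's constraint); it is
kept positive because these endpoints worsen with dose. On the
extra-risk scale ER(d) = (p(d) − g)/(1 − g) = F(a + b·ln d), the
benchmark concentration for benchmark response BMR solves ER = BMR in
closed form:

    BMC = exp((logit(BMR) − a)/b),   BMC₅₀ = exp(−a/b).

BMC₅₀ is therefore independent of `g` — a property the tests verify
numerically.

**Estimation.** The binomial log-likelihood is maximized by L-BFGS-B on
the unconstrained scale (logit g, a, ln b) from ten starts: a
moment-style start (g = smoothed control rate; a, b from a logit-linear
regression of group extra risks on ln dose) plus a 3×3 grid of slope ×
half-effect-dose combinations. Probabilities are clipped at 1e-12
inside the likelihood. A flat observed response (all group rates equal)
is not identifiable; it is returned as a boundary solution flagged
`identifiable=False` and reported downstream as "no response" rather
than as a number.

**Profile-likelihood bounds.** With the BMC as a free parameter
(a = logit(BMR) − b·ln BMC), the profile log-likelihood maximizes over
(g, b) by Nelder-Mead from two starts. Each confidence bound is the BMC
where the profile drops `1.3528 = χ²₁(0.90)/2` below the maximum —
one-sided 95% per bound, so the two-sided interval covers ≈ 90%. The
cutoff is a configurable argument; 0.90 is the conventional choice for
benchmark-dose software when each bound is read as a one-sided 95%
limit. Bounds are located by expanding steps on the log-dose scale
followed by Brent root-finding (xtol 1e-10); a profile that never
crosses the cutoff within [max dose × 10⁻³, max dose × 10³] yields a
NaN bound and an invalid verdict.

**Reporting filters.** A BMC is `valid` iff it lies within the tested
positive dose range, both bounds are estimable, and BMCu/BMCl < 40;
the failing filter is named in `reason`. Embryos are pooled to group
counts before fitting — the binomial likelihood is identical either
way, and the vial-effect diagnostic (below) decides whether pooling
across vials is defensible.

## Vial-effect GLMM

Vials are the exposure unit, so outcomes within a vial may be
correlated. Per chemical we fit

    logit P(y_ij = 1 | u_j) = β₀ + β₁·ln(dose_ij + 1) + u_j,
    u_j ~ N(0, σ²_vial),

by marginal maximum likelihood. Each vial's likelihood integral is
computed by *adaptive* Gauss–Hermite quadrature: the integrand is
re-centred at its mode (found by Newton iteration) and scaled by the
Laplace curvature, then evaluated at 25 nodes by default. One node
reproduces the Laplace approximation; at the screen's 8-embryo vials
the Laplace error is O(1/n) per vial, which is why adaptive quadrature
with ≥ 7 nodes is the default path (15- vs 61-node agreement is below
1e-6 on the test fixtures). σ is optimized on its natural scale with a
zero lower bound so variance-free data can reach the σ² = 0 boundary
exactly. The log-plus-one dose scaling uses the natural log; the
decision ratios below are invariant to linear rescalings of the
predictor, so the base is inconsequential.

**Variance partition.** On the latent logit scale, with
σ²_f = var(β₁·x) across observations:

    R²_fixed  = σ²_f / (σ²_f + σ²_vial + π²/3)
    R²_random = σ²_vial / (σ²_f + σ²_vial + π²/3)
    remaining = 1 − R²_fixed − R²_random  (the logistic residual share)

This is the latent-scale mixed-model R² decomposition with the standard
logistic residual variance π²/3; the three shares are nonnegative and
sum to one by construction.

**Decision rule.** Embryos are treated as individual observations when
R²_fixed : R²_random > 1, or, failing that, when
R²_random : remaining < 1; otherwise the vial effect is flagged
non-negligible. R²_random = 0 makes the first ratio +∞ and the decision
treat-individually.

Small-sample behaviour: at 24 vials of 8 embryos the ML variance
component is noisy and its median is biased downward (boundary
estimates at zero are common). Our estimates agree with
`lme4::glmer(nAGQ=25)` to ~1e-6 in log-likelihood on test fixtures, so
this is a property of maximum likelihood at that design, not of the
implementation; the recovery tests hold the slope to 20% but give σ a
wider band.

## Photomotor LEL

Movement is recorded per well in 6-s bins over minutes 6–24. The
tracking protocol's epoch layout is configurable; the default tiles the
window with alternating 3-minute light and dark epochs, and the first
light+dark pair (minutes 6–12) is the assay cycle, treating the
preceding span as calibration. Per period the statistic is the
rectangular AUC of ln(movement + 1) over the cycle's 30 bins (natural
log and +1 offset are configurable; the t-tests are invariant to the
constant bin-width factor, so no Δt multiplication is applied).

Wells flagged dead/malformed are excluded; a treatment with > 30% of
wells excluded is removed entirely. Each retained concentration is
compared to the same-table control by a pooled two-sided t-test; Holm
correction is applied across concentrations *within one (chemical,
period)* — light and dark are separate families, matching per-period
reporting. The LEL is the lowest concentration with adjusted p ≤ 0.05
whose next-highest tested concentration is also significant in the same
direction; the highest concentration qualifies without a successor.
Because of the confirmation rule the realized family-wise false-call
rate under a null generator sits below the nominal 5% (measured by the
acceptance script).

## Body burden and uptake

Measured ng/mL extract concentrations convert as
total nmol = ng/mL × 0.5 mL ÷ MW (g/mol), body burden =
total nmol / (32 fish × body weight), with body weights 0.31 mg (24
hpf) and 0.26 mg (48 hpf). The uptake ratio is
(nmol/embryo)/(nominal nmol); the standard exposure of 20 μM in 2 mL
makes the denominator 40 nmol. Molecular weights come from a built-in
table keyed by chemical name, computed from molecular formulas with
standard atomic weights; an explicit `mw=` argument overrides the
table for chemicals not on it. Timepoint comparisons use the
pooled-variance t-test on replicate body burdens (pooled samples are
destroyed at collection, so no pairing exists), with percent reduction
100·(1 − mean₄₈/mean₂₄); note the reduction is computed on the
burden (per-mg) scale, so it also reflects the lighter 48-hpf body
weight. Between-chemical comparisons at 24 hpf use one-way ANOVA
followed by Dunn's rank-based pairwise test with a compact letter
display (Kruskal–Wallis is available as the global test for users who
prefer the rank-consistent pairing with Dunn).

## Shared statistics

* **Student's t** is the pooled-variance test by default (`pooled=False`
  gives Welch for sensitivity analysis). Two identical zero-variance
  samples return t = 0, p = 1 by convention.
* **Holm** is the standard step-down adjustment with monotonicity
  enforcement and capping at 1. (It is *not* idempotent in general —
  re-adjusting an adjusted vector re-multiplies the smallest entry — so
  the tests validate it against an independent step-down computation
  instead.)
* **Spearman** uses average ranks. For tie-free samples with n ≤ 10 the
  two-sided p-value is exact: the full n! permutation distribution of ρ
  is enumerated in vectorised blocks and the tail |ρ| ≥ |ρ_obs| counted
  with a 1e-12 comparison tolerance. Ties or n > 10 fall back to the
  t-distribution approximation, flagged via `exact=False`.
* **Dunn's test** ranks all observations jointly with tie correction
  Σ(t³−t)/(12(N−1)); pairwise z = (R̄_i − R̄_j)/SE with
  SE² = (N(N+1)/12 − tie term)(1/n_i + 1/n_j), stored antisymmetrically.
  In the two-group tie-free case |z| equals the Wilcoxon rank-sum normal
  approximation, which the tests verify. The compact letter display uses
  insert-and-absorb over the nonsignificance graph with deterministic
  ordering by smallest group index.
* **IQR outliers** use type-7 (linear interpolation) quartiles and the
  1.5·IQR fences.

## logK_ow potency model

Ordinary least squares of BMC₅₀ (raw μM scale) on predicted logK_ow,
restricted to chemicals with an estimable BMC; chemicals without one
are carried alongside unmodeled (their qualitative "high logK_ow, no
effect" pattern is itself evidence against narcosis). Outlier screening
applies the IQR rule to the *predictor only*; fitting with and without
flagged predictors corresponds to the screening workflow's model A /
model B pair. The average relative error is mean(|obs − pred|/obs)·100
on the raw BMC scale, as the defining formula implies.

## Transcriptomic summaries

Upper-quartile normalization scales each sample so that the 75th
percentile of its nonzero counts equals the geometric mean of all
samples' 75th percentiles (factors therefore have geometric mean 1).
Differential expression itself is consumed as an input table (gene,
chemical, log₂FC, adjusted p); the DE flag is adjusted p ≤ 0.05 and
|log₂FC| ≥ 1. The frequent-DEG tally keeps genes DE in at least
⌈0.25 × n_chemicals⌉ of the chemicals present in the table and returns
the top five by count (ties at the cut retained; deterministic ordering
by count then name). Potency correlation is per-gene Spearman of log₂FC
against BMC₅₀ with 50 μM imputed for chemicals lacking a BMC — the
imputation creates ties, hence the t-approximation path — Holm-adjusted
across the gene family; significance requires adjusted p ≤ 0.05 and
|ρ| ≥ 0.5 (magnitude, because BMC is inverse potency and either sign of
the printed ρ may be meaningful).

## Docking ranks

Per (chemical, protein) the minimum energy across pockets and
prediction methods is kept; per chemical the proteins are ranked
ascending with competition (minimum) ranking for ties — docking scores
rarely tie exactly, but the rule is fixed for reproducibility. Ranks
rather than raw energies are compared across chemicals because the
per-chemical mean energy varies; the rank matrix is invariant to
per-chemical energy offsets, which the tests check. Top-k membership
(default k = 10) lists proteins ranked ≤ k for at least one chemical.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the screen's
study conditions.

* **Morphology**: six concentrations (0, 3.125, 6.25, 12.5, 25, 50 μM),
  4 vials × 8 embryos. Each vial draws an intercept u ~ N(0, σ_vial) that
  is added on the *logit of the full conditional probability*
  (matching the diagnostic GLMM's scale, not the extra-risk scale);
  outcomes are Bernoulli. With g = 0 a control responds with
  probability 0 regardless of u. Default truth: g = 0.05, BMC₅₀ = 20 μM,
  b = 4. The screen does not report vial-variance magnitudes, so
  σ_vial defaults to 0 and is raised in tests purely for coverage of
  the decision rules.
* **Movement traces**: per-well log-normal 6-s bins with
  period-specific log-means (light 1.0, dark 2.5, SD 0.6 — chosen to
  emulate the dark-phase hyperactivity of control larvae at realistic
  dispersion); treatments at or above a threshold concentration
  (default 25 μM) have their dark log-mean shifted by `lpr_effect`.
* **Body burden**: the true pooled-sample content is
  uptake_true × 40 nmol × 32 fish, reduced by a settable fraction at
  48 hpf, with multiplicative LogNormal(0, cv) measurement noise
  (cv = 0.1 default, in line with replicate-level analytical
  variability); cv = 0 makes the burden equations exact inverses of the
  generator.
* **Docking**: energies N(μ_chem, σ = 0.8) with μ_chem drawn uniformly
  from (−7.5, −5.5) kcal/mol per chemical (emulating between-chemical
  mean-energy variability), planted high-affinity proteins shifted by
  −4 kcal/mol.

Every generator takes an explicit seed and owns its own numpy
`default_rng` stream; a fixed seed reproduces byte-identical CSVs. What
the generator does *not* emulate: toxicokinetics and chemical fate
(volatilization, degradation), plate/day batch structure, mortality-
driven missingness correlated with dose (exclusions are independent
Bernoulli), inter-endpoint correlation (all endpoints share one curve),
and count-level transcriptomic noise for the DE table (DE results are
consumed, not generated). Passing tests therefore demonstrate
correctness of the statistical machinery under its stated assumptions,
not robustness to those unmodeled features of real screens.

## Problem sizes in tests and the acceptance script

The simulation studies are sized to be decisive yet quick: profile
interval coverage uses 500 replicates at n = 2000/group in the
acceptance script (120 in the test suite); BMC₅₀ recovery uses 200
simulated chemicals at the screen's 32-embryo design with true BMC₅₀
cycling through {14, 20, 30, 47} μM; the LEL null study uses 200
simulated chemicals; the vial-decision check 25 screens. Calibration
assertions use bands of ± ~2.6 binomial standard errors around the
nominal rate.

## Known limitations

* The profile bound search assumes a unimodal profile; pathological
  multimodal profiles (conceivable with near-flat responses) would be
  caught only by the validity filters.
* The exact Spearman path is capped at n = 10 (10! ≈ 3.6M permutations);
  beyond that the t-approximation is used even without ties.
* The GLMM fits a single fixed effect and a single random intercept —
  no random slopes or crossed effects — because the decision rule is
  defined on exactly that decomposition.
* Compact letter displays are not unique in general; the
  insert-and-absorb construction with deterministic ordering makes this
  implementation reproducible, but other valid letterings exist.
* Molecular weights are tabulated for naphthalene and the alkyl
  naphthalenes only; other chemicals need `mw=` supplied.
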