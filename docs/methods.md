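# Methods

`metacurve` synthesizes study-level Pearson correlations between whole-brain
volume and IQ scores, and quantifies how much the summary depends on which
studies are included and how they are analyzed.  This note documents the
statistical models, the defaults and their rationale, the numerical choices,
and the known limitations — in particular what can and cannot be
reconstructed from the packaged study table.

## Data model and independence resolution

One record is one coded correlation: study label, publication year, sample
type (healthy/patient), mean age, male ratio, reporting status
(journal-reported / grey literature / personal communication), raw IQ-domain
label, test description, optional g-ness rating and volume type, n, and r.
Records with `r == 0` exactly are flagged `zero_imputed`: they stand for
published results reported only as "not significant", set to zero by the
standard conservative convention.  `n >= 4` is enforced throughout because
the Fisher-z sampling variance is `1/(n-3)`.

Raw domain labels map onto three analysis domains: FSIQ and fluid-reasoning
tests to full-scale, spatial tests to performance, verbal and performance
unchanged.  The mapping is an argument, not a constant, so the sensitivity
of any result to it is one call away.

Many studies contribute several correlations per sample (subtests, sex
subsamples).  Two rows are treated as the same independent sample when they
agree on (study label, mean age, male ratio, sample type), unless an
explicit `sample_id` column overrides the key.  Within a sample and domain,
one effect is selected by (1) ordered preference patterns — the domain's own
scale score first, then conceptually closer subtests (verbal comprehension
and vocabulary over working-memory spans; performance scales and perceptual
indices over processing-speed subtests) — then (2) larger n, then (3) file
order.  The resolution is deterministic, idempotent, order-invariant, and
logged decision by decision.

**Limitation (important).**  The packaged 454-row table supports this key
only approximately: it yields 198/122/93 independent samples for
full-scale/verbal/performance, whereas the source publication's bookkeeping
reports 194/115/82.  We verified by exhaustive search over within-study
merges that no assignment of rows to samples reproduces all of the
publication's printed cell counts simultaneously — its own subtotals
disagree with each other (the healthy full-scale N, the publication-status
breakdown, and the overall N cannot all be satisfied by any partition of the
table's rows).  The exact clustering exists only in the authors' deposited
files.  Consequently the headline pooled correlations reproduce to 2 dp for
full-scale and verbal IQ, while quantities sensitive to exactly which rows
count as one sample (the performance-domain summary, the median study power
of the published subset, quartiles of the combinatorial distribution) are
reproduced to within roughly 0.01–0.02 in r or a few percentage points, not
to printed precision.  The acceptance suite asserts the tighter tolerances
anyway and lets those checks fail visibly rather than widening bands.

## Effect scales and artifact corrections

Four pooling scales are supported: raw r (large-sample variance
`(1-r^2)^2/(n-1)`), Fisher z (variance `1/(n-3)`), small-sample
bias-corrected r using the first-order Olkin–Pratt expansion
`r (1 + (1-r^2)/(2(n-3)))`, and r corrected for direct range restriction by
the Thorndike Case II formula `r u / sqrt(1 + r^2 (u^2 - 1))` with
`u = reference SD / observed SD` (reference IQ SD 15).  The corrected
standard error uses the delta method, `|d case2/dr| * se(r)`; it agrees
with central-difference numerical differentiation to 1e-6 over
r ∈ [-0.9, 0.9], u ∈ [0.5, 3].  Because the table prints no per-study IQ
SDs, range-corrected analyses require user-supplied u ratios; without them
those specifications are dropped with an explicit reason code, which mirrors
the reduced k of corrected analyses in practice.

## Pooling

*Hedges–Olkin random effects.*  Inverse-variance weights `1/(v_i + tau^2)`;
tau^2 by REML (Fisher scoring to 1e-8, with a bounded direct search of the
restricted likelihood as a safeguard against oscillation near flat optima)
or by the DerSimonian–Laird moment estimator.  Confidence intervals use the
Knapp–Hartung adjustment by default: `se^2 = sum w (y - mu)^2 / ((k-1) sum w)`
with t(k-1) quantiles.  Estimates and CIs computed on the Fisher scale are
back-transformed for reporting.  I^2 is reported from Cochran's Q as
`max(0, (Q - df)/Q) * 100`.  REML is the primary estimator (the reference
toolchain's default); DL is used inside the combinatorial sampler and the
specification curve for throughput — on the packaged table the difference
in pooled r is below 0.005.

*Hunter–Schmidt.*  `rbar = sum(n r)/sum(n)`; observed variance
`sum n (r - rbar)^2 / sum n`; sampling-error variance `k (1-rbar^2)^2 /
sum n`; residual (true) variance is their truncated difference;
`se(rbar) = sqrt(var_obs / k)` with normal quantiles (the source is silent
on HS intervals; this is documented and swappable).  Corrected mode applies
the Case II correction per record before pooling.

*Unweighted.*  Arithmetic mean with `sd/sqrt(k)` and t(k-1) intervals;
degenerate constant sets collapse to point intervals rather than erroring
(the combinatorial sampler needs that).

*Diagnostics.*  Leave-one-out refits, and case-deletion influence measures
(studentized deleted residual, Cook's distance, hat value, DFFITS,
covariance ratio).  A study is flagged when |t| > 1.96 and a leverage
criterion exceeds its conventional cutoff (hat > 2/k, |DFFITS| >
3 sqrt(1/(k-1)), or Cook's D > 0.45).

## Robust variance estimation

The correlated-effects working model keeps every coded effect: effects from
the same sample are assumed equicorrelated with working correlation rho
(default 0.8, the conventional choice; results on the packaged table move
by < 0.005 in r as rho sweeps 0.4–1.0).  Working weights are
`1/(k_j (vbar_j + tau^2 + omega^2))`.  The default tau^2 is the
correlated-effects method-of-moments estimator with the exact trace
correction (`tau^2 = (Q_E - tr(P V_rho)) / tr(P B)`), under which
omega^2 = 0; an alternative estimates tau^2 by REML on cluster means and
omega^2 from within-cluster dispersion (`tau2_method="cluster_reml"`).  The
default was chosen because on real tables a few clusters mix genuinely
different subsamples, which the within-cluster moment estimator absorbs
into an implausibly large omega^2.  Inference is cluster-robust: a CR2-type
small-sample adjustment (symmetric `(I - H_jj)^(-1/2)` residual inflation)
and Satterthwaite-style per-coefficient degrees of freedom from the
cluster-wise variance contributions; coefficients with df < 4 are flagged
unreliable.  With singleton clusters the fit reduces exactly to
heteroskedasticity-robust precision-weighted least squares.

## Moderator analyses

Subgroup analyses fit a separate random-effects model per level (own
tau^2), and compare levels with the Wald-type statistic
`Q_between = sum w_l (mu_l - mubar)^2`, `w_l = 1/se(mu_l)^2`, against
chi-square(levels-1).  Meta-regressions are precision-weighted
mixed-effects fits on the Fisher scale: residual tau^2 by REML given the
design, Knapp–Hartung-type scaling of the coefficient covariance, t-tests
on k - p df.  R^2 is the proportional reduction in tau^2 against the
intercept-only model (capped at [0, 100]); VIFs come from the unweighted
moderator matrix.  Hierarchical block models share complete-case rows
across blocks and are compared with likelihood-ratio tests on ML (not REML)
refits; when a block does not improve fit at .05 the next block is compared
against the last block that did.

## Dissemination-bias battery

Run by convention on reported (journal-published), healthy, independent
effects; zero-imputed records are excluded from p-value-based methods (their
p-values would be fabrications) and retained elsewhere.

- **Power / TES / R-index.**  Two-tailed power of the Fisher-z test at the
  subset's own random-effects summary; sunset thresholds root-solve for the
  true r giving a target median power.  TES compares observed and
  power-expected significant counts by chi-square (binomial variant
  reported).  R-index = median power − (success rate − median power).
  Calibration caveat: with power evaluated at the *estimated* summary the
  TES is conservative (the expectation tracks the observed count); evaluated
  at a known true effect in simulation it is nominally calibrated.
- **Egger–Sterne.**  OLS of z/SE on 1/SE; intercept t-test, p < .10 flags
  asymmetry.  Exactly nominal at tau = 0 in simulation; inflates under
  heterogeneity, as documented for this test generally.
- **Trim-and-fill.**  Duval–Tweedie on the Fisher scale, L0 estimator by
  default (R0 available), left-side imputation for positive summaries,
  random-effects refit on the augmented set.  Verified run-for-run against
  the reference R implementation on truncated-funnel datasets.
- **p-curve.**  Full- and half-curve Stouffer right-skew tests on pp-values,
  binomial variant, 33%-power flatness test, and effect estimation by
  minimizing the KS distance between implied pp-values (noncentral-t) and
  uniformity, grid search plus local refinement.
- **p-uniform / p-uniform*.**  Method P (Irwin–Hall: sum of conditional
  exceedance probabilities equals k/2) with profile CI and a
  publication-bias test against the fixed-effect estimate; the LNP variant
  is available.  p-uniform* maximizes the conditional likelihood over all
  effects (significant and not) jointly in (mu, tau^2).  Both inherit the
  methods' homogeneity assumptions; the bias test is conservative and
  shifts under tau > 0.
- **A-priori selection models.**  Weighted ML of (mu, tau^2) under the four
  conventional step weight functions on one-tailed p (moderate/severe ×
  one-/two-tailed presets over the standard 14 cutpoints); with unit
  weights the estimate reduces to the ML random-effects fit (verified to
  1e-4).
- **Henmi–Copas.**  Fixed-effect weights with DL heterogeneity in the
  variance, normal quantiles (documented fallback for the exact adjusted
  quantile), reported next to the conventional DL interval.
- **Cumulative meta-analysis.**  By publication year ascending and by
  sample size descending; each prefix is an independent refit.

## Combinatorial and specification-curve analysis

GOSH sampling includes each study independently with probability 1/2,
rejects subsets with k < 2, and fits DL random-effects per subset, fully
vectorized (100 000 subsets of ~120 studies run in seconds).  Quartiles are
stable to < 0.005 in r across seeds at that size.  At k = 4 the sampled
distribution matches exhaustive enumeration of the 11 valid subsets.

The specification grid crosses *which* factors — sample age (adults vs
children/adolescents at mean age 18, vs either), sample type (healthy vs
patient vs either), and for full-scale IQ only g-ness (fair/good vs
excellent vs either) — with *how* factors: effect scale (raw r, Fisher z,
bias-corrected r, range-corrected r) and approach (Hedges–Olkin RE,
Hunter–Schmidt, unweighted, RVE).  That is 3×3×3×4×4 = 432 specifications
for full-scale and 144 for verbal/performance.  Specifications with fewer
than two effects, or needing unavailable inputs (range correction without
SDs, g-ness cells without ratings), are dropped with reason codes.  The RVE
approach pools all coded effects of the filtered samples, clustered; the
other approaches use the resolved independent set.

## Synthetic data

The generator emulates the coded-table schema with the structure the
analyses assume: per study a uniform publication year, a log-normal sample
size (defaults log-mean 4.0, log-sd 0.8, floor 10 — median n ≈ 55, long
right tail, matching the shape of real n distributions in this literature),
a true Fisher-z effect `atanh(rho) + slope (year - midyear) + N(0, tau^2)`,
and an observed z with variance `1/(n-3)`.  Default conditions are
rho = 0.25, tau = 0.1 — the magnitudes the analyses themselves estimate on
the real table — with no decline and no selection unless configured.
Selective reporting is a step function on the study's one-tailed p
(moderate and severe presets); a configurable fraction of censored
non-significant effects re-enters as published zero-imputed rows.  The
generator reproduces two qualitative signatures of the real data: published
subsets overestimate the all-effects summary under selection, and year
trends are recovered by the meta-regression.  It does not attempt the real
table's marginal distributions (study sizes, domain mix per study,
correlated subtest structure within samples), so passing recovery tests
demonstrates correctness of the estimators under the assumed model, not
robustness to every feature of real data.

## Numerical choices

- REML: Fisher scoring, tolerance 1e-8, max 100 iterations, bounded direct
  search fallback; tau^2 compared against the zero boundary.
- ML fits for LRTs and selection models: Nelder–Mead on (mu, log tau^2)
  with multi-start for the selection likelihoods; log-space conditional
  probabilities throughout p-uniform to avoid 0/0 at extreme trial values.
- Degenerate inputs: constant effect sets return point intervals; subgroup
  levels with k < 2 are dropped with a warning; empty filter results raise.
- Ties in independence resolution break by larger n then file order —
  deterministic and logged.
- All randomness flows through explicit `numpy.random.default_rng` seeds.

## Reported-value provenance

Every number the package reports (tests, the acceptance script, the
reproduce-paper runner) is computed at run time from the packaged table or
from seeded simulations.  During development the pooling, meta-regression,
Egger and trim-and-fill paths were additionally cross-checked against the
independent R reference implementation on identical inputs and agree to
four decimals; the test suite carries self-contained brute-force oracles
instead.
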