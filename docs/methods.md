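# Methods

## Model

All observations are measured log-concentrations. For analyte k, biological
sample i and technical replicate j,

    y_ij^(k) = μ + a^(k) + b_i^(k) + e_ij^(k)

with independent zero-mean Gaussian components:

| term | variance | meaning |
|---|---|---|
| a^(k) | v_d | dynamic range: spread of true mean concentration across analytes |
| b_i^(k) | v_b^(k) | biological signal: spread across individuals at analyte k |
| e_ij^(k) | v_e^(k) | experimental noise per observation |

Gaussianity is an explicit modelling assumption; it is what the parametric
bootstrap simulates from, and heavier-tailed noise is out of scope.

## Estimation

Per analyte we fit the classical unbalanced one-way random-effects ANOVA
by method of moments (closed form; no iterative REML/ML, which keeps a
full-pipeline bootstrap cheap). With I samples carrying n_i replicates,
N = Σ n_i:

    v̂_e = MSW = Σ_ij (y_ij − ȳ_i·)² / (N − I)
    v̂_b = (MSB − MSW) / n0′,   MSB = Σ_i n_i (ȳ_i· − ȳ··)² / (I − 1),
                               n0′ = (N − Σ n_i²/N) / (I − 1)

Negative v̂_b (possible whenever MSB < MSW) is truncated to zero: upward
bias, smaller mean-squared error. v̂_e = MSW is non-negative by
construction and is not truncated. Repeatability is R̂ = v̂_b/(v̂_b + v̂_e),
defined as 0 in the degenerate case v̂_b = v̂_e = 0 (an analyte with no
information is treated as never powered — the conservative choice for
design). Analytes whose own data cannot support the fit (fewer than two
samples observed, or no replicated sample) are excluded with a logged
reason rather than imputed; estimation fails only if every analyte fails.

The dynamic-range variance is estimated as the between-analyte sample
variance (denominator p − 1) of the per-analyte grand means, minus the
average first-order sampling variance of those means under each analyte's
own design, v̂_b Σn_i²/N² + v̂_e/N, truncated at zero. The subtraction
removes the upward bias that within-analyte sampling noise adds to the
spread of the means; it matters little when v_d dominates (the typical
case) but keeps the estimator honest on narrow-range panels.

The Bland–Altman repeatability coefficient 1.96·√(2 v̂_e) is provided as a
complementary, measurement-scale summary (a 95% one-sided bound on the
absolute difference between two replicate readings); unlike R it ignores
v_b and cannot inform design.

## Why inter-replicate r is not a precision measure

For one sample's pair of replicate vectors across p analytes, Pearson's r
converges in probability (p → ∞) to (v_d + v̄_b)/(v_d + v̄_b + v̄_e),
where v̄_b, v̄_e are analyte-averages. Since real multiplex assays have
v_d two to three orders of magnitude above v̄_e, r ≈ 1 is compatible with
noise as large as the biological signal. `replicate_correlation`,
`convergence_curve` and `subset_relative_deviation` exist to demonstrate
this confound and its fast finite-p convergence (r is typically within 1%
of its full-panel value by p ≈ 100), not to recommend r. Where a sample
has more than two replicates, scatter/r diagnostics use the two lowest
replicate indices; the ANOVA uses all replicates.

## Study design

Reference design: balanced two-group comparison, two-sided equal-variance
t-test. Power is computed exactly from the noncentral t distribution
(noncentrality Δ·√(m/2) for m per group, df = 2m − 2). The baseline n0 is
the smallest even total reaching the target power at the stated Δ and α —
at Δ = 1, α = 0.05, power 0.8 this gives n0 = 34 (17 per group).

Measurement error attenuates the standardized effect to Δ√R, equivalently
inflates the relevant variance by the VIF 1/R. The planning rule is:
analyte k is well powered at total size n = SIF·n0 iff SIF > 1/R^(k)
(strict inequality; boundary analytes count as unpowered; R = 0 maps to an
infinite threshold rather than an error so zero-signal analytes flow
through reports). Adjusted sizes are rounded up to the next even integer
to preserve balance. With many analytes tested, α should be tightened,
e.g. Bonferroni α/p; `bonferroni_alpha` implements exactly that and
nothing fancier (no FDR-based power).

The SIF > 1/R bound is sufficient, not tight: n0 itself is rounded up to
an even total (its exact power at Δ = 1 is 0.807, not 0.800) and the
inflated design gains degrees of freedom, so sizes slightly below n0/R can
still exceed the nominal power floor. `monte_carlo_power` (built on
scipy's t-test, independent of the analytic formula) lets users verify
any specific (n, Δ, α, R) combination by simulation.

## Parametric bootstrap

Confidence intervals come from simulating complete pilot datasets at the
fitted parameter values — truncated v̂_b^(k), v̂_e^(k), v̂_d, μ̂ — under
the original per-sample replication pattern n_i, then re-running the whole
pipeline (ANOVA, truncation, R, % powered per SIF) on each draw.
Percentile intervals at the requested level (default 95%) are reported;
BCa is not implemented, a deliberate simplicity trade-off users should
know when comparing to other software. Analyte offsets a^(k) are redrawn
from N(0, v̂_d) in every replicate — analytes are exchangeable under the
model — rather than conditioned on the fitted means; the result's
metadata records this. Where analytes have heterogeneous missingness the
design used is the per-sample maximum replicate count across analytes;
complete designs are reproduced exactly. Defaults: n_boot = 1000 for
variance-component intervals, 200 when the %-powered curve is
re-estimated per draw; both configurable, all draws reproducible from
(inputs, seed, n_boot). Nested-simulation checks in the test suite put
the realized coverage of the 95% interval for v̄_e near nominal
(≈ 94–95% over 200 outer pilots of 200 analytes, 100 samples, 50
duplicated).

## Synthetic data

`simulate_dataset` draws from the model above: a pure function of
(config, seed). Per-analyte variances are constant or log-normal across
analytes (log-normal parametrized by mean and SD on the variance scale),
optionally with a monotone concentration→noise multiplier to emulate the
common difficulty of measuring low-abundance analytes. The default
replication design — duplicates for the first n_replicated samples,
singletons for the rest — matches real pilot layouts. The default
worked-example components (v_d ≈ 3–8, v̄_b ≈ 0.02–0.05, v̄_e ≈ 0.01–0.07
on log2 scales, 69–287 samples with 15–69 duplicated) span the range
observed on published microRNA, mRNA, protein and metabolite panels.

What the generator does not emulate: missingness mechanisms,
limit-of-detection censoring, batch effects, non-Gaussian tails, and
correlation between analytes beyond the shared a^(k) level. Tests passing
on this generator therefore validate the estimators under the model, not
robustness to those violations.

## Numerical and interface choices

- Sums of squares are clamped at zero before division; computational
  cancellation can otherwise produce v̂_e ≈ −1e−16 and R̂ > 1.
- Estimates files print floats at round-trip precision (`%.17g`) and are
  re-read with pandas' round-trip parser, so write-then-read is exact.
- Running quantiles for the repeatability-vs-concentration smoother use a
  Gaussian kernel (default bandwidth = concentration range / 10, exposed
  as an option), weights renormalized per grid point, and a midpoint-rule
  weighted quantile with linear interpolation — monotone across quantile
  levels by construction, so q25 ≤ q50 ≤ q75 everywhere.
- Histograms: 30 fixed bins for R on [0, 1]; Freedman–Diaconis for
  concentration.
- Every figure writes its plotted points/curves as a TSV sidecar so
  graphical claims are testable without image parsing.
- Replicate indices are re-labelled 1..n_i per cell on ingestion;
  replicate identity is exchangeable under the model and carries no
  meaning. Missing cells are simply dropped per (analyte, sample).
- Exit codes: 0 success, 1 user/data error, 2 usage or internal error.

## Problem sizes

The test suite exercises the estimators at the scale of real panels where
that matters scientifically (p = 1624 analytes with 69 duplicated samples
for the convergence study; 100,000-replicate Monte Carlo for power
floors) and at reduced scale elsewhere (e.g. 40–200 bootstrap draws in
unit tests against 1000 in production defaults), sizes chosen so the full
pipeline is still the thing being tested.

## Known limitations

- Balanced two-group designs only: no paired, ANCOVA, unequal-group or
  multi-arm power calculations.
- ANOVA point estimation only: no REML/ML, no shrinkage across analytes.
- The asymptotic r formula assumes the model's independence structure;
  correlated noise across analytes (e.g. plate effects) violates it.
- No raw-assay preprocessing or normalization: inputs are assumed already
  log-scale (an optional log2 ingestion transform is provided) and
  quality-controlled.
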