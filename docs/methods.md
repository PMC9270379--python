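# Methods

This note records the statistical model the package implements, the choices
made where the method leaves room, and what the synthetic-data tests do and
do not establish.

## Trial model and joint ANOVA

The data model is a balanced genotype × environment × replication trial in
long format, one replicate-level yield per row. The joint analysis of
variance treats all factors as fixed:

```
Y_ijk = μ + r/e_k(j) + e_j + g_i + ge_ij + ε_ijk
```

and decomposes the corrected total sum of squares into Environment (e−1),
Repetition (r−1), Genotypes (g−1), replication-within-environment R/E
((r−1)(e−1)), GxE ((g−1)(e−1)) and a pooled residual, every tested row
compared against the residual mean square. Splitting replication into a
main effect plus R/E mirrors the classical presentation for a block design
repeated over environments and yields the df pattern 3/2/42/6/126/336 for a
43 × 4 × 3 trial. No mixed-model (REML) variant is offered: the analysis
pools a single residual after checking homogeneity.

Hartley's Fmax test checks that per-environment residual variances (from
one randomized-complete-block ANOVA per environment) may be pooled. Its
critical values are computed by Monte Carlo — 100,000 draws of k
independent scaled χ² variance estimates, fixed internal seed — rather than
by interpolating printed tables, so arbitrary (k, df) pairs are supported;
the simulated upper-5% point for k=3, df=9 agrees with the classical table
value 5.34 to within Monte Carlo error. Heterogeneity produces a warning,
not an abort: the pipeline reports the verdict and proceeds, since the
downstream regression carries its own per-genotype variance.

Unbalanced tables are rejected for the ANOVA and the index computation; the
data layer flags balance by comparing the observed cell set against the
full g × e × r lattice.

## Environmental index and hinge design

`I_j` is the mean over all genotypes and replications in environment j
minus the grand mean, so Σ I_j = 0 on balanced data. The hinge transform is

```
T(I_j) = 0          if I_j ≤ 0
T(I_j) = I_j − Ī₊   otherwise,  Ī₊ = mean of the positive I_j
```

which makes the hinge column sum to zero over the favorable environments.
Ties at I_j = 0 are grouped with the unfavorable regime. The change in
slope β_i2 is identified only when at least two distinct favorable design
points and at least one unfavorable point exist; otherwise both the OLS and
the Bayesian fit fall back to a single-slope model with β_i2 pinned at 0
and a warning. If no environment index is positive, Ī₊ is undefined and the
index computation raises.

## Bayesian bisegmented regression

Per genotype i, observations are replicate-level yields with mean
β_i0 + β_i1 I_j + β_i2 T(I_j) and variance σ²_ie. Priors are independent:
N(μ, σ²) on each β and Gamma(α, β) on the precision τ_ie = 1/σ²_ie
(mean α/β, variance α/β²). The posterior is conditionally conjugate, so the
sampler is a component-wise Gibbs scheme with exact full conditionals:

* each β_k from a normal whose precision is (prior precision + τ Σ x_k²)
  and whose mean precision-weights the prior mean and the partial-residual
  regression, by completing the square;
* τ from Gamma(α + n/2, β + SSE/2).

Because every genotype shares the same design points in a balanced trial,
the sampler vectorises across genotypes: one chain updates all genotypes'
parameters simultaneously, which keeps even 100,000-iteration protocols
cheap. Chains initialize overdispersed from the priors, truncated to a
numerically safe box (|β| ≤ 1e6, τ ∈ [1e−6, 1e6]) so the vague Gamma(0.001,
0.001) prior cannot start a chain at a denormal precision; the first few
conditional updates immediately move the state into the data-supported
region and burn-in discards the transient.

Defaults follow the study protocol: 4 chains × 100,000 iterations, burn-in
10,000, thinning 4. Tests and the acceptance script use shorter protocols
(typically 2–4 chains of a few thousand iterations) — at those lengths the
batch-means MCSEs are already far smaller than the posterior sds for these
small conjugate posteriors, which is the criterion that matters for the
checks performed.

Two priors ship ready-made:

* **vague** — N(0, 100000) on every β, Gamma(0.001, 0.001) on τ (prior mean
  precision 1);
* **elicited** — centered on earlier frequentist bisegmented estimates with
  prior variances = (standard error)² × an inflation factor (default 10),
  and τ moment-matched so its prior mean is 1/(earlier residual MS) with
  shape 1/inflation. The literature the method descends from gives no
  explicit mapping from past estimates to hyperparameters; this
  inflation-factor scheme is this package's explicit, configurable rule.
  Inflation 10 weakly centers on past data without letting it dominate a
  new trial's likelihood.

Posterior summaries are means, sds, equal-tailed 95% credibility intervals
(HPD available behind a flag — the method's literature says "95%
credibility interval" without specifying a construction), and batch-means
MCSEs with batch size ⌊√n⌋. Each genotype is fit independently with its own
variance; no hierarchical pooling across genotypes.

Stability draws are obtained by applying σ²_di = σ²_ie − MSR/r to every
kept σ²_ie draw, so the reported σ²_di posterior is exact given the chains.
Negative summaries are legitimate (sampling noise around a small deviation
variance), are flagged, and are treated as maximally stable by the
classifier — the raw value enters the z-score. R² is 1 − SSE/SST evaluated
at the posterior-mean coefficients, reported raw (clipping to [0, 1] is a
display concern).

The frequentist companion fit is ordinary least squares on the same hinge
design (via statsmodels), with t-intervals on n−3 df; it supplies prior
elicitation and the frequentist-vs-Bayesian interval-width comparison.

## Diagnostics and model selection

**Geweke.** z = (mean of first 10% − mean of last 50%) / √(se² + se²), with
each window's squared standard error S(0)/n estimated by a Bartlett-tapered
lag-window autocovariance estimator of the spectral density at zero, window
length 4·(n/100)^(1/3). This follows the standard diagnostic's structure;
the lag-window estimator (rather than an AR-fit spectral estimate) is this
package's choice, made for reproducibility without model-selection inside
the diagnostic. |z| < 1.96 passes. Constant chains raise; a pinned β_2 in a
degraded single-slope fit is reported as trivially passed in the panel
table.

**DIC.** Deviance D(θ) = −2 log L; D̄ averages over kept draws; D(θ̂) plugs
in posterior means of (β_0, β_1, β_2, σ²); p_D = D̄ − D(θ̂); DIC = D(θ̂) +
2 p_D = D̄ + p_D. Genotype-level DICs sum to a panel DIC since likelihoods
are independent. Priors are compared by lowest DIC with an equivalence band
|Δ| < 2 — differences inside the band are read as "no informative
increment" and the vaguer prior (listed first by the caller) is kept.

**Cross-validation.** Replicate-level observations are partitioned into 10
folds, stratified by genotype: each genotype's observations are shuffled
and dealt round-robin from a random starting fold, so per-genotype fold
sizes differ by at most one and every genotype appears in every training
set. Per fold, each genotype is refit on its training observations and its
held-out yields predicted from posterior-mean coefficients; the per-fold
Pearson correlation between predictions and observations is averaged. The
partition unit (observation, stratified by genotype) is this package's
choice; the method description it follows does not state one.

## Classification

Z-scores across the genotype panel use the population sd. A genotype is
*productive* when its posterior-intercept z-score is positive ("top tier"
above 1 — more than one sd above the panel mean), *stable* when its σ²_di
z-score is negative (no numeric stability cutoff exists in the method's
lineage; below-panel-average is the operationalization here), and
*responsive* when the posterior mean of β_1 + β_2 exceeds 1, the classical
responsiveness criterion; the threshold is configurable and unit-dependent
(slopes are yield units per index unit). Both the posterior intercept and
the raw harvest mean are emitted per genotype; classification uses the
posterior intercept.

## Synthetic data

Two generators produce balanced trials. The additive generator draws one
effect per factor level from centered normals (GxE double-centered,
replication effects centered within environment) plus iid residuals; the
sum-to-zero constraints make the simulated environmental index equal the
environment effect up to residual noise, so index-recovery tests are exact
in expectation. The hinge generator takes per-genotype true (β_0, β_1,
β_2), an index vector, and per-genotype residual sds, and returns replicate
yields around the exact bisegmented means. Both split a single integer
seed into fixed named substreams (one per factor), so silencing or adding a
factor leaves the other factors' draws untouched.

Default scales emulate a coffee-yield panel: grand mean 100 bags/ha,
environment sd 15, genotype sd 12, GxE sd 6, block sd 3, residual sd 8, and
for the hinge generator intercepts ~N(100, 15²), unfavorable slopes
~N(1, 0.4²), slope changes ~N(0, 0.6²), residual sd 5 — genotypes then span
non-responsive to strongly responsive, as in real germplasm. What the
generators deliberately omit: unbalance and missing plots, heteroscedastic
environments, non-normal yields, spatial/temporal correlation within
blocks, and any climate covariates (environments are abstract levels).
Passing tests therefore demonstrate correctness of the machinery under the
model's own assumptions, not robustness to their violation.

## Problem sizes used in tests and the acceptance run

Calibration checks run at sizes chosen to make their Monte Carlo error
comfortably smaller than the asserted bands: interval coverage over 100
genotypes × 4 parameters (pooled binomial sd ≈ 0.011 against a ±0.03
band); Geweke over 500 iid chains of length 2000; Hartley type-I over 2000
replicates at k=4, df=84; DIC effective parameters over 100 replicate fits
at n=200; GxE power over 200 replicates of a 10×4×3 trial. The pipeline
acceptance run uses 4 chains × 20,000 iterations on the full 43-genotype
panel — chain-length studies in the test suite confirm the between-chain
spread of running means has long stabilized by then for these conjugate
posteriors.

## Known limitations

* Balanced designs only; a single missing plot currently requires the user
  to impute or drop to balance before analysis.
* The environmental index is estimated from the same data it then
  conditions on; measurement error in I_j is ignored, as in the classical
  method.
* No hierarchical prior across genotypes, no heteroscedastic-by-environment
  extension, no HMC/NUTS alternative sampler, and no WAIC/LOO — DIC is the
  only information criterion offered.
* The degenerate-design fallback (single slope) changes the meaning of
  "responsive" for the affected genotypes; the warning should be heeded.
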