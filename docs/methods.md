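# Methods

## Problem and model

`mbpower` estimates the statistical power of case-control differential
abundance (DA) studies of microbiome count data (16S ASV tables). Power
cannot be computed analytically for the standard negative binomial (NB)
testing pipeline, so the package takes the simulation route: learn a
generative model of a community from a pilot dataset, simulate many
synthetic studies from it, run the DA test on each, and summarise how often
each kind of taxon is detected.

### Count model

Counts follow the standard NB regression used throughout DA analysis:

    K_ij ~ NB(mean = mu_ij, dispersion = alpha_i)
    mu_ij = s_j * q_ij,      log q_ij = beta_i0 + beta_i1 * x_j

with `x_j` the 0/1 treatment indicator, `s_j` per-sample size factors and
`var(K) = mu + alpha * mu^2`. The effect size is the log2 fold change
(LFC) `beta_i1 / ln 2`.

### Community model

Three fitted pieces describe a community:

1. **Log2 mean abundance** across taxa: a univariate Gaussian mixture.
   The number of components (1–5) is chosen by a sequential parametric
   bootstrap likelihood-ratio test at level 0.05 with 100 bootstrap
   replicates per test: simulate from the k-component null fit, refit both
   k and k+1 on each replicate, and stop at the first test whose bootstrap
   p-value (with the +1/(B+1) correction) exceeds the level.
2. **Log2 fold change given abundance**: a conditional Gaussian mixture
   `y | x ~ sum_i pi_i N(m_i0 + m_i1 x, exp(f_i(x))^2)` with softmax
   weights (`lambda_1 = 0` for identifiability) and `f_i` linear or
   quadratic in `x`. The component count and variance form are selected
   jointly by minimum AIC with `#params = (K-1) + 2K + K(deg+1)`.
3. **Dispersion trend** `d(m) = scale * (c0 + c1/m)`: `c0` is the
   asymptotic dispersion of abundant taxa, `c1` the low-abundance excess.
   Per-taxon ML dispersion estimates are noisy and upward-heavy, so the
   predicted dispersion is compressed by a scale factor (default 0.3)
   chosen to make simulated coefficients of variation match observed
   data. The scale is applied at prediction time only; the stored
   (c0, c1) are the raw fit. A corollary: refitting the model to its own
   simulation output recovers `scale * (c0, c1)`, not (c0, c1) — the
   recovery tests therefore use a generating model with scale 1.

### Simulation procedure

Per taxon: draw `x ~` mean mixture; draw `y ~` LFC mixture given `x`;
predict `d = scale*(c0 + c1/2^x)`; split `M = 2^x` into group means with
`FC = 2^y`, `mu_c = 2M/(1+FC)`, `mu_t = FC * mu_c` (arithmetic mean exactly
`M`); draw counts independently per sample from NB(mu_group, d) using the
`size = 1/d`, `p = size/(size + mu)` transform (`d = 0` falls back to
Poisson). Simulated samples have size factors identically 1; an optional
lognormal depth multiplier exists for stress tests but is off by default
because the generative procedure does not model library-size variation.
Means are floored at 1e-6 to avoid degenerate NB parameters after extreme
mixture draws. One `SeedSequence` per dataset spawns named substreams
(mean, LFC, counts, depth) so runs are bit-reproducible.

### Differential abundance engine

The NB Wald pipeline is implemented in-package so power results are
self-contained:

- **Size factors**: median-of-ratios with the "positive counts" geometric
  mean (nonzero samples only), rescaled to geometric mean 1 — sparse ASV
  tables degenerate under the all-sample variant.
- **Dispersion**: per-taxon profile ML over `alpha` in [1e-8, 50]
  (group means profiled out by Newton steps); boundary optima report
  `alpha = 0` (Poisson limit). No Cox-Reid adjustment — a documented
  simplification that slightly biases `alpha` downward at small n.
- **Wald test**: per-taxon NB GLM with log link, offset `log s_j`, fixed
  dispersion, fitted by IRLS vectorised across taxa; two-sided normal
  p-value on `beta_1/se`. Linear predictors are capped at ±30 so taxa
  observed in only one group get a large-but-finite LFC with a huge
  standard error rather than a divergent fit.
- **Shrinkage**: empirical-Bayes normal prior N(0, tau^2); tau^2 is the
  moment estimate `mean(lfc^2) - mean(se^2)` floored at 0.01, and
  `lfc_shrunk = lfc * tau^2/(tau^2 + se^2)`. This pulls the wild LFCs of
  rare taxa towards zero while leaving precise estimates untouched, and it
  is what the community model is fitted to (raw LFCs of group-exclusive
  taxa are numerically extreme and would corrupt the mixture).
- **BH**: hand-written step-up with monotonicity enforcement; undefined
  p-values (all-zero taxa) are excluded from the denominator.
- Significance threshold defaults to q < 0.1; every output records the
  threshold used. A plug-in interface (`engine.run(cm) -> DataFrame`)
  allows substituting an external test engine.

### Power estimation

Each simulated study is filtered (default: ≥5 reads in ≥3 samples), tested,
and every taxon contributes a Bernoulli outcome `y = 1[q < alpha_sig]`
indexed by its TRUE log2 mean abundance (`x1`) and TRUE |log2 FC| (`x2`).
Using |LFC| keeps the monotonicity constraint meaningful — detection is
symmetric in effect sign. Taxa removed by the pre-filter count as `y = 0`
(power unconditional on surviving the filter); a flag computes
filter-conditional power instead.

The power surface is a Bernoulli GAM `logit p = beta0 + f(x1, x2)` where
`f` is a cubic tensor-product B-spline (6 basis functions per margin,
knots at equal steps over the data range) whose coefficient grid is a
double cumulative sum of exponentials — non-decreasing along both indices
by construction, which makes the fitted surface monotone non-decreasing in
both abundance and effect size at machine precision (a structural, not
statistical, guarantee; this mirrors the double-monotone tensor
construction of shape-constrained additive models). A second-difference
penalty on the unconstrained coefficients is tuned by GCV over a small
grid (0.01–100), with effective degrees of freedom from a local
linearisation. Predictions outside the training box are clamped to the
boundary, never extrapolated. Any residual variation beyond the smooth is
treated as absorbed into the Bernoulli noise; no extra random-effect term
is fitted.

Summaries: per-taxon power `p_i = surface(x1_i, x2_i)`, average power
`p_hat = mean(p_i)`, and the expected number of significant taxa
`mu = sum_i p_i = n * p_hat` (exact identity, asserted in tests), plus
deciles of the `p_i` distribution. The sample-size sweep repeats the whole
procedure per group size (defaults 30–190 by 20) and reports power at a
reference abundance (`x1 = 5`) for |LFC| in {2, 3, 4}, and `mu` over a
fixed reference taxon set drawn once from the model.

## Numerical choices

- EM (both mixtures): convergence when the relative log-likelihood change
  drops below 1e-8, max 500 iterations (300 for the conditional mixture);
  log-likelihood monotonicity asserted at every iteration (tolerance
  1e-7 relative). Components collapsing below sd 1e-6 trigger a restart;
  all-restart collapse is an error.
- Observed fits use 5 (univariate) / 3 (conditional) k-means-seeded
  restarts. Bootstrap refits use one deterministic sorted-block start and
  run batched across all replicates; the observed LRT statistic is
  computed with the same single-start routine so the statistic and its
  bootstrap reference distribution are exchangeable (the multi-restart fit
  still supplies the returned parameters). This follows the usual practice
  of single-start EM inside bootstrap model-order tests.
- Conditional-mixture M-step: weighted least squares for the mean
  coefficients, L-BFGS (analytic gradient, ≤50 inner iterations) for the
  log-sd coefficients, accepted only when the objective improves
  (generalized EM, preserving monotonicity). `x` is standardised
  internally and coefficients mapped back, for conditioning.
- Dispersion trend: NNLS on (1, 1/m); a robust soft-L1 first pass defines
  the trend from which points >10-fold off are trimmed before the final
  NNLS. Predictions are floored at 1e-8.
- BH, group-mean splitting, and the mu = n*p_hat identity are exact.

## The synthetic-data generator

The built-in reference model (`default_community_model`) is synthetic — a
hand-specified community typical of published 16S case-control surveys: a
3-component abundance mixture (modes at log2 abundance 2.5/5.5/8.5,
weights 0.5/0.3/0.2), a 2-component LFC mixture (75% near-null bulk with
sd ≈ 0.5 shrinking slightly with abundance; 25% "affected" component with
mean 0.5 + 0.15·x and sd ≈ 1.35), and trend d = 0.3·(0.2 + 5/m). It
emulates the marginal abundance spectrum, the abundance-dependent effect
distribution, and the dispersion–mean decay of real ASV tables. It does
NOT emulate taxon–taxon correlation, compositional closure, library-size
variation, or technical zero-inflation — so passing tests demonstrate
correctness of the method under independent-taxon NB sampling, not
robustness to those real-data features.

## Problem sizes used in tests

The full design for a production power analysis is 1000 taxa, 100 samples
per group, 100 simulations (the package defaults). The test suite and the
acceptance script run scaled-down designs chosen to keep the statistical
claims sharp while remaining desk-sized: e.g. 300 taxa / sizes {30, 100} /
20 simulations for the sample-size monotonicity check, 500 taxa / 50 per
group / 20 simulations for null FDR control, and 600–800 taxa for the
fit → re-simulate self-consistency round trip.

## Known limitations

- Wald tests without Cox-Reid-adjusted dispersions are mildly liberal at
  small sample sizes; the null-calibration tests bound this empirically.
- The LFC shrinkage prior is a single normal component, lighter-tailed
  than the priors of dedicated DA packages; extreme true effects are
  shrunk slightly more than they would be there.
- The bootstrap order-selection test inherits the usual conservatism of
  sequential testing; mixture orders separated by less than ~3 sd are
  rarely resolved.
- The double-cumulative-sum surface constrains not only both partial
  differences but also their interaction increments to be non-negative
  (total positivity), which is slightly stronger than pure bivariate
  monotonicity.
- Power estimates are conditional on the fitted community model; they do
  not propagate pilot-study estimation uncertainty.
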