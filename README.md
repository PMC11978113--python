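# mbpower

Simulation-based power analysis for case-control microbiome differential
abundance studies.

Microbiome surveys routinely test hundreds of taxa (16S ASVs) for
differential abundance between a control and a treatment group, yet most
are designed without any power calculation — partly because no analytic
power formula exists for the negative binomial (NB) testing pipeline that
dominates the field. `mbpower` closes that gap for study planners: fit a
generative model of a community to pilot data, simulate realistic synthetic
studies of any size from it, run the NB test on each, and read off the
power of each kind of taxon and the expected number of discoveries.

## The model

Counts follow the standard NB regression,

    K_ij ~ NB(mean = mu_ij, dispersion = alpha_i),
    mu_ij = s_j q_ij,   log q_ij = beta_i0 + beta_i1 x_j,
    var(K) = mu + alpha mu^2,

with `x_j` the treatment indicator and `s_j` median-of-ratios size
factors. A community is summarised by three fitted pieces:

1. log2 mean abundance across taxa — a Gaussian mixture whose order is
   chosen by a sequential parametric bootstrap likelihood-ratio test
   (1–5 components, 100 bootstrap replicates, level 0.05);
2. log2 fold change conditional on abundance — a heteroscedastic Gaussian
   mixture `y|x ~ sum_i pi_i N(m_i0 + m_i1 x, exp(f_i(x))^2)` with the
   component count and variance form (linear/quadratic `f`) selected by
   AIC;
3. a dispersion–mean trend `d(m) = scale (c0 + c1/m)` with `scale = 0.3`
   calibrating simulated coefficients of variation to observed data.

Simulated studies are tested with the in-package NB Wald pipeline
(profile-ML dispersions, IRLS GLM fits, empirical-Bayes LFC shrinkage,
Benjamini–Hochberg correction, significance at q < 0.1 by default). Each
taxon's detection outcome is a Bernoulli trial; a shape-constrained
logistic tensor-spline surface — monotone non-decreasing in both log mean
abundance and |log2 fold change| by construction — maps (abundance, effect
size) to power `p_i`. The expected number of significant taxa is

    mu = sum_i p_i = n * p_hat,

the sum of per-taxon powers (equivalently, taxon count times average
power).

## Worked example

Estimate power for a 50-samples-per-group study of the built-in reference
community (300 taxa, 10 simulated studies):

```python
from mbpower import (default_community_model, run_power_simulation,
                     fit_power_surface, power_summary)

model = default_community_model()
outcomes = run_power_simulation(model, n_taxa=300, n_per_group=50,
                                n_sims=10, alpha_sig=0.1, seed=7)
surface = fit_power_surface(outcomes)
taxa = outcomes[outcomes["sim"] == 0][["x1", "x2"]].to_numpy()
summ = power_summary(surface, taxa, alpha_sig=0.1)

print(f"average power p-hat = {summ.average_power:.3f}")
print(f"expected significant taxa mu = {summ.expected_significant:.1f} of {summ.n_taxa}")
print(f"power at (x1=5, |lfc|=1) = {surface.predict([[5.0, 1.0]])[0]:.3f}")
```

prints

```
average power p-hat = 0.699
expected significant taxa mu = 209.8 of 300
power at (x1=5, |lfc|=1) = 0.999
```

So a study with 50 samples per group would detect on average 70% of this
community's taxa at q < 0.1 — about 210 of 300 expected discoveries — and
a two-fold change in a taxon of moderate abundance (log2 mean 5, i.e.
~32 normalized counts) is detected essentially always. Low-abundance,
small-effect taxa pull the average down; `summ.quantiles()` shows the full
spread.

The same workflow runs from the shell: `mbpower fixture` writes a
synthetic pilot dataset with known ground truth, `mbpower fit` fits the
community model to a count table + metadata, `mbpower simulate` draws
synthetic studies from a fitted model, `mbpower power` and `mbpower sweep`
produce the power reports, and `mbpower compare` checks simulated against
observed taxon mean/variance distributions.

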