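"""Simulate case-control count matrices from a fitted community model.

The five-step generative procedure, per taxon t:

1. draw log2 mean abundance x_t from the mean-abundance mixture;
2. draw log2 fold change y_t from the LFC mixture conditional on x_t;
3. predict dispersion d_t = scale * (c0 + c1 / 2^x_t) from the trend;
4. split the overall mean M = 2^x_t into group means so their arithmetic
   mean is exactly M:  mu_control = 2M / (1 + FC), mu_treatment = FC *
   mu_control with FC = 2^y_t;
5. draw counts independently per sample from NB(mean = mu_group,
   dispersion = d_t), i.e. numpy's parameterisation with size r = 1/d and
   success probability p = r / (r + mu); d = 0 falls back to Poisson.

Simulated samples carry size factors identically 1 (no library-size
variation) unless lognormal depth multipliers are switched on.  A single
seed drives named substreams (one per generative step) so every dataset is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityModel
from .io import CONTROL, TREATMENT, CountMatrix

_MEAN_FLOOR = 1e-6


@dataclass(frozen=True)
class SimulatedDataset:
    """Counts plus the ground-truth per-taxon parameters that generated them."""

    counts: CountMatrix
    truth: pd.DataFrame  # taxon_id, M, lfc, dispersion, mu_control, mu_treatment
    seed: int | None
    model: CommunityModel


def group_means(M: float | np.ndarray, lfc: float | np.ndarray, log_base: float = 2.0):
    """Split an overall mean into (mu_control, mu_treatment) with mean exactly M.

    FC = base**lfc; mu_control = 2M / (1 + FC); mu_treatment = FC * mu_control.
    """
    M = np.asarray(M, float)
    if np.any(M <= 0):
        raise ValueError("overall mean abundance must be positive")
    fc = np.power(log_base, np.asarray(lfc, float))
    mu_control = 2.0 * M / (1.0 + fc)
    mu_treatment = 2.0 * M * fc / (1.0 + fc)
    return mu_control, mu_treatment


def sample_nb(
    mean: np.ndarray, dispersion: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """NB draws in (mean, dispersion) form: var = mu + alpha * mu^2."""
    mean = np.asarray(mean, float)
    disp = np.broadcast_to(np.asarray(dispersion, float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = disp < 1e-12
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    nbm = ~pois
    if nbm.any():
        r = 1.0 / disp[nbm]
        p = r / (r + mean[nbm])
        out[nbm] = rng.negative_binomial(r, p)
    return out


def simulate_community(
    model: CommunityModel,
    n_taxa: int,
    n_control: int,
    n_treatment: int,
    seed: int | None = None,
    library_size_sd: float = 0.0,
) -> SimulatedDataset:
    """Generate a synthetic case-control dataset with known per-taxon truth.

    ``library_size_sd`` > 0 adds lognormal per-sample depth multipliers
    (stress-testing only; off by default).
    """
    model.validate()
    if n_taxa < 1 or n_control < 2 or n_treatment < 2:
        raise ValueError("need n_taxa >= 1 and >= 2 samples per group")
    ss = np.random.SeedSequence(seed)
    s_mean, s_lfc, s_counts, s_depth = ss.spawn(4)
    base = model.log_base

    x = model.mean_mixture.sample(n_taxa, random_state=np.random.default_rng(s_mean))
    y = model.lfc_mixture.sample(x, random_state=np.random.default_rng(s_lfc))
    M = np.maximum(np.power(base, x), _MEAN_FLOOR)
    d = model.dispersion_trend.predict(M)
    mu_c, mu_t = group_means(M, y, log_base=base)
    mu_c = np.maximum(mu_c, _MEAN_FLOOR)
    mu_t = np.maximum(mu_t, _MEAN_FLOOR)

    mu = np.concatenate(
        [np.repeat(mu_c[:, None], n_control, axis=1),
         np.repeat(mu_t[:, None], n_treatment, axis=1)],
        axis=1,
    )
    if library_size_sd > 0:
        depth_rng = np.random.default_rng(s_depth)
        depth = np.exp(depth_rng.normal(0.0, library_size_sd, n_control + n_treatment))
        mu = mu * depth[None, :]
    counts = sample_nb(mu, d[:, None], np.random.default_rng(s_counts))

    taxon_ids = [f"taxon_{i:05d}" for i in range(n_taxa)]
    sample_ids = [f"ctrl_{j:04d}" for j in range(n_control)] + [
        f"trt_{j:04d}" for j in range(n_treatment)
    ]
    group = np.array([CONTROL] * n_control + [TREATMENT] * n_treatment, dtype=object)
    cm = CountMatrix(counts=counts, taxon_ids=taxon_ids, sample_ids=sample_ids, group=group)
    truth = pd.DataFrame(
        {
            "taxon_id": taxon_ids,
            "M": M,
            "lfc": y,
            "dispersion": d,
            "mu_control": mu_c,
            "mu_treatment": mu_t,
        }
    )
    return SimulatedDataset(counts=cm, truth=truth, seed=seed, model=model)


@dataclass(frozen=True)
class DistributionComparison:
    """Self-consistency report: observed vs simulated taxon-level distributions."""

    ks_log_mean: float
    ks_log_var: float
    qq_table: pd.DataFrame  # quantile, real/sim log-mean and log-var

    def to_frame(self) -> pd.DataFrame:
        return self.qq_table


def compare_distributions(real: CountMatrix, sim: CountMatrix) -> DistributionComparison:
    """Compare per-taxon mean and variance distributions on the log scale.

    Reports two-sample Kolmogorov-Smirnov statistics and a decile
    quantile-quantile table for log2(mean + 0.5) and log2(variance + 0.5).
    """
    if real.n_taxa == 0 or sim.n_taxa == 0:
        raise ValueError("both matrices must be non-empty")

    def log_moments(cm: CountMatrix):
        k = cm.counts.astype(float)
        return np.log2(k.mean(axis=1) + 0.5), np.log2(k.var(axis=1, ddof=1) + 0.5)

    rm, rv = log_moments(real)
    sm, sv = log_moments(sim)
    qs = np.arange(0.1, 1.0, 0.1)
    qq = pd.DataFrame(
        {
            "quantile": qs,
            "real_log_mean": np.quantile(rm, qs),
            "sim_log_mean": np.quantile(sm, qs),
            "real_log_var": np.quantile(rv, qs),
            "sim_log_var": np.quantile(sv, qs),
        }
    )
    return DistributionComparison(
        ks_log_mean=float(stats.ks_2samp(rm, sm).statistic),
        ks_log_var=float(stats.ks_2samp(rv, sv).statistic),
        qq_table=qq,
    )


def plot_comparison(report: DistributionComparison, real: CountMatrix, sim: CountMatrix, path) -> None:
    """Density overlay of observed vs simulated log2 taxon means and variances."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, stat_idx, label in ((axes[0], 0, "log2 mean"), (axes[1], 1, "log2 variance")):
        for cm, name, style in ((real, "observed", "k--"), (sim, "simulated", "C0-")):
            k = cm.counts.astype(float)
            vals = np.log2((k.mean(axis=1) if stat_idx == 0 else k.var(axis=1, ddof=1)) + 0.5)
            grid = np.linspace(vals.min() - 1, vals.max() + 1, 200)
            dens = stats.gaussian_kde(vals)(grid)
            ax.plot(grid, dens, style, label=name)
        ax.set_xlabel(label)
        ax.set_ylabel("density")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
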