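"""Monte-Carlo power estimation for NB differential abundance tests.

Workflow: repeatedly simulate case-control datasets from a community model,
run the full NB test pipeline on each, and record for every taxon whether it
was called significant (q < alpha_sig).  Each Bernoulli outcome is indexed
by the taxon's TRUE log2 mean abundance (x1) and TRUE absolute log2 fold
change (x2); a shape-constrained logistic tensor-product-spline surface is
then fitted so that estimated power is monotone non-decreasing in both
abundance and effect size.  Summaries report per-taxon powers p_i, their
mean p_hat, and the expected number of significant taxa mu = sum_i p_i
= n * p_hat.

x2 is the ABSOLUTE log fold change: detection power is symmetric in the
sign of the effect, and monotonicity is meaningful only in its magnitude.

Taxa eliminated by the low-abundance pre-filter are recorded with outcome 0
(they can never be detected), so power is unconditional on surviving the
filter; pass ``filter_conditional=True`` to drop them instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, optimize
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import nb
from .community import CommunityModel
from .io import filter_low_abundance
from .simulate import simulate_community

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_SIG = 0.1
DEFAULT_SWEEP_SIZES = (30, 50, 70, 90, 110, 130, 150, 170, 190)
DEFAULT_SWEEP_LFCS = (2.0, 3.0, 4.0)

OUTCOME_COLUMNS = ["sim", "taxon", "x1", "x2", "y", "q_value"]


def run_power_simulation(
    model: CommunityModel,
    n_taxa: int = 1000,
    n_per_group: int = 100,
    n_sims: int = 100,
    alpha_sig: float = DEFAULT_ALPHA_SIG,
    seed: int | None = None,
    min_count: int = 5,
    min_samples: int = 3,
    engine: nb.NBWaldEngine | None = None,
    filter_conditional: bool = False,
) -> pd.DataFrame:
    """Simulate, test, and tabulate significance outcomes.

    Returns a long-format DataFrame (``OUTCOME_COLUMNS``): one row per
    (simulation, taxon) with the taxon's true x1 = log2 mean abundance,
    x2 = |log2 fold change| and binary outcome y = 1[q < alpha_sig].
    The defaults (1000 taxa, 100 per group, 100 simulations) are the
    standard design for a full power surface.
    """
    engine = engine or nb.NBWaldEngine()
    ss = np.random.SeedSequence(seed)
    rows = []
    n_failed = 0
    for s, child in enumerate(ss.spawn(n_sims)):
        sim_seed = int(child.generate_state(1)[0] % 2**31)
        ds = simulate_community(model, n_taxa, n_per_group, n_per_group, seed=sim_seed)
        try:
            filtered = filter_low_abundance(ds.counts, min_count, min_samples)
            res = engine.run(filtered)
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            logger.warning("simulation replicate %d failed: %s", s, exc)
            n_failed += 1
            continue
        qmap = dict(zip(res["taxon_id"], res["q_value"]))
        truth = ds.truth
        x1 = np.log2(truth["M"].to_numpy())
        x2 = np.abs(truth["lfc"].to_numpy())
        for t, tid in enumerate(truth["taxon_id"]):
            q = qmap.get(tid, np.nan)
            tested = tid in qmap and np.isfinite(q)
            if not tested and filter_conditional:
                continue
            y = int(tested and q < alpha_sig)
            rows.append((s, t, x1[t], x2[t], y, q))
    if n_failed > 0.1 * n_sims:
        raise RuntimeError(f"{n_failed}/{n_sims} simulation replicates failed")
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)


# ---------------------------------------------------------------------------
# shape-constrained power surface
# ---------------------------------------------------------------------------

def _bspline_basis(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    return interpolate.BSpline.design_matrix(x, knots, degree).toarray()


def _make_knots(lo: float, hi: float, n_basis: int, degree: int) -> np.ndarray:
    n_interior = n_basis - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


def _second_diff_penalty(k1: int, k2: int) -> np.ndarray:
    """Second-difference penalty on the coefficient grid, both margins."""
    def dmat(k):
        d = np.zeros((k - 2, k))
        for i in range(k - 2):
            d[i, i : i + 3] = (1.0, -2.0, 1.0)
        return d

    i1, i2 = np.eye(k1), np.eye(k2)
    s1 = np.kron(dmat(k1).T @ dmat(k1), i2)
    s2 = np.kron(i1, dmat(k2).T @ dmat(k2))
    return s1 + s2


class MonotonePowerSurface(BaseEstimator):
    """Bernoulli GAM with a bivariate monotone tensor-product smooth.

    The linear predictor is eta = beta0 + sum_ab theta_ab B_a(x1) B_b(x2)
    with cubic B-spline marginal bases.  Coefficients are parameterised as a
    double cumulative sum of exponentials, theta = cumsum_a cumsum_b
    exp(gamma), so the coefficient grid -- and hence the fitted surface --
    is non-decreasing along both axes by construction.  A second-difference
    smoothing penalty on gamma is applied; its weight is chosen by
    generalized cross-validation over ``lambda_grid``.  Predictions outside
    the training box are clamped to the boundary.
    """

    def __init__(
        self,
        n_basis: int = 6,
        degree: int = 3,
        lambda_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0),
        max_iter: int = 400,
    ):
        self.n_basis = n_basis
        self.degree = degree
        self.lambda_grid = lambda_grid
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2): columns x1, x2")
        if y.min() == y.max():
            raise ValueError("outcomes are all identical; surface is not identifiable")
        self.box_ = np.array([[X[:, 0].min(), X[:, 0].max()],
                              [X[:, 1].min(), X[:, 1].max()]])
        k = self.n_basis
        self.knots1_ = _make_knots(self.box_[0, 0], self.box_[0, 1], k, self.degree)
        self.knots2_ = _make_knots(self.box_[1, 0], self.box_[1, 1], k, self.degree)
        m = self._monotone_design(X)
        penalty = _second_diff_penalty(k, k)

        best = None
        for lam in self.lambda_grid:
            fit = self._fit_lambda(m, y, lam, penalty)
            if best is None or fit["gcv"] < best["gcv"]:
                best = {**fit, "lambda": lam}
        self.beta0_ = best["beta0"]
        self.gamma_ = best["gamma"]
        self.lambda_ = best["lambda"]
        self.gcv_ = best["gcv"]
        self.edf_ = best["edf"]
        theta = np.exp(self.gamma_).reshape(k, k)
        self.theta_ = theta.cumsum(axis=0).cumsum(axis=1)
        return self

    def _monotone_design(self, X: np.ndarray) -> np.ndarray:
        """Design mapping exp(gamma) to the smooth: M = (B1 (x) B2) (L (x) L)."""
        x1 = np.clip(X[:, 0], self.box_[0, 0], self.box_[0, 1])
        x2 = np.clip(X[:, 1], self.box_[1, 0], self.box_[1, 1])
        b1 = _bspline_basis(x1, self.knots1_, self.degree)
        b2 = _bspline_basis(x2, self.knots2_, self.degree)
        tensor = np.einsum("ni,nj->nij", b1, b2).reshape(X.shape[0], -1)
        k = self.n_basis
        lower = np.tril(np.ones((k, k)))
        return tensor @ np.kron(lower, lower)

    def _fit_lambda(self, m: np.ndarray, y: np.ndarray, lam: float, penalty: np.ndarray) -> dict:
        n, p = m.shape

        def objective(params):
            beta0, gamma = params[0], params[1:]
            e = np.exp(np.clip(gamma, -40.0, 40.0))
            eta = beta0 + m @ e
            # Bernoulli negative loglik, numerically stable
            nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
            pen = 0.5 * lam * float(gamma @ penalty @ gamma)
            mu = expit(eta)
            grad = np.empty(p + 1)
            grad[0] = float(np.sum(mu - y))
            grad[1:] = (m.T @ (mu - y)) * e + lam * (penalty @ gamma)
            return nll + pen, grad

        x0 = np.concatenate([[float(np.log(np.mean(y) / (1 - np.mean(y))))],
                             np.full(p, -4.0)])
        res = optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "maxfun": 4 * self.max_iter},
        )
        beta0, gamma = res.x[0], res.x[1:]
        e = np.exp(np.clip(gamma, -40.0, 40.0))
        eta = beta0 + m @ e
        mu = expit(eta)
        # binary outcomes: the saturated log-likelihood is 0
        dev = 2.0 * float(np.sum(np.logaddexp(0.0, eta) - y * eta))
        # effective degrees of freedom via local linearisation in (beta0, gamma)
        jac = np.column_stack([np.ones(n), m * e[None, :]])
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        h = jac.T @ (jac * w[:, None])
        pen_full = np.zeros((p + 1, p + 1))
        pen_full[1:, 1:] = lam * penalty
        try:
            edf = float(np.trace(np.linalg.solve(h + pen_full + 1e-10 * np.eye(p + 1), h)))
        except np.linalg.LinAlgError:
            edf = p + 1.0
        gcv = n * dev / max(n - edf, 1.0) ** 2
        return {"beta0": float(beta0), "gamma": gamma, "gcv": gcv, "edf": edf}

    def predict(self, X) -> np.ndarray:
        """Estimated power in [0, 1] at (x1, x2), clamped to the training box."""
        check_is_fitted(self, "gamma_")
        X = np.atleast_2d(np.asarray(X, float))
        m = self._monotone_design(X)
        return expit(self.beta0_ + m @ np.exp(np.clip(self.gamma_, -40.0, 40.0)))


def fit_power_surface(outcomes: pd.DataFrame, **kwargs) -> MonotonePowerSurface:
    """Fit the monotone power surface to a significance-outcome table."""
    X = outcomes[["x1", "x2"]].to_numpy(float)
    y = outcomes["y"].to_numpy(float)
    return MonotonePowerSurface(**kwargs).fit(X, y)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSummary:
    """Per-taxon powers and the expected number of significant taxa."""

    per_taxon_power: np.ndarray
    alpha_sig: float
    n_per_group: int | None = None
    n_sims: int | None = None

    @property
    def n_taxa(self) -> int:
        return self.per_taxon_power.size

    @property
    def average_power(self) -> float:
        """p_hat: mean of the per-taxon powers."""
        return float(self.per_taxon_power.mean())

    @property
    def expected_significant(self) -> float:
        """mu = sum_i p_i; identically n * p_hat."""
        return float(self.per_taxon_power.sum())

    def quantiles(self, qs=np.arange(0.1, 1.0, 0.1)) -> pd.Series:
        return pd.Series(np.quantile(self.per_taxon_power, qs), index=np.round(qs, 2))

    def to_frame(self) -> pd.DataFrame:
        qs = self.quantiles()
        rows = {
            "n_taxa": self.n_taxa,
            "average_power": self.average_power,
            "expected_significant": self.expected_significant,
            "alpha_sig": self.alpha_sig,
            "n_per_group": self.n_per_group,
            "n_sims": self.n_sims,
            **{f"power_q{int(q * 100)}": v for q, v in qs.items()},
        }
        return pd.DataFrame([rows])


def power_summary(
    surface: MonotonePowerSurface,
    taxa: np.ndarray,
    alpha_sig: float = DEFAULT_ALPHA_SIG,
    n_per_group: int | None = None,
    n_sims: int | None = None,
) -> PowerSummary:
    """Evaluate the surface on a taxon set (n, 2) of (x1, x2) and summarise."""
    taxa = np.atleast_2d(np.asarray(taxa, float))
    if taxa.size == 0:
        raise ValueError("empty taxon list")
    clamped = np.sum(
        (taxa[:, 0] < surface.box_[0, 0]) | (taxa[:, 0] > surface.box_[0, 1])
        | (taxa[:, 1] < surface.box_[1, 0]) | (taxa[:, 1] > surface.box_[1, 1])
    )
    if clamped:
        logger.info("%d taxa outside the training box were clamped", int(clamped))
    return PowerSummary(
        per_taxon_power=surface.predict(taxa),
        alpha_sig=alpha_sig,
        n_per_group=n_per_group,
        n_sims=n_sims,
    )


def sample_size_sweep(
    model: CommunityModel,
    sizes: tuple[int, ...] = DEFAULT_SWEEP_SIZES,
    lfc_values: tuple[float, ...] = DEFAULT_SWEEP_LFCS,
    x1_ref: float = 5.0,
    n_taxa: int = 1000,
    n_sims: int = 100,
    alpha_sig: float = DEFAULT_ALPHA_SIG,
    seed: int | None = None,
) -> pd.DataFrame:
    """Power and expected detections as a function of samples per group.

    For every group size, runs a full power simulation, fits the surface,
    and records (a) predicted power at the reference abundance ``x1_ref``
    for each |log2 FC| in ``lfc_values`` and (b) the expected number of
    significant taxa mu over a fixed reference taxon set drawn once from
    the model.  Long-format output: size, lfc, power, mu, average_power.
    """
    ss = np.random.SeedSequence(seed)
    ref_stream, *size_streams = ss.spawn(len(sizes) + 1)
    ref_rng = np.random.default_rng(ref_stream)
    x1_ref_set = model.mean_mixture.sample(n_taxa, random_state=ref_rng)
    lfc_ref_set = np.abs(model.lfc_mixture.sample(x1_ref_set, random_state=ref_rng))
    ref_taxa = np.column_stack([x1_ref_set, lfc_ref_set])

    rows = []
    for size, stream in zip(sizes, size_streams):
        outcomes = run_power_simulation(
            model, n_taxa=n_taxa, n_per_group=size, n_sims=n_sims,
            alpha_sig=alpha_sig, seed=int(stream.generate_state(1)[0] % 2**31),
        )
        surface = fit_power_surface(outcomes)
        summ = power_summary(surface, ref_taxa, alpha_sig, size, n_sims)
        for lfc in lfc_values:
            p = float(surface.predict([[x1_ref, lfc]])[0])
            rows.append(
                {
                    "size": size,
                    "lfc": lfc,
                    "power": p,
                    "mu": summ.expected_significant,
                    "average_power": summ.average_power,
                }
            )
    return pd.DataFrame(rows)


def plot_power_surface(
    surface: MonotonePowerSurface, outcomes: pd.DataFrame, path, n_grid: int = 60
) -> None:
    """Contour plot of the fitted surface with outcome points overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g1 = np.linspace(*surface.box_[0], n_grid)
    g2 = np.linspace(*surface.box_[1], n_grid)
    gg1, gg2 = np.meshgrid(g1, g2)
    z = surface.predict(np.column_stack([gg1.ravel(), gg2.ravel()])).reshape(gg1.shape)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    cs = ax.contourf(gg1, gg2, z, levels=np.linspace(0, 1, 11), cmap="viridis")
    fig.colorbar(cs, ax=ax, label="estimated power")
    sub = outcomes.sample(min(len(outcomes), 2000), random_state=0)
    for yval, marker, color in ((0, ".", "white"), (1, ".", "red")):
        pts = sub[sub["y"] == yval]
        ax.plot(pts["x1"], pts["x2"], marker, color=color, ms=2, alpha=0.4)
    ax.set_xlabel("log2 mean abundance")
    ax.set_ylabel("|log2 fold change|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
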