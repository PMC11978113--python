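"""Gaussian mixture models for community structure.

Two estimators:

* :class:`GaussianMixtureModel` — a univariate Gaussian mixture for log mean
  abundance, with the number of components chosen by a sequential parametric
  bootstrap likelihood-ratio test (k vs k+1 components, k = 1..K_max).
* :class:`ConditionalLfcMixture` — a mixture of Gaussians for the log fold
  change y conditional on log mean abundance x:

      y ~ sum_i pi_i N(m_i0 + m_i1 x, sigma_i(x)^2),
      sigma_i(x) = exp(f_i(x)),  f_i linear or quadratic in x,
      pi_i = exp(lambda_i) / sum_i exp(lambda_i),  lambda_1 = 0,

  fitted by ECM and selected (over component count and variance form) by
  minimum AIC.

Both EM loops assert a non-decreasing log-likelihood at every iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

_MIN_SD = 1e-6
_LL_SLACK = 1e-7  # numerical slack for the monotone-loglik assertion


class EMError(RuntimeError):
    """EM failed: all restarts collapsed or diverged."""


def _assert_monotone(trace: list[float]) -> None:
    prev = -np.inf
    for ll in trace:
        if ll < prev - _LL_SLACK * (1.0 + abs(prev)):
            raise EMError(f"EM log-likelihood decreased: {prev} -> {ll}")
        prev = ll


# ---------------------------------------------------------------------------
# univariate Gaussian mixture
# ---------------------------------------------------------------------------

def _em_gaussian_1d(
    data: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_restarts: int,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, list[float]]:
    """Best-of-restarts EM for a K-component univariate Gaussian mixture."""
    x = np.asarray(data, float).ravel()
    n = x.size
    if n < 5 * k:
        raise ValueError(f"need at least {5 * k} points to fit {k} components")
    if k == 1:
        mu, sd = float(x.mean()), float(max(x.std(), _MIN_SD))
        ll = float(np.sum(_norm_logpdf(x, mu, sd)))
        return np.array([1.0]), np.array([mu]), np.array([sd]), ll, [ll]

    best = None
    n_collapsed = 0
    for r in range(n_restarts):
        km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(x[:, None])
        w = np.array([max((labels == c).mean(), 1e-3) for c in range(k)])
        w /= w.sum()
        mu = np.array([x[labels == c].mean() if (labels == c).any() else x.mean()
                       for c in range(k)])
        sd = np.array([max(x[labels == c].std(), 0.1 * x.std(), _MIN_SD)
                       if (labels == c).any() else x.std() for c in range(k)])
        try:
            w, mu, sd, ll, trace = _em_gaussian_run(x, w, mu, sd, max_iter, tol)
        except EMError:
            n_collapsed += 1
            continue
        if best is None or ll > best[3]:
            best = (w, mu, sd, ll, trace)
    if best is None:
        raise EMError(f"all {n_restarts} EM restarts collapsed for K={k}")
    return best


def _norm_logpdf(x: np.ndarray, mu, sd) -> np.ndarray:
    return -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def _em_gaussian_run(x, w, mu, sd, max_iter, tol):
    n = x.size
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        log_comp = np.log(w)[None, :] + _norm_logpdf(x[:, None], mu[None, :], sd[None, :])
        peak = log_comp.max(axis=1)
        log_norm = peak + np.log(np.exp(log_comp - peak[:, None]).sum(axis=1))
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0)
        if (nk < 1e-10).any():
            raise EMError("empty component")
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(var)
        if (sd < _MIN_SD).any():
            raise EMError("component collapsed (sd below threshold)")
        if np.isfinite(prev) and ll - prev < tol * (1.0 + abs(ll)):
            break
        prev = ll
    _assert_monotone(trace)
    return w, mu, sd, trace[-1], trace


def _em_batch(X: np.ndarray, k: int, max_iter: int, tol: float):
    """EM on a batch of datasets at once (bootstrap refits).

    X has shape (B, n): one univariate dataset per row.  Each row gets a
    single deterministic start (sorted-block means, pooled sd) and iterates
    until its own relative log-likelihood change drops below ``tol``.
    Returns (weights, means, sds, logliks, ok) where ``ok`` flags rows that
    neither collapsed nor emptied a component.
    """
    B, n = X.shape
    if k == 1:
        mu = X.mean(axis=1, keepdims=True)
        sd = np.maximum(X.std(axis=1, keepdims=True), _MIN_SD)
        ll = np.sum(_norm_logpdf(X, mu, sd), axis=1)
        return np.ones((B, 1)), mu, sd, ll, np.ones(B, bool)

    xs = np.sort(X, axis=1)
    edges = np.linspace(0, n, k + 1).astype(int)
    mu = np.stack([xs[:, edges[c]: edges[c + 1]].mean(axis=1) for c in range(k)], axis=1)
    sd = np.maximum(np.repeat(X.std(axis=1)[:, None], k, axis=1), 1e-3)
    w = np.full((B, k), 1.0 / k)
    ll = np.full(B, -np.inf)
    ok = np.ones(B, bool)
    active = np.ones(B, bool)
    const = 0.5 * np.log(2.0 * np.pi)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        x = X[idx]
        lc = (
            np.log(w[idx])[:, :, None]
            - np.log(sd[idx])[:, :, None]
            - 0.5 * ((x[:, None, :] - mu[idx][:, :, None]) / sd[idx][:, :, None]) ** 2
            - const
        )
        peak = lc.max(axis=1)
        lnorm = peak + np.log(np.exp(lc - peak[:, None, :]).sum(axis=1))
        new_ll = lnorm.sum(axis=1)
        r = np.exp(lc - lnorm[:, None, :])
        nk = r.sum(axis=2)
        sx = (r * x[:, None, :]).sum(axis=2)
        sxx = (r * x[:, None, :] ** 2).sum(axis=2)
        safe_nk = np.maximum(nk, 1e-300)
        mu_new = sx / safe_nk
        var = sxx / safe_nk - mu_new**2
        bad = (nk < 1e-10).any(axis=1) | (var < _MIN_SD**2).any(axis=1)
        good = ~bad
        conv = good & np.isfinite(ll[idx]) & (new_ll - ll[idx] < tol * (1.0 + np.abs(new_ll)))
        w[idx[good]] = nk[good] / n
        mu[idx[good]] = mu_new[good]
        sd[idx[good]] = np.sqrt(var[good])
        ll[idx[good]] = new_ll[good]
        ok[idx[bad]] = False
        active[idx[bad]] = False
        active[idx[conv]] = False
    return w, mu, sd, ll, ok


@dataclass
class ComponentTest:
    """One step of the sequential bootstrap LRT for mixture order."""

    k_null: int
    k_alt: int
    statistic: float
    p_value: float
    n_bootstrap: int


class GaussianMixtureModel(BaseEstimator):
    """Univariate Gaussian mixture with bootstrap model-order selection.

    When ``n_components`` is None, the order is chosen by sequentially
    testing k against k+1 components: the observed likelihood-ratio
    statistic 2*(ll_{k+1} - ll_k) is compared with its distribution over
    ``n_bootstrap`` parametric-bootstrap datasets simulated from the fitted
    k-component (null) model; testing stops at the first bootstrap p-value
    above ``level`` (or at ``k_max``) and the null model of the terminating
    test is returned.

    Parameters
    ----------
    n_components : int or None
        Fixed component count; None triggers bootstrap selection.
    k_max : int, default 5
        Largest component count considered during selection.
    n_bootstrap : int, default 100
        Parametric-bootstrap replicates per test.
    level : float, default 0.05
        Significance threshold of the sequential test.
    n_restarts : int, default 5
        K-means-seeded EM restarts (2 are used inside bootstrap refits).
    """

    def __init__(
        self,
        n_components: int | None = None,
        k_max: int = 5,
        n_bootstrap: int = 100,
        level: float = 0.05,
        n_restarts: int = 5,
        max_iter: int = 500,
        tol: float = 1e-8,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.k_max = k_max
        self.n_bootstrap = n_bootstrap
        self.level = level
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, float).ravel()
        if not np.all(np.isfinite(x)):
            raise ValueError("data must be finite")
        rng = np.random.default_rng(self.random_state)
        if self.n_components is not None:
            w, mu, sd, ll, trace = _em_gaussian_1d(
                x, self.n_components, rng, self.n_restarts, self.max_iter, self.tol
            )
            self._set_fit(w, mu, sd, ll, trace, [])
            return self
        self._fit_select(x, rng)
        return self

    def _set_fit(self, w, mu, sd, ll, trace, selection):
        order = np.argsort(mu)
        self.weights_ = w[order]
        self.means_ = mu[order]
        self.sds_ = sd[order]
        self.loglik_ = ll
        self.loglik_trace_ = trace
        self.selection_ = selection
        self.n_components_ = len(w)

    def _fit_select(self, x: np.ndarray, rng: np.random.Generator) -> None:
        selection: list[ComponentTest] = []
        fit_k = _em_gaussian_1d(x, 1, rng, self.n_restarts, self.max_iter, self.tol)
        for k in range(1, self.k_max):
            fit_k1 = _em_gaussian_1d(
                x, k + 1, rng, self.n_restarts, self.max_iter, self.tol
            )
            # the observed statistic uses the same single-start EM routine as
            # the bootstrap refits, so the reference distribution is exchangeable
            # with it; the multi-restart fits above provide the model parameters
            _, _, _, ll_on, ok_on = _em_batch(x[None, :], k, self.max_iter, self.tol)
            _, _, _, ll_oa, ok_oa = _em_batch(x[None, :], k + 1, self.max_iter, self.tol)
            if ok_on[0] and ok_oa[0]:
                stat = max(0.0, 2.0 * (ll_oa[0] - ll_on[0]))
            else:
                stat = max(0.0, 2.0 * (fit_k1[3] - fit_k[3]))
            xb = np.stack(
                [_sample_mixture(fit_k[0], fit_k[1], fit_k[2], x.size, rng)
                 for _ in range(self.n_bootstrap)]
            )
            _, _, _, ll_null, ok_null = _em_batch(xb, k, self.max_iter, self.tol)
            _, _, _, ll_alt, ok_alt = _em_batch(xb, k + 1, self.max_iter, self.tol)
            usable = ok_null & ok_alt
            failures = int((~usable).sum())
            if failures > 0.2 * self.n_bootstrap:
                raise EMError(
                    f"bootstrap refits failed on {failures}/{self.n_bootstrap} replicates"
                )
            boot_stats = np.maximum(0.0, 2.0 * (ll_alt[usable] - ll_null[usable]))
            b = int(usable.sum())
            p = (1.0 + np.sum(boot_stats >= stat)) / (b + 1.0)
            selection.append(ComponentTest(k, k + 1, stat, float(p), b))
            if p > self.level:
                self._set_fit(*fit_k, selection)
                return
            fit_k = fit_k1
        self._set_fit(*fit_k, selection)

    def score_samples(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        x = np.asarray(X, float).ravel()
        log_comp = (
            np.log(self.weights_)[None, :]
            + _norm_logpdf(x[:, None], self.means_[None, :], self.sds_[None, :])
        )
        return logsumexp(log_comp, axis=1)

    def sample(self, n: int, random_state=None) -> np.ndarray:
        check_is_fitted(self, "weights_")
        rng = np.random.default_rng(random_state)
        return _sample_mixture(self.weights_, self.means_, self.sds_, n, rng)


def _sample_mixture(w, mu, sd, n, rng: np.random.Generator) -> np.ndarray:
    comp = rng.choice(len(w), size=n, p=np.asarray(w) / np.sum(w))
    return rng.normal(np.asarray(mu)[comp], np.asarray(sd)[comp])


def fit_gaussian_mixture_em(
    data, k: int, seed: int | None = None, n_restarts: int = 5
) -> tuple[dict, float]:
    """Functional wrapper: EM fit of a fixed-order mixture; returns (params, loglik)."""
    m = GaussianMixtureModel(n_components=k, n_restarts=n_restarts, random_state=seed).fit(data)
    params = {"weights": m.weights_, "means": m.means_, "sds": m.sds_}
    return params, m.loglik_


def select_components_bootstrap(
    data, k_max: int = 5, n_bootstrap: int = 100, level: float = 0.05,
    seed: int | None = None,
) -> GaussianMixtureModel:
    """Functional wrapper around the sequential bootstrap LRT selection."""
    return GaussianMixtureModel(
        k_max=k_max, n_bootstrap=n_bootstrap, level=level, random_state=seed
    ).fit(data)


# ---------------------------------------------------------------------------
# conditional LFC mixture
# ---------------------------------------------------------------------------

def _design(z: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(z, degree + 1, increasing=True)  # [1, z, z^2...]


def _logsd(phi: np.ndarray, g: np.ndarray) -> np.ndarray:
    return np.clip(phi @ g, -30.0, 30.0)


class ConditionalLfcMixture(BaseEstimator):
    """Heteroscedastic Gaussian mixture of log fold change given log mean abundance.

    Component means are linear in x; component log standard deviations are
    linear or quadratic in x; mixture weights are softmax(lambda) with
    lambda_1 = 0.  Fitted by ECM (responsibility E-step; weighted least
    squares for means, L-BFGS for log-sd coefficients).  When
    ``n_components`` or ``variance_form`` is None, candidates over
    ``k_range`` x {linear, quadratic} are fitted and the minimum-AIC model
    is kept, with #params = (K-1) + 2K + K*(degree+1).
    """

    _DEGREE = {"linear": 1, "quadratic": 2}

    def __init__(
        self,
        n_components: int | None = None,
        variance_form: str | None = None,
        k_range: tuple[int, ...] = (1, 2, 3, 4, 5),
        n_restarts: int = 3,
        max_iter: int = 300,
        tol: float = 1e-8,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.variance_form = variance_form
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        x = np.asarray(X, float).ravel()
        y = np.asarray(y, float).ravel()
        if x.size != y.size or x.size < 50:
            raise ValueError("x and y must have equal length >= 50")
        rng = np.random.default_rng(self.random_state)
        # standardise x internally for conditioning; coefs mapped back after
        a, b = float(x.mean()), float(max(x.std(), 1e-8))
        z = (x - a) / b

        ks = [self.n_components] if self.n_components else list(self.k_range)
        forms = [self.variance_form] if self.variance_form else ["linear", "quadratic"]
        candidates = []
        for k in ks:
            for form in forms:
                try:
                    fit = self._fit_one(z, y, k, self._DEGREE[form], rng)
                except (EMError, np.linalg.LinAlgError) as exc:
                    logger.warning("candidate K=%d form=%s failed: %s", k, form, exc)
                    continue
                n_params = (k - 1) + 2 * k + k * (self._DEGREE[form] + 1)
                aic = 2.0 * n_params - 2.0 * fit["loglik"]
                candidates.append({"k": k, "form": form, "aic": aic, **fit})
        if not candidates:
            raise EMError("all LFC-mixture candidates failed")
        best = min(candidates, key=lambda c: c["aic"])
        self._store(best, a, b)
        self.candidates_ = [
            {k: c[k] for k in ("k", "form", "aic", "loglik")} for c in candidates
        ]
        return self

    def _store(self, best: dict, a: float, b: float) -> None:
        k, deg = best["k"], self._DEGREE[best["form"]]
        # map coefficients from z = (x - a)/b back to x-space
        mean_coefs = np.empty((k, 2))
        mean_coefs[:, 0] = best["m"][:, 0] - best["m"][:, 1] * a / b
        mean_coefs[:, 1] = best["m"][:, 1] / b
        logsd_coefs = np.zeros((k, deg + 1))
        for i in range(k):
            poly = np.polynomial.Polynomial(best["g"][i])(
                np.polynomial.Polynomial([-a / b, 1.0 / b])
            )
            logsd_coefs[i, : len(poly.coef)] = poly.coef
        self.n_components_ = k
        self.variance_form_ = best["form"]
        self.weights_ = best["pi"]
        self.lambda_ = np.log(best["pi"] / best["pi"][0])
        self.mean_coefs_ = mean_coefs
        self.logsd_coefs_ = logsd_coefs
        self.loglik_ = best["loglik"]
        self.loglik_trace_ = best["trace"]
        self.aic_ = best["aic"] if "aic" in best else np.nan

    def _fit_one(self, z, y, k, degree, rng: np.random.Generator) -> dict:
        phi = _design(z, degree)
        xmat = np.column_stack([np.ones_like(z), z])
        best = None
        for _ in range(self.n_restarts if k > 1 else 1):
            try:
                fit = self._ecm(z, y, phi, xmat, k, degree, rng)
            except EMError:
                continue
            if best is None or fit["loglik"] > best["loglik"]:
                best = fit
        if best is None:
            raise EMError(f"all restarts failed for K={k}, degree={degree}")
        return best

    def _ecm(self, z, y, phi, xmat, k, degree, rng) -> dict:
        n = z.size
        if k == 1:
            resp = np.ones((n, 1))
        else:
            km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31)))
            labels = km.fit_predict(y[:, None])
            resp = np.full((n, k), 0.05 / max(k - 1, 1))
            resp[np.arange(n), labels] = 0.95
        pi = resp.mean(axis=0)
        m = np.zeros((k, 2))
        g = np.zeros((k, degree + 1))
        for i in range(k):
            m[i] = _wls(xmat, y, resp[:, i])
            res = y - xmat @ m[i]
            g[i, 0] = 0.5 * np.log(
                max(np.sum(resp[:, i] * res**2) / max(resp[:, i].sum(), 1e-10), 1e-12)
            )

        trace: list[float] = []
        prev = -np.inf
        for _ in range(self.max_iter):
            log_comp = self._log_components(y, xmat, phi, pi, m, g)
            log_norm = logsumexp(log_comp, axis=1)
            ll = float(log_norm.sum())
            trace.append(ll)
            if not np.isfinite(ll):
                raise EMError("log-likelihood diverged")
            resp = np.exp(log_comp - log_norm[:, None])
            nk = resp.sum(axis=0)
            if (nk < 1e-8).any():
                raise EMError("empty component")
            pi = nk / n
            for i in range(k):
                sd2 = np.exp(2.0 * _logsd(phi, g[i]))
                m[i] = _wls(xmat, y, resp[:, i] / sd2)
                g[i] = _optimise_logsd(phi, y - xmat @ m[i], resp[:, i], g[i])
            if np.isfinite(prev) and ll - prev < self.tol * (1.0 + abs(ll)):
                break
            prev = ll
        _assert_monotone(trace)
        return {"pi": pi, "m": m, "g": g, "loglik": trace[-1], "trace": trace}

    @staticmethod
    def _log_components(y, xmat, phi, pi, m, g):
        k = len(pi)
        out = np.empty((y.size, k))
        for i in range(k):
            mu = xmat @ m[i]
            ls = _logsd(phi, g[i])
            out[:, i] = (
                np.log(pi[i])
                - 0.5 * np.log(2 * np.pi)
                - ls
                - 0.5 * (y - mu) ** 2 * np.exp(-2.0 * ls)
            )
        return out

    # -- fitted-model interface ---------------------------------------------

    def component_means(self, x) -> np.ndarray:
        """Per-component conditional means, shape (n, K)."""
        check_is_fitted(self, "mean_coefs_")
        x = np.asarray(x, float).ravel()
        return np.column_stack([np.ones_like(x), x]) @ self.mean_coefs_.T

    def component_sds(self, x) -> np.ndarray:
        """Per-component conditional standard deviations, shape (n, K)."""
        check_is_fitted(self, "logsd_coefs_")
        x = np.asarray(x, float).ravel()
        deg = self.logsd_coefs_.shape[1] - 1
        phi = _design(x, deg)
        return np.exp(np.clip(phi @ self.logsd_coefs_.T, -30, 30))

    def score_samples(self, X, y) -> np.ndarray:
        """Conditional log-density log p(y | x)."""
        x = np.asarray(X, float).ravel()
        y = np.asarray(y, float).ravel()
        mus = self.component_means(x)
        sds = self.component_sds(x)
        log_comp = (
            np.log(self.weights_)[None, :]
            - 0.5 * np.log(2 * np.pi)
            - np.log(sds)
            - 0.5 * ((y[:, None] - mus) / sds) ** 2
        )
        return logsumexp(log_comp, axis=1)

    def sample(self, x, random_state=None) -> np.ndarray:
        """Draw one y per entry of x from the fitted conditional mixture."""
        check_is_fitted(self, "weights_")
        rng = np.random.default_rng(random_state)
        x = np.asarray(x, float).ravel()
        comp = rng.choice(self.n_components_, size=x.size, p=self.weights_ / self.weights_.sum())
        mus = self.component_means(x)
        sds = self.component_sds(x)
        idx = np.arange(x.size)
        return rng.normal(mus[idx, comp], sds[idx, comp])


def _wls(xmat: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    wx = xmat * w[:, None]
    return np.linalg.solve(xmat.T @ wx + 1e-12 * np.eye(xmat.shape[1]), wx.T @ y)


def _optimise_logsd(phi, resid, w, g0) -> np.ndarray:
    """Maximise sum_j w_j [-phi_j.g - resid_j^2 exp(-2 phi_j.g)/2] over g."""
    r2 = resid**2

    def negq(g):
        u = np.clip(phi @ g, -50.0, 50.0)
        e = np.exp(-2.0 * u)
        val = np.sum(w * (u + 0.5 * r2 * e))
        grad = phi.T @ (w * (1.0 - r2 * e))
        return val, grad

    res = optimize.minimize(negq, g0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 50})
    # generalized EM: only accept an improvement
    return res.x if res.fun <= negq(g0)[0] else g0


def fit_lfc_mixture(x, y, k_range=(1, 2, 3, 4, 5), seed: int | None = None) -> ConditionalLfcMixture:
    """Functional wrapper: AIC-selected conditional LFC mixture."""
    return ConditionalLfcMixture(k_range=tuple(k_range), random_state=seed).fit(x, y)
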