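"""The fitted generative community model and its components.

A :class:`CommunityModel` bundles three fitted pieces:

* a Gaussian mixture for log2 mean abundance across taxa,
* a conditional Gaussian mixture for the log2 fold change given log2 mean
  abundance, and
* a dispersion-mean trend d(m) = scale * (c0 + c1 / m), where c0 is the
  asymptotic dispersion of high-abundance taxa and c1 the low-abundance
  excess.  The scale factor (default 0.3) compresses raw per-taxon
  dispersion estimates so that simulated coefficients of variation match
  observed data; it is applied at prediction time so the raw (c0, c1) fit
  stays inspectable.

Models serialise to a versioned human-readable YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares, nnls
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import CountMatrix
from .mixtures import ConditionalLfcMixture, GaussianMixtureModel
from . import nb

SCHEMA_VERSION = 1

#: default dispersion scale factor (calibrates simulated CVs to observed data)
DEFAULT_DISPERSION_SCALE = 0.3


class DispersionTrendModel(BaseEstimator):
    """Non-increasing dispersion-mean trend d(m) = scale * (c0 + c1 / m).

    Fitted by non-negative least squares of dispersion on (1, 1/m), with one
    robustness pass that drops points more than 10-fold off the first trend
    and refits.

    Parameters
    ----------
    scale : float in (0, 1], default 0.3
        Multiplier applied at prediction time.
    """

    def __init__(self, scale: float = DEFAULT_DISPERSION_SCALE):
        self.scale = scale

    def fit(self, base_means, dispersions):
        m = np.asarray(base_means, float).ravel()
        d = np.asarray(dispersions, float).ravel()
        ok = np.isfinite(m) & np.isfinite(d) & (m > 0) & (d >= 0)
        m, d = m[ok], d[ok]
        if m.size < 10:
            raise ValueError(f"need >= 10 usable taxa to fit the dispersion trend, got {m.size}")
        # robust first pass so gross outliers cannot corrupt the trim reference
        c0 = self._nnls_fit(m, d)
        robust = least_squares(
            lambda c: c[0] + c[1] / m - d, c0, loss="soft_l1", f_scale=0.1,
            bounds=([0.0, 0.0], [np.inf, np.inf]),
        ).x
        pred = robust[0] + robust[1] / m
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pred > 0, d / pred, np.inf)
        keep = (ratio < 10.0) & (ratio > 0.1)
        c = self._nnls_fit(m[keep], d[keep]) if 10 <= keep.sum() else self._nnls_fit(m, d)
        self.c0_, self.c1_ = float(c[0]), float(c[1])
        self.n_taxa_ = int(m.size)
        return self

    @staticmethod
    def _nnls_fit(m: np.ndarray, d: np.ndarray) -> np.ndarray:
        design = np.column_stack([np.ones_like(m), 1.0 / m])
        coef, _ = nnls(design, d)
        return coef

    def predict(self, base_means) -> np.ndarray:
        """Scaled dispersion at mean abundance m; floored at 1e-8 so it stays positive."""
        check_is_fitted(self, "c0_")
        m = np.asarray(base_means, float)
        return np.maximum(self.scale * (self.c0_ + self.c1_ / m), 1e-8)


@dataclass
class CommunityModel:
    """Fitted generative model of a case-control microbiome community."""

    mean_mixture: GaussianMixtureModel
    lfc_mixture: ConditionalLfcMixture
    dispersion_trend: DispersionTrendModel
    log_base: float = 2.0
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        check_is_fitted(self.mean_mixture, "weights_")
        check_is_fitted(self.lfc_mixture, "weights_")
        check_is_fitted(self.dispersion_trend, "c0_")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        mm, lm, dt = self.mean_mixture, self.lfc_mixture, self.dispersion_trend
        return {
            "schema_version": SCHEMA_VERSION,
            "log_base": self.log_base,
            "mean_mixture": {
                "weights": mm.weights_.tolist(),
                "means": mm.means_.tolist(),
                "sds": mm.sds_.tolist(),
                "selection": [
                    {
                        "k_null": int(t.k_null), "k_alt": int(t.k_alt),
                        "statistic": float(t.statistic), "p_value": float(t.p_value),
                        "n_bootstrap": int(t.n_bootstrap),
                    }
                    for t in getattr(mm, "selection_", [])
                ],
            },
            "lfc_mixture": {
                "weights": lm.weights_.tolist(),
                "mean_coefs": lm.mean_coefs_.tolist(),
                "logsd_coefs": lm.logsd_coefs_.tolist(),
                "variance_form": lm.variance_form_,
            },
            "dispersion_trend": {
                "c0": float(dt.c0_), "c1": float(dt.c1_), "scale": float(dt.scale),
            },
            "meta": {k: (v.item() if hasattr(v, "item") else v)
                     for k, v in self.meta.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityModel":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema: {d.get('schema_version')}")
        mm = GaussianMixtureModel()
        mmd = d["mean_mixture"]
        mm.weights_ = np.asarray(mmd["weights"], float)
        mm.means_ = np.asarray(mmd["means"], float)
        mm.sds_ = np.asarray(mmd["sds"], float)
        mm.n_components_ = len(mm.weights_)
        mm.selection_ = []
        lm = ConditionalLfcMixture()
        lmd = d["lfc_mixture"]
        lm.weights_ = np.asarray(lmd["weights"], float)
        lm.mean_coefs_ = np.asarray(lmd["mean_coefs"], float)
        lm.logsd_coefs_ = np.asarray(lmd["logsd_coefs"], float)
        lm.variance_form_ = lmd["variance_form"]
        lm.n_components_ = len(lm.weights_)
        lm.lambda_ = np.log(lm.weights_ / lm.weights_[0])
        dt = DispersionTrendModel(scale=float(d["dispersion_trend"]["scale"]))
        dt.c0_ = float(d["dispersion_trend"]["c0"])
        dt.c1_ = float(d["dispersion_trend"]["c1"])
        model = cls(mm, lm, dt, log_base=float(d.get("log_base", 2.0)),
                    meta=d.get("meta", {}))
        model.validate()
        return model

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CommunityModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def compute_taxon_summaries(
    cm: CountMatrix, estimates: pd.DataFrame, log_base: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-taxon (x, y): log2 arithmetic-mean normalized abundance and shrunken LFC.

    Taxa with zero base mean are excluded (they carry no abundance signal).
    """
    base_mean = estimates["base_mean"].to_numpy(float)
    lfc = estimates["lfc_shrunk"].to_numpy(float)
    ok = base_mean > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        import logging

        logging.getLogger(__name__).info(
            "excluded %d taxa with zero base mean from summaries", n_excluded
        )
    x = np.log(base_mean[ok]) / np.log(log_base)
    return x, lfc[ok]


def fit_dispersion_trend(base_means, dispersions, scale: float = DEFAULT_DISPERSION_SCALE) -> DispersionTrendModel:
    """Functional wrapper over :class:`DispersionTrendModel`."""
    return DispersionTrendModel(scale=scale).fit(base_means, dispersions)


def fit_community_model(
    cm: CountMatrix,
    k_max: int = 5,
    n_bootstrap: int = 100,
    bootstrap_level: float = 0.05,
    lfc_k_range: tuple[int, ...] = (1, 2, 3, 4, 5),
    dispersion_scale: float = DEFAULT_DISPERSION_SCALE,
    log_base: float = 2.0,
    seed: int | None = None,
    estimates: pd.DataFrame | None = None,
) -> CommunityModel:
    """Fit the full community model to a (pre-filtered) pilot count matrix.

    Runs the NB differential pipeline (unless ``estimates`` is supplied),
    fits the mean-abundance mixture with bootstrap order selection, the
    conditional LFC mixture by AIC, and the dispersion trend on taxa whose
    dispersion is off the Poisson boundary.
    """
    if estimates is None:
        estimates = nb.run_pipeline(cm)
    x, y = compute_taxon_summaries(cm, estimates, log_base=log_base)
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    s_mean, s_lfc = ss.spawn(2)
    mean_mixture = GaussianMixtureModel(
        k_max=k_max, n_bootstrap=n_bootstrap, level=bootstrap_level,
        random_state=int(s_mean.generate_state(1)[0] % 2**31),
    ).fit(x)
    lfc_mixture = ConditionalLfcMixture(
        k_range=lfc_k_range, random_state=int(s_lfc.generate_state(1)[0] % 2**31)
    ).fit(x, y)
    off_boundary = estimates["dispersion"].to_numpy(float) > 0
    trend = DispersionTrendModel(scale=dispersion_scale).fit(
        estimates.loc[off_boundary, "base_mean"],
        estimates.loc[off_boundary, "dispersion"],
    )
    model = CommunityModel(
        mean_mixture, lfc_mixture, trend, log_base=log_base,
        meta={"n_taxa_fit": int(cm.n_taxa), "seed": seed},
    )
    model.validate()
    return model
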