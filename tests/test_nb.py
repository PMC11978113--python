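"""The negative binomial Wald pipeline: size factors, dispersion, test, shrinkage, BH."""

import numpy as np
import pytest
from scipy import stats

from mbpower import (
    bh_adjust,
    estimate_dispersions,
    estimate_size_factors,
    shrink_lfc,
    wald_test,
)
from mbpower.io import CountMatrix

from conftest import make_counts


def nb_counts(rng, mu, alpha, size):
    if alpha <= 0:
        return rng.poisson(mu, size)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_counts([[3, 3, 3, 3], [8, 8, 8, 8]])
        assert np.allclose(estimate_size_factors(cm), 1.0)

    def test_doubled_column_scaling(self):
        base = np.array([[10, 20], [30, 60], [7, 14], [2, 4]])
        cm = make_counts(np.hstack([base, base]),
                         ["control", "treatment", "control", "treatment"])
        s = estimate_size_factors(cm)
        assert np.allclose(s[1] / s[0], 2.0)

    def test_hand_median_of_ratios(self):
        # refs: sqrt(200), sqrt(1800); both ratio columns are (1/sqrt2, sqrt2)
        cm = make_counts(np.array([[10, 20, 10, 20], [30, 60, 30, 60]]))
        s = estimate_size_factors(cm)
        expected = np.array([1 / np.sqrt(2), np.sqrt(2), 1 / np.sqrt(2), np.sqrt(2)])
        assert np.allclose(s, expected)
        assert np.isclose(stats.gmean(s), 1.0)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            estimate_size_factors(make_counts([[1, 0, 2, 3], [4, 0, 5, 6]]))


class TestDispersion:
    def test_poisson_taxon_estimated_near_zero(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            counts = rng.poisson(100.0, size=(1, 400))
            cm = make_counts(counts)
            a = estimate_dispersions(cm, np.ones(400))
            hits += a[0] < 0.05
        assert hits >= 45

    def test_nb_taxon_recovers_alpha(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(20):
            counts = nb_counts(rng, 100.0, 0.5, (1, 1000))
            cm = make_counts(counts)
            a = estimate_dispersions(cm, np.ones(1000))
            hits += 0.35 <= a[0] <= 0.65
        assert hits >= 18

    def test_constant_taxon_is_poisson_limit(self):
        cm = make_counts(np.full((1, 10), 17))
        assert estimate_dispersions(cm, np.ones(10))[0] == 0.0


class TestWald:
    def test_null_pvalues_calibrated(self):
        rng = np.random.default_rng(2)
        counts = nb_counts(rng, 50.0, 0.2, (500, 200))
        cm = make_counts(counts)
        res = wald_test(cm, np.ones(200), np.full(500, 0.2))
        rej = float(np.mean(res["p_value"] < 0.05))
        assert 0.03 <= rej <= 0.07

    def test_fourfold_change_detected(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(20):
            c = nb_counts(rng, 100.0, 0.1, (1, 100))
            t = nb_counts(rng, 400.0, 0.1, (1, 100))
            counts = np.hstack([c, t])
            cm = make_counts(counts, ["control"] * 100 + ["treatment"] * 100)
            sf = np.ones(200)
            res = wald_test(cm, sf, estimate_dispersions(cm, sf))
            hits += res["q_value"].iloc[0] < 0.1
        assert hits >= 19

    def test_lfc_matches_truth(self):
        rng = np.random.default_rng(4)
        c = nb_counts(rng, 100.0, 0.05, (40, 300))
        t = nb_counts(rng, 200.0, 0.05, (40, 300))
        cm = make_counts(np.hstack([c, t]), ["control"] * 300 + ["treatment"] * 300)
        res = wald_test(cm, np.ones(600), np.full(40, 0.05))
        assert np.allclose(res["lfc_raw"], 1.0, atol=0.15)

    def test_all_zero_taxon_flagged_and_excluded_from_bh(self):
        rng = np.random.default_rng(5)
        counts = np.vstack([np.zeros((1, 40), int), rng.poisson(20, (9, 40))])
        cm = make_counts(counts)
        res = wald_test(cm, np.ones(40), np.zeros(10))
        assert np.isnan(res["p_value"].iloc[0]) and np.isnan(res["q_value"].iloc[0])
        # BH denominator must be 9: the largest q equals the largest defined p
        defined = res.dropna(subset=["p_value"])
        assert np.isclose(defined["q_value"].max(),
                          min(1.0, defined["p_value"].max()))

    def test_group_relabel_flips_sign_keeps_pvalues(self):
        rng = np.random.default_rng(6)
        counts = nb_counts(rng, 60.0, 0.3, (30, 50))
        labels = np.array(["control"] * 25 + ["treatment"] * 25, object)
        flipped = np.where(labels == "control", "treatment", "control")
        cm1 = make_counts(counts, labels)
        cm2 = make_counts(counts, flipped)
        sf = estimate_size_factors(cm1)
        disp = estimate_dispersions(cm1, sf)
        r1 = wald_test(cm1, sf, disp)
        r2 = wald_test(cm2, sf, disp)
        assert np.allclose(r1["lfc_raw"], -r2["lfc_raw"], atol=1e-6)
        assert np.allclose(r1["p_value"], r2["p_value"], atol=1e-8)

    def test_agrees_with_statsmodels_glm(self):
        """Independent cross-check of the IRLS fit against statsmodels."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        counts = np.vstack(
            [np.hstack([nb_counts(rng, 50, 0.2, 20), nb_counts(rng, 120, 0.2, 20)])
             for _ in range(5)]
        )
        cm = make_counts(counts, ["control"] * 20 + ["treatment"] * 20)
        sf = estimate_size_factors(cm)
        disp = np.full(5, 0.2)
        res = wald_test(cm, sf, disp)
        X = sm.add_constant((cm.group == "treatment").astype(float))
        for i in range(5):
            glm = sm.GLM(
                cm.counts[i], X,
                family=sm.families.NegativeBinomial(alpha=0.2),
                offset=np.log(sf),
            ).fit()
            assert np.isclose(res["lfc_raw"].iloc[i], glm.params[1] / np.log(2), atol=1e-4)
            assert np.isclose(res["se_lfc"].iloc[i], glm.bse[1] / np.log(2), atol=1e-3)


class TestShrinkage:
    def test_small_se_unchanged_large_se_pulled_in(self):
        import pandas as pd

        est = pd.DataFrame(
            {
                "lfc_raw": [2.0, 20.0, 0.0],
                "se_lfc": [1e-6, 50.0, 1.0],
            }
        )
        out = shrink_lfc(est)
        assert np.isclose(out["lfc_shrunk"].iloc[0], 2.0, atol=1e-6)
        assert abs(out["lfc_shrunk"].iloc[1]) < abs(out["lfc_raw"].iloc[1])
        assert np.isfinite(out["lfc_shrunk"]).all()
        assert out["lfc_shrunk"].iloc[2] == 0.0
        assert (np.abs(out["lfc_shrunk"]) <= np.abs(out["lfc_raw"]) + 1e-12).all()


def bh_bruteforce(p):
    """Literal definition: q_i = min over {j : p_j >= p_i} of n*p_(j)/rank(j), capped."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(n, int)
    ranks[order] = np.arange(1, n + 1)
    q = np.empty(n)
    for i in range(n):
        cand = [n * p[j] / ranks[j] for j in range(n) if p[j] >= p[i]]
        q[i] = min(1.0, min(cand))
    return q


class TestBH:
    def test_single_p(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_textbook_vector(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_ties_all_equal(self):
        q = bh_adjust(np.full(7, 0.2))
        assert np.allclose(q, 0.2)

    def test_matches_bruteforce_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 100))
            q = bh_adjust(p)
            assert np.allclose(q, bh_bruteforce(p), atol=1e-12)
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_nan_propagates_without_affecting_others(self):
        p = np.array([0.01, np.nan, 0.04])
        q = bh_adjust(p)
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], bh_adjust(np.array([0.01, 0.04])))
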