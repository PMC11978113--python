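"""Power simulation outcomes, the monotone surface, summaries, and the sweep."""

import inspect

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mbpower import (
    MonotonePowerSurface,
    PowerSummary,
    fit_power_surface,
    power_summary,
    run_power_simulation,
    sample_size_sweep,
)


@pytest.fixture(scope="module")
def logistic_outcomes():
    """50k Bernoulli outcomes from a known monotone power surface."""
    rng = np.random.default_rng(0)
    x1 = rng.uniform(0, 10, 50000)
    x2 = rng.uniform(0, 4, 50000)
    p = expit(-3 + 0.3 * x1 + 1.5 * x2)
    y = (rng.random(50000) < p).astype(int)
    return pd.DataFrame({"sim": 0, "taxon": np.arange(50000), "x1": x1, "x2": x2,
                         "y": y, "q_value": np.nan})


@pytest.fixture(scope="module")
def logistic_surface(logistic_outcomes):
    return fit_power_surface(logistic_outcomes)


class TestOutcomeTable:
    def test_defaults_match_standard_design(self):
        sig = inspect.signature(run_power_simulation)
        assert sig.parameters["n_taxa"].default == 1000
        assert sig.parameters["n_per_group"].default == 100
        assert sig.parameters["n_sims"].default == 100

    def test_outcome_consistency_and_filtered_taxa(self, reference_model):
        out = run_power_simulation(
            reference_model, n_taxa=150, n_per_group=25, n_sims=2,
            alpha_sig=0.1, seed=1,
        )
        assert len(out) == 2 * 150
        tested = out.dropna(subset=["q_value"])
        assert ((tested["q_value"] < 0.1) == (tested["y"] == 1)).all()
        filtered = out[out["q_value"].isna()]
        assert (filtered["y"] == 0).all()
        assert np.isfinite(out[["x1", "x2"]].to_numpy()).all()

    def test_deterministic_under_seed(self, reference_model):
        a = run_power_simulation(reference_model, n_taxa=60, n_per_group=10,
                                 n_sims=2, seed=3)
        b = run_power_simulation(reference_model, n_taxa=60, n_per_group=10,
                                 n_sims=2, seed=3)
        assert a.equals(b)

    def test_strong_signals_nearly_always_detected(self, reference_model):
        out = run_power_simulation(
            reference_model, n_taxa=400, n_per_group=100, n_sims=2,
            alpha_sig=0.1, seed=4,
        )
        strong = out[(out["x2"] >= 2.0) & (out["x1"] >= 7.0)]
        assert len(strong) >= 10
        assert strong["y"].mean() >= 0.9


class TestMonotoneSurface:
    def test_recovers_known_logistic_surface(self, logistic_surface):
        g1, g2 = np.meshgrid(np.linspace(0.5, 9.5, 10), np.linspace(0.2, 3.8, 10))
        grid = np.column_stack([g1.ravel(), g2.ravel()])
        pred = logistic_surface.predict(grid)
        true = expit(-3 + 0.3 * grid[:, 0] + 1.5 * grid[:, 1])
        assert np.mean(np.abs(pred - true)) < 0.05

    def test_no_monotonicity_violations_on_grid(self, logistic_surface):
        g1 = np.linspace(*logistic_surface.box_[0], 20)
        g2 = np.linspace(*logistic_surface.box_[1], 20)
        gg1, gg2 = np.meshgrid(g1, g2, indexing="ij")
        z = logistic_surface.predict(
            np.column_stack([gg1.ravel(), gg2.ravel()])
        ).reshape(20, 20)
        assert (np.diff(z, axis=0) >= -1e-12).all()
        assert (np.diff(z, axis=1) >= -1e-12).all()

    def test_shuffled_outcomes_give_flat_surface(self, logistic_outcomes):
        rng = np.random.default_rng(5)
        shuffled = logistic_outcomes.copy()
        shuffled["y"] = rng.permutation(shuffled["y"].to_numpy())
        surf = fit_power_surface(shuffled)
        g1, g2 = np.meshgrid(np.linspace(0, 10, 15), np.linspace(0, 4, 15))
        pred = surf.predict(np.column_stack([g1.ravel(), g2.ravel()]))
        assert pred.max() - pred.min() < 0.1

    def test_binned_calibration(self, logistic_outcomes, logistic_surface):
        df = logistic_outcomes.copy()
        df["b1"] = pd.cut(df["x1"], 5)
        df["b2"] = pd.cut(df["x2"], 4)
        for (_, _), grp in df.groupby(["b1", "b2"], observed=True):
            if len(grp) < 200:
                continue
            emp = grp["y"].mean()
            pred = logistic_surface.predict(grp[["x1", "x2"]].to_numpy()).mean()
            assert abs(emp - pred) <= 0.1

    def test_predictions_clamped_outside_box(self, logistic_surface):
        inside = logistic_surface.predict([[9.99, 3.99]])[0]
        outside = logistic_surface.predict([[50.0, 50.0]])[0]
        assert outside == pytest.approx(
            logistic_surface.predict([[logistic_surface.box_[0, 1],
                                       logistic_surface.box_[1, 1]]])[0]
        )
        assert outside >= inside - 1e-12

    def test_constant_outcomes_rejected(self):
        df = pd.DataFrame({"x1": [1.0, 2.0], "x2": [1.0, 2.0], "y": [1, 1]})
        with pytest.raises(ValueError, match="identical"):
            MonotonePowerSurface().fit(df[["x1", "x2"]].to_numpy(), df["y"].to_numpy())


class TestPowerSummary:
    def test_expected_count_is_sum_and_n_times_mean(self):
        rng = np.random.default_rng(6)
        p = rng.beta(0.5, 2.0, 1000)
        s = PowerSummary(per_taxon_power=p, alpha_sig=0.1)
        assert s.expected_significant == pytest.approx(p.sum(), rel=1e-15)
        assert abs(s.expected_significant - s.n_taxa * s.average_power) <= 1e-12 * max(
            1.0, s.expected_significant
        )

    def test_uniform_half_power(self):
        s = PowerSummary(per_taxon_power=np.full(1000, 0.5), alpha_sig=0.1)
        assert s.expected_significant == pytest.approx(500.0)

    def test_right_skewed_powers_mean_exceeds_median(self):
        p = np.concatenate([np.full(90, 0.05), np.full(10, 0.95)])
        s = PowerSummary(per_taxon_power=p, alpha_sig=0.1)
        assert s.average_power > s.quantiles()[0.5]

    def test_summary_from_surface(self, logistic_surface):
        taxa = np.column_stack([np.linspace(1, 9, 50), np.linspace(0.5, 3.5, 50)])
        s = power_summary(logistic_surface, taxa, alpha_sig=0.1)
        assert 0.0 <= s.per_taxon_power.min() and s.per_taxon_power.max() <= 1.0
        assert abs(s.expected_significant - s.n_taxa * s.average_power) <= 1e-12 * max(
            1.0, s.expected_significant
        )

    def test_empty_taxa_rejected(self, logistic_surface):
        with pytest.raises(ValueError, match="empty"):
            power_summary(logistic_surface, np.empty((0, 2)))


class TestSweep:
    def test_defaults_match_standard_grid(self):
        sig = inspect.signature(sample_size_sweep)
        assert sig.parameters["sizes"].default == (30, 50, 70, 90, 110, 130, 150, 170, 190)
        assert sig.parameters["lfc_values"].default == (2.0, 3.0, 4.0)
        assert sig.parameters["x1_ref"].default == 5.0

    def test_tiny_sweep_schema_and_determinism(self, reference_model):
        kwargs = dict(model=reference_model, sizes=(10, 20), lfc_values=(2.0,),
                      n_taxa=60, n_sims=2, seed=7)
        a = sample_size_sweep(**kwargs)
        b = sample_size_sweep(**kwargs)
        assert a.equals(b)
        assert set(a.columns) == {"size", "lfc", "power", "mu", "average_power"}
        assert len(a) == 2
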