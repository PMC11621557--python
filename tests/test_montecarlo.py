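"""Monte Carlo propagation: fitting, seeding, collapse, and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import soilrisk as sr
from soilrisk.errors import ValidationError
from soilrisk.montecarlo import DistributionSpec, SimulationConfig, run_simulation


def constant_specs(values):
    return {m: DistributionSpec.constant(v) for m, v in values.items()}


class TestDistributionSpec:
    def test_family_and_param_validation(self):
        with pytest.raises(ValidationError):
            DistributionSpec("cauchy", {"loc": 0})
        with pytest.raises(ValidationError):
            DistributionSpec("gamma", {"shape": -1, "scale": 2})
        with pytest.raises(ValidationError):
            DistributionSpec("lognormal", {"mu": 0})  # missing sigma

    def test_constant_sampling(self):
        rng = np.random.default_rng(0)
        draws = DistributionSpec.constant(3.5).sample(100, rng)
        assert (draws == 3.5).all()

    def test_normal_truncation_keeps_draws_nonnegative(self):
        rng = np.random.default_rng(1)
        spec = DistributionSpec("normal", {"mean": 0.5, "sd": 1.0})
        assert (spec.sample(5000, rng) >= 0).all()

    def test_hopeless_truncation_hits_retry_cap(self):
        rng = np.random.default_rng(2)
        spec = DistributionSpec("normal", {"mean": -1e9, "sd": 1.0})
        with pytest.raises(ValidationError, match="cap"):
            spec.sample(100, rng)


class TestFitting:
    def test_degenerate_lognormal_returns_the_constant(self):
        spec = sr.fit_concentration_distribution([4.0, 4.0, 4.0], "lognormal")
        assert spec.params["sigma"] == 0.0
        draws = spec.sample(50, np.random.default_rng(0))
        np.testing.assert_allclose(draws, 4.0, rtol=1e-12)

    def test_gamma_method_of_moments(self):
        # sample mean 10, sample variance 25 -> shape 4, scale 2.5
        spec = sr.fit_concentration_distribution([5.0, 10.0, 15.0], "gamma")
        assert spec.params["shape"] == pytest.approx(4.0, rel=1e-12)
        assert spec.params["scale"] == pytest.approx(2.5, rel=1e-12)

    def test_nonpositive_values_rejected_for_log_families(self):
        with pytest.raises(ValidationError):
            sr.fit_concentration_distribution([1.0, 0.0, 2.0], "lognormal")

    @pytest.mark.parametrize("family, params", [
        ("lognormal", {"mu": 1.0, "sigma": 0.5}),
        ("gamma", {"shape": 4.0, "scale": 2.5}),
    ])
    def test_parameter_recovery_within_three_standard_errors(self, family, params):
        n = 10_000
        rng = np.random.default_rng(7)
        spec = DistributionSpec(family, params)
        fitted = sr.fit_concentration_distribution(spec.sample(n, rng), family)
        if family == "lognormal":
            se_mu = params["sigma"] / np.sqrt(n)
            se_sigma = params["sigma"] / np.sqrt(2 * (n - 1))
            assert abs(fitted.params["mu"] - params["mu"]) < 3 * se_mu
            assert abs(fitted.params["sigma"] - params["sigma"]) < 3 * se_sigma
        else:
            # asymptotic SEs of the moment estimators, via the delta method:
            # Var(shape) = 2k(k+1)/n, Var(scale) = theta^2 (2k+3)/(k n)
            k, th = params["shape"], params["scale"]
            se_shape = np.sqrt(2 * k * (k + 1) / n)
            se_scale = th * np.sqrt((2 * k + 3) / (k * n))
            assert abs(fitted.params["shape"] - k) < 3 * se_shape
            assert abs(fitted.params["scale"] - th) < 3 * se_scale

    def test_specs_from_samples_uses_declared_families(self, survey):
        specs = sr.specs_from_samples(survey)
        assert specs["Ni"].family == "gamma"
        assert specs["As"].family == "lognormal"


class TestSimulation:
    def test_all_constant_niter1_equals_pipeline_exactly(
        self, tiny_table, profiles, toxicity
    ):
        """Degenerate distributions collapse to the deterministic pipeline."""
        site = tiny_table.data.iloc[0]
        specs = constant_specs({m: float(site[m]) for m in tiny_table.panel})
        cfg = SimulationConfig(n_iter=1, seed=0)
        summary = run_simulation(specs, profiles, toxicity, cfg)

        one = tiny_table.data.iloc[[0]].reset_index(drop=True)
        det = sr.risk_pipeline(
            sr.SampleTable(one, tiny_table.panel), profiles, toxicity
        ).records
        for _, row in det.dropna(subset=["cr"]).iterrows():
            for stat in ("mean", "p5", "p50", "p95"):
                assert summary.value(
                    row["metal"], row["route"], row["age_group"], "cr", stat
                ) == row["cr"]
        for _, row in det.dropna(subset=["hq"]).iterrows():
            assert summary.value(
                row["metal"], row["route"], row["age_group"], "hq", "p50"
            ) == row["hq"]

    def test_same_seed_bitwise_identical_different_seed_close(
        self, profiles, toxicity
    ):
        specs = {"As": DistributionSpec("lognormal", {"mu": 1.0, "sigma": 0.5})}
        cfg = SimulationConfig(n_iter=2000, seed=11)
        a = run_simulation(specs, profiles, toxicity, cfg)
        b = run_simulation(specs, profiles, toxicity, cfg)
        pd.testing.assert_frame_equal(a.table, b.table)
        c = run_simulation(
            specs, profiles, toxicity, SimulationConfig(n_iter=2000, seed=12)
        )
        va = a.value("As", "oral", "adult", "cr", "mean")
        vc = c.value("As", "oral", "adult", "cr", "mean")
        assert va != vc
        assert vc == pytest.approx(va, rel=0.2)

    def test_percentile_monotonicity(self, survey, profiles, toxicity):
        cfg = SimulationConfig(n_iter=1000, seed=5)
        summary = run_simulation(survey, profiles, toxicity, cfg)
        wide = summary.table.pivot_table(
            index=["metal", "route", "age_group", "quantity"],
            columns="stat", values="value",
        )
        assert (wide["p5"] <= wide["p50"]).all()
        assert (wide["p50"] <= wide["p95"]).all()
        assert (wide >= 0).all().all()

    def test_scaling_a_constant_csf_scales_every_cr_statistic(
        self, profiles, toxicity
    ):
        specs = {"As": DistributionSpec("lognormal", {"mu": 1.0, "sigma": 0.5})}
        cfg = SimulationConfig(n_iter=500, seed=3)
        base = run_simulation(specs, profiles, toxicity, cfg)
        k = 4.0
        scaled_tox = dict(toxicity)
        scaled_tox["As"] = sr.ToxicityRecord(
            "As", RfD_ing=3e-4, RfD_derm=1.23e-4,
            CSF_ing=1.5 * k, CSF_derm=1.5 * k, CSF_inh=15.1 * k,
        )
        scaled = run_simulation(specs, profiles, scaled_tox, cfg)
        for stat in ("mean", "sd", "p5", "p50", "p95"):
            assert scaled.value("As", "oral", "adult", "cr", stat) == pytest.approx(
                k * base.value("As", "oral", "adult", "cr", stat), rel=1e-12
            )

    def test_lognormal_concentration_closed_form_oracle(self, profiles, toxicity):
        """Empirical CR mean and 95th percentile against lognormal identities."""
        mu, sigma, n = 1.0, 0.5, 10_000
        specs = {"As": DistributionSpec("lognormal", {"mu": mu, "sigma": sigma})}
        cfg = SimulationConfig(n_iter=n, seed=17)
        summary = run_simulation(specs, profiles, toxicity, cfg,
                                 routes=("oral",), age_groups=("adult",))
        p = profiles["adult"]
        scale = p.IR_ingestion / p.BW * 1e-6 * 1.5   # EF*ED/AT = 1/365 per day
        true_mean = scale * np.exp(mu + sigma**2 / 2)
        ln_sd = np.sqrt((np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2))
        mc_se = scale * ln_sd / np.sqrt(n)
        assert abs(summary.value("As", "oral", "adult", "cr", "mean") - true_mean) \
            < 3 * mc_se
        true_q95 = scale * np.exp(mu + sigma * scipy.stats.norm.ppf(0.95))
        assert summary.value("As", "oral", "adult", "cr", "p95") == pytest.approx(
            true_q95, rel=0.02
        )

    def test_stochastic_exposure_inputs_ride_the_profile(self, profiles, toxicity):
        specs = {"As": DistributionSpec.constant(100.0)}
        cfg = SimulationConfig(
            n_iter=4000, seed=23,
            inputs={"exposure.adult.BW": DistributionSpec("normal", {"mean": 70, "sd": 10})},
        )
        summary = run_simulation(specs, profiles, toxicity, cfg,
                                 routes=("oral",), age_groups=("adult",))
        det = 100.0 * 100.0 / 70.0 * 1e-6 * 1.5
        assert summary.value("As", "oral", "adult", "cr", "p5") < det
        assert summary.value("As", "oral", "adult", "cr", "p95") > det

    def test_fitted_survey_simulation_is_finite(self, survey, profiles, toxicity):
        cfg = SimulationConfig(n_iter=500, seed=9)
        summary = run_simulation(survey, profiles, toxicity, cfg)
        assert np.isfinite(summary.table["value"]).all()
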