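"""Threshold animal-model fits: determinism, null behaviour, bivariate limits."""

import numpy as np
import pytest

from haploquant import (
    ModelSpec,
    SimulationConfig,
    diagnostics,
    fit_bivariate,
    fit_univariate,
    genetic_correlation,
    simulate_dataset,
    trait_series,
    variance_proportions,
)


@pytest.fixture(scope="module")
def null_data():
    """Scores with no additive signal: liabilities are pure noise."""
    cfg = SimulationConfig(
        n_nests=40, brood_mean=8.0, v_additive=0.0, seed=17,
        cross_generation_links=0,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="module")
def heritable_data():
    cfg = SimulationConfig(
        n_nests=40, brood_mean=8.0, v_additive=3.0, seed=23,
        cross_generation_links=2,
    )
    return simulate_dataset(cfg)


class TestUnivariate:
    def test_null_additive_proportion_near_zero(self, null_data):
        ped, phen, _ = null_data
        fit = fit_univariate(
            trait_series(phen, "trait"), ped,
            ModelSpec(iterations=3000, burn_in=1000, thinning=3, seed=1),
        )
        vs = variance_proportions(fit)
        add = vs.components["additive"]
        assert add["proportion_mode"] < 0.2
        assert add["proportion_low"] < 0.05

    def test_deterministic_given_seed(self, heritable_data):
        ped, phen, _ = heritable_data
        spec = ModelSpec(iterations=800, burn_in=300, thinning=2, seed=9)
        a = fit_univariate(trait_series(phen, "trait"), ped, spec)
        b = fit_univariate(trait_series(phen, "trait"), ped, spec)
        np.testing.assert_array_equal(
            a.components["additive"], b.components["additive"]
        )
        np.testing.assert_array_equal(a.tau["trait"], b.tau["trait"])

    def test_retained_draw_count(self, heritable_data):
        ped, phen, _ = heritable_data
        spec = ModelSpec(iterations=1000, burn_in=400, thinning=3, seed=2)
        fit = fit_univariate(trait_series(phen, "trait"), ped, spec)
        assert fit.n_draws == (1000 - 400) // 3 == spec.n_retained

    def test_variance_draws_positive_thresholds_increasing(self, heritable_data):
        ped, phen, _ = heritable_data
        spec = ModelSpec(iterations=800, burn_in=300, thinning=2, seed=4)
        fit = fit_univariate(trait_series(phen, "trait"), ped, spec)
        assert np.all(fit.components["additive"] > 0)
        tau = fit.tau["trait"]
        full = np.column_stack([np.zeros(len(tau)), tau])
        assert np.all(np.diff(full, axis=1) > 0)

    def test_single_category_trait_fatal(self, heritable_data):
        ped, phen, _ = heritable_data
        scores = trait_series(phen, "trait") * 0
        with pytest.raises(ValueError, match="single observed category"):
            fit_univariate(scores, ped, ModelSpec(iterations=100, burn_in=50, thinning=1))

    def test_diagnostics_reported(self, heritable_data):
        ped, phen, _ = heritable_data
        spec = ModelSpec(iterations=1500, burn_in=500, thinning=2, seed=5)
        fit = fit_univariate(trait_series(phen, "trait"), ped, spec)
        diag = diagnostics(fit)
        assert "additive" in diag
        assert diag["additive"]["ess"] > 0
        assert np.isfinite(diag["additive"]["rhat"])


class TestPriorRobustness:
    def test_prior_scale_times_ten_moves_mode_little(self, heritable_data):
        """Additive-proportion mode shifts < 0.1 when variance-prior scale x10."""
        ped, phen, _ = heritable_data
        scores = trait_series(phen, "trait")
        base = ModelSpec(iterations=4000, burn_in=1500, thinning=3, seed=11)
        wide = base.replace(prior_scale=10.0)
        modes = []
        for spec in (base, wide):
            fit = fit_univariate(scores, ped, spec)
            vs = variance_proportions(fit)
            modes.append(vs.components["additive"]["proportion_mode"])
        assert abs(modes[0] - modes[1]) < 0.1


class TestBivariate:
    def test_self_paired_trait_correlation_near_one(self):
        """A trait paired with itself recovers a genetic correlation near 1.

        Duplicated scores share the same breeding values; only the
        independent residuals differ, so r_G must concentrate high.
        """
        cfg = SimulationConfig(
            n_nests=30, brood_mean=8.0, v_additive=4.0, seed=31,
            cross_generation_links=0,
        )
        ped, phen, _ = simulate_dataset(cfg)
        scores = trait_series(phen, "trait")
        spec = ModelSpec(iterations=4000, burn_in=1500, thinning=3, seed=7)
        fit = fit_bivariate(scores, scores, ped, spec)
        rg = genetic_correlation(fit)
        assert np.median(rg["draws"]) > 0.8
        assert rg["significant"]

    def test_null_correlation_interval_contains_zero(self):
        g = np.diag([3.0, 3.0])
        cfg = SimulationConfig(
            n_nests=30, brood_mean=8.0, g_additive=g,
            trait_names=("t1", "t2"), seed=37, cross_generation_links=0,
        )
        ped, phen, _ = simulate_dataset(cfg)
        spec = ModelSpec(iterations=4000, burn_in=1500, thinning=3, seed=8)
        fit = fit_bivariate(
            trait_series(phen, "t1"), trait_series(phen, "t2"), ped, spec
        )
        rg = genetic_correlation(fit)
        assert rg["low"] < 0.0 < rg["high"]

    def test_maternal_term_unsupported(self, heritable_data):
        ped, phen, _ = heritable_data
        scores = trait_series(phen, "trait")
        spec = ModelSpec(
            random_terms=("additive", "maternal"),
            iterations=100, burn_in=50, thinning=1,
        )
        with pytest.raises(NotImplementedError):
            fit_bivariate(scores, scores, ped, spec)

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(
            n_nests=10, brood_mean=5.0, seed=41, cross_generation_links=0
        )
        ped, phen, _ = simulate_dataset(cfg)
        scores = trait_series(phen, "trait")
        spec = ModelSpec(iterations=400, burn_in=150, thinning=1, seed=12)
        a = fit_bivariate(scores, scores, ped, spec)
        b = fit_bivariate(scores, scores, ped, spec)
        np.testing.assert_array_equal(a.g_additive, b.g_additive)
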