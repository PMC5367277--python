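"""Gibbs full conditionals checked against grid-integration oracles.

All checks use a three-female pedigree (dam + two full-sister daughters)
whose haplodiploid relationship matrix is small enough for brute-force
numerical integration of the unnormalized conditional densities.
"""

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import invgamma

from haploquant import Individual, ModelSpec, Pedigree, additive_matrix
from haploquant.animal_model import (
    _OrdinalGibbs,
    _dam_year_codes,
    _sample_truncated_normal,
)


@pytest.fixture
def trio():
    ped = Pedigree(
        [
            Individual("dam", "female", nest="n"),
            Individual("sire", "male", nest="n"),
            Individual("d1", "female", dam="dam", sire="sire", nest="n"),
            Individual("d2", "female", dam="dam", sire="sire", nest="n"),
        ]
    )
    ids = ("dam", "d1", "d2")
    s = additive_matrix(ped, ids)
    y = np.array([0, 1, 2])
    spec = ModelSpec(iterations=20, burn_in=10, thinning=1, seed=3, n_levels=3)
    dam_codes, year_codes = _dam_year_codes(ped, ids)
    sampler = _OrdinalGibbs(y, s, dam_codes, year_codes, spec)
    return sampler, s


def _grid_moments(grid, log_density):
    w = np.exp(log_density - log_density.max())
    w /= np.trapezoid(w, grid)
    mean = np.trapezoid(w * grid, grid)
    var = np.trapezoid(w * (grid - mean) ** 2, grid)
    return mean, var


class TestLiabilityConditional:
    def test_truncated_normal_matches_grid(self, trio):
        """The liability update targets N(eta, 1) confined to the category window."""
        sampler, _ = trio
        eta, lo, hi = 0.3, 0.0, 1.2
        grid = np.linspace(lo + 1e-9, hi - 1e-9, 4001)
        log_dens = -0.5 * (grid - eta) ** 2
        g_mean, g_var = _grid_moments(grid, log_dens)
        rng = np.random.default_rng(0)
        draws = _sample_truncated_normal(
            rng, np.full(200_000, eta), np.full(200_000, lo), np.full(200_000, hi)
        )
        assert np.all((draws > lo) & (draws < hi))
        assert draws.mean() == pytest.approx(g_mean, abs=0.005)
        assert draws.var() == pytest.approx(g_var, abs=0.005)


class TestBreedingValueConditional:
    def test_blocked_update_matches_grid(self, trio):
        """Single-site conditional of one breeding value vs 1-D grid integration.

        The blocked eigenbasis update implies a | l ~ N(M r, M) with
        M = (I + S^{-1}/V_A)^{-1}.  The conditional of a_i given the other
        breeding values from that joint must match the density
        p(a_i | a_-i, l) found by integrating prior x likelihood on a grid.
        """
        sampler, s = trio
        v_a = 2.0
        sampler.v["additive"] = v_a
        rng = np.random.default_rng(1)
        liab = np.array([0.4, -0.3, 0.9])
        mu = 0.1
        r = liab - mu
        s_inv = np.linalg.inv(s.values)
        prec = np.eye(3) + s_inv / v_a  # joint conditional precision
        # conditional of a_0 given a_1, a_2 from the joint Gaussian
        a_rest = np.array([0.2, -0.1])
        cond_var = 1.0 / prec[0, 0]
        joint_mean = np.linalg.solve(prec, r)
        cond_mean = joint_mean[0] - cond_var * prec[0, 1:] @ (a_rest - joint_mean[1:])
        # oracle: grid over a_0 of  N(l_0; mu + a_0, 1) * N((a_0, a_rest); 0, V_A S)
        grid = np.linspace(-5, 5, 8001)
        log_dens = np.empty_like(grid)
        for k, a0 in enumerate(grid):
            a = np.array([a0, *a_rest])
            log_dens[k] = -0.5 * (liab[0] - mu - a0) ** 2 - 0.5 * a @ s_inv @ a / v_a
        g_mean, g_var = _grid_moments(grid, log_dens)
        assert cond_mean == pytest.approx(g_mean, abs=1e-3)
        assert cond_var == pytest.approx(g_var, rel=1e-3)

    def test_eigenbasis_update_equals_direct_solve(self, trio):
        """Rotated-coordinate conditional mean equals (I + S^{-1}/V_A)^{-1} r."""
        sampler, s = trio
        sampler.v["additive"] = 3.0
        r = np.array([0.5, -1.0, 0.7])
        mean_rot, var_rot = sampler.additive_conditional(sampler.u.T @ r)
        mean_direct = np.linalg.solve(
            np.eye(3) + np.linalg.inv(s.values) / 3.0, r
        )
        np.testing.assert_allclose(sampler.u @ mean_rot, mean_direct, atol=1e-10)


class TestVarianceConditional:
    def test_inverse_gamma_matches_grid(self, trio):
        """V_A full conditional density equals prior x likelihood on a grid."""
        sampler, s = trio
        sampler.a = np.array([0.8, -0.5, 0.3])
        shape, rate = sampler.variance_conditional("additive")
        s_inv = np.linalg.inv(s.values)
        q = sampler.a @ s_inv @ sampler.a
        nu0, s0 = sampler.spec.prior_nu, sampler.spec.prior_scale
        grid = np.linspace(0.01, 20.0, 20_000)
        log_dens = (
            -0.5 * (nu0 + 3 + 2) * np.log(grid)  # prior and likelihood powers
            + np.zeros_like(grid)
        )
        # assemble explicitly: prior V^-(nu0/2+1) e^{-nu0 s0/2V}, lik V^{-n/2} e^{-q/2V}
        log_dens = (
            -(nu0 / 2 + 1) * np.log(grid)
            - nu0 * s0 / (2 * grid)
            - (3 / 2) * np.log(grid)
            - q / (2 * grid)
        )
        # identical shapes up to normalization: log-density difference constant
        ref = invgamma.logpdf(grid, a=shape, scale=rate)
        diff = log_dens - ref
        assert np.std(diff) < 1e-9

    def test_sampler_uses_matching_quadratic_form(self, trio):
        sampler, s = trio
        sampler.a = np.array([0.8, -0.5, 0.3])
        shape, rate = sampler.variance_conditional("additive")
        q = sampler.a @ np.linalg.inv(s.values) @ sampler.a
        nu0, s0 = sampler.spec.prior_nu, sampler.spec.prior_scale
        assert shape == pytest.approx(0.5 * (nu0 + 3))
        assert rate == pytest.approx(0.5 * (nu0 * s0 + q), rel=1e-9)


class TestThresholdMove:
    def test_collapsed_move_stationary_distribution(self, trio):
        """The threshold chain's stationary law matches a 1-D grid posterior.

        With the linear predictor pinned at zero and y = (0, 1, 2), the only
        free threshold gap g = tau_2 has posterior proportional to
        Phi(0) * [Phi(g) - Phi(0)] * [1 - Phi(g)] * Gamma(g; shape, rate).
        The collapsed MH move plus the liability redraw must reproduce its
        mean and variance.
        """
        sampler, _ = trio
        sampler.eta = np.zeros(3)
        shape = sampler.spec.prior_tau_shape
        rate = sampler.spec.prior_tau_rate

        grid = np.linspace(1e-4, 12.0, 12_000)
        log_dens = (
            np.log(ndtr(grid) - 0.5)
            + np.log(1.0 - ndtr(grid))
            + (shape - 1.0) * np.log(grid)
            - rate * grid
        )
        g_mean, g_var = _grid_moments(grid, log_dens)

        draws = []
        for it in range(30_000):
            sampler._update_thresholds()
            sampler.liab = sampler._draw_liabilities()
            if it >= 2_000:
                draws.append(sampler.cuts[2])
        draws = np.asarray(draws)
        assert draws.mean() == pytest.approx(g_mean, abs=0.06)
        assert draws.std() == pytest.approx(np.sqrt(g_var), rel=0.12)
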