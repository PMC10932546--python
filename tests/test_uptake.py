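"""Plasmid uptake model: closed forms, simulation, enumeration oracle, fitting."""

import itertools
import math

import numpy as np
import pytest

from pcdhgamma import (
    ColorFractions,
    Plasmid,
    UptakeDesign,
    UptakeParams,
    expected_mean_types,
    fit_mu_sigma,
    fixed_n_fractions,
    normal_n_fractions,
    simulate_uptake,
    six_plasmid_design,
    two_plasmid_design,
)


class TestDesign:
    def test_six_plasmid_green_fraction(self):
        assert six_plasmid_design().q_green == pytest.approx(5 / 6)

    def test_two_plasmid_green_fraction(self):
        assert two_plasmid_design().q_green == pytest.approx(1 / 2)

    def test_single_color_rejected(self):
        with pytest.raises(ValueError):
            UptakeDesign(plasmids=(Plasmid("a", "green"), Plasmid("b", "green")))

    def test_molar_weights_set_draw_probabilities(self):
        d = UptakeDesign(plasmids=(Plasmid("a", "green", 3.0),
                                   Plasmid("b", "red", 1.0)))
        assert d.q_green == pytest.approx(0.75)


class TestFixedN:
    def test_single_plasmid_cannot_be_both_colors(self):
        assert fixed_n_fractions(two_plasmid_design(), 1).r_co == 0.0

    def test_single_draw_red_fraction(self):
        assert fixed_n_fractions(six_plasmid_design(), 1).r_red_in_total == (
            pytest.approx(1 / 6))

    def test_red_in_total_at_n18(self):
        f = fixed_n_fractions(six_plasmid_design(), 18)
        assert f.r_red_in_total == pytest.approx(1 - (5 / 6) ** 18)
        assert f.r_red_in_total == pytest.approx(0.9624, abs=1e-4)

    def test_fraction_conservation_and_red_identity(self):
        for n in (1, 2, 7, 30):
            f = fixed_n_fractions(six_plasmid_design(), n)
            assert f.r_gfp_only + f.r_rfp_only + f.r_co == pytest.approx(1.0)
            assert f.r_red_in_total == pytest.approx(f.r_co + f.r_rfp_only)

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            fixed_n_fractions(six_plasmid_design(), 0)


class TestEnumerationOracle:
    """Brute force over all 6^n equally likely draw sequences."""

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_color_fractions_exact(self, n):
        design = six_plasmid_design()
        green = set(range(5))  # species 0-4 green, species 5 red
        tallies = {"g": 0, "r": 0, "co": 0}
        total = 0
        for seq in itertools.product(range(6), repeat=n):
            total += 1
            has_g = any(s in green for s in seq)
            has_r = 5 in seq
            if has_g and has_r:
                tallies["co"] += 1
            elif has_g:
                tallies["g"] += 1
            else:
                tallies["r"] += 1
        f = fixed_n_fractions(design, n)
        assert f.r_gfp_only == pytest.approx(tallies["g"] / total, abs=1e-12)
        assert f.r_rfp_only == pytest.approx(tallies["r"] / total, abs=1e-12)
        assert f.r_co == pytest.approx(tallies["co"] / total, abs=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_distinct_type_expectation_exact(self, n):
        design = six_plasmid_design()
        total = types_sum = 0
        for seq in itertools.product(range(6), repeat=n):
            total += 1
            types_sum += len(set(seq))
        assert expected_mean_types(design, n) == pytest.approx(
            types_sum / total, abs=1e-12)


class TestSimulation:
    def test_headline_mean_types(self):
        res = simulate_uptake(six_plasmid_design(), UptakeParams(18, 6, 10_000),
                              seed=0)
        assert res.mean_types == pytest.approx(5.6, abs=0.05)

    def test_degenerate_single_plasmid_cells(self):
        res = simulate_uptake(six_plasmid_design(), UptakeParams(1, 0, 2000),
                              seed=1)
        assert np.all(res.per_cell_types == 1)
        assert res.fractions.r_co == 0.0

    @pytest.mark.parametrize("n", [3, 10, 25])
    def test_sigma_zero_matches_closed_form(self, n):
        res = simulate_uptake(six_plasmid_design(), UptakeParams(n, 0, 20_000),
                              seed=2)
        expect = expected_mean_types(six_plasmid_design(), n)
        # binomial-ish MC error on the mean of 20k cells
        assert res.mean_types == pytest.approx(expect, abs=0.05)

    def test_mean_types_monotone_in_mu(self):
        means = [simulate_uptake(six_plasmid_design(), UptakeParams(mu, 3, 5000),
                                 seed=3).mean_types for mu in (2, 6, 12, 24)]
        assert means == sorted(means)

    def test_types_bounded_by_n_and_species(self):
        res = simulate_uptake(six_plasmid_design(), UptakeParams(4, 3, 1000),
                              seed=4)
        assert np.all(res.per_cell_types >= 1)
        assert np.all(res.per_cell_types <= np.minimum(res.per_cell_n, 6))

    def test_deterministic_given_seed(self):
        a = simulate_uptake(six_plasmid_design(), UptakeParams(18, 6, 500), seed=5)
        b = simulate_uptake(six_plasmid_design(), UptakeParams(18, 6, 500), seed=5)
        np.testing.assert_array_equal(a.per_cell_types, b.per_cell_types)

    def test_simulation_fraction_conservation(self):
        f = simulate_uptake(six_plasmid_design(), UptakeParams(18, 6, 5000),
                            seed=6).fractions
        assert f.r_gfp_only + f.r_rfp_only + f.r_co == pytest.approx(1.0)


class TestNormalNFractions:
    def test_sigma_zero_reduces_to_fixed_n(self):
        f = normal_n_fractions(six_plasmid_design(), UptakeParams(18, 0, 1000),
                               seed=0)
        g = fixed_n_fractions(six_plasmid_design(), 18)
        assert f.r_red_in_total == pytest.approx(g.r_red_in_total)
        assert f.r_rfp_only == pytest.approx(g.r_rfp_only)

    def test_two_plasmid_mu1_no_coexpression(self):
        f = normal_n_fractions(two_plasmid_design(), UptakeParams(1, 0, 100),
                               seed=0)
        assert f.r_co == pytest.approx(0.0)

    def test_agrees_with_simulation(self):
        params = UptakeParams(18, 6, 50_000)
        analytic = normal_n_fractions(six_plasmid_design(), params, seed=1)
        sim = simulate_uptake(six_plasmid_design(), params, seed=2)
        assert sim.fractions.r_red_in_total == pytest.approx(
            analytic.r_red_in_total, abs=0.01)

    def test_matches_discretized_normal_expectation(self):
        # independent oracle: numerically average 1-(5/6)^n over the
        # discretized, truncated normal pmf
        mu, sigma = 18, 6
        from scipy import stats

        ns = np.arange(-20, 61)
        pmf = stats.norm.cdf(ns + 0.5, mu, sigma) - stats.norm.cdf(ns - 0.5, mu, sigma)
        ns_trunc = np.maximum(ns, 1)
        oracle = np.sum(pmf * (1 - (5 / 6) ** ns_trunc)) / pmf.sum()
        f = normal_n_fractions(six_plasmid_design(), UptakeParams(mu, sigma, 200_000),
                               seed=3)
        assert f.r_red_in_total == pytest.approx(oracle, abs=0.002)


class TestFit:
    def test_single_draw_signature_recovers_mu1_sigma0(self):
        observed = ColorFractions(r_gfp_only=5 / 6, r_rfp_only=1 / 6, r_co=0.0)
        fit = fit_mu_sigma(observed, six_plasmid_design(),
                           mu_grid=range(1, 11), sigma_grid=range(0, 6),
                           k=2000, seed=0)
        assert (fit.mu, fit.sigma) == (1, 0)

    def test_recovery_at_sigma_zero(self):
        truth = normal_n_fractions(six_plasmid_design(), UptakeParams(10, 0, 20_000),
                                   seed=5)
        fit = fit_mu_sigma(truth, six_plasmid_design(),
                           mu_grid=range(1, 21), sigma_grid=range(0, 6),
                           k=20_000, seed=6)
        assert fit.mu == 10
        assert fit.sigma in (0, 1)

    def test_self_generated_recovery_is_exact(self):
        # observations generated by the model with the fitting seed and k
        # are recovered exactly (common random numbers across the grid)
        truth = normal_n_fractions(six_plasmid_design(), UptakeParams(18, 6, 20_000),
                                   seed=9)
        fit = fit_mu_sigma(truth, six_plasmid_design(),
                           mu_grid=range(12, 25), sigma_grid=range(0, 11),
                           k=20_000, seed=9)
        assert (fit.mu, fit.sigma) == (18, 6)

    def test_objective_surface_shape_and_empty_grid(self):
        observed = ColorFractions(r_gfp_only=5 / 6, r_rfp_only=1 / 6, r_co=0.0)
        fit = fit_mu_sigma(observed, six_plasmid_design(),
                           mu_grid=range(1, 4), sigma_grid=range(0, 3),
                           k=500, seed=0)
        assert fit.objective.shape == (3, 3)
        with pytest.raises(ValueError):
            fit_mu_sigma(observed, six_plasmid_design(), mu_grid=[],
                         sigma_grid=range(3), k=100, seed=0)
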