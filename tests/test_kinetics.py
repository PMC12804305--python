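"""Decay-chain math and effective-half-life fitting."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from biodist import (BatemanSystem, WholeBodySeries, bateman_daughter,
                     daughter_peak_time, fit_effective_half_life,
                     generate_wholebody, get_nuclide, mother_from_daughter,
                     secular_daughter, time_to_equilibrium, transient_ratio)

LN2 = math.log(2.0)


def _ode_daughter(A_m0, lam_m, lam_d, BR, t):
    """Independent oracle: integrate dN/dt for the mother-daughter pair."""
    n_m0 = A_m0 / lam_m if lam_m > 0 else A_m0  # atoms (arbitrary scale)

    def rhs(_, y):
        n_m, n_d = y
        return [-lam_m * n_m, BR * lam_m * n_m - lam_d * n_d]

    if lam_m == 0:  # constant mother feeding the daughter
        def rhs(_, y):  # noqa: F811
            return [0.0, BR * A_m0 - lam_d * y[1]]
        n_m0 = A_m0

    sol = solve_ivp(rhs, (0.0, t), [n_m0, 0.0], rtol=1e-11, atol=1e-14,
                    dense_output=True)
    return lam_d * sol.y[1, -1]


class TestBateman:
    def test_daughter_starts_at_zero(self):
        sys_ = BatemanSystem(A_m0=100.0, lambda_m=0.1, lambda_d=1.0)
        assert bateman_daughter(sys_, 0.0) == 0.0

    def test_secular_case_reaches_half_after_one_daughter_half_life(self):
        lam_d = 2.0
        sys_ = BatemanSystem(A_m0=100.0, lambda_m=0.0, lambda_d=lam_d, BR=1.0)
        assert bateman_daughter(sys_, LN2 / lam_d) == pytest.approx(50.0)

    def test_against_numerical_integration(self):
        got = bateman_daughter(
            BatemanSystem(A_m0=100.0, lambda_m=0.1, lambda_d=1.0, BR=1.0), 2.0)
        assert got == pytest.approx(75.93, abs=0.01)
        assert got == pytest.approx(_ode_daughter(100.0, 0.1, 1.0, 1.0, 2.0),
                                    rel=1e-8)

    @pytest.mark.parametrize("lam_m", [0.0, 0.01, 0.3, 0.999, 1.0 - 1e-13])
    @pytest.mark.parametrize("t", [0.3, 2.0, 7.0])
    def test_matches_ode_over_grid_including_near_degenerate(self, lam_m, t):
        lam_d = 1.0
        sys_ = BatemanSystem(A_m0=50.0, lambda_m=lam_m, lambda_d=lam_d, BR=0.9)
        assert bateman_daughter(sys_, t) == pytest.approx(
            _ode_daughter(50.0, lam_m, lam_d, 0.9, t), rel=1e-8)

    def test_degenerate_rates_use_analytic_limit(self):
        lam = 0.5
        sys_ = BatemanSystem(A_m0=10.0, lambda_m=lam, lambda_d=lam, BR=1.0)
        t = 3.0
        assert bateman_daughter(sys_, t) == pytest.approx(
            10.0 * lam * t * math.exp(-lam * t), rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            bateman_daughter(BatemanSystem(1.0, 0.0, 1.0), -1.0)


class TestSecular:
    def test_asymptote_after_ten_half_lives(self):
        lam_d = 1.0
        got = secular_daughter(100.0, lam_d, 1.0, 10 * LN2 / lam_d)
        assert got == pytest.approx(0.999 * 100.0, abs=0.1)

    def test_half_ingrowth_after_one_half_life(self):
        lam_d = 3.7
        assert secular_daughter(80.0, lam_d, 0.5, LN2 / lam_d) == \
            pytest.approx(0.5 * 80.0 * 0.5)

    def test_is_the_stable_mother_limit_of_full_bateman(self):
        lam_d = 1.0
        for t in np.linspace(0.1, 20.0, 25):
            full = bateman_daughter(
                BatemanSystem(A_m0=42.0, lambda_m=1e-12, lambda_d=lam_d,
                              BR=0.8), t)
            simple = secular_daughter(42.0, lam_d, 0.8, t)
            assert full == pytest.approx(simple, rel=1e-9)


class TestEquilibriumTiming:
    def test_half_fraction_is_one_daughter_half_life(self):
        lam_d = 0.37
        assert time_to_equilibrium(lam_d, 0.5) == pytest.approx(LN2 / lam_d)

    def test_99_percent_for_a_45p6_min_daughter_is_about_5_hours(self):
        lam_d = LN2 / (45.6 / 60.0)  # per hour
        t = time_to_equilibrium(lam_d, 0.99)
        assert t == pytest.approx(302.9 / 60.0, abs=0.01)
        assert round(t) == 5

    def test_95_percent_needs_five_integer_half_lives(self):
        n = next(n for n in range(1, 20) if 1 - 2.0 ** -n >= 0.95)
        assert n == 5

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_bounds(self, fraction):
        with pytest.raises(ValueError):
            time_to_equilibrium(1.0, fraction)


class TestTransient:
    def test_ratio_formula(self):
        assert transient_ratio(0.1, 1.0, 1.0) == pytest.approx(10.0 / 9.0)

    def test_secular_limit_of_ratio(self):
        assert transient_ratio(0.0, 1.0, 0.7) == pytest.approx(0.7)

    def test_equal_rates_have_no_transient_equilibrium(self):
        with pytest.raises(ValueError):
            transient_ratio(1.0, 1.0)

    def test_daughter_peak_matches_analytic_argmax(self):
        lam_m, lam_d = 0.2, 1.3
        t_max = daughter_peak_time(lam_m, lam_d)
        sys_ = BatemanSystem(A_m0=1.0, lambda_m=lam_m, lambda_d=lam_d)
        grid = np.linspace(0.0, 10.0, 20001)
        numeric = grid[int(np.argmax(bateman_daughter(sys_, grid)))]
        assert t_max == pytest.approx(numeric, abs=1e-3)


class TestMotherFromDaughter:
    def test_equilibrium_identity(self):
        lam_d = 2.0
        a_d = secular_daughter(7.0, lam_d, 1.0, 20.0 / lam_d)
        assert mother_from_daughter(a_d, 20.0 / lam_d, 0.0, lam_d) == \
            pytest.approx(7.0, rel=1e-6)

    def test_round_trip_inversion(self):
        sys_ = BatemanSystem(A_m0=7.3, lambda_m=0.03, lambda_d=0.9, BR=0.85)
        a_d = bateman_daughter(sys_, 4.0)
        assert mother_from_daughter(a_d, 4.0, 0.03, 0.9, 0.85) == \
            pytest.approx(7.3, rel=1e-12)

    def test_radium_lead_generator_scenario(self):
        # Ra-224 breakthrough assay: remeasure ~5 days after elution so the
        # initially eluted Pb-212 has decayed and fresh Pb-212 is in
        # equilibrium with the remaining Ra-224
        lam_m = get_nuclide("Ra-224").lam_per_hour
        lam_d = get_nuclide("Pb-212").lam_per_hour
        assert lam_m == pytest.approx(LN2 / (3.63 * 24.0), rel=1e-12)
        assert lam_d == pytest.approx(LN2 / 10.6, rel=1e-12)
        a_m0 = 0.37  # MBq of Ra-224 breakthrough
        t = 5 * 24.0
        a_d = bateman_daughter(
            BatemanSystem(A_m0=a_m0, lambda_m=lam_m, lambda_d=lam_d), t)
        assert mother_from_daughter(a_d, t, lam_m, lam_d) == \
            pytest.approx(a_m0, rel=1e-9)

    def test_too_early_inversion_is_ill_conditioned(self):
        with pytest.raises(ValueError, match="ill-conditioned"):
            mother_from_daughter(1.0, 1e-9, 0.0, 1.0)


class TestEffectiveHalfLifeFit:
    def test_exact_one_phase_recovery(self):
        t = np.linspace(0.0, 300.0, 8)
        a = 100.0 * np.exp(-0.01 * t)
        fit = fit_effective_half_life(WholeBodySeries("m1", t, a),
                                      model="one_phase")
        assert fit.rates[0] == pytest.approx(0.01, rel=1e-6)
        assert fit.t_half_eff[0] == pytest.approx(69.3147, abs=1e-3)
        assert fit.amplitudes[0] == pytest.approx(100.0, rel=1e-6)

    def test_auto_collapses_degenerate_two_phase_to_one(self):
        t = np.linspace(0.0, 200.0, 10)
        a = 50.0 * np.exp(-0.02 * t)  # A2 = 0
        fit = fit_effective_half_life(WholeBodySeries("m1", t, a), model="auto")
        assert fit.model == "one_phase"

    def test_exact_two_phase_recovery(self):
        t = np.linspace(0.0, 120.0, 12)
        a = 80.0 * np.exp(-0.2 * t) + 20.0 * np.exp(-0.01 * t)
        fit = fit_effective_half_life(WholeBodySeries("m1", t, a),
                                      model="two_phase")
        assert fit.rates[0] == pytest.approx(0.2, rel=1e-6)
        assert fit.rates[1] == pytest.approx(0.01, rel=1e-6)
        assert fit.rates[0] > fit.rates[1]

    def test_auto_prefers_two_phase_when_clearly_better(self):
        t = np.linspace(0.0, 120.0, 12)
        a = 80.0 * np.exp(-0.2 * t) + 20.0 * np.exp(-0.01 * t)
        fit = fit_effective_half_life(WholeBodySeries("m1", t, a), model="auto")
        assert fit.model == "two_phase"

    def test_noisy_recovery_median_error_under_5_percent(self):
        errors = []
        for seed in range(100):
            series, truth = generate_wholebody(78.41, 120.0, n_points=10,
                                               noise_cv=0.05, seed=seed)
            fit = fit_effective_half_life(series, model="one_phase")
            errors.append(abs(fit.rates[0] - truth["lam_eff_per_h"])
                          / truth["lam_eff_per_h"])
        assert np.median(errors) < 0.05

    def test_excreted_tracer_effective_half_life_below_physical(self):
        t_phys = 78.41
        for seed in range(20):
            series, _ = generate_wholebody(t_phys, 150.0, n_points=10,
                                           noise_cv=0.03, seed=seed)
            fit = fit_effective_half_life(series, model="one_phase",
                                          nuclide="Zr-89")
            assert fit.t_half_eff[0] < t_phys
            assert fit.t_half_biological is not None

    def test_biological_half_life_combines_rates(self):
        series, _ = generate_wholebody(78.41, 120.0, n_points=8, noise_cv=0.0)
        fit = fit_effective_half_life(series, model="one_phase",
                                      nuclide="Zr-89")
        assert fit.t_half_biological == pytest.approx(120.0, rel=1e-6)

    def test_point_count_preconditions(self):
        t = np.array([0.0, 1.0])
        with pytest.raises(ValueError):
            fit_effective_half_life(
                WholeBodySeries("m1", t, np.array([1.0, 0.5])))
        t4 = np.linspace(0, 3, 4)
        with pytest.raises(ValueError):
            fit_effective_half_life(
                WholeBodySeries("m1", t4, np.exp(-t4)), model="two_phase")

    def test_series_validation(self):
        with pytest.raises(ValueError):
            WholeBodySeries("m1", np.array([0.0, 2.0, 1.0]),
                            np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            WholeBodySeries("m1", np.array([0.0, 1.0]), np.array([1.0, -1.0]))
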