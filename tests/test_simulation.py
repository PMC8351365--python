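"""Monte-Carlo simulator and brute-force optimizers as independent oracles."""

import dataclasses

import numpy as np
import pytest

import poctecon as pc
from conftest import draw_fee, draw_params


def _z(closed, est, se):
    return abs(est - closed) / se if se > 0 else 0.0


class TestSimulatePhysician:
    def test_reproducible_bit_identical(self, params):
        cfg = pc.SimulationConfig(2000, 50, seed=42, strategy="empiric")
        assert pc.simulate_physician(params, 0.4, cfg) == pc.simulate_physician(
            params, 0.4, cfg
        )

    def test_no_uncertainty_empiric(self, params):
        cfg = pc.SimulationConfig(50_000, 20, seed=1, strategy="empiric")
        out = pc.simulate_physician(params, 0.0, cfg)
        w0 = params.B - params.p * (1 - params.a_bar)
        assert _z(w0, out.mean_welfare, out.se_welfare) < 3
        assert out.prescription_rate == pytest.approx(1 - params.a_bar, abs=0.01)
        assert out.test_rate == 0.0

    def test_empiric_matches_closed_forms(self, params):
        cfg = pc.SimulationConfig(20_000, 300, seed=7, strategy="empiric")
        out = pc.simulate_physician(params, 0.4, cfg)
        assert _z(9.2166667, out.mean_welfare, out.se_welfare) < 3
        assert (
            _z(0.7666667, out.prescription_rate, out.se_prescription_rate) < 3
        )

    def test_poct_matches_closed_forms(self, params):
        tariff = pc.Tariff(C=0.1, t=0.5)
        cfg = pc.SimulationConfig(20_000, 300, seed=8, strategy="poct",
                                  tariff=tariff)
        out = pc.simulate_physician(params, 0.4, cfg)
        assert _z(9.1545455, out.mean_welfare, out.se_welfare) < 3
        assert _z(0.1818182, out.test_rate, out.se_test_rate) < 3
        assert (
            _z(0.6495868, out.prescription_rate, out.se_prescription_rate) < 3
        )

    def test_panel_accounting_identity(self, params):
        # treated + untreated-cured + untreated-sick = 1; the simulator
        # reports two of the three, welfare pins the third
        tariff = pc.Tariff(C=0.0, t=0.3)
        cfg = pc.SimulationConfig(5000, 100, seed=3, strategy="poct",
                                  tariff=tariff)
        out = pc.simulate_physician(params, 0.6, cfg)
        untreated_cured = 1 - out.prescription_rate - out.untreated_sick_rate
        expected_gross = (
            out.prescription_rate * (params.B - params.p)
            + untreated_cured * params.B
            - out.untreated_sick_rate * params.l
            - tariff.t * out.test_rate
        )
        assert out.mean_welfare == pytest.approx(expected_gross, abs=1e-9)

    def test_se_scaling_ladder(self, params):
        # the welfare SE is dominated by the threshold-draw layer, so it
        # shrinks as 1/sqrt(n_draws); check the full ladder within a
        # factor of 2 of the ideal 1/sqrt(8)
        ses = []
        for k, n_d in enumerate([50, 100, 200, 400]):
            cfg = pc.SimulationConfig(4000, n_d, seed=100 + k,
                                      strategy="empiric")
            ses.append(pc.simulate_physician(params, 0.4, cfg).se_welfare)
        ideal = 1 / np.sqrt(8)
        assert 0.5 * ideal < ses[-1] / ses[0] < 2 * ideal

    def test_input_validation(self, params):
        with pytest.raises(pc.ParameterError):
            pc.SimulationConfig(0, 10, seed=1)
        with pytest.raises(pc.ParameterError):
            pc.SimulationConfig(10, 10, seed=1, strategy="poct")
        with pytest.raises(pc.InfeasibleTariffError):
            pc.simulate_physician(
                params,
                0.4,
                pc.SimulationConfig(10, 10, seed=1, strategy="poct",
                                    tariff=pc.Tariff(C=0, t=5.0)),
            )


class TestConditionalExact:
    def test_scenario_conditional_components(self, params):
        # condition the realized threshold on each scenario sub-interval
        # and average the exact panel benefit: must match EB1..EB3
        b, t = 0.4, 0.5
        lo, hi = pc.testing_interval(params, b, t)
        lo0, hi0 = params.a_bar - 0.5 * b, params.a_bar + 0.5 * b
        rng = np.random.default_rng(12)
        eb = pc.gross_benefit_components(params, b, t)
        for k, (a_lo, a_hi) in enumerate([(lo0, lo), (hi, hi0), (lo, hi)]):
            a = rng.uniform(a_lo, a_hi, 400_000)
            gross, _ = pc.poct_panel_given_a(params, b, t, a)
            se = gross.std(ddof=1) / np.sqrt(a.size)
            assert _z(float(eb[k]), gross.mean(), se) < 3

    def test_unconditional_mean_matches_simplified_form(self, params):
        b, t = 0.4, 0.5
        rng = np.random.default_rng(13)
        a = rng.uniform(params.a_bar - 0.5 * b, params.a_bar + 0.5 * b, 400_000)
        gross, presc = pc.poct_panel_given_a(params, b, t, a)
        se = gross.std(ddof=1) / np.sqrt(a.size)
        assert _z(float(pc.poct_gross_benefit(params, b, t)), gross.mean(), se) < 3
        se_p = presc.std(ddof=1) / np.sqrt(a.size)
        assert _z(float(pc.poct_prescriptions(params, b, t)), presc.mean(), se_p) < 3

    def test_empiric_panel_given_a(self, params):
        b = 0.4
        rng = np.random.default_rng(14)
        a = rng.uniform(params.a_bar - 0.5 * b, params.a_bar + 0.5 * b, 400_000)
        gross, presc = pc.empiric_panel_given_a(params, b, a)
        se = gross.std(ddof=1) / np.sqrt(a.size)
        assert _z(float(pc.empiric_welfare(params, b)), gross.mean(), se) < 3
        np.testing.assert_allclose(presc, 1 - 0.2333333333, atol=1e-9)


class TestBruteForceThreshold:
    def test_degenerate(self, params):
        assert pc.brute_force_threshold(params, 0.0) == params.a_bar

    def test_baseline(self, params):
        got = pc.brute_force_threshold(params, 0.4, grid_step=1e-4)
        assert got == pytest.approx(0.2333333333, abs=1e-4)

    def test_optimum_beats_naive_midpoint(self, params):
        # expected benefit at the optimizer is at least the benefit of
        # cutting at the expected threshold a_bar
        b = 0.4
        s_opt = pc.brute_force_threshold(params, b, 1e-4)

        def exact_welfare(s):
            lo0 = params.a_bar - 0.5 * b
            shortfall = (s - lo0) ** 2 / (2 * b)
            return params.B - params.p * (1 - s) - (params.B + params.l) * shortfall

        assert exact_welfare(s_opt) >= exact_welfare(params.a_bar)

    def test_empiric_simulation_never_beats_optimal_threshold(self, params):
        # welfare simulated with the closed-form cutoff is optimal: a
        # perturbed cutoff cannot do better beyond noise
        b = 0.4
        rng = np.random.default_rng(15)
        a = rng.uniform(params.a_bar - 0.5 * b, params.a_bar + 0.5 * b, 200_000)
        w_opt, _ = pc.empiric_panel_given_a(params, b, a)
        for s_alt in (0.3, 0.21, 0.26):
            shortfall = np.maximum(s_alt - a, 0.0)
            w_alt = (
                params.B
                - params.p * (1 - s_alt)
                - (params.B + params.l) * shortfall
            )
            diff = w_opt - w_alt
            se = diff.std(ddof=1) / np.sqrt(a.size)
            assert diff.mean() > -3 * se


class TestBruteForceTestingSet:
    def test_free_testing_full_interval(self, params):
        lo, hi = pc.brute_force_testing_set(params, 0.4, 0.0, 1e-4)
        assert lo == pytest.approx(0.2, abs=1e-4)
        assert hi == pytest.approx(0.6, abs=1e-4)

    def test_baseline(self, params):
        lo, hi = pc.brute_force_testing_set(params, 0.4, 0.5, 1e-4)
        assert lo == pytest.approx(0.2181818, abs=1e-4)
        assert hi == pytest.approx(0.4, abs=1e-4)

    def test_boundary_fee_degenerate(self, params):
        lo, hi = pc.brute_force_testing_set(params, 0.4, params.max_test_fee, 1e-4)
        assert hi - lo == pytest.approx(0.0, abs=2e-4)

    def test_recovers_interval_on_random_draws(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            pr = draw_params(rng)
            b = rng.uniform(0.1, 1.0) * pr.b_max
            t = draw_fee(rng, pr)
            lo_a, hi_a = pc.testing_interval(pr, b, t)
            lo, hi = pc.brute_force_testing_set(pr, b, t, 1e-4)
            assert lo == pytest.approx(float(lo_a), abs=1.5e-4)
            assert hi == pytest.approx(float(hi_a), abs=1.5e-4)


class TestBruteForceTariff:
    def test_degenerate_grid(self, params, uniform_dist):
        tariff, profit = pc.brute_force_tariff(
            params, uniform_dist, 100, n_c=2, n_t=2, refine=False
        )
        assert profit >= 0

    def test_best_response_consistency(self, params, uniform_dist):
        # at the returned tariff, the implied adopter set is exactly the
        # best-response set from the welfare comparison
        tariff, profit = pc.brute_force_tariff(params, uniform_dist, 100,
                                               n_c=50, n_t=50)
        b = np.linspace(0.01, params.b_max, 200)
        adopts = np.array([pc.adopts_poct(params, x, tariff) for x in b])
        caps = np.asarray(pc.adoption_price_cap(params, b, tariff.t))
        np.testing.assert_array_equal(adopts, tariff.C <= caps)

    def test_profit_is_exact_at_returned_tariff(self, params, uniform_dist):
        tariff, profit = pc.brute_force_tariff(params, uniform_dist, 100,
                                               n_c=80, n_t=80)
        # recompute profit independently by integrating best responses
        from scipy import integrate

        def integrand(x):
            if not pc.adopts_poct(params, x, tariff):
                return 0.0
            return (
                tariff.C + tariff.t * float(pc.tests_count(params, x, tariff.t))
            ) * float(uniform_dist.g(x))

        # split the integral at the adoption boundary (jump discontinuity)
        cap_slope = float(
            pc.adoption_price_cap(params, params.b_max, tariff.t)
        ) / params.b_max
        b0 = min(tariff.C / cap_slope, params.b_max)
        ref = (
            integrate.quad(integrand, 0, b0)[0]
            + integrate.quad(integrand, b0, params.b_max)[0]
        )
        assert profit == pytest.approx(100 * ref, rel=1e-6)
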