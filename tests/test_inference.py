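"""Flux inference: rate fits, ratio inversions, bootstrap, end-to-end recovery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fructoflux.inference import (
    ModelViolationError,
    bootstrap_sd,
    estimate_backflux,
    estimate_ppp,
    fit_linear_rate,
    infer_all,
    slope_bootstrap_sd,
    steady_state_fractions,
)
from fructoflux.simulate import FluxConfig, run_resting_cell
from fructoflux.synthdata import DEFAULT_TIME_GRID, NoiseModel, generate_experiment


class TestFitLinearRate:
    def test_exact_linear_consumption(self):
        t = np.array([0.0, 10.0, 20.0])
        rate, sd = fit_linear_rate(t, 50.0 - 1.47 * t)
        assert rate == pytest.approx(1.47, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_constant_series_has_zero_rate(self):
        rate, _ = fit_linear_rate([0, 15, 30], [5.0, 5.0, 5.0])
        assert rate == 0.0

    def test_requires_three_points_and_time_variance(self):
        with pytest.raises(ValueError, match="3 points"):
            fit_linear_rate([0, 15], [1, 2])
        with pytest.raises(ValueError, match="variance"):
            fit_linear_rate([5, 5, 5], [1, 2, 3])

    def test_window_restricts_fit(self):
        t = np.array([0.0, 10, 20, 30, 40])
        v = np.where(t <= 20, 50 - 2.0 * t, 10.0)
        rate, _ = fit_linear_rate(t, v, window=(0, 20))
        assert rate == pytest.approx(2.0, abs=1e-12)


class TestEstimateBackflux:
    def test_zero_reversal_means_zero_backflux(self):
        assert estimate_backflux(0.9, 0.0, 1.47) == 0.0

    def test_ratio_inversion_matches_forward_formula(self):
        f_r = estimate_backflux(0.9, 0.1, 1.47)
        assert f_r == pytest.approx(2 * 1.47 / (9 - 1), abs=1e-12)  # 0.3675
        # substitute back: (2 f_in + f_r)/f_r must reproduce the ratio 9
        assert (2 * 1.47 + f_r) / f_r == pytest.approx(0.9 / 0.1, abs=1e-9)

    @given(
        st.floats(0.05, 5.0),    # f_in
        st.floats(0.01, 10.0),   # true f_r
    )
    def test_inversion_is_exact_on_formula_generated_ratios(self, f_in, f_r):
        rho = (2 * f_in + f_r) / f_r
        m_rev = 1.0 / (1.0 + rho)
        m_orig = rho / (1.0 + rho)
        assert estimate_backflux(m_orig, m_rev, f_in) == pytest.approx(
            f_r, rel=1e-9
        )

    def test_equal_fractions_violate_the_model(self):
        with pytest.raises(ModelViolationError):
            estimate_backflux(0.5, 0.5, 1.47)
        with pytest.raises(ModelViolationError):
            estimate_backflux(0.2, 0.4, 1.47)


class TestEstimatePPP:
    def test_zero_m1_means_zero_ppp(self):
        assert estimate_ppp(0.0, 0.8, 0.1, 1.47) == 0.0

    def test_all_ppp_limit_returns_f_in(self):
        assert estimate_ppp(0.3, 0.0, 0.0, 1.47) == pytest.approx(1.47)

    def test_worked_arithmetic(self):
        got = estimate_ppp(0.02, 0.85, 0.10, 1.47)
        assert got == pytest.approx(1.5 * 0.02 * 1.47 / 0.98, abs=1e-12)  # ~0.045

    @given(st.floats(0.01, 0.3), st.floats(0.1, 0.9), st.floats(0.0, 0.3),
           st.floats(0.5, 3.0))
    def test_scale_free_in_the_mole_fractions(self, m1, m2, m5, scale):
        base = estimate_ppp(m1, m2, m5, 1.47)
        scaled = estimate_ppp(scale * m1, scale * m2, scale * m5, 1.47)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_all_zero_fractions_error(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_ppp(0.0, 0.0, 0.0, 1.47)


class TestSteadyStateFractions:
    def test_time_constant_composition_recovered_exactly(self, noiseless_pair):
        tc = noiseless_pair[0]
        ss = steady_state_fractions(tc, "fructose", t_min=30)
        # composition is frozen, so a different window gives the same answer
        ss2 = steady_state_fractions(tc, "fructose", t_min=45)
        assert ss.as_array() == pytest.approx(ss2.as_array(), abs=1e-9)
        # only C1/C6 positions are reachable under the C1 tracer; the sum
        # falls slightly short of 1 because the PPP burns some label to CO2
        assert ss.at(2) == ss.at(3) == ss.at(4) == ss.at(5) == 0.0
        assert 0.9 < ss.at(1) + ss.at(6) <= 1.0
        assert ss.at(6) > 0

    def test_c2_fixture_has_the_expected_positional_signature(self, noiseless_pair):
        ss = steady_state_fractions(noiseless_pair[1], "fructose", t_min=30)
        assert ss.at(2) > 0.5          # direct route dominates
        assert ss.at(5) > 0.05         # reversal
        assert ss.at(1) > 0            # PPP first cycle ([1] and [1,3])
        assert ss.at(3) > 0            # [1,3] and second-cycle [2,3]

    def test_requires_two_window_points(self, noiseless_pair):
        with pytest.raises(ValueError, match="2 time points"):
            steady_state_fractions(noiseless_pair[0], "fructose", t_min=120)


class TestBootstrap:
    def test_constant_data_has_zero_sd(self):
        sd = bootstrap_sd(np.mean, np.full(10, 3.0), B=100, seed=0)
        assert sd == 0.0

    def test_exact_linear_slope_has_zero_sd(self):
        t = np.array([0.0, 15.0, 30.0])
        assert slope_bootstrap_sd(t, 50 - 1.47 * t, B=100, seed=0) == 0.0

    def test_requires_minimum_replicates(self):
        with pytest.raises(ValueError, match="50"):
            bootstrap_sd(np.mean, np.arange(5.0), B=10)

    def test_slope_sd_grows_with_injected_noise(self):
        t = np.arange(0.0, 31.0, 5.0)
        rng = np.random.default_rng(11)
        sds = []
        for sigma in (0.05, 0.5, 2.0):
            v = 50 - 1.47 * t + rng.normal(0, sigma, size=t.size)
            sds.append(slope_bootstrap_sd(t, v, B=200, seed=5))
        assert sds[0] < sds[1] < sds[2]


class TestInferAll:
    def test_noiseless_fixture_recovery(self, fixture_configs, fixture_estimate):
        cfg = fixture_configs[0]
        est = fixture_estimate
        assert est.f_in == pytest.approx(cfg.f_in, rel=0.01)
        assert est.f_fru == pytest.approx(cfg.f_fru, rel=0.01)
        assert est.f_r == pytest.approx(cfg.f_r, rel=0.15)
        assert est.r_back == pytest.approx(0.48, abs=0.02)
        assert est.r_divert == pytest.approx(0.86, abs=0.02)
        # noiseless data: bootstrap SDs collapse
        assert est.f_in_sd == pytest.approx(0.0, abs=1e-9)

    def test_zero_backflux_infers_zero(self, network):
        cfgs = [
            FluxConfig(f_in=1.47, f_fru=0.68, f_ppp=0.08, f_r=0.0, tracer=tr)
            for tr in (1, 2)
        ]
        tcs = [run_resting_cell(c, DEFAULT_TIME_GRID, network) for c in cfgs]
        est = infer_all(*tcs)
        assert est.f_r == 0.0 and est.r_back == 0.0

    def test_rejects_swapped_tracers(self, noiseless_pair):
        with pytest.raises(ValueError, match="tracer|expected"):
            infer_all(noiseless_pair[1], noiseless_pair[0])

    def test_noisy_estimates_center_on_truth(self, fixture_configs, network):
        """Mean inferred f_in over several noisy replicates stays near 1.47."""
        c1, c2 = fixture_configs
        estimates = []
        for seed in range(5):
            tc1 = generate_experiment(c1, NoiseModel(seed=seed), DEFAULT_TIME_GRID, network)
            tc2 = generate_experiment(c2, NoiseModel(seed=seed + 1000), DEFAULT_TIME_GRID, network)
            est = infer_all(tc1, tc2, n_bootstrap=60, seed=seed)
            estimates.append(est.f_in)
            assert est.f_in_sd > 0
        assert np.mean(estimates) == pytest.approx(1.47, rel=0.10)

    def test_report_fields_finite_and_summary_prints(self, fixture_estimate):
        d = fixture_estimate.to_dict()
        for key in ("f_in", "f_fru", "f_r", "f_ppp", "r_back", "r_divert"):
            assert np.isfinite(d[key])
        text = fixture_estimate.summary()
        assert "f_in" in text and "back-flux" in text
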