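"""Stern-Volmer calibration: schedule rules, parameter recovery, forward and
inverse consistency, prediction intervals, and agreement statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from oxyphase import (
    SternVolmerCalibration,
    SternVolmerModel,
    bland_altman,
    fit_stern_volmer_1d,
    fit_stern_volmer_2d,
    invert_pO2,
    make_schedule,
    predict_lifetime,
    relative_error_profile,
    simulate_calibration_points,
)
from oxyphase.calibration import InvalidRegimeError

SETPOINTS_0_100 = [0, 5, 10, 15, 20, 30, 40, 50, 60, 80, 100]


def setpoints(p_min, p_max):
    return [s.pO2_mmHg for s in make_schedule(p_min, p_max)]


class TestSchedule:
    def test_protocol_steps_0_100(self):
        assert setpoints(0, 100) == SETPOINTS_0_100

    def test_minimal_range(self):
        assert setpoints(0, 5) == [0, 5]

    def test_spacing_above_60_is_20(self):
        pts = np.array(setpoints(0, 160))
        high = pts[pts >= 60]
        assert np.all(np.diff(high) == 20)

    def test_dwell_and_cadence(self):
        step = make_schedule(0, 10)[0]
        assert step.dwell_s == 300.0
        assert step.cadence_s == 3.0

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(50, 50)
        with pytest.raises(ValueError):
            make_schedule(-5, 50)


class TestForwardInverse:
    def test_zero_oxygen_lifetime(self, sv_model):
        assert predict_lifetime(sv_model, 0.0, 24.0) == pytest.approx(
            sv_model.tau0_s + sv_model.f_s, rel=1e-12
        )

    def test_hand_evaluation_at_50_mmHg(self):
        m = SternVolmerModel(tau0_s=60e-6, k0_per_mmHg=0.02, kT_per_mmHg_c=0.0, f_s=0.0)
        assert predict_lifetime(m, 50.0, m.tc_c) == pytest.approx(30e-6, rel=1e-12)
        p, flag = invert_pO2(m, 30e-6, m.tc_c)
        assert flag == "ok" and p == pytest.approx(50.0, rel=1e-9)

    def test_round_trip_over_domain(self, sv_model):
        for temp in (24.0, 30.0, 36.0):
            for p in (0.0, 5.0, 50.0, 100.0, 250.0):
                tau = predict_lifetime(sv_model, p, temp)
                got, flag = invert_pO2(sv_model, tau, temp)
                assert flag in ("ok", "clamped")
                assert got == pytest.approx(p, abs=1e-9 + 1e-9 * p)

    def test_monotone_in_oxygen_and_in_lifetime(self, sv_model):
        p = np.linspace(0, 150, 200)
        tau = predict_lifetime(sv_model, p, 30.0)
        assert np.all(np.diff(tau) < 0)
        inverted = [invert_pO2(sv_model, t, 30.0)[0] for t in tau]
        assert np.all(np.diff(inverted) > 0)

    def test_infeasible_and_clamped_flags(self, sv_model):
        p, flag = invert_pO2(sv_model, sv_model.f_s / 2, 24.0)
        assert flag == "infeasible" and math.isnan(p)
        # lifetime slightly above the zero-oxygen value -> tiny negative, clamped
        tau_hi = predict_lifetime(sv_model, 0.0, 24.0) * (1 + 1e-9)
        p, flag = invert_pO2(sv_model, tau_hi, 24.0)
        assert flag == "clamped" and p == 0.0

    def test_invalid_regime_rejected(self):
        m = SternVolmerModel(tau0_s=60e-6, k0_per_mmHg=0.02, kT_per_mmHg_c=-0.01, tc_c=24.0)
        with pytest.raises(InvalidRegimeError):
            predict_lifetime(m, 10.0, 30.0)
        with pytest.raises(InvalidRegimeError):
            invert_pO2(m, 30e-6, 30.0)


class TestFitting:
    def test_1d_noise_free_recovery(self):
        truth = SternVolmerModel(tau0_s=60e-6, k0_per_mmHg=0.02, f_s=5e-6, tc_c=24.0)
        df = simulate_calibration_points(
            truth, SETPOINTS_0_100, [24.0], noise_sd_s=0.0, samples_per_setpoint=3
        )
        res = fit_stern_volmer_1d(df, fixed_temp=24.0)
        assert res.sv.tau0_s == pytest.approx(60e-6, rel=1e-6)
        assert res.sv.k0_per_mmHg == pytest.approx(0.02, rel=1e-6)
        assert res.sv.f_s == pytest.approx(5e-6, rel=1e-6)
        assert res.sv.kT_per_mmHg_c == 0.0
        assert res.sigma == pytest.approx(0.0, abs=1e-12)

    def test_2d_noise_free_recovery(self, sv_model):
        df = simulate_calibration_points(
            sv_model, SETPOINTS_0_100, [24.0, 30.0, 36.0], noise_sd_s=0.0, samples_per_setpoint=2
        )
        res = fit_stern_volmer_2d(df, tc_c=24.0)
        assert res.sv.tau0_s == pytest.approx(sv_model.tau0_s, rel=1e-6)
        assert res.sv.k0_per_mmHg == pytest.approx(sv_model.k0_per_mmHg, rel=1e-6)
        assert res.sv.kT_per_mmHg_c == pytest.approx(sv_model.kT_per_mmHg_c, rel=1e-6)
        assert res.sv.f_s == pytest.approx(sv_model.f_s, rel=1e-6)

    def test_degenerate_spread_rejected(self):
        df = pd.DataFrame(
            {"lifetime_s": [60e-6] * 6, "pO2_ref_mmHg": [0.0] * 6, "temp_c": [24.0] * 6}
        )
        with pytest.raises(ValueError, match="degenerate"):
            fit_stern_volmer_1d(df, fixed_temp=24.0)

    def test_2d_requires_two_temperatures(self, sv_model):
        df = simulate_calibration_points(
            sv_model, SETPOINTS_0_100, [24.0], noise_sd_s=0.0, samples_per_setpoint=2
        )
        with pytest.raises(ValueError, match="1-D fit"):
            fit_stern_volmer_2d(df, tc_c=24.0)

    def test_noisy_1d_recovery(self):
        # Monte-Carlo oracle: 200 seeded replicates, ~200 points each at
        # lifetime noise SD 0.5 us.  tau0 and k0 land within 5% of truth in
        # >= 95% of replicates.  The background offset f is only weakly
        # identified over a 0-100 mmHg span (quenching saturates far above
        # it), so for f we assert its t-based 95% CI covers the truth at the
        # nominal rate instead of a fixed relative accuracy.
        truth = SternVolmerModel(tau0_s=60e-6, k0_per_mmHg=0.02, f_s=5e-6, tc_c=24.0)
        ok_tau0 = ok_k0 = cover_f = 0
        n_rep = 200
        for seed in range(n_rep):
            df = simulate_calibration_points(
                truth, SETPOINTS_0_100, [24.0], noise_sd_s=0.5e-6,
                samples_per_setpoint=18, seed=seed,
            )
            res = fit_stern_volmer_1d(df, fixed_temp=24.0)
            ok_tau0 += abs(res.sv.tau0_s - truth.tau0_s) / truth.tau0_s < 0.05
            ok_k0 += abs(res.sv.k0_per_mmHg - truth.k0_per_mmHg) / truth.k0_per_mmHg < 0.05
            ci = res.conf_int()
            cover_f += ci.loc["f_s", "lower"] <= truth.f_s <= ci.loc["f_s", "upper"]
        assert ok_tau0 / n_rep >= 0.95
        assert ok_k0 / n_rep >= 0.95
        # nominal 95% coverage within ~3.5 binomial SEs (sqrt(.95*.05/200)=1.5%)
        assert 0.895 <= cover_f / n_rep <= 1.0

    def test_2d_matches_1d_at_calibration_temperature(self, sv_model):
        df = simulate_calibration_points(
            sv_model, SETPOINTS_0_100, [24.0, 30.0, 36.0],
            noise_sd_s=0.3e-6, samples_per_setpoint=40, seed=4,
        )
        res2 = fit_stern_volmer_2d(df, tc_c=24.0)
        res1 = fit_stern_volmer_1d(df[df["temp_c"] == 24.0], fixed_temp=24.0)
        grid = np.linspace(0, 100, 21)
        np.testing.assert_allclose(
            res2.predict(grid, 24.0), res1.predict(grid, 24.0), atol=3 * res2.sigma
        )

    def test_from_dataframe_and_summary(self, sv_model):
        df = simulate_calibration_points(
            sv_model, SETPOINTS_0_100, [24.0, 36.0], noise_sd_s=0.5e-6,
            samples_per_setpoint=10, seed=2,
        )
        cal = SternVolmerCalibration.from_dataframe(df, tc_c=24.0)
        res = cal.fit()
        assert res.temperature_compensated
        text = res.summary()
        for name in res.param_names:
            assert name in text
        ci = res.conf_int()
        assert (ci["lower"] < ci["upper"]).all()


class TestPredictionInterval:
    @staticmethod
    def _fit(noise, seed=0, samples=30):
        truth = SternVolmerModel(tau0_s=60e-6, k0_per_mmHg=0.02, f_s=5e-6, tc_c=24.0)
        df = simulate_calibration_points(
            truth, SETPOINTS_0_100, [24.0], noise_sd_s=noise,
            samples_per_setpoint=samples, seed=seed,
        )
        return fit_stern_volmer_1d(df, fixed_temp=24.0)

    def test_zero_residuals_zero_width(self):
        # noise-free fit: residual SD is numerically zero (optimizer leaves
        # sub-femtosecond residuals), so the band collapses
        res = self._fit(0.0, samples=3)
        band = res.prediction_interval([0.0, 20.0, 50.0, 100.0])
        np.testing.assert_allclose(band["tau_hi_s"] - band["tau_lo_s"], 0.0, atol=1e-11)

    def test_large_n_halfwidth_converges_to_1_96_sigma(self):
        # normal-limit oracle: with many points t -> 1.96 and the leverage
        # term vanishes, so the lifetime-scale half-width -> 1.96 * sigma
        res = self._fit(0.5e-6, samples=400)
        band = res.prediction_interval([50.0], level=0.95)
        half = float((band["tau_hi_s"] - band["tau_hat_s"]).iloc[0])
        assert half == pytest.approx(1.959964 * res.sigma, rel=0.01)

    def test_pO2_band_widens_with_oxygen(self):
        # constant lifetime noise maps through a shrinking |dtau/dpO2|:
        # the pO2-scale band must widen toward high oxygen
        res = self._fit(0.5e-6, samples=50)
        grid = np.array([10.0, 30.0, 60.0, 100.0])
        band = res.prediction_interval(grid)
        widths = band["pO2_hi_mmHg"] - band["pO2_lo_mmHg"]
        assert np.all(np.diff(widths) > 0)

    def test_too_few_points_rejected(self):
        truth = SternVolmerModel(tau0_s=60e-6, k0_per_mmHg=0.02, f_s=5e-6, tc_c=24.0)
        df = simulate_calibration_points(
            truth, [0, 20, 60, 100], [24.0], noise_sd_s=0.0, samples_per_setpoint=1
        )
        res = fit_stern_volmer_1d(df, fixed_temp=24.0)
        with pytest.raises(ValueError, match="few"):
            res.prediction_interval([10.0])


class TestBlandAltman:
    def test_identical_vectors(self):
        stats = bland_altman([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert stats.bias == 0.0
        assert stats.loa_low == 0.0 and stats.loa_high == 0.0

    def test_hand_computed_example(self):
        # diffs [-2, 2, -3]: bias -1, sample SD sqrt(7)
        stats = bland_altman([10.0, 20.0, 30.0], [12.0, 18.0, 33.0])
        assert stats.bias == pytest.approx(-1.0, abs=1e-12)
        assert stats.sd_diff == pytest.approx(math.sqrt(7), rel=1e-12)
        assert stats.loa_low == pytest.approx(-1.0 - 1.96 * math.sqrt(7), rel=1e-12)
        assert stats.loa_high == pytest.approx(-1.0 + 1.96 * math.sqrt(7), rel=1e-12)
        assert stats.n == 3

    def test_antisymmetry(self):
        m = np.array([5.0, 8.0, 14.0, 2.0])
        r = np.array([6.0, 7.0, 15.0, 1.0])
        a = bland_altman(m, r)
        b = bland_altman(r, m)
        assert b.bias == pytest.approx(-a.bias)
        assert b.loa_low == pytest.approx(-a.loa_high)
        assert b.loa_high == pytest.approx(-a.loa_low)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])


class TestRelativeErrorProfile:
    def test_noise_free_all_zero(self, sv_model):
        df = simulate_calibration_points(
            sv_model, SETPOINTS_0_100, [24.0], noise_sd_s=0.0, samples_per_setpoint=2
        )
        prof = relative_error_profile(sv_model, df, 10.0, 100.0)
        assert prof["max"] == pytest.approx(0.0, abs=1e-9)

    def test_error_propagation_at_50_mmHg(self):
        # oracle: sigma_p ~= sigma_tau / |dtau/dpO2|; choose sigma_tau so the
        # relative pO2 error at 50 mmHg is ~10%, then the median |error|
        # should be ~0.675 * 10% (half-normal median)
        truth = SternVolmerModel(tau0_s=60e-6, k0_per_mmHg=0.02, f_s=0.0, tc_c=24.0)
        dtau_dp = truth.tau0_s * truth.k0_per_mmHg / (1 + truth.k0_per_mmHg * 50.0) ** 2
        sigma_tau = 0.10 * 50.0 * dtau_dp
        df = simulate_calibration_points(
            truth, [50.0] * 3, [24.0], noise_sd_s=sigma_tau,
            samples_per_setpoint=2000, seed=8,
        )
        prof = relative_error_profile(truth, df, 10.0, 100.0)
        assert prof["median"] == pytest.approx(0.6745 * 0.10, rel=0.10)

    def test_empty_range_rejected(self, sv_model):
        df = simulate_calibration_points(
            sv_model, [50.0], [24.0], noise_sd_s=0.0, samples_per_setpoint=2
        )
        with pytest.raises(ValueError, match="no calibration points"):
            relative_error_profile(sv_model, df, 60.0, 100.0)
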