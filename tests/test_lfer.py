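import numpy as np
import pytest

from ircmech import lfer
from ircmech import synthetic as syn
from ircmech.constants import GAS_CONSTANT_KCAL, LOG10_FACTOR
from ircmech.exceptions import NumericalError, ValidationError
from ircmech.io_formats import StationaryPoint

T = 383.45  # 110.3 degrees C


class TestActivationParameters:
    def _points(self, dH, dG):
        r = StationaryPoint(role="reactant", H=0.0, G=0.0)
        ts = StationaryPoint(role="transition_state", H=dH, G=dG)
        return r, ts

    def test_equal_enthalpy_free_energy_zero_entropy(self):
        r, ts = self._points(20.0, 20.0)
        assert lfer.activation_parameters(r, ts, T).dS == pytest.approx(0.0)

    def test_hand_computed_entropy(self):
        # (20 - 23.8345)/383.45 = -0.01 kcal/(mol K)
        r, ts = self._points(20.0, 23.8345)
        params = lfer.activation_parameters(r, ts, T)
        assert params.dS == pytest.approx(-0.01, abs=1e-9)

    def test_ea_convention(self):
        # Ea = dH + R*T = 20 + 1.987204e-3*383.45 = 20.762 kcal/mol
        r, ts = self._points(20.0, 20.0)
        params = lfer.activation_parameters(r, ts, T)
        assert params.Ea == pytest.approx(20.0 + GAS_CONSTANT_KCAL * T, abs=1e-12)
        assert params.Ea == pytest.approx(20.762, abs=1e-3)

    def test_invariants(self):
        r, ts = self._points(18.0, 21.5)
        p = lfer.activation_parameters(r, ts, T)
        assert p.dS == pytest.approx((p.dH - p.dG) / p.T, abs=1e-9)
        assert p.Ea == pytest.approx(p.dH + GAS_CONSTANT_KCAL * p.T, abs=1e-9)

    def test_missing_field_rejected(self):
        r = StationaryPoint(role="reactant", H=0.0)
        ts = StationaryPoint(role="transition_state", H=20.0, G=21.0)
        with pytest.raises(ValidationError):
            lfer.activation_parameters(r, ts, T)

    def test_nonpositive_temperature_rejected(self):
        r, ts = self._points(20.0, 20.0)
        with pytest.raises(ValidationError):
            lfer.activation_parameters(r, ts, 0.0)


class TestLogRateRatio:
    def test_zero_for_equal(self):
        assert lfer.log_rate_ratio(20.0, 20.0, T) == 0.0

    def test_unit_value(self):
        # 2.303*R*T = 1.7549 kcal/mol at 383.45 K
        factor = LOG10_FACTOR * GAS_CONSTANT_KCAL * T
        assert factor == pytest.approx(1.7549, abs=1e-4)
        assert lfer.log_rate_ratio(factor, 0.0, T) == pytest.approx(1.0, abs=1e-12)

    def test_antisymmetry(self):
        assert lfer.log_rate_ratio(22.0, 20.0, T) == pytest.approx(
            -lfer.log_rate_ratio(20.0, 22.0, T), abs=1e-15
        )

    def test_bad_temperature(self):
        with pytest.raises(ValidationError):
            lfer.log_rate_ratio(1.0, 0.0, -5.0)


class TestEntropyFromIntercept:
    def test_zero(self):
        assert lfer.entropy_from_intercept(0.0) == 0.0

    def test_paper_scale_value(self):
        # 0.01 -> 4.577e-5 kcal/(mol K), which prints as 4.6e-5 at 2 sig figs
        value = lfer.entropy_from_intercept(0.01)
        assert value == pytest.approx(4.577e-5, abs=1e-8)
        assert float(f"{value:.2g}") == pytest.approx(4.6e-5)

    def test_unit_intercept(self):
        assert lfer.entropy_from_intercept(1.0) == pytest.approx(4.577e-3, abs=1e-6)


class TestHammettFit:
    def test_noiseless_exact_recovery(self):
        series = syn.make_hammett_series(2.0, [0.0, 0.5, 1.0], noise_sd=0.0)
        fit = lfer.hammett_fit(series, response="enthalpy")
        assert fit.rho == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-9)
        assert fit.delta_delta_S == pytest.approx(0.0, abs=1e-9)

    def test_positive_rho_sign_rule(self):
        series = syn.make_hammett_series(2.33, [0.0, 0.23, 0.78], noise_sd=0.0)
        fit = lfer.hammett_fit(series)
        assert fit.charge_interpretation == "negative charge developed"

    def test_negative_rho_sign_rule(self):
        series = syn.make_hammett_series(-1.5, [0.0, 0.23, 0.78], noise_sd=0.0)
        assert lfer.hammett_fit(series).charge_interpretation == "positive charge developed"

    def test_free_energy_equals_enthalpy_with_constant_entropy(self):
        series = syn.make_hammett_series(1.7, [0.0, -0.27, 0.06, 0.23, 0.78])
        fg = lfer.hammett_fit(series, response="free_energy")
        fh = lfer.hammett_fit(series, response="enthalpy")
        assert fg.rho == pytest.approx(fh.rho, abs=1e-9)
        assert fh.intercept == pytest.approx(0.0, abs=1e-9)

    def test_entropy_offset_recovered_from_intercept(self):
        # shift the reference dG by a constant entropy offset and verify the
        # enthalpy-form intercept converts back to it
        series = syn.make_hammett_series(2.0, [0.0, 0.2, 0.5, 0.9], dS_activation=-0.004)
        fit = lfer.hammett_fit(series, response="enthalpy")
        # constant dS across the series: intercept stays 0 by construction
        assert lfer.entropy_from_intercept(fit.intercept) == pytest.approx(0.0, abs=1e-9)

    def test_all_sigma_identical_singular(self):
        entries = [
            lfer.HammettEntry("a", 0.0, dH=20.0),
            lfer.HammettEntry("b", 0.0, dH=21.0),
            lfer.HammettEntry("c", 0.0, dH=22.0),
        ]
        with pytest.raises(ValidationError):
            # two sigma=0 entries also violate the unique-reference invariant
            lfer.HammettSeries(entries=entries)

    def test_singular_fit_error(self):
        series = syn.make_hammett_series(2.0, [0.0, 0.5, 1.0])
        for e in series.entries:
            e.sigma = 0.3  # force identical predictors post-validation
        with pytest.raises(NumericalError):
            lfer.hammett_fit(series)

    def test_too_few_entries(self):
        with pytest.raises(ValidationError):
            syn.make_hammett_series(2.0, [0.0, 0.5])

    def test_missing_response_field(self):
        entries = [
            lfer.HammettEntry("H", 0.0, dH=20.0),
            lfer.HammettEntry("X", 0.5, dH=19.0),
            lfer.HammettEntry("Y", 1.0, dG=18.0),
        ]
        series = lfer.HammettSeries(entries=entries)
        with pytest.raises(ValidationError, match="dH"):
            lfer.hammett_fit(series, response="enthalpy")


class TestStochasticRecovery:
    def test_mean_rho_within_two_percent(self):
        # 200 noisy series, noise_sd=0.05 kcal/mol on dH, n=6 substituents
        rho_true = 2.0
        sigmas = [0.0, -0.27, -0.17, 0.06, 0.23, 0.78]
        fits = [
            lfer.hammett_fit(
                syn.make_hammett_series(rho_true, sigmas, noise_sd=0.05, seed=s)
            )
            for s in range(200)
        ]
        rhos = np.array([f.rho for f in fits])
        assert abs(rhos.mean() - rho_true) < 0.02 * rho_true

    def test_dispersion_matches_analytic_ols_se(self):
        rho_true = 2.0
        sigmas = np.array([0.0, -0.27, -0.17, 0.06, 0.23, 0.78])
        noise = 0.05
        factor = LOG10_FACTOR * GAS_CONSTANT_KCAL * T
        # y noise: reference noise shifts all y equally (absorbed by the
        # intercept); per-entry noise on dH propagates to y with sd noise/factor
        rhos = np.array(
            [
                lfer.hammett_fit(
                    syn.make_hammett_series(rho_true, list(sigmas), noise_sd=noise, seed=s)
                ).rho
                for s in range(200)
            ]
        )
        sxx = np.sum((sigmas - sigmas.mean()) ** 2)
        se_analytic = (noise / factor) / np.sqrt(sxx)
        # sample sd of fitted slopes should sit near the analytic OLS s.e.
        assert rhos.std(ddof=1) == pytest.approx(se_analytic, rel=0.25)


class TestCorrelateWithSigma:
    def test_exact_line(self):
        sigmas = [0.0, 0.2, 0.5, 0.9]
        values = [3 * s + 1 for s in sigmas]
        slope, intercept, r = lfer.correlate_with_sigma(values, sigmas)
        assert slope == pytest.approx(3.0, abs=1e-12)
        assert intercept == pytest.approx(1.0, abs=1e-12)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_error(self):
        with pytest.raises(NumericalError):
            lfer.correlate_with_sigma([2.0, 2.0, 2.0], [0.0, 0.5, 1.0])

    def test_pairing_enforced(self):
        with pytest.raises(ValidationError):
            lfer.correlate_with_sigma([1.0, 2.0], [0.0, 0.5, 1.0])


class TestChargeEnergyCorrelation:
    def test_perfect_linear(self):
        charges = [-0.5, -0.4, -0.3, -0.2]
        ea = [30.0, 28.0, 26.0, 24.0]
        res = lfer.charge_energy_correlation(charges, ea)
        assert res.r == pytest.approx(-1.0, abs=1e-12)
        assert not res.constant_function

    def test_opposite_sign_slopes_recovered(self, rng):
        ea = np.array([20.0, 22.0, 24.0, 26.0, 28.0])
        q_carbon = -0.1 - 0.02 * ea + rng.normal(0, 1e-6, 5)
        q_hydrogen = 0.3 + 0.02 * ea + rng.normal(0, 1e-6, 5)
        res_c = lfer.charge_energy_correlation(q_carbon, ea)
        res_h = lfer.charge_energy_correlation(q_hydrogen, ea)
        assert res_c.slope < 0 < res_h.slope
        assert res_c.slope == pytest.approx(-res_h.slope, rel=1e-3)
        assert res_c.slope == pytest.approx(-0.02, rel=1e-3)

    def test_near_constant_charge_flagged(self):
        charges = np.array([-0.30000001, -0.3, -0.29999999, -0.30000002])
        ea = np.array([20.0, 25.0, 30.0, 35.0])
        res = lfer.charge_energy_correlation(charges, ea)
        assert res.constant_function


class TestSigmaTable:
    def test_bundled_table_loads(self):
        df = lfer.load_sigma_table()
        assert {"substituent", "sigma"} <= set(df.columns)
        assert (df["sigma"] == 0.0).sum() == 1  # H reference present

    def test_custom_path(self, tmp_path):
        p = tmp_path / "sigma.csv"
        p.write_text("substituent,sigma\nH,0.0\np-X,0.5\n")
        df = lfer.load_sigma_table(p)
        assert len(df) == 2
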