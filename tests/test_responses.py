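"""Light/temperature response models, partitioning and daily budgets."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chamberflux.config import CARBON_MOLAR_MASS
from chamberflux.responses import (DailyFlux, K_REF, LightResponseParams,
                                   T_SHIFT, TemperatureResponseParams,
                                   daily_course, fit_light_response,
                                   fit_temperature_response,
                                   fit_temperature_response_loglinear,
                                   indices, nee_model, partition, reco_model,
                                   sinusoidal_drivers)

LR = LightResponseParams(alpha_qy=0.02, f_inf=-12.0, rd=3.0)
TR = TemperatureResponseParams(rref=2.0, e0=200.0)


class TestNeeModel:
    def test_dark_value_is_daytime_respiration(self):
        assert nee_model(LR, 0.0) == pytest.approx(LR.rd)

    def test_asymptote_is_finf_plus_rd(self):
        assert nee_model(LR, 1e9) == pytest.approx(-9.0, abs=1e-9)

    def test_value_at_reference_light(self):
        # direct evaluation: u = -2*0.02*2000/-12 = 20/3;
        # 2*(-12)*(0.5 - 1/(1+e^{20/3})) + 3
        expected = 2 * -12.0 * (0.5 - 1.0 / (1.0 + np.exp(20.0 / 3.0))) + 3.0
        assert nee_model(LR, 2000.0) == pytest.approx(expected, rel=1e-12)
        assert nee_model(LR, 2000.0) == pytest.approx(-8.97, abs=0.005)

    def test_initial_slope_is_minus_alpha(self):
        h = 1e-4
        deriv = (nee_model(LR, h) - nee_model(LR, 0.0)) / h
        assert deriv == pytest.approx(-LR.alpha_qy, abs=1e-6)

    def test_uptake_magnitude_nondecreasing_in_light(self):
        p = np.linspace(0, 3000, 200)
        nee = nee_model(LR, p)
        assert np.all(np.diff(nee) <= 1e-12)

    def test_degenerate_finf_with_positive_alpha_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            nee_model(LightResponseParams(0.02, 0.0, 3.0), 100.0)


class TestRecoModel:
    def test_reference_temperature_identity(self):
        # 1/(10+46.02) equals the shifted-scale constant to 7 decimals
        assert K_REF == pytest.approx(1.0 / (10.0 + T_SHIFT), abs=1e-7)
        assert reco_model(TR, 10.0) == pytest.approx(TR.rref, abs=1e-7)

    def test_value_at_twenty_degrees(self):
        expected = 2.0 * np.exp(200.0 * (K_REF - 1.0 / 66.02))
        assert reco_model(TR, 20.0) == pytest.approx(expected, rel=1e-12)
        assert reco_model(TR, 20.0) == pytest.approx(3.434, abs=2e-3)

    def test_zero_sensitivity_is_flat(self):
        flat = TemperatureResponseParams(rref=2.0, e0=0.0)
        temps = np.linspace(-10, 30, 50)
        np.testing.assert_allclose(reco_model(flat, temps), 2.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(-20.0, 29.0), st.floats(0.01, 5.0))
    def test_strictly_increasing_in_temperature(self, t, dt):
        assert reco_model(TR, t + dt) > reco_model(TR, t)

    def test_domain_error_below_shift(self):
        with pytest.raises(ValueError):
            reco_model(TR, -47.0)


class TestFitLightResponse:
    def test_noise_free_recovery_on_ppfd_grid(self):
        import pandas as pd
        ppfd = np.arange(0.0, 2001.0, 50.0)
        obs = pd.DataFrame({"nee": nee_model(LR, ppfd), "ppfd": ppfd})
        fit = fit_light_response(obs)
        assert fit.alpha_qy == pytest.approx(LR.alpha_qy, rel=1e-6)
        assert fit.f_inf == pytest.approx(LR.f_inf, rel=1e-6)
        assert fit.rd == pytest.approx(LR.rd, rel=1e-6)

    def test_light_insensitive_group(self):
        import pandas as pd
        ppfd = np.arange(0.0, 2001.0, 200.0)
        obs = pd.DataFrame({"nee": np.full(ppfd.size, 3.0), "ppfd": ppfd})
        fit = fit_light_response(obs)
        assert fit.alpha_qy == pytest.approx(0.0, abs=1e-6)
        assert fit.rd == pytest.approx(3.0, abs=1e-6)

    def test_all_dark_group_is_respiration_only(self):
        import pandas as pd
        obs = pd.DataFrame({"nee": [3.1, 2.9, 3.0, 3.2, 2.8],
                            "ppfd": np.zeros(5)})
        fit = fit_light_response(obs)
        assert fit.respiration_only
        assert fit.alpha_qy == 0.0 and fit.f_inf == 0.0
        assert fit.rd == pytest.approx(3.0)

    def test_too_few_light_levels_rejected(self):
        import pandas as pd
        obs = pd.DataFrame({"nee": [3.0, -1.0, 3.1, -1.1, 3.2],
                            "ppfd": [0.0, 800.0, 0.0, 800.0, 0.0]})
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_light_response(obs)


class TestFitTemperatureResponse:
    def test_noise_free_recovery(self):
        t = np.linspace(5.0, 20.0, 10)
        fit = fit_temperature_response(reco_model(TR, t), t)
        assert fit.rref == pytest.approx(2.0, rel=1e-6)
        assert fit.e0 == pytest.approx(200.0, rel=1e-6)

    def test_flat_respiration_gives_zero_sensitivity(self):
        t = np.linspace(5.0, 20.0, 8)
        fit = fit_temperature_response(np.full(t.size, 2.5), t)
        assert fit.e0 == pytest.approx(0.0, abs=1e-6)
        assert fit.rref == pytest.approx(2.5, rel=1e-6)

    def test_loglinear_cross_check_noise_free(self):
        t = np.linspace(2.0, 18.0, 12)
        reco = reco_model(TR, t)
        direct = fit_temperature_response(reco, t)
        loglin = fit_temperature_response_loglinear(reco, t)
        assert direct.rref == pytest.approx(loglin.rref, rel=0.01)
        assert direct.e0 == pytest.approx(loglin.e0, rel=0.01)

    def test_insufficient_temperature_spread_rejected(self):
        t = np.linspace(10.0, 11.0, 8)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_temperature_response(reco_model(TR, t), t)


class TestIndicesAndPartition:
    def test_reference_light_indices(self):
        ix = indices(LR, TR)
        assert ix.nee2000 == pytest.approx(-8.97, abs=0.005)
        assert ix.gee2000 == pytest.approx(ix.nee2000 - 3.0)
        assert ix.r10 == TR.rref

    def test_zero_respiration_equates_the_indices(self):
        lr0 = LightResponseParams(0.02, -12.0, 0.0)
        ix = indices(lr0, TR)
        assert ix.gee2000 == ix.nee2000

    def test_r10_is_rref_for_any_sensitivity(self):
        for e0 in (0.0, 100.0, 400.0):
            ix = indices(LR, TemperatureResponseParams(2.0, e0))
            assert ix.r10 == 2.0

    def test_partition_reproduces_intermediate_transect_budget(self):
        # daily means of the LIA-moraine transect: NEE -7.6, Reco 4.1
        assert partition(-7.6, 4.1) == pytest.approx(-11.7)

    def test_partition_reproduces_old_transect_budget(self):
        assert partition(-6.3, 4.1) == pytest.approx(-10.4)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(-30, 30), st.floats(0, 15))
    def test_partition_identity_restores_nee(self, nee, reco):
        gee = partition(nee, reco)
        assert gee + reco == pytest.approx(nee, abs=1e-9)


class TestDailyCourse:
    def test_unit_conversion_oracle_constant_flux(self):
        # constant -7.32 umol m-2 s-1 -> * 12.011 * 86400 * 1e-6
        lr = LightResponseParams(0.0, -1e-12, 0.0)
        tr = TemperatureResponseParams(7.32, 0.0)
        ppfd = np.zeros(48)
        tair = np.full(48, 10.0)
        d = daily_course(lr, tr, ppfd, tair)
        expected = -7.32 * CARBON_MOLAR_MASS * 86400 * 1e-6
        assert d.reco == pytest.approx(-expected, rel=1e-12)
        assert -d.reco == pytest.approx(-7.60, abs=0.005)

    def test_all_dark_day_has_zero_gee_and_nee_equals_reco(self):
        tr = TemperatureResponseParams(2.0, 200.0)
        ppfd = np.zeros(48)
        tair = 10.0 + 4.0 * np.sin(np.linspace(0, 2 * np.pi, 48))
        d = daily_course(LR, tr, ppfd, tair)
        assert d.gee == pytest.approx(0.0, abs=1e-12)
        assert d.nee == pytest.approx(d.reco, abs=1e-12)

    def test_conservation_at_daily_scale(self):
        ppfd, tair = sinusoidal_drivers(96)
        d = daily_course(LR, TR, ppfd, tair)
        assert d.nee == pytest.approx(d.gee + d.reco, abs=1e-9)

    def test_riemann_refinement_stability(self):
        d48 = daily_course(LR, TR, *sinusoidal_drivers(48))
        d96 = daily_course(LR, TR, *sinusoidal_drivers(96))
        assert d96.nee == pytest.approx(d48.nee, rel=0.01)

    def test_driver_gaps_are_reported(self):
        ppfd, tair = sinusoidal_drivers(48)
        tair[13] = np.nan
        with pytest.raises(ValueError, match=r"step\(s\) \[13\]"):
            daily_course(LR, TR, ppfd, tair)

    def test_coarse_drivers_rejected(self):
        with pytest.raises(ValueError, match="24 h"):
            daily_course(LR, TR, np.zeros(12), np.zeros(12))
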