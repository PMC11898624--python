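"""Raw-cycle processing: humidity conversion, dilution correction,
fit window, slope regression, QC screens and gap filling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stemresp import (SimulationConfig, dilution_correct_o2,
                      extract_fit_window, fill_gaps, fit_slope,
                      magnus_saturation_vp_hpa, process_cycle, qc_flags,
                      rh_to_h2o, simulate_cycle)
from stemresp.chamber import SlopeFit


class TestHumidity:
    def test_magnus_at_20C(self):
        # hand evaluation: 6.112·exp(17.62·20/263.12) = 23.33 hPa
        assert magnus_saturation_vp_hpa(20.0) == pytest.approx(23.33, abs=0.01)

    @pytest.mark.parametrize("rh, temp, p, expected, tol", [
        (0.0, 20.0, 101.325, 0.0, 1e-12),
        (50.0, 20.0, 101.325, 11513.0, 3.0),  # (0.5·2.333 kPa/101.325)·1e6
        (100.0, 0.0, 101.325, 6032.0, 5.0),
    ])
    def test_rh_to_h2o_hand_values(self, rh, temp, p, expected, tol):
        assert rh_to_h2o(rh, temp, p) == pytest.approx(expected, abs=tol)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            rh_to_h2o(-1.0, 20.0, 101.325)
        with pytest.raises(ValueError):
            rh_to_h2o(50.0, 20.0, 0.0)
        with pytest.raises(ValueError):
            rh_to_h2o(100.0, 99.0, 90.0)  # boiling: e_sat exceeds P

    @given(t=st.floats(-20, 45), rh=st.floats(0, 100))
    def test_h2o_increases_with_temperature_and_rh(self, t, rh):
        base = rh_to_h2o(rh, t, 101.325)
        assert rh_to_h2o(rh, t + 1.0, 101.325) >= base
        assert rh_to_h2o(min(rh + 1.0, 100.0), t, 101.325) >= base


class TestDilutionCorrection:
    def test_constant_o2_under_rising_diluters_stays_flat(self):
        # pure dilution: O2 moles fixed while CO2+H2O moles grow
        n_o2, n_inert = 209_500.0, 770_000.0
        added = np.linspace(0.0, 30_000.0, 50)  # µmol-equivalents of CO2+H2O
        n_tot = n_o2 + n_inert + 20_500.0 + added
        o2_wet = n_o2 / n_tot * 1e6
        diluters = (20_500.0 + added) / n_tot * 1e6
        corr = dilution_correct_o2(o2_wet, diluters, np.zeros(50))
        assert np.ptp(corr) / corr[0] < 1e-12

    def test_corrected_slope_matches_molar_o2_loss(self, quiet_config,
                                                   chamber, env):
        cyc = simulate_cycle(quiet_config, chamber, env)
        h2o = rh_to_h2o(cyc.rh_pct, cyc.temp_C, cyc.pressure_kPa)
        corr = dilution_correct_o2(cyc.o2_ppm_wet, h2o, cyc.co2_ppm)
        fit = fit_slope(cyc.t_s, corr)
        n_tot0 = cyc.ledger["n_tot"].iloc[0]
        truth = -np.polyfit(cyc.t_s, cyc.ledger["n_o2"] / n_tot0 * 1e6, 1)[0]
        assert fit.slope_ppm_s == pytest.approx(-truth, rel=1e-3)

    def test_rejects_saturated_matrix(self):
        with pytest.raises(ValueError):
            dilution_correct_o2(np.array([500000.0]), 400000.0, 200000.0)

    def test_uncorrected_decline_steeper_under_evaporation(
            self, quiet_config, chamber, env):
        # dilution inflates the apparent O2 decline
        cyc = simulate_cycle(quiet_config, chamber, env)
        h2o = rh_to_h2o(cyc.rh_pct, cyc.temp_C, cyc.pressure_kPa)
        raw = fit_slope(cyc.t_s, cyc.o2_ppm_wet).slope_ppm_s
        corr = fit_slope(cyc.t_s, dilution_correct_o2(
            cyc.o2_ppm_wet, h2o, cyc.co2_ppm)).slope_ppm_s
        assert raw < corr < 0


class TestFitWindow:
    def test_full_cycle_gives_120_points(self, quiet_config, chamber, env):
        cyc = simulate_cycle(quiet_config, chamber, env)
        win = extract_fit_window(cyc)
        assert win.t_s.size == 120

    def test_boundary_convention(self, quiet_config, chamber, env):
        win = extract_fit_window(simulate_cycle(quiet_config, chamber, env))
        assert win.t_s[0] == 300.0      # 290 s excluded, 300 s included
        assert win.t_s[-1] == 1490.0    # 1500 s excluded

    def test_truncated_cycle_rejected(self, quiet_config, chamber, env):
        cyc = simulate_cycle(quiet_config, chamber, env)
        short = cyc.subset(cyc.t_s <= 1200.0)
        with pytest.raises(ValueError):
            extract_fit_window(short)


class TestSlopeFit:
    def test_exact_line(self):
        t = np.arange(0.0, 1200.0, 10.0)
        fit = fit_slope(t, 400.0 + 0.05 * t)
        assert fit.slope_ppm_s == pytest.approx(0.05, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_reported_as_flat_with_zero_r2(self):
        fit = fit_slope(np.arange(5.0), np.full(5, 400.0))
        assert fit.slope_ppm_s == 0.0 and fit.r2 == 0.0
        qc = qc_flags(fit, SlopeFit(-0.01, 0, 1.0, 5), 50.0)
        assert not qc.overall

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            fit_slope([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_slope(np.ones(5), np.arange(5.0))

    def test_noisy_slope_within_2_se_of_truth(self, chamber, env):
        cfg = SimulationConfig(resp_flux=2.0, rq_true=1.0, evap_rate=0.5,
                               noise_sd_co2=2.0, seed=42)
        win = extract_fit_window(simulate_cycle(cfg, chamber, env))
        fit = fit_slope(win.t_s, win.co2_ppm)
        truth = fit_slope(
            win.t_s, win.ledger["n_co2"] / win.ledger["n_tot"] * 1e6
        ).slope_ppm_s
        # closed-form OLS slope SE for white noise on the 10-s grid
        se = 2.0 / np.sqrt(np.sum((win.t_s - win.t_s.mean()) ** 2))
        assert abs(fit.slope_ppm_s - truth) < 2 * se


class TestQCFlags:
    def good(self, r2=0.98, slope=0.05):
        return SlopeFit(slope, 400.0, r2, 120)

    def test_all_pass(self):
        qc = qc_flags(self.good(), self.good(slope=-0.05), 80.0)
        assert qc.overall

    @pytest.mark.parametrize("kwargs, failing", [
        (dict(fit_co2_r2=0.95), "pass_r2_co2"),
        (dict(fit_o2_r2=0.959), "pass_r2_o2"),
        (dict(rh=99.5), "pass_rh"),
        (dict(o2_slope=0.01), "pass_sign"),
    ])
    def test_single_failures(self, kwargs, failing):
        qc = qc_flags(
            self.good(r2=kwargs.get("fit_co2_r2", 0.98)),
            self.good(r2=kwargs.get("fit_o2_r2", 0.98),
                      slope=kwargs.get("o2_slope", -0.05)),
            kwargs.get("rh", 80.0))
        assert not getattr(qc, failing)
        assert not qc.overall

    def test_threshold_is_configurable(self):
        qc = qc_flags(self.good(r2=0.5), self.good(r2=0.5, slope=-0.05),
                      80.0, r2_threshold=0.0)
        assert qc.overall


class TestGapFilling:
    def series(self, values):
        idx = pd.date_range("2018-07-05", periods=len(values), freq="1h")
        return pd.Series(values, index=idx, dtype=float)

    def test_single_hour_gap_midpoint(self):
        out = fill_gaps(self.series([2.0, np.nan, 3.0]))
        assert out["value"].iloc[1] == pytest.approx(2.5)
        assert out["interpolated"].tolist() == [False, True, False]

    def test_three_hour_gap_left_missing(self):
        out = fill_gaps(self.series([2.0, np.nan, np.nan, np.nan, 3.0]))
        assert out["value"].isna().sum() == 3
        assert not out["interpolated"].any()

    def test_no_gaps_is_identity(self):
        s = self.series([1.0, 2.0, 3.0])
        out = fill_gaps(s)
        assert np.array_equal(out["value"].to_numpy(), s.to_numpy())

    def test_leading_gap_never_extrapolated(self):
        out = fill_gaps(self.series([np.nan, 2.0, 3.0]))
        assert np.isnan(out["value"].iloc[0])


def test_full_chain_on_clean_cycle(quiet_config, chamber, env):
    """QC → dilution → slopes on a clean simulated cycle passes screening."""
    rec = process_cycle(simulate_cycle(quiet_config, chamber, env))
    assert rec.qc.overall
    assert rec.r2_co2 > 0.999 and rec.r2_o2 > 0.999
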