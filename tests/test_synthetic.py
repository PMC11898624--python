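"""Forward simulator: molar bookkeeping, measurement-model inversion,
seeded reproducibility, flasks, atmosphere and stained-section images."""

import numpy as np
import pytest

from stemresp import (ChamberSpec, EnvState, SimulationConfig, SubstrateMix,
                      compute_flux, fit_slope, make_linear_atmosphere,
                      process_cycle, simulate_campaign, simulate_cycle,
                      simulate_flask, simulate_oro_image)
from stemresp.lipid import stain_mask
from stemresp.synthetic import OROImage


class TestCycleSimulation:
    def test_molar_bookkeeping_closes(self, quiet_config, chamber, env):
        led = simulate_cycle(quiet_config, chamber, env).ledger
        # inert matrix is untouched; totals close component-wise
        assert np.allclose(led["n_inert"], led["n_inert"].iloc[0], rtol=1e-12)
        recon = led[["n_co2", "n_o2", "n_h2o", "n_inert"]].sum(axis=1)
        assert np.allclose(recon, led["n_tot"], rtol=1e-9)
        # CO2 increments equal the configured efflux · area · Δt
        inc = np.diff(led["n_co2"])
        assert np.allclose(inc, 2.0 * 0.0028 * 10.0, rtol=1e-9)

    def test_noise_free_co2_slope_inverts_exactly(self, chamber, env):
        # choose the efflux whose noise-free slope is exactly 0.05 ppm/s
        target = 0.05
        flux = compute_flux(target, chamber, env)
        cfg = SimulationConfig(resp_flux=flux, rq_true=1.0, evap_rate=0.0)
        cyc = simulate_cycle(cfg, chamber, env)
        fit = fit_slope(cyc.t_s, cyc.co2_ppm)
        assert fit.slope_ppm_s == pytest.approx(target, rel=1e-9)

    @pytest.mark.parametrize("flux", [0.1, 1.0, 10.0])
    def test_measurement_model_inversion_across_fluxes(self, flux, chamber,
                                                       env):
        cfg = SimulationConfig(resp_flux=flux, rq_true=1.0, evap_rate=0.0)
        rec = process_cycle(simulate_cycle(cfg, chamber, env))
        assert rec.e_co2 == pytest.approx(flux, rel=1e-3)

    def test_stoichiometric_symmetry_rq1(self, chamber, env):
        cfg = SimulationConfig(resp_flux=2.0, rq_true=1.0, evap_rate=0.0)
        rec = process_cycle(simulate_cycle(cfg, chamber, env))
        assert rec.slope_o2_corr == pytest.approx(-rec.slope_co2, rel=1e-3)

    def test_seeded_determinism(self, chamber, env):
        cfg = SimulationConfig(resp_flux=2.0, noise_sd_co2=2.0,
                               noise_sd_o2=2.0, seed=7)
        a = simulate_cycle(cfg, chamber, env)
        b = simulate_cycle(cfg, chamber, env)
        assert np.array_equal(a.co2_ppm, b.co2_ppm)
        assert np.array_equal(a.o2_ppm_wet, b.o2_ppm_wet)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(resp_flux=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(rq_true=0.2)
        with pytest.raises(ValueError):
            ChamberSpec(volume_cm3=10.0)

    def test_rh_clamps_at_saturation(self, chamber):
        cfg = SimulationConfig(resp_flux=2.0, evap_rate=50.0)
        cyc = simulate_cycle(cfg, chamber, EnvState(rh_pct=99.0))
        assert cyc.rh_pct.max() <= 100.0 + 1e-9
        assert cyc.rh_pct[-1] == pytest.approx(100.0, abs=1e-6)


class TestCampaign:
    def test_one_day_gives_24_cycles_per_chamber(self, quiet_config):
        chambers = [ChamberSpec(tree_id="A"), ChamberSpec(tree_id="B")]
        cycles = simulate_campaign(quiet_config, chambers, n_days=1)
        assert len(cycles) == 48
        per_a = [c for c in cycles if c.chamber.tree_id == "A"]
        assert len(per_a) == 24
        starts = [c.start_time for c in per_a]
        assert all((b - a).total_seconds() == 3600.0
                   for a, b in zip(starts, starts[1:]))

    def test_linear_drift_offsets_day_21_by_210ppm(self, chamber):
        cfg = SimulationConfig(resp_flux=2.0, drift_ppm_per_day=10.0)
        cycles = simulate_campaign(cfg, [chamber], n_days=22)
        # same clock hour, 21 days apart → identical conditions, pure drift
        assert cycles[21 * 24].co2_ppm[0] - cycles[0].co2_ppm[0] == \
            pytest.approx(210.0, abs=1e-9)

    def test_chambers_receive_independent_noise(self):
        cfg = SimulationConfig(resp_flux=2.0, noise_sd_co2=2.0, seed=3)
        chambers = [ChamberSpec(tree_id="A"), ChamberSpec(tree_id="B")]
        a, b = simulate_campaign(cfg, chambers, n_days=1)[0::24]
        assert not np.array_equal(a.co2_ppm, b.co2_ppm)

    def test_diel_temperature_cycle_applied(self, quiet_config, chamber):
        cycles = simulate_campaign(quiet_config, [chamber], n_days=1)
        temps = np.array([c.temp_C[0] for c in cycles])
        assert temps.max() > temps.min()
        assert np.argmax(temps) == 15  # peak at mid-afternoon


class TestFlasksAndAtmosphere:
    def test_linear_atmosphere_hand_values(self):
        atm = make_linear_atmosphere(2018, 2.3, 4.7, 2)
        assert atm(2018) == pytest.approx(2.3)
        assert atm(2019) == pytest.approx(-2.4)
        flat = make_linear_atmosphere(2000, 10.0, 0.0, 5)
        assert flat(2002.5) == pytest.approx(10.0)
        long = make_linear_atmosphere(2000, 100.0, 4.7, 22)
        assert long(2021) == pytest.approx(100.0 - 4.7 * 21)

    def test_flask_endmember_and_midpoint_signatures(self):
        atm = make_linear_atmosphere(2000, 50.0, 4.7, 22)
        carb = simulate_flask(SubstrateMix(f_lipid=0.0), atm, 2018.0)
        assert carb.d13c_raw == pytest.approx(-27.11)
        mid = simulate_flask(SubstrateMix(f_lipid=0.5), atm, 2018.0)
        assert mid.d13c_raw == pytest.approx(-29.125)

    def test_zero_age_inherits_current_atmosphere(self):
        atm = make_linear_atmosphere(2018, 2.3, 4.7, 2)
        s = simulate_flask(SubstrateMix(age_years=0.0), atm, 2018.0)
        assert s.D14C == pytest.approx(2.3)

    def test_fixation_year_outside_record_raises(self):
        atm = make_linear_atmosphere(2018, 2.3, 4.7, 2)
        with pytest.raises(ValueError):
            simulate_flask(SubstrateMix(age_years=30.0), atm, 2018.0)


class TestOROImages:
    def test_zero_target_is_blank(self):
        img = simulate_oro_image(0.0, size_px=(400, 200), seed=1)
        assert img.true_coverage_pct == 0.0
        assert not stain_mask(img).any()

    def test_realized_coverage_matches_pixel_count(self):
        img = simulate_oro_image(1.0, droplet_radius_um=(10, 40),
                                 um_per_px=2.0, size_px=(2000, 2000), seed=5)
        frac = stain_mask(img).mean() * 100.0
        assert frac == pytest.approx(img.true_coverage_pct, abs=1e-9)
        assert img.true_coverage_pct == pytest.approx(1.0, abs=0.02)

    def test_same_seed_is_bit_identical(self):
        a = simulate_oro_image(2.0, size_px=(500, 300), seed=9)
        b = simulate_oro_image(2.0, size_px=(500, 300), seed=9)
        assert np.array_equal(a.pixels, b.pixels)

    def test_unreachable_coverage_raises(self):
        # smallest admissible droplet (100 px radius) alone exceeds a 5%
        # target on a 300×300 px image
        with pytest.raises(ValueError):
            simulate_oro_image(5.0, droplet_radius_um=(200, 400),
                               um_per_px=2.0, size_px=(300, 300), seed=0)

    def test_png_round_trip(self, tmp_path):
        img = simulate_oro_image(1.5, size_px=(300, 200), seed=2)
        img.save(tmp_path / "section.png")
        back = OROImage.load(tmp_path / "section.png")
        assert np.array_equal(back.pixels, img.pixels)
        assert back.um_per_px == img.um_per_px
        assert back.true_coverage_pct == pytest.approx(img.true_coverage_pct)
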