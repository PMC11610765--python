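"""Biphasic effective-temperature model and thermal lineshape response."""

import numpy as np
import pytest

from qband import fixtures
from qband.spectral import VibronicBand
from qband.thermal import (
    ThermalConfig,
    deposited_energy,
    energy_flow,
    peak_time,
    predict_band_evolution,
    simulate_Tm,
    temp_to_linewidth,
)


class TestDepositedEnergy:
    def test_resonant_excitation_deposits_nothing(self):
        cfg = ThermalConfig(E_photon=14925.0, E_00=14925.0)
        assert deposited_energy(cfg) == 0.0

    def test_b_excitation_deposits_more_than_q(self):
        b = fixtures.load_thermal_config("acetone", "B")
        q = fixtures.load_thermal_config("acetone", "Q")
        assert deposited_energy(b) > deposited_energy(q) > 0.0

    def test_blue_excitation_value(self):
        cfg = ThermalConfig(E_photon=23256.0, E_00=14925.0)
        assert deposited_energy(cfg) == pytest.approx(8331.0)


class TestTemperatureTrace:
    def test_closed_form_peak_time(self):
        assert peak_time(1.0, 8.0) == pytest.approx(8.0 * np.log(8.0) / 7.0, abs=1e-12)
        assert peak_time(1.0, 8.0) == pytest.approx(2.377, abs=5e-4)

    def test_no_deposited_energy_stays_at_bath(self):
        cfg = ThermalConfig(E_photon=14925.0, E_00=14925.0)
        tr = simulate_Tm(cfg, np.linspace(0, 40, 100))
        assert np.allclose(tr.T_m, cfg.T_bath)

    def test_rise_then_decay_with_peak_at_tstar(self):
        cfg = fixtures.load_thermal_config("acetone", "B")
        t = np.linspace(0.0, 60.0, 6001)
        tr = simulate_Tm(cfg, t)
        tstar = peak_time(cfg.tau_ivr, cfg.tau_vc)
        i = np.argmax(tr.T_m)
        assert t[i] == pytest.approx(tstar, abs=0.02)
        assert np.all(np.diff(tr.T_m[: i - 1]) > 0)
        assert np.all(np.diff(tr.T_m[i + 1 :]) < 0)
        assert np.all(tr.T_m >= cfg.T_bath)

    def test_peak_temperature_ordering_b_above_q(self):
        t = np.linspace(0.0, 60.0, 600)
        peak_b = simulate_Tm(fixtures.load_thermal_config("acetone", "B"), t).T_m.max()
        peak_q = simulate_Tm(fixtures.load_thermal_config("acetone", "Q"), t).T_m.max()
        assert peak_b > peak_q

    def test_tail_slope_is_cooling_rate(self):
        cfg = fixtures.load_thermal_config("acetone", "B")
        t = np.linspace(4.0 * cfg.tau_vc, 10.0 * cfg.tau_vc, 400)
        tr = simulate_Tm(cfg, t)
        slope = np.polyfit(t, np.log(tr.T_m - cfg.T_bath), 1)[0]
        assert slope == pytest.approx(-1.0 / cfg.tau_vc, rel=0.01)

    def test_confluent_limit_handled(self):
        with pytest.raises(ValueError):
            ThermalConfig(E_photon=2e4, tau_ivr=2.0, tau_vc=2.0)
        # the near-degenerate case uses the confluent form smoothly
        cfg = ThermalConfig(E_photon=2e4, tau_ivr=2.0, tau_vc=2.0 + 1e-13)
        tr = simulate_Tm(cfg, np.array([2.0]))
        assert np.isfinite(tr.T_m).all()

    def test_solvent_fixtures_order_cooling_tails(self):
        t = np.linspace(30.0, 60.0, 200)
        tails = {}
        for solvent in ("benzonitrile", "acetone", "ethanol"):
            cfg = fixtures.load_thermal_config(solvent, "B")
            tails[solvent] = simulate_Tm(cfg, t).T_m[-1]
        # slower cooling (larger tau_vc) leaves a hotter tail
        assert tails["ethanol"] > tails["acetone"] > tails["benzonitrile"]


class TestEnergyBookkeeping:
    def test_heat_delivered_to_bath_equals_deposit(self):
        cfg = fixtures.load_thermal_config("acetone", "B")
        flow = energy_flow(cfg, np.array([0.0, 1.0, 200.0]))
        assert flow["to_bath"][0] == pytest.approx(0.0, abs=1e-9)
        assert flow["to_bath"][-1] == pytest.approx(flow["E_dep"], rel=1e-8)

    def test_pools_always_sum_to_deposit(self):
        cfg = fixtures.load_thermal_config("acetone", "B")
        t = np.linspace(0.0, 100.0, 500)
        flow = energy_flow(cfg, t)
        total = flow["hot"] + flow["thermal"] + flow["to_bath"]
        assert np.allclose(total, flow["E_dep"], rtol=1e-12)


class TestLineshapeResponse:
    def test_width_at_bath_temperature_is_sigma0(self, qy_band):
        assert temp_to_linewidth(293.0, qy_band, T_bath=293.0) == qy_band.sigma

    def test_width_monotone_in_temperature(self, qy_band):
        T = np.linspace(293.0, 500.0, 50)
        sig = temp_to_linewidth(T, qy_band, T_bath=293.0)
        assert np.all(np.diff(sig) > 0)

    def test_negative_temperature_rejected(self, qy_band):
        with pytest.raises(ValueError):
            temp_to_linewidth(-1.0, qy_band)

    def test_band_width_peaks_at_tstar_and_relaxes(self, qy_band):
        cfg = fixtures.load_thermal_config("acetone", "B")
        axis = np.linspace(12000.0, 18500.0, 2000)
        delays = [0.2, peak_time(cfg.tau_ivr, cfg.tau_vc), 20.0]
        specs = predict_band_evolution(cfg, qy_band, delays, axis)
        widths = [s.meta["sigma"] for s in specs]
        assert widths[1] > widths[0] and widths[1] > widths[2]
        assert widths[2] == pytest.approx(qy_band.sigma, rel=0.02)

    def test_band_area_conserved(self, qy_band):
        cfg = fixtures.load_thermal_config("acetone", "B")
        axis = np.linspace(10000.0, 21000.0, 4000)
        specs = predict_band_evolution(cfg, qy_band, [0.2, 1.0, 20.0], axis)
        areas = [np.trapezoid(s.values, s.axis) for s in specs]
        assert np.allclose(areas, areas[0], rtol=1e-8)

    def test_no_deposit_means_static_spectra(self, qy_band):
        cfg = ThermalConfig(E_photon=14925.0, E_00=14925.0)
        axis = np.linspace(12000.0, 18500.0, 500)
        specs = predict_band_evolution(cfg, qy_band, [0.1, 5.0, 30.0], axis)
        for s in specs[1:]:
            assert np.array_equal(s.values, specs[0].values)
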