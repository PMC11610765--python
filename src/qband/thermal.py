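"""Biphasic heat-flow model: effective molecular temperature and lineshape.

Photoexcitation above the Q_y origin deposits the excess photon energy into
the vibrational manifold.  Intramolecular vibrational redistribution (IVR,
timescale ``tau_ivr`` ~ 1 ps) thermalizes that energy into an effective
molecular temperature T_m, which then relaxes by vibrational cooling (VC,
``tau_vc`` ~ 7-9 ps) into the solvation shell:

    T_m(t) = T_bath + (E_dep / C) * k * (exp(-t/tau_vc) - exp(-t/tau_ivr))

with k normalizing the biphasic bracket to unit peak, so the peak
temperature rise is exactly E_dep / C.  The underlying two-compartment flow
(hot-mode pool -> thermal pool -> bath) conserves energy: the heat
integrated into the bath equals E_dep.

The hot Q_y band responds through a harmonic-bath-motivated width law
``sigma(T) = sqrt(sigma0^2 + a^2 (T - T_bath))``: broadening while T_m
rises, narrowing while it cools, at constant integrated band area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import Spectrum, VibronicBand, fc_progression

__all__ = [
    "ThermalConfig",
    "TemperatureTrace",
    "deposited_energy",
    "peak_time",
    "simulate_Tm",
    "temp_to_linewidth",
    "predict_band_evolution",
]


@dataclass
class ThermalConfig:
    """Parameters of the biphasic energy-flow model.

    Energies in cm^-1, times in ps, temperatures in K; ``heat_capacity`` is
    an effective constant in cm^-1 per K (peak temperature rise is
    deposited energy divided by it).
    """

    E_photon: float
    E_00: float = 14925.0
    tau_ivr: float = 1.0
    tau_vc: float = 8.0
    T_bath: float = 293.0
    heat_capacity: float = 83.3

    def __post_init__(self):
        if self.tau_ivr <= 0 or self.tau_vc <= 0:
            raise ValueError("timescales must be > 0")
        if self.tau_vc <= self.tau_ivr:
            raise ValueError("tau_vc must exceed tau_ivr (cooling slower than IVR)")
        if self.heat_capacity <= 0:
            raise ValueError("heat_capacity must be > 0")


@dataclass
class TemperatureTrace:
    times: np.ndarray  # ps
    T_m: np.ndarray  # K

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.T_m = np.asarray(self.T_m, dtype=float)
        if self.times.shape != self.T_m.shape:
            raise ValueError("times and T_m must have the same shape")


def deposited_energy(config: ThermalConfig) -> float:
    """Excess vibrational energy E_dep = max(E_photon - E_00, 0) in cm^-1."""
    return max(config.E_photon - config.E_00, 0.0)


def peak_time(tau_ivr: float, tau_vc: float) -> float:
    """Closed-form peak time of the biphasic bracket (ps).

    t* = tau_i tau_v ln(tau_v / tau_i) / (tau_v - tau_i); the confluent
    limit tau_v -> tau_i gives t* = tau.
    """
    if abs(tau_vc - tau_ivr) < 1e-12 * tau_vc:
        return tau_ivr
    return tau_ivr * tau_vc * np.log(tau_vc / tau_ivr) / (tau_vc - tau_ivr)


def _biphasic(t, tau_ivr, tau_vc):
    t = np.asarray(t, dtype=float)
    if abs(tau_vc - tau_ivr) < 1e-12 * tau_vc:
        # confluent (equal-timescale) limit: (t/tau) e^(1 - t/tau), unit peak
        x = np.clip(t, 0, None) / tau_ivr
        return x * np.exp(1.0 - x)
    bracket = np.exp(-np.clip(t, 0, None) / tau_vc) - np.exp(-np.clip(t, 0, None) / tau_ivr)
    bracket[t < 0] = 0.0
    tstar = peak_time(tau_ivr, tau_vc)
    peak = np.exp(-tstar / tau_vc) - np.exp(-tstar / tau_ivr)
    return bracket / peak


def simulate_Tm(config: ThermalConfig, times) -> TemperatureTrace:
    """Effective molecular temperature T_m(t) on the given time axis (ps)."""
    e_dep = deposited_energy(config)
    dT = e_dep / config.heat_capacity
    tm = config.T_bath + dT * _biphasic(times, config.tau_ivr, config.tau_vc)
    return TemperatureTrace(times=np.asarray(times, dtype=float), T_m=tm)


def energy_flow(config: ThermalConfig, times) -> dict:
    """Two-compartment energy bookkeeping underlying T_m(t).

    The deposited energy enters a hot (unthermalized) pool that relaxes
    into the thermal pool with tau_ivr; the thermal pool cools into the
    bath with tau_vc.  Returns the pool energies and the cumulative heat
    delivered to the bath (cm^-1); the latter tends to E_dep, so energy is
    conserved exactly.
    """
    t = np.clip(np.asarray(times, dtype=float), 0.0, None)
    e = deposited_energy(config)
    ti, tv = config.tau_ivr, config.tau_vc
    hot = e * np.exp(-t / ti)
    if abs(tv - ti) < 1e-12 * tv:
        thermal = e * (t / ti) * np.exp(-t / ti)
    else:
        thermal = e * tv / (tv - ti) * (np.exp(-t / tv) - np.exp(-t / ti))
    to_bath = e - hot - thermal
    return {"times": t, "hot": hot, "thermal": thermal, "to_bath": to_bath, "E_dep": e}


def temp_to_linewidth(T, band: VibronicBand, coupling_sd: float = 15.0, T_bath: float = 293.0):
    """Temperature-dependent Gaussian sub-band width (cm^-1).

    sigma(T) = sqrt(sigma0^2 + coupling_sd^2 (T - T_bath)); ``coupling_sd``
    in cm^-1 per sqrt(K) sets the broadening strength.  Monotone in T.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("temperature must be >= 0 K")
    return np.sqrt(band.sigma**2 + coupling_sd**2 * np.clip(T - T_bath, 0.0, None))


def predict_band_evolution(
    config: ThermalConfig,
    band: VibronicBand,
    delays_ps,
    axis,
    coupling_sd: float = 15.0,
) -> list[Spectrum]:
    """Q_y band re-rendered at each delay with the width sigma(T_m(t)).

    The integrated area of every sub-band is held constant (amplitudes
    rescaled by sigma0/sigma), so broadening lowers the peak.
    """
    axis = np.asarray(axis, dtype=float)
    trace = simulate_Tm(config, delays_ps)
    weights = fc_progression(band.huang_rhys, band.n_quanta)
    centers = band.E00 + np.arange(band.n_quanta) * band.omega_vib
    out = []
    for t, T in zip(trace.times, trace.T_m):
        sig = float(temp_to_linewidth(T, band, coupling_sd, config.T_bath))
        vals = np.zeros_like(axis)
        for w, c in zip(weights, centers):
            vals += w * (band.sigma / sig) * np.exp(-0.5 * ((axis - c) / sig) ** 2)
        vals *= band.amplitude
        out.append(
            Spectrum(axis, vals, "absorbance", {"delay_ps": float(t), "T_m": float(T), "sigma": sig})
        )
    return out
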