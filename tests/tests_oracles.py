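"""Independent analytic/brute-force oracles shared by the test suite.

Each function returns a discrepancy between a package computation and an
independently coded reference (closed form or full nonlinear fit), so the
calling tests stay free of implementation details.
"""

import numpy as np
from scipy.optimize import least_squares

from qband.anisotropy import AnisotropyTrace, decompose
from qband.constants import C_CM_PER_FS, HBAR_EV_FS
from qband.globalfit import GlobalKineticModel
from qband.kinetics import InstrumentModel, KineticScheme, SpeciesSpectra, exponential_basis
from qband.qdyn import CouplingSpec, QDConfig, build_model, delta_excitation, propagate
from qband.spectral import Spectrum
from qband.synthesize import gen_ta_map


def varpro_vs_brute_force():
    """Relative lifetime disagreement: variable projection vs full fit."""
    axis = np.linspace(15000.0, 15400.0, 5)
    delays = np.linspace(-50.0, 4000.0, 35)
    rng = np.random.default_rng(12)
    spectra = rng.normal(size=(2, 5))
    ta = gen_ta_map(
        KineticScheme([300.0, 2000.0]),
        SpeciesSpectra(axis=axis, spectra=spectra, kind="SAS"),
        InstrumentModel(irf_fwhm=30.0),
        None,
        "magic",
        delays,
        axis,
        noise_sd=0.005,
        seed=8,
    )
    res = GlobalKineticModel(ta, "sequential", 2, InstrumentModel(30.0)).fit([200.0, 3000.0])

    def full_residual(p):
        taus = np.exp(p[:2])
        das = p[2:].reshape(2, 5)
        basis = exponential_basis(ta.delays[:, None], taus, 30.0, 0.0)[:, 0, :]
        return (ta.dA - basis @ das).ravel()

    p0 = np.concatenate([np.log([200.0, 3000.0]), rng.normal(0, 0.1, 10)])
    brute = least_squares(full_residual, p0, method="lm", xtol=1e-15, ftol=1e-15)
    taus_brute = np.sort(np.exp(brute.x[:2]))
    return float(np.max(np.abs(np.sort(res.lifetimes) - taus_brute) / taus_brute))


def rabi_max_error():
    """Max deviation of a two-level split-operator run from sin^2(Vt/hbar)."""
    V = 0.05
    cfg = QDConfig(
        state_energies=(("S0", 0.0), ("Q_y", 2.0), ("Q_x", 2.0), ("B_x", 9.0), ("B_y", 9.5)),
        couplings=((("Q_x", "Q_y"), CouplingSpec(V, "constant")),),
        dt=0.1,
        t_final=60.0,
    )
    H = build_model(cfg)
    tr, _ = propagate(H, delta_excitation(H, "Q_y"), store_every=1, basis="diabatic")
    expected = np.sin(V * tr.times / HBAR_EV_FS) ** 2
    return float(np.max(np.abs(tr.pop("Q_x") - expected)))


def revival_peak_time():
    """(measured, expected) autocorrelation revival of a coherent state."""
    cfg = QDConfig(couplings=(), mode_freqs_cm1=(1489.0, 1489.0), dt=0.05)
    H = build_model(cfg)
    wf = delta_excitation(H, "S0")
    Q1, Q2 = np.meshgrid(H.q1, H.q2, indexing="ij")
    phi = np.exp(-0.5 * ((Q1 - 1.5) ** 2 + Q2**2))
    wf.amps[0] = phi / np.sqrt(np.sum(np.abs(phi) ** 2) * H.dV)
    psi0 = wf.amps.copy()
    times, ac = [], []
    t = 0.0
    for _ in range(300):
        _, wf = propagate(H, wf, dt=0.025, t_final=0.1, store_every=10, basis="diabatic")
        t += 0.1
        times.append(t)
        ac.append(abs(np.sum(psi0.conj() * wf.amps) * H.dV))
    times, ac = np.array(times), np.array(ac)
    sel = (times > 15.0) & (times < 30.0)
    return float(times[sel][np.argmax(ac[sel])]), 1.0 / (C_CM_PER_FS * 1489.0)


def decomposition_round_trip_error():
    """(additivity error, anisotropy round-trip error) for a random input."""
    rng = np.random.default_rng(21)
    axis = np.linspace(14000.0, 16000.0, 300)
    s = Spectrum(axis, 0.5 + rng.uniform(0.5, 1.5, 300))
    r_in = rng.uniform(-0.19, 0.39, 300)
    comps = decompose(s, AnisotropyTrace(axis, r_in), 17.0)
    additivity = float(
        np.max(np.abs(comps.S_parallel.values + comps.S_orthogonal.values - s.values))
    )
    fr = comps.frame
    r_back = (
        comps.S_parallel.values * fr.r_parallel + comps.S_orthogonal.values * fr.r_orthogonal
    ) / s.values
    round_trip = float(np.max(np.abs(r_back - r_in)))
    return additivity, round_trip
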