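"""End-to-end analysis recipes on the packaged fixtures.

These functions chain the generators and the analysis operations exactly
as a user would at the command line, with the analysis windows and delay
ranges frozen as part of the protocol:

* steady state: optimize the frame angle on the Q_y 0-0 window
  (14700-15200 cm^-1) of the excitation spectrum;
* polarized TA: optimize the frame angle on the red flank of the Q_y
  band (14200-14950 cm^-1) of the noise-free decomposition at the
  representative 120 fs delay (the frame angle is a geometry property;
  determining it on the clean fixture separates it from the noise study),
  then apply it to the noisy maps averaged over 0.3-1 ps - where the
  transient B-band ESA has decayed - and fit the surviving Q_x ground-state
  bleach doublet with a bi-gaussian;
* global analysis: fit/select the sequential model with the longest
  lifetime held at its fluorescence value.
"""

from __future__ import annotations

import numpy as np

from . import fixtures
from .anisotropy import (
    AnisotropyTrace,
    anisotropy_from_pair,
    decompose,
    fit_bigaussian,
    magic_from_pair,
    optimize_beta,
)
from .globalfit import fit_global, select_order
from .spectral import Spectrum
from .synthesize import gen_steady_state_set

__all__ = [
    "steady_state_analysis",
    "taa_analysis",
    "global_analysis",
    "order_selection",
    "quantum_dynamics_summary",
]

QY_WINDOW_STEADY = (14700.0, 15200.0)
QY_WINDOW_TAA = (14200.0, 14950.0)
QX_DOUBLET_WINDOW = (15300.0, 17900.0)
TAA_BETA_DELAY_FS = 120.0
TAA_DOUBLET_DELAYS_FS = (300.0, 1000.0)


def steady_state_analysis(noise_sd: float = 0.0, seed: int | None = None) -> dict:
    """Decompose the steady-state fixture; returns beta*, theta and traces."""
    system, axis = fixtures.load_band_system()
    exc, em, r_exc, r_em = gen_steady_state_set(system, axis, noise_sd=noise_sd, seed=seed)
    beta = optimize_beta(exc, r_exc, QY_WINDOW_STEADY)
    comps = decompose(exc, r_exc, beta)
    i_peak = int(np.argmin(np.abs(axis - system.band("Q_y").E00)))
    return {
        "beta_star": beta,
        "theta_deg": 90.0 - beta,
        "r_at_qy_peak": float(r_exc.r[i_peak]),
        "excitation": exc,
        "emission": em,
        "r_exc": r_exc,
        "r_em": r_em,
        "components": comps,
    }


def _averaged_pair(par, perp, lo_fs, hi_fs):
    """Polarized pair averaged over a delay range -> (S_iso, r trace)."""
    sel = (par.delays >= lo_fs) & (par.delays <= hi_fs)
    ip = par.dA[sel].mean(axis=0)
    ix = perp.dA[sel].mean(axis=0)
    denom = ip + 2.0 * ix
    mask = np.abs(denom) < 1e-3 * np.max(np.abs(denom))
    r = AnisotropyTrace(
        axis=par.axis,
        r=np.where(mask, 0.0, (ip - ix) / np.where(mask, 1.0, denom)),
        mask=mask,
    )
    return Spectrum(par.axis, denom / 3.0, "delta_A"), r


def taa_analysis(seed: int, noise_sd: float | None = None) -> dict:
    """Polarized-TA decomposition: beta*, surviving Q_x doublet, spacing."""
    # frame angle from the clean fixture at the representative delay
    par0, perp0 = fixtures.make_taa_pair(seed=seed, noise_sd=0.0)
    traces = anisotropy_from_pair(par0, perp0)
    i120 = int(np.argmin(np.abs(par0.delays - TAA_BETA_DELAY_FS)))
    iso0 = magic_from_pair(par0, perp0)
    beta = optimize_beta(
        iso0.slice_at(TAA_BETA_DELAY_FS),
        traces[i120],
        QY_WINDOW_TAA,
        suppress="parallel",
        min_intensity=0.05,
    )

    # doublet from the noisy pair, averaged after the B ESA has decayed
    par, perp = fixtures.make_taa_pair(seed=seed, noise_sd=noise_sd)
    s_late, r_late = _averaged_pair(par, perp, *TAA_DOUBLET_DELAYS_FS)
    s_x = decompose(s_late, r_late, beta).S_parallel
    lo, hi = QX_DOUBLET_WINDOW
    win = (s_x.axis >= lo) & (s_x.axis <= hi)
    doublet = Spectrum(s_x.axis[win], s_x.values[win], "delta_A")
    fit = fit_bigaussian(doublet, (16000.0, 17100.0))
    return {
        "beta_star": beta,
        "spacing_cm1": fit.spacing,
        "fit": fit,
        "s_x": s_x,
        "doublet": doublet,
    }


def global_analysis(fixture: str, seed: int, n_components: int | None = None) -> dict:
    """Sequential global fit of a magic-angle fixture map."""
    fx = fixtures.load_ta_fixture(fixture)
    ta = fixtures.make_ta_map(fixture, seed=seed)
    scheme = fx["scheme"]
    n = scheme.n_components if n_components is None else n_components
    # generic initial ladders; best-of-three multistart guards against the
    # local minimum that splits the fast component in two
    from .globalfit import _LADDERS, _ladder_inits

    fix_last = float(scheme.lifetimes[-1]) if scheme.fixed_mask[-1] else None
    res = None
    for ladder in _LADDERS:
        init = _ladder_inits(n, ta.delays, fix_last, ladder)
        cand = fit_global(
            ta,
            "sequential",
            n,
            init,
            fixed_mask=scheme.fixed_mask[:n],
            instrument=fx["instrument"],
        )
        if res is None or cand.ssr < res.ssr:
            res = cand
    # the transfer component is the fastest one carrying significant
    # spectral amplitude and resolvable against the instrument response;
    # near-zero-amplitude or sub-IRF components are unassignable
    amps = np.max(np.abs(res.das.spectra), axis=1)
    significant = amps >= 0.05 * amps.max()
    resolvable = res.lifetimes >= 2.0 * fx["instrument"].irf_fwhm
    fast = float(np.min(res.lifetimes[significant & resolvable]))
    return {
        "result": res,
        "lifetimes_fs": res.lifetimes,
        "fast_lifetime_fs": fast,
        "map": ta,
    }


def quantum_dynamics_summary(
    t_final: float | None = None,
    include_toggles: bool = True,
    include_pulse: bool = True,
) -> dict:
    """Run the frozen coupled-surface model: gap, B 1/e time, toggles, pulse."""
    from .qdyn import apply_pulse, build_model, delta_excitation, propagate, toggle_coupling

    cfg, pulse, pulse_dt = fixtures.load_qd_config()
    H = build_model(cfg)
    trace, _ = propagate(H, delta_excitation(H, "B_y"), t_final=t_final)
    out = {
        "fc_gap_ev": H.adiabatic_gap("Q_x", "Q_y"),
        "b_one_over_e_fs": trace.one_over_e_time("B"),
        "trace": trace,
        "max_norm_drift": float(np.max(np.abs(trace.norms - 1.0))),
        "max_energy_drift_rel": float(
            np.max(np.abs(trace.energies - trace.energies[0])) / abs(trace.energies[0])
        ),
    }
    if include_toggles:
        for pair, key in (("B/Q_x", "b_one_over_e_no_bqx_fs"), ("B/Q_y", "b_one_over_e_no_bqy_fs")):
            cfg_off = toggle_coupling(cfg, pair, off=True)
            H_off = build_model(cfg_off)
            tr_off, _ = propagate(H_off, delta_excitation(H_off, "B_y"), t_final=t_final)
            out[key] = tr_off.one_over_e_time("B")
    if include_pulse:
        wf, _ = apply_pulse(H, pulse, dt=pulse_dt)
        pops = wf.populations("diabatic")
        out["pulse_b_population"] = float(pops[3] + pops[4])
    return out


def order_selection(fixture: str, seed: int, orders=(1, 2, 3, 4, 5), alpha: float = 0.01):
    """Model-order scan of a fixture map with the long lifetime fixed.

    The protocol level is alpha = 0.01: for nested *nonlinear* fits the
    linear-theory F-test is measurably anticonservative (about one seed in
    five adds a spurious component at 0.05 on the four-component fixture),
    and the genuine components here are detected with p far below 1e-3.
    """
    fx = fixtures.load_ta_fixture(fixture)
    ta = fixtures.make_ta_map(fixture, seed=seed)
    fix_last = float(fx["scheme"].lifetimes[-1]) if fx["scheme"].fixed_mask[-1] else None
    return select_order(
        ta,
        "sequential",
        orders,
        alpha=alpha,
        instrument=fx["instrument"],
        fix_last=fix_last,
    )
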