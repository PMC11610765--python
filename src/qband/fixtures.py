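"""Loaders turning the packaged YAML fixtures into model objects.

Fixtures encode the study conditions (lifetimes, geometries, band
positions, noise levels) with known ground truth; every stochastic
generator call takes an explicit seed.
"""

from __future__ import annotations

import numpy as np

from .io import fixture_path, load_yaml
from .kinetics import InstrumentModel, KineticScheme, SpeciesSpectra
from .qdyn import CouplingSpec, PumpPulse, QDConfig, STATES
from .spectral import BandSystem, VibronicBand
from .synthesize import PumpGeometry, add_noise, gen_ta_map
from .tamap import TAMap
from .thermal import ThermalConfig

__all__ = [
    "load_band_system",
    "load_ta_fixture",
    "make_ta_map",
    "make_taa_pair",
    "load_qd_config",
    "load_thermal_config",
]


def _axis(spec: dict) -> np.ndarray:
    return np.linspace(spec["start"], spec["stop"], int(spec["num"]))


def _delays(spec: dict) -> np.ndarray:
    parts = []
    if "linear" in spec:
        p = spec["linear"]
        parts.append(np.arange(p["start"], p["stop"] + 0.5 * p["step"], p["step"]))
    if "log" in spec:
        p = spec["log"]
        parts.append(np.geomspace(p["start"], p["stop"], int(p["num"])))
    return np.unique(np.concatenate(parts))


def _features_to_spectra(species: list, axis: np.ndarray) -> SpeciesSpectra:
    rows = []
    for comp in species:
        vals = np.zeros_like(axis)
        for f in comp["features"]:
            vals += f["amplitude"] * np.exp(-0.5 * ((axis - f["center"]) / f["sigma"]) ** 2)
        rows.append(vals)
    return SpeciesSpectra(axis=axis, spectra=np.asarray(rows), kind="SAS")


def load_band_system(name: str = "chl_a_bands"):
    """Return (BandSystem, axis) of a steady-state band fixture."""
    cfg = load_yaml(fixture_path(name))
    bands = [
        VibronicBand(
            E00=b["E00"],
            omega_vib=b["omega_vib"],
            huang_rhys=b["huang_rhys"],
            sigma=b["sigma"],
            tdm_angle=b["tdm_angle"],
            amplitude=b["amplitude"],
            n_quanta=b["n_quanta"],
            name=b["name"],
        )
        for b in cfg["bands"]
    ]
    return BandSystem(bands), _axis(cfg["axis_cm1"])


def load_ta_fixture(name: str) -> dict:
    """Parse a TA fixture into scheme/instrument/axes/species objects."""
    cfg = load_yaml(fixture_path(name))
    axis = _axis(cfg["axis_cm1"])
    out = {
        "name": name,
        "version": cfg.get("version", 0),
        "scheme": KineticScheme(
            lifetimes=np.asarray(cfg["scheme"]["lifetimes_fs"], dtype=float),
            topology=cfg["scheme"]["topology"],
            fixed_mask=np.asarray(cfg["scheme"]["fixed"], dtype=bool),
        ),
        "instrument": InstrumentModel(
            irf_fwhm=cfg["instrument"]["irf_fwhm_fs"],
            t0=cfg["instrument"]["t0_fs"],
            chirp_coeffs=np.asarray(cfg["instrument"].get("chirp_coeffs", [0.0])),
        ),
        "axis": axis,
        "delays": _delays(cfg["delays_fs"]),
        "noise_sd": float(cfg.get("noise_sd", 0.0)),
        "meta": {
            "fixture": name,
            "fixture_version": cfg.get("version", 0),
            "excitation_band": cfg.get("excitation_band", "?"),
            "solvent": cfg.get("solvent", "?"),
        },
    }
    for key in ("species", "species_x", "species_y"):
        if key in cfg:
            out[key] = _features_to_spectra(cfg[key], axis)
    if "pump_geometry" in cfg:
        out["pump_geometry"] = cfg["pump_geometry"]
    return out


def make_ta_map(name: str, seed: int, noise_sd: float | None = None) -> TAMap:
    """Generate the magic-angle map of a TA fixture with its stated noise."""
    fx = load_ta_fixture(name)
    return gen_ta_map(
        fx["scheme"],
        fx["species"],
        fx["instrument"],
        None,
        "magic",
        fx["delays"],
        fx["axis"],
        noise_sd=fx["noise_sd"] if noise_sd is None else noise_sd,
        seed=seed,
        meta=fx["meta"],
    )


def make_taa_pair(name: str = "chl_a_taa", seed: int = 0, noise_sd: float | None = None):
    """Generate the (parallel, perpendicular) pair of the polarized fixture.

    Each compartment's spectrum is the sum of an x-polarized part (TDM
    along the pumped TDM) and a y-polarized part; the two groups are
    generated separately and summed, so the magic-angle identity holds by
    linearity.  Noise is added once per polarization with seeds derived
    from the master seed.
    """
    fx = load_ta_fixture(name)
    if noise_sd is None:
        noise_sd = fx["noise_sd"]
    geo = fx["pump_geometry"]
    n_comp = fx["scheme"].n_components
    maps = {}
    for i, pol in enumerate(("parallel", "perpendicular")):
        total = None
        for key, angle_key in (("species_x", "x_tdm_angle"), ("species_y", "y_tdm_angle")):
            geometry = PumpGeometry(np.full(n_comp, geo[angle_key]))
            part = gen_ta_map(
                fx["scheme"],
                fx[key],
                fx["instrument"],
                geometry,
                pol,
                fx["delays"],
                fx["axis"],
                noise_sd=0.0,
                seed=None,
                meta=fx["meta"],
            )
            total = part if total is None else TAMap(
                part.delays, part.axis, total.dA + part.dA, pol, part.meta
            )
        if noise_sd > 0:
            total = add_noise(total, noise_sd, seed=int(seed) * 2 + i + 1)
        maps[pol] = total
    return maps["parallel"], maps["perpendicular"]


def load_qd_config(name: str = "qd_default"):
    """Return (QDConfig, PumpPulse, pulse_dt) from a quantum-dynamics fixture."""
    cfg = load_yaml(fixture_path(name))
    energies = tuple((s, float(cfg["state_energies_ev"][s])) for s in STATES)
    couplings = tuple(
        (
            tuple(sorted(c["pair"])),
            CouplingSpec(
                value=float(c["value"]),
                shape=c.get("shape", "linear"),
                mode=int(c.get("mode", 0)),
                center=float(c.get("center", 0.0)),
                width=float(c.get("width", 1.0)),
                center2=None if c.get("center2") is None else float(c["center2"]),
                width2=float(c.get("width2", 1.0)),
            ),
        )
        for c in cfg["couplings"]
    )
    qd = QDConfig(
        mode_freqs_cm1=tuple(cfg["mode_freqs_cm1"]),
        n_points=tuple(cfg["n_points"]),
        extent=float(cfg["extent"]),
        state_energies=energies,
        couplings=couplings,
        dt=float(cfg["dt_fs"]),
        t_final=float(cfg["t_final_fs"]),
    )
    p = cfg["pulse"]
    pulse = PumpPulse(
        peak_field=float(p["peak_field_gv_cm"]),
        fwhm=float(p["fwhm_fs"]),
        omega0=float(p["omega0_ev"]),
        t_center=float(p["t_center_fs"]),
        transition_dipoles=tuple(
            (s, float(v)) for s, v in p["transition_dipoles_au"].items()
        ),
    )
    return qd, pulse, float(p.get("dt_fs", 0.05))


def load_thermal_config(solvent: str = "acetone", band: str = "B") -> ThermalConfig:
    cfg = load_yaml(fixture_path("thermal_solvents"))
    sv = cfg["solvents"][solvent]
    return ThermalConfig(
        E_photon=float(cfg["excitation"][band]["E_photon_cm1"]),
        E_00=float(cfg["E_00_cm1"]),
        tau_ivr=float(sv["tau_ivr_ps"]),
        tau_vc=float(sv["tau_vc_ps"]),
        T_bath=float(cfg["T_bath_K"]),
        heat_capacity=float(cfg["heat_capacity_cm1_per_K"]),
    )
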