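"""Synthetic steady-state and transient-absorption data with known truth.

Everything the analysis chain consumes can be generated here: polarized
steady-state excitation/emission spectra with their anisotropy traces, and
polarized / magic-angle delta-A maps produced by a sequential kinetic scheme
convolved with a Gaussian IRF and an optional probe chirp.

Polarization weights are the standard photoselection factors for an
isotropic ensemble: a species whose probed TDM makes an angle delta with
the pumped TDM contributes with weight ``1 + 0.8 P2(cos delta)`` to the
parallel signal and ``1 - 0.4 P2(cos delta)`` to the perpendicular signal
(magic angle weight 1), so that (parallel + 2 perpendicular)/3 is always
the isotropic signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anisotropy import LOW_INTENSITY_FRACTION, AnisotropyTrace, fundamental_anisotropy
from .kinetics import InstrumentModel, KineticScheme, SpeciesSpectra, sequential_concentrations, exponential_basis
from .spectral import BandSystem, Spectrum, make_vibronic_band
from .tamap import TAMap

__all__ = [
    "PumpGeometry",
    "gen_steady_state_set",
    "gen_ta_map",
    "add_noise",
    "polarization_weight",
]


@dataclass
class PumpGeometry:
    """Per-compartment TDM angles (degrees) relative to the pumped TDM."""

    species_tdm_angles: np.ndarray
    pumped_tdm_angle: float = 0.0

    def __post_init__(self):
        self.species_tdm_angles = np.atleast_1d(
            np.asarray(self.species_tdm_angles, dtype=float)
        )


def polarization_weight(delta_deg, polarization: str):
    """Photoselection factor f_pol for probed-TDM angle delta to the pump."""
    p2 = fundamental_anisotropy(delta_deg) / 0.4
    if polarization == "parallel":
        return 1.0 + 0.8 * p2
    if polarization == "perpendicular":
        return 1.0 - 0.4 * p2
    if polarization == "magic":
        return np.ones_like(np.asarray(delta_deg, dtype=float)) if np.ndim(delta_deg) else 1.0
    raise ValueError(f"unknown polarization {polarization!r}")


def _rng(noise_sd, seed):
    if noise_sd < 0:
        raise ValueError("noise fraction must be >= 0")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    return np.random.default_rng(seed)


def gen_steady_state_set(
    system: BandSystem,
    axis,
    noise_sd: float = 0.0,
    seed: int | None = None,
    emission_band: str = "Q_y",
    stokes_shift: float = 120.0,
    excitation_nm: float = 660.0,
):
    """Excitation/emission spectra and their anisotropy traces.

    Band TDM angles are taken relative to the emissive TDM.  The polarized
    excitation intensities are built per band with the photoselection
    factors and noise is added to the polarized pair, so the returned
    anisotropy carries realistic noise amplification at low intensity.

    Returns ``(excitation, emission, r_exc, r_em)``.
    """
    axis = np.asarray(axis, dtype=float)
    rng = _rng(noise_sd, seed)

    band_specs = [make_vibronic_band(b, axis) for b in system]
    intens = np.array([s.values for s in band_specs])  # (n_bands, n_axis)
    r0 = np.array([fundamental_anisotropy(b.tdm_angle) for b in system])

    iso = intens.sum(axis=0)
    ipar = np.einsum("b,bx->x", 1.0 + 2.0 * r0, intens) / 3.0
    iperp = np.einsum("b,bx->x", 1.0 - r0, intens) / 3.0
    # note ipar + 2*iperp = iso exactly

    scale = noise_sd * np.max(np.abs(iso))
    ipar = ipar + rng.normal(0.0, scale, axis.size) if scale else ipar
    iperp = iperp + rng.normal(0.0, scale, axis.size) if scale else iperp

    denom = ipar + 2.0 * iperp
    mask = np.abs(denom) < LOW_INTENSITY_FRACTION * np.max(np.abs(denom))
    with np.errstate(divide="ignore", invalid="ignore"):
        r_exc = np.where(mask, 0.0, (ipar - iperp) / np.where(mask, 1.0, denom))

    excitation = Spectrum(axis, denom, "excitation", {"seed": seed})
    r_exc_trace = AnisotropyTrace(axis=axis, r=r_exc, mask=mask)

    # emission: mirrored progression of the emissive band, small Stokes shift
    em_band = system.band(emission_band) if emission_band else system.bands[0]
    from .spectral import fc_progression

    weights = fc_progression(em_band.huang_rhys, em_band.n_quanta)
    centers = (em_band.E00 - stokes_shift) - np.arange(em_band.n_quanta) * em_band.omega_vib
    em = np.zeros_like(axis)
    for w, c in zip(weights, centers):
        em += w * np.exp(-0.5 * ((axis - c) / em_band.sigma) ** 2)
    if em.max() > 0:
        em = em / em.max()
    if scale:
        em = em + rng.normal(0.0, noise_sd * 1.0, axis.size)
    emission = Spectrum(axis, em, "emission", {"seed": seed})

    # emission anisotropy: pumped at a fixed wavelength, probed through the
    # emissive TDM -> constant trace at the intensity-weighted r0 there
    exc_wn = 1e7 / excitation_nm
    j = int(np.argmin(np.abs(axis - exc_wn)))
    tot = intens[:, j].sum()
    r_em_val = float(np.dot(intens[:, j], r0) / tot) if tot > 0 else 0.0
    em_mask = np.abs(em) < LOW_INTENSITY_FRACTION
    r_em_trace = AnisotropyTrace(
        axis=axis, r=np.full(axis.size, r_em_val), mask=em_mask
    )
    return excitation, emission, r_exc_trace, r_em_trace


def gen_ta_map(
    scheme: KineticScheme,
    species: SpeciesSpectra,
    instrument: InstrumentModel,
    geometry: PumpGeometry | None,
    polarization: str,
    delays,
    axis,
    noise_sd: float = 0.0,
    seed: int | None = None,
    meta: dict | None = None,
) -> TAMap:
    """Generate a delta-A map from a kinetic scheme and species spectra.

    Concentrations come from the closed-form solution of the scheme's
    first-order ODEs convolved analytically with the Gaussian IRF; the
    chirp enters as a wavenumber-dependent shift of time zero.  Additive
    Gaussian noise has sd ``noise_sd * max|dA|``.
    """
    delays = np.asarray(delays, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if species.n_components != scheme.n_components:
        raise ValueError("species count must equal compartment count")
    if polarization in ("parallel", "perpendicular") and geometry is None:
        raise ValueError(f"{polarization} polarization requested without pump geometry")
    rng = _rng(noise_sd, seed)

    t0 = instrument.t0_of(axis)  # (n_axis,)
    tt = delays[:, None]  # broadcast against t0
    if scheme.topology == "sequential":
        conc = sequential_concentrations(tt, scheme.lifetimes, instrument.irf_fwhm, t0)
    else:
        conc = exponential_basis(tt, scheme.lifetimes, instrument.irf_fwhm, t0)
    # conc: (n_delays, n_axis, n_comp)

    if geometry is not None:
        if geometry.species_tdm_angles.size != scheme.n_components:
            raise ValueError("geometry must give one TDM angle per compartment")
        fpol = np.array(
            [polarization_weight(d, polarization) for d in geometry.species_tdm_angles]
        )
    else:
        fpol = np.ones(scheme.n_components)

    dA = np.einsum("twi,i,iw->tw", conc, fpol, species.spectra)
    if noise_sd > 0:
        dA = dA + rng.normal(0.0, noise_sd * np.max(np.abs(dA)), dA.shape)
    md = {"seed": seed, "noise_sd": noise_sd, **(meta or {})}
    return TAMap(delays=delays, axis=axis, dA=dA, polarization=polarization, meta=md)


def add_noise(obj, noise_sd_fraction: float, seed: int | None = None):
    """Additive white Gaussian noise, sd = fraction * max|values|.

    Deterministic for a fixed seed; fraction 0 returns the input unchanged
    bit-for-bit (same object values, new container).
    """
    if noise_sd_fraction < 0:
        raise ValueError("noise fraction must be >= 0")
    if noise_sd_fraction == 0:
        return obj
    rng = _rng(noise_sd_fraction, seed)
    if isinstance(obj, TAMap):
        sd = noise_sd_fraction * np.max(np.abs(obj.dA))
        return TAMap(
            delays=obj.delays,
            axis=obj.axis,
            dA=obj.dA + rng.normal(0.0, sd, obj.dA.shape),
            polarization=obj.polarization,
            meta=dict(obj.meta, noise_sd=noise_sd_fraction, noise_seed=seed),
        )
    if isinstance(obj, Spectrum):
        sd = noise_sd_fraction * np.max(np.abs(obj.values))
        return obj.copy(
            values=obj.values + rng.normal(0.0, sd, obj.values.shape),
            meta=dict(obj.meta, noise_sd=noise_sd_fraction, noise_seed=seed),
        )
    raise TypeError(f"cannot add noise to {type(obj).__name__}")
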