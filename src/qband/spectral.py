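"""Vibronic band systems and 1D spectra.

Bands are modelled as Franck-Condon progressions of Gaussian sub-bands on a
wavenumber axis: a 0-0 line at ``E00`` and replicas spaced by the vibronic
mode frequency ``omega_vib`` with Poisson intensity weights set by the
Huang-Rhys factor S.  This is the standard displaced-harmonic-oscillator
lineshape at zero temperature and is the stand-in used for the Q_y, Q_x and
B bands of chlorophyll-type chromophores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import exp, lgamma, log

import numpy as np

__all__ = [
    "Spectrum",
    "VibronicBand",
    "BandSystem",
    "fc_progression",
    "make_vibronic_band",
]

_DOMAIN_TAGS = ("absorbance", "excitation", "emission", "delta_A")


@dataclass
class Spectrum:
    """Intensity (or delta-A) versus a strictly ascending wavenumber axis.

    Parameters
    ----------
    axis : array
        Wavenumber grid in cm^-1, strictly ascending.
    values : array
        Intensity (arbitrary units) or delta-A (mOD), same length as axis.
    domain_tag : str
        One of absorbance / excitation / emission / delta_A.
    meta : dict
        Free-form provenance metadata (warnings, seeds, fixture versions).
    """

    axis: np.ndarray
    values: np.ndarray
    domain_tag: str = "absorbance"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis.ndim != 1 or self.axis.shape != self.values.shape:
            raise ValueError("axis and values must be 1D arrays of equal length")
        if self.axis.size >= 2 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly ascending")
        if np.any(~np.isfinite(self.axis)) or np.any(~np.isfinite(self.values)):
            raise ValueError("axis/values must be finite (no NaN/inf)")
        if self.domain_tag not in _DOMAIN_TAGS:
            raise ValueError(f"domain_tag must be one of {_DOMAIN_TAGS}")

    def copy(self, **changes) -> "Spectrum":
        out = replace(self, **changes)
        out.meta = dict(self.meta, **changes.get("meta", {}))
        return out

    def __len__(self):
        return self.axis.size


@dataclass
class VibronicBand:
    """One electronic transition with its Franck-Condon progression.

    ``tdm_angle`` is the angle (degrees) of this band's transition dipole
    moment to the reference TDM of the experiment (the emissive TDM for
    excitation anisotropy, the pumped TDM for transient anisotropy).
    """

    E00: float
    omega_vib: float
    huang_rhys: float
    sigma: float
    tdm_angle: float = 0.0
    amplitude: float = 1.0
    n_quanta: int = 3
    name: str = ""

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.omega_vib <= 0:
            raise ValueError("omega_vib must be > 0")
        if self.huang_rhys < 0:
            raise ValueError("Huang-Rhys factor must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.n_quanta < 1:
            raise ValueError("n_quanta must be >= 1")
        if not 0.0 <= self.tdm_angle <= 90.0:
            raise ValueError("tdm_angle must lie in [0, 90] degrees")


@dataclass
class BandSystem:
    """Ordered collection of vibronic bands (e.g. Q_y, Q_x, B_x, B_y)."""

    bands: list

    def __post_init__(self):
        if not self.bands:
            raise ValueError("band system must contain at least one band")

    def __iter__(self):
        return iter(self.bands)

    def band(self, name: str) -> VibronicBand:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)


def fc_progression(huang_rhys: float, n_quanta: int) -> np.ndarray:
    """Poisson Franck-Condon weights ``w_n = exp(-S) S^n / n!``.

    Returns the first ``n_quanta`` weights (n = 0 .. n_quanta-1).  For S < 1
    the sequence decreases monotonically; the full sum converges to 1.
    """
    if huang_rhys < 0:
        raise ValueError("Huang-Rhys factor must be >= 0")
    if n_quanta < 1:
        raise ValueError("n_quanta must be >= 1")
    n = np.arange(n_quanta)
    if huang_rhys == 0.0:
        w = np.zeros(n_quanta)
        w[0] = 1.0
        return w
    # log-space evaluation keeps large n exact to rounding
    logw = -huang_rhys + n * log(huang_rhys) - np.array([lgamma(k + 1) for k in n])
    return np.exp(logw)


def make_vibronic_band(band: VibronicBand, axis: np.ndarray) -> Spectrum:
    """Render a vibronic band on a wavenumber axis.

    The band is a weight sum of Gaussians centred at ``E00 + n*omega_vib``
    with common width ``sigma``, rescaled so its global maximum equals
    ``amplitude``.  If the axis does not cover E00 +- 3 sigma a
    ``coverage_warning`` flag is set in the result metadata.
    """
    axis = np.asarray(axis, dtype=float)
    weights = fc_progression(band.huang_rhys, band.n_quanta)
    centers = band.E00 + np.arange(band.n_quanta) * band.omega_vib
    vals = np.zeros_like(axis)
    for w, c in zip(weights, centers):
        vals += w * np.exp(-0.5 * ((axis - c) / band.sigma) ** 2)
    meta = {}
    if axis[0] > band.E00 - 3 * band.sigma or axis[-1] < band.E00 + 3 * band.sigma:
        meta["coverage_warning"] = True
    peak = vals.max()
    if band.amplitude == 0.0 or peak == 0.0:
        vals = np.zeros_like(axis)
    else:
        vals *= band.amplitude / peak
    return Spectrum(axis=axis, values=vals, domain_tag="absorbance", meta=meta)


def render_system(system: BandSystem, axis: np.ndarray) -> Spectrum:
    """Sum of all bands of a system on a common axis."""
    axis = np.asarray(axis, dtype=float)
    total = np.zeros_like(axis)
    meta = {}
    for b in system:
        sp = make_vibronic_band(b, axis)
        total += sp.values
        if sp.meta.get("coverage_warning"):
            meta.setdefault("coverage_warning_bands", []).append(b.name or "?")
    return Spectrum(axis=axis, values=total, domain_tag="absorbance", meta=meta)
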