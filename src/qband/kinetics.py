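"""Compartmental kinetic schemes and their IRF-convolved time profiles.

The sequential (unbranched-chain) scheme is solved in closed form: each
compartment concentration is a linear combination of single-exponential
decays (Bateman amplitudes), and the convolution of an exponential decay
with a Gaussian instrument response has the exponentially-modified-Gaussian
(EMG) closed form.  Fitting therefore never integrates ODEs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfcx

__all__ = [
    "KineticScheme",
    "InstrumentModel",
    "SpeciesSpectra",
    "emg_basis",
    "exponential_basis",
    "sequential_amplitudes",
    "sequential_concentrations",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class KineticScheme:
    """Compartmental model: topology, lifetimes (fs) and fixed flags."""

    lifetimes: np.ndarray
    topology: str = "sequential"
    fixed_mask: np.ndarray | None = None

    def __post_init__(self):
        self.lifetimes = np.atleast_1d(np.asarray(self.lifetimes, dtype=float))
        if np.any(self.lifetimes <= 0):
            raise ValueError("lifetimes must be > 0")
        if self.topology not in ("sequential", "parallel"):
            raise ValueError("topology must be 'sequential' or 'parallel'")
        if self.fixed_mask is None:
            self.fixed_mask = np.zeros(self.lifetimes.size, dtype=bool)
        else:
            self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
            if self.fixed_mask.shape != self.lifetimes.shape:
                raise ValueError("fixed_mask must match lifetimes in length")

    @property
    def n_components(self) -> int:
        return self.lifetimes.size


@dataclass
class InstrumentModel:
    """Gaussian IRF plus a polynomial probe chirp t0(wavenumber).

    ``chirp_coeffs`` are polynomial coefficients (ascending powers, degree
    <= 3) in the reduced variable ``(nu - nu_center)/1000`` so that they are
    O(1) numbers; ``t0`` is the global time zero in fs.
    """

    irf_fwhm: float = 30.0
    t0: float = 0.0
    chirp_coeffs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    chirp_center: float | None = None

    def __post_init__(self):
        if self.irf_fwhm <= 0:
            raise ValueError("irf_fwhm must be > 0")
        self.chirp_coeffs = np.atleast_1d(np.asarray(self.chirp_coeffs, dtype=float))
        if self.chirp_coeffs.size > 4:
            raise ValueError("chirp polynomial degree must be <= 3")

    @property
    def irf_sigma(self) -> float:
        return self.irf_fwhm * _FWHM_TO_SIGMA

    def t0_of(self, axis: np.ndarray) -> np.ndarray:
        """Per-wavenumber time zero t0(nu) in fs."""
        axis = np.asarray(axis, dtype=float)
        t0 = np.full(axis.shape, self.t0)
        if self.chirp_coeffs.size and np.any(self.chirp_coeffs != 0):
            center = self.chirp_center if self.chirp_center is not None else axis.mean()
            x = (axis - center) / 1000.0
            t0 = t0 + np.polynomial.polynomial.polyval(x, self.chirp_coeffs)
        return t0


@dataclass
class SpeciesSpectra:
    """Per-compartment spectra (SAS, EAS or DAS) on a common axis.

    Sign convention for delta-A: GSB and SE negative, ESA positive.
    """

    axis: np.ndarray
    spectra: np.ndarray  # (n_components, n_axis)
    kind: str = "SAS"

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if self.spectra.shape[1] != self.axis.size:
            raise ValueError("spectra must have shape (n_components, n_axis)")
        if self.kind not in ("SAS", "EAS", "DAS"):
            raise ValueError("kind must be SAS, EAS or DAS")

    @property
    def n_components(self) -> int:
        return self.spectra.shape[0]


def emg_basis(t, tau: float, irf_fwhm: float, t0=0.0) -> np.ndarray:
    """Exponential decay convolved with a normalized Gaussian IRF.

    Closed form (exponentially modified Gaussian), evaluated through
    ``erfcx`` for numerical stability::

        c(t) = 1/2 * exp(-u^2/2) * erfcx((s/tau - u)/sqrt(2)),
        u = (t - t0)/s,  s = irf_fwhm / (2 sqrt(2 ln 2))

    which tends to the step-function decay ``exp(-(t-t0)/tau)`` as the IRF
    width goes to zero, and to 1/2 of the step amplitude at t = t0 in that
    limit.  ``t`` and ``t0`` may be arrays (broadcast together).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if irf_fwhm < 0:
        raise ValueError("irf_fwhm must be >= 0")
    t = np.asarray(t, dtype=float)
    dt = t - np.asarray(t0, dtype=float)
    if irf_fwhm == 0.0:
        out = np.where(dt >= 0, np.exp(-np.clip(dt, 0, None) / tau), 0.0)
        return out
    s = irf_fwhm * _FWHM_TO_SIGMA
    u = dt / s
    z = (s / tau - u) / np.sqrt(2.0)
    # erfcx(z) exp(-u^2/2) overflows for z << 0; switch to the plain EMG
    # branch exp(s^2/2tau^2 - dt/tau) * erfc(z)/2 with erfc(z) ~= 2 there
    out = np.empty_like(np.broadcast_arrays(u, z)[0], dtype=float)
    late = z < -6.0
    with np.errstate(over="ignore", invalid="ignore"):
        u_b, z_b = np.broadcast_arrays(u, z)
        early = ~late
        out[early] = 0.5 * np.exp(-0.5 * u_b[early] ** 2) * erfcx(z_b[early])
        dt_b = np.broadcast_to(dt, out.shape)
        out[late] = np.exp(0.5 * (s / tau) ** 2 - dt_b[late] / tau)
    return out


def exponential_basis(t, lifetimes, irf_fwhm: float, t0=0.0) -> np.ndarray:
    """Stack of EMG decays, shape ``t.shape + (n_components,)``."""
    cols = [emg_basis(t, tau, irf_fwhm, t0) for tau in np.atleast_1d(lifetimes)]
    return np.stack(cols, axis=-1)


def sequential_amplitudes(lifetimes) -> np.ndarray:
    """Bateman amplitude matrix A of an unbranched sequential chain.

    The concentration of compartment i (unit population entering compartment
    0 at t = 0) is ``c_i(t) = sum_j A[i, j] * exp(-t/tau_j)``; convolution
    with the IRF acts on the exponentials only, so the same matrix links the
    IRF-convolved basis to the compartment profiles, and links EAS to DAS
    (``DAS = A.T @ EAS``).

    Raises
    ------
    ValueError
        if two lifetimes coincide (the transform is singular).
    """
    k = 1.0 / np.atleast_1d(np.asarray(lifetimes, dtype=float))
    n = k.size
    if np.unique(k).size != n:
        raise ValueError("repeated lifetimes: sequential amplitudes singular")
    A = np.zeros((n, n))
    for i in range(n):
        prefac = np.prod(k[:i])  # product of feeding rates
        for j in range(i + 1):
            denom = np.prod([k[l] - k[j] for l in range(i + 1) if l != j])
            A[i, j] = prefac / denom if i else 1.0
    return A


def sequential_concentrations(t, lifetimes, irf_fwhm: float = 0.0, t0=0.0) -> np.ndarray:
    """Compartment concentrations of a sequential chain, IRF-convolved.

    Returns shape ``t.shape + (n_components,)``.
    """
    A = sequential_amplitudes(lifetimes)
    basis = exponential_basis(t, lifetimes, irf_fwhm, t0)
    return basis @ A.T
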