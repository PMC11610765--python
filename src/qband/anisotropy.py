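"""Polarization math: anisotropy, rotated-frame decomposition, band fitting.

The decomposition splits an isotropic spectrum into two components assigned
to a rotated orthogonal frame.  The frame is rotated by an angle ``beta``
from the reference transition dipole (the emissive TDM for excitation data,
the pumped TDM for transient data); the component along the rotated axis
carries the fundamental anisotropy ``0.4 P2(cos beta)`` and the component
along the rotated-orthogonal axis carries ``0.4 P2(cos(90deg - beta))``.
Non-orthogonal pairs of transitions (TDM separation theta = 90deg - beta)
are thereby separated cleanly — beta = 0 recovers the classical orthogonal
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit.models import GaussianModel

from .spectral import Spectrum
from .tamap import TAMap

__all__ = [
    "AnisotropyTrace",
    "DecompositionFrame",
    "PolarizedComponents",
    "BiGaussianFit",
    "fundamental_anisotropy",
    "anisotropy_from_pair",
    "magic_from_pair",
    "decompose",
    "optimize_beta",
    "fit_bigaussian",
]

#: relative intensity below which anisotropy points are flagged invalid
LOW_INTENSITY_FRACTION = 1e-3


def _p2(x):
    return 0.5 * (3.0 * x * x - 1.0)


def fundamental_anisotropy(delta_deg) -> float:
    """Fundamental anisotropy r0 = 0.4 P2(cos delta) for TDM angle delta.

    delta is the angle (degrees, 0..180) between the probed/absorbing TDM
    and the reference TDM; the result lies in [-0.2, 0.4].
    """
    delta = np.asarray(delta_deg, dtype=float)
    if np.any(delta < 0) or np.any(delta > 180):
        raise ValueError("delta must lie in [0, 180] degrees")
    out = 0.4 * _p2(np.cos(np.deg2rad(delta)))
    return float(out) if out.ndim == 0 else out


@dataclass
class AnisotropyTrace:
    """Per-wavenumber anisotropy with a validity mask.

    ``mask`` is True where the point is *invalid* (total intensity below
    `LOW_INTENSITY_FRACTION` of the maximum).
    """

    axis: np.ndarray
    r: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.axis.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.axis.shape == self.r.shape == self.mask.shape):
            raise ValueError("axis, r and mask must have identical shapes")


@dataclass
class DecompositionFrame:
    """Rotated decomposition frame and its two component anisotropies."""

    beta: float
    r_parallel: float = field(init=False)
    r_orthogonal: float = field(init=False)

    def __post_init__(self):
        if not 0.0 <= self.beta <= 45.0:
            raise ValueError("beta must lie in [0, 45] degrees")
        self.r_parallel = fundamental_anisotropy(self.beta)
        self.r_orthogonal = fundamental_anisotropy(90.0 - self.beta)


@dataclass
class PolarizedComponents:
    """The two polarization-associated spectra and their frame.

    ``S_parallel`` is conventionally called S_y for emission-referenced data
    and S_x for pump-referenced data; ``S_parallel + S_orthogonal``
    reconstructs the isotropic input exactly at unmasked points.
    """

    S_parallel: Spectrum
    S_orthogonal: Spectrum
    frame: DecompositionFrame
    mask: np.ndarray


def _check_axes(a, b):
    if a.shape != b.shape or not np.allclose(a, b, rtol=0, atol=1e-9):
        raise ValueError("axes do not match (no silent interpolation)")


def anisotropy_from_pair(par, perp):
    """r = (I_par - I_perp) / (I_par + 2 I_perp) from a polarized pair.

    Accepts two `Spectrum` (returns one `AnisotropyTrace`) or two `TAMap`
    (returns a list of traces, one per delay).  Points where the isotropic
    intensity falls below `LOW_INTENSITY_FRACTION` of its maximum are masked.
    """
    if isinstance(par, TAMap) and isinstance(perp, TAMap):
        _check_axes(par.axis, perp.axis)
        _check_axes(par.delays, perp.delays)
        return [
            _pair_to_trace(par.axis, par.dA[i], perp.dA[i])
            for i in range(par.delays.size)
        ]
    _check_axes(par.axis, perp.axis)
    return _pair_to_trace(par.axis, par.values, perp.values)


def _pair_to_trace(axis, ipar, iperp):
    denom = ipar + 2.0 * iperp
    mask = np.abs(denom) < LOW_INTENSITY_FRACTION * np.max(np.abs(denom))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(mask, 0.0, (ipar - iperp) / np.where(mask, 1.0, denom))
    return AnisotropyTrace(axis=axis, r=r, mask=mask)


def magic_from_pair(par, perp):
    """Isotropic signal (I_par + 2 I_perp) / 3 from a polarized pair."""
    if isinstance(par, TAMap) and isinstance(perp, TAMap):
        _check_axes(par.axis, perp.axis)
        _check_axes(par.delays, perp.delays)
        return TAMap(
            delays=par.delays,
            axis=par.axis,
            dA=(par.dA + 2.0 * perp.dA) / 3.0,
            polarization="magic",
            meta=dict(par.meta, derived_from="polarized_pair"),
        )
    _check_axes(par.axis, perp.axis)
    return par.copy(values=(par.values + 2.0 * perp.values) / 3.0)


def decompose(S_iso: Spectrum, r: AnisotropyTrace, beta: float) -> PolarizedComponents:
    """Split an isotropic spectrum into rotated-frame polarized components.

    ``S_parallel = S_iso (r - r_o) / (r_p - r_o)`` with r_p, r_o the frame
    anisotropies; ``S_orthogonal = S_iso - S_parallel`` so additivity is
    exact by construction.  Masked anisotropy points propagate to the
    output mask (component values there are set to zero).
    """
    if not 0.0 <= beta < 45.0:
        raise ValueError("beta must lie in [0, 45) degrees; beta = 45 is degenerate")
    _check_axes(S_iso.axis, r.axis)
    frame = DecompositionFrame(beta)
    rp, ro = frame.r_parallel, frame.r_orthogonal
    if abs(rp - ro) < 1e-12:
        raise ValueError("degenerate frame: r_parallel equals r_orthogonal")
    frac = (r.r - ro) / (rp - ro)
    s_par = np.where(r.mask, 0.0, S_iso.values * frac)
    s_ort = np.where(r.mask, 0.0, S_iso.values - s_par)
    # compensate the last rounding so S_par + S_orth == S_iso bit-for-bit:
    # recompute the smaller-magnitude component from the larger (rounding
    # error below the sum's half-ulp), nudging the larger on exact ties
    err = np.where(r.mask, 0.0, (s_par + s_ort) - S_iso.values)
    for i in np.nonzero(err)[0]:
        s_i = S_iso.values[i]
        for _ in range(5):
            if abs(s_par[i]) <= abs(s_ort[i]):
                s_par[i] = s_i - s_ort[i]
            else:
                s_ort[i] = s_i - s_par[i]
            if s_par[i] + s_ort[i] == s_i:
                break
            if abs(s_par[i]) <= abs(s_ort[i]):
                s_ort[i] = np.nextafter(s_ort[i], 0.0)
            else:
                s_par[i] = np.nextafter(s_par[i], 0.0)
    meta = dict(S_iso.meta, beta=beta, r_parallel=rp, r_orthogonal=ro)
    return PolarizedComponents(
        S_parallel=Spectrum(S_iso.axis, s_par, S_iso.domain_tag, dict(meta)),
        S_orthogonal=Spectrum(S_iso.axis, s_ort, S_iso.domain_tag, dict(meta)),
        frame=frame,
        mask=r.mask.copy(),
    )


def optimize_beta(
    S_iso: Spectrum,
    r: AnisotropyTrace,
    window: tuple[float, float],
    grid=None,
    suppress: str = "orthogonal",
    min_intensity: float = 0.0,
) -> float:
    """Frame angle that best suppresses one component inside a window.

    Scans ``grid`` (default 0..44.9 deg in 0.1 deg steps) and returns the
    angle minimizing the integrated |component| over the wavenumber window;
    ``suppress`` selects which component is driven to zero there.  For
    emission-referenced data the reference-aligned band is suppressed from
    S_orthogonal (default); for pump-referenced transient data the
    orthogonally polarized band is suppressed from S_parallel.  Ties break
    toward smaller beta.  ``min_intensity`` (fraction of the window maximum
    of |S_iso|) excludes near-zero-signal points whose noisy anisotropy
    would otherwise bias the objective.
    """
    if grid is None:
        grid = np.arange(0.0, 45.0, 0.1)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid >= 45.0):
        raise ValueError("beta grid must lie in [0, 45)")
    if suppress not in ("orthogonal", "parallel"):
        raise ValueError("suppress must be 'orthogonal' or 'parallel'")
    lo, hi = min(window), max(window)
    sel = (S_iso.axis >= lo) & (S_iso.axis <= hi) & ~r.mask
    if not np.any(sel):
        raise ValueError("window lies outside the axis (or is fully masked)")
    if min_intensity > 0:
        sel &= np.abs(S_iso.values) >= min_intensity * np.max(np.abs(S_iso.values[sel]))
    dx = np.gradient(S_iso.axis)[sel]
    best = None
    best_cost = np.inf
    for beta in grid:
        comps = decompose(S_iso, r, beta)
        comp = comps.S_orthogonal if suppress == "orthogonal" else comps.S_parallel
        cost = np.sum(np.abs(comp.values[sel]) * dx)
        if cost < best_cost - 1e-15:  # strict improvement: ties keep smaller beta
            best_cost = cost
            best = beta
    return float(best)


@dataclass
class BiGaussianFit:
    """Two-Gaussian least-squares fit result (centers ascending)."""

    centers: np.ndarray
    widths: np.ndarray
    amplitudes: np.ndarray
    spacing: float
    residual_norm: float
    degenerate: bool = False


def fit_bigaussian(spectrum: Spectrum, init_centers) -> BiGaussianFit:
    """Fit A1 G(c1, s1) + A2 G(c2, s2) to a spectrum.

    ``init_centers`` are the two initial band centers (cm^-1).  The fit is a
    bounded Levenberg-Marquardt least squares; a degenerate outcome (one
    Gaussian swallowing the other: amplitude ratio > 50 or centers closer
    than half the smaller width) is flagged rather than raised.
    """
    c1, c2 = sorted(float(c) for c in init_centers)
    x, y = spectrum.axis, spectrum.values
    if x.size < 10:
        raise ValueError("need at least 10 points to fit a bi-gaussian")
    if not (x[0] <= c1 <= x[-1] and x[0] <= c2 <= x[-1]):
        raise ValueError("initial centers must lie inside the spectral axis")
    span = x[-1] - x[0]
    sign = np.sign(y[np.argmax(np.abs(y))]) or 1.0
    model = GaussianModel(prefix="g1_") + GaussianModel(prefix="g2_")
    params = model.make_params()
    guess_sigma = max(min(abs(c2 - c1) / 3.0, span / 6.0), np.mean(np.diff(x)))
    for pre, c in (("g1_", c1), ("g2_", c2)):
        i = int(np.argmin(np.abs(x - c)))
        params[f"{pre}center"].set(value=c, min=x[0], max=x[-1])
        params[f"{pre}sigma"].set(value=guess_sigma, min=np.mean(np.diff(x)) / 2, max=span)
        height = y[i] if abs(y[i]) > 0 else sign * np.max(np.abs(y))
        params[f"{pre}amplitude"].set(value=height * guess_sigma * np.sqrt(2 * np.pi))
    out = model.fit(y, params, x=x)
    if not out.success:
        raise RuntimeError(
            f"bi-gaussian fit failed to converge (residual {np.linalg.norm(out.residual):.3g})"
        )
    g = [
        (
            out.params[f"{pre}center"].value,
            out.params[f"{pre}sigma"].value,
            out.params[f"{pre}height"].value,
        )
        for pre in ("g1_", "g2_")
    ]
    g.sort(key=lambda t: t[0])
    centers = np.array([g[0][0], g[1][0]])
    widths = np.array([g[0][1], g[1][1]])
    amps = np.array([g[0][2], g[1][2]])
    ratio = np.inf if np.min(np.abs(amps)) == 0 else np.max(np.abs(amps)) / np.min(np.abs(amps))
    degenerate = bool(ratio > 50.0 or abs(centers[1] - centers[0]) < 0.5 * np.min(widths))
    return BiGaussianFit(
        centers=centers,
        widths=widths,
        amplitudes=amps,
        spacing=float(centers[1] - centers[0]),
        residual_norm=float(np.linalg.norm(out.residual)),
        degenerate=degenerate,
    )
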