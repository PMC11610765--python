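"""Excited-state-associated spectra by ground-state-bleach subtraction.

A transient spectrum is the sum of negative ground-state bleach (GSB, a
scaled mirror of the ground-state absorption), negative stimulated emission
and positive excited-state absorption (ESA).  Adding a scaled absorption
spectrum removes the GSB and leaves the excited-state-only (SE + ESA)
spectrum, which can then be compared with externally computed ESA stick
spectra broadened to bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import Spectrum

__all__ = ["ESASticks", "subtract_gsb", "broaden_sticks"]


@dataclass
class ESASticks:
    """Stick spectrum of computed excited-state absorption transitions."""

    energies: np.ndarray  # cm^-1
    strengths: np.ndarray  # oscillator strengths >= 0
    origin_state: str = "Q_y"

    def __post_init__(self):
        self.energies = np.atleast_1d(np.asarray(self.energies, dtype=float))
        self.strengths = np.atleast_1d(np.asarray(self.strengths, dtype=float))
        if self.energies.shape != self.strengths.shape:
            raise ValueError("energies and strengths must have equal length")
        if np.any(self.strengths < 0):
            raise ValueError("oscillator strengths must be >= 0")


def subtract_gsb(
    ta_slice: Spectrum,
    absorption: Spectrum,
    scale: float | str = "auto",
    anchor: float | None = None,
) -> Spectrum:
    """Remove the ground-state bleach from a transient spectrum.

    ``result = ta_slice + s * absorption`` (GSB is negative, so adding a
    scaled absorption removes it).  With ``scale="auto"`` the factor s is
    chosen so the result is zero at ``anchor`` (a wavenumber where only GSB
    contributes, e.g. the blue edge of the Q_y bleach).
    """
    if ta_slice.axis.shape != absorption.axis.shape or not np.allclose(
        ta_slice.axis, absorption.axis
    ):
        raise ValueError("transient and absorption spectra must share one axis")
    if scale == "auto":
        if anchor is None:
            raise ValueError("auto scaling requires an anchor wavenumber")
        if not ta_slice.axis[0] <= anchor <= ta_slice.axis[-1]:
            raise ValueError("anchor lies outside the spectral axis")
        i = int(np.argmin(np.abs(ta_slice.axis - anchor)))
        if absorption.values[i] == 0:
            raise ValueError("absorption vanishes at the anchor: cannot scale")
        s = -ta_slice.values[i] / absorption.values[i]
    else:
        s = float(scale)
    out = ta_slice.values + s * absorption.values
    return Spectrum(
        ta_slice.axis,
        out,
        "delta_A",
        dict(ta_slice.meta, gsb_scale=s, gsb_anchor=anchor),
    )


def broaden_sticks(sticks: ESASticks, sigma: float, axis) -> Spectrum:
    """Broaden a stick spectrum with unit-area Gaussians scaled by strength.

    The integral of the result equals ``sum(strengths) * sigma * sqrt(2 pi)``
    when every stick is covered by the axis.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    axis = np.asarray(axis, dtype=float)
    vals = np.zeros_like(axis)
    for e, f in zip(sticks.energies, sticks.strengths):
        vals += f * np.exp(-0.5 * ((axis - e) / sigma) ** 2)
    return Spectrum(axis, vals, "absorbance", {"origin_state": sticks.origin_state})
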