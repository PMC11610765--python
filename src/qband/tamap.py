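"""Time- and wavelength-resolved transient-absorption containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

POLARIZATIONS = ("parallel", "perpendicular", "magic")


@dataclass
class TAMap:
    """delta-A(delay, wavenumber) matrix with a polarization tag.

    Parameters
    ----------
    delays : array
        Pump-probe delays in fs, ascending.
    axis : array
        Probe wavenumber grid in cm^-1, ascending.
    dA : array, shape (n_delays, n_axis)
        delta-A in mOD.
    polarization : str
        parallel / perpendicular / magic.
    meta : dict
        Excitation band tag, solvent, seed, fixture version, ...
    """

    delays: np.ndarray
    axis: np.ndarray
    dA: np.ndarray
    polarization: str = "magic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.dA = np.asarray(self.dA, dtype=float)
        if self.dA.shape != (self.delays.size, self.axis.size):
            raise ValueError("dA shape must be (n_delays, n_axis)")
        for name, ax in (("delays", self.delays), ("axis", self.axis)):
            if ax.size >= 2 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} must be strictly ascending")
        if np.any(~np.isfinite(self.dA)):
            raise ValueError("dA must not contain NaN/inf")
        if self.polarization not in POLARIZATIONS:
            raise ValueError(f"polarization must be one of {POLARIZATIONS}")

    def slice_at(self, delay_fs: float):
        """Nearest-delay spectral slice as a `Spectrum` (delta_A)."""
        from .spectral import Spectrum

        i = int(np.argmin(np.abs(self.delays - delay_fs)))
        return Spectrum(
            axis=self.axis,
            values=self.dA[i],
            domain_tag="delta_A",
            meta={"delay_fs": float(self.delays[i]), **self.meta},
        )
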