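"""Physical constants and unit conversions.

Internal conventions used throughout the package:

* energy axes in wavenumber (cm^-1), strictly ascending; wavelength (nm)
  appears only at I/O boundaries,
* time in femtoseconds (kinetics, quantum dynamics) or picoseconds (thermal),
* quantum-dynamics energies in eV with hbar in eV*fs,
* dimensionless normal-mode coordinates for the wavepacket grids.
"""

from __future__ import annotations

import numpy as np

#: hbar in eV*fs
HBAR_EV_FS = 0.6582119569

#: 1 cm^-1 in eV  (h*c/e)
CM1_TO_EV = 1.2398419843e-4

#: speed of light in cm/fs (for vibrational periods: T = 1/(c*nu_tilde))
C_CM_PER_FS = 2.99792458e-5

#: atomic unit of electric field expressed in GV/cm
AU_FIELD_GV_CM = 5.14220675  # 5.142e9 V/cm = 5.142 GV/cm

#: hartree in eV
HARTREE_EV = 27.211386


def nm_to_cm1(value_nm):
    """Convert wavelength (nm) to wavenumber (cm^-1). Involutive with itself.

    Raises
    ------
    ValueError
        for non-positive input.
    """
    arr = np.asarray(value_nm, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("wavelength/wavenumber must be positive")
    out = 1e7 / arr
    return out if arr.ndim else float(out)


# the map x -> 1e7/x is its own inverse
cm1_to_nm = nm_to_cm1


def cm1_to_ev(value_cm1):
    return np.asarray(value_cm1, dtype=float) * CM1_TO_EV


def ev_to_cm1(value_ev):
    return np.asarray(value_ev, dtype=float) / CM1_TO_EV
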