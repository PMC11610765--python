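"""Readers and writers: two-column text spectra, HDF5 TA maps, YAML configs.

Units are always declared, never inferred: text spectra carry an
``# axis: nm|cm-1`` header line and TA-map containers store delays in fs
and wavenumbers in cm^-1 as named datasets with provenance attributes.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import h5py
import numpy as np
import yaml

from .constants import nm_to_cm1
from .spectral import Spectrum
from .tamap import TAMap

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_tamap",
    "write_tamap",
    "load_yaml",
    "fixture_path",
]


def read_spectrum(path) -> Spectrum:
    """Read a two-column whitespace/CSV text spectrum.

    The axis unit comes from a ``# axis: nm`` / ``# axis: cm-1`` comment
    line (default cm-1); nm axes are converted to ascending wavenumber with
    the values reordered accordingly.
    """
    unit = "cm-1"
    domain = "absorbance"
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                body = s.lstrip("#").strip()
                if body.lower().startswith("axis:"):
                    unit = body.split(":", 1)[1].strip().lower()
                elif body.lower().startswith("domain:"):
                    domain = body.split(":", 1)[1].strip()
                continue
            parts = s.replace(",", " ").split()
            try:
                x, y = float(parts[0]), float(parts[1])
            except (IndexError, ValueError) as err:
                raise ValueError(f"{path}: malformed row at line {lineno}: {s!r}") from err
            rows.append((x, y))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    axis, values = arr[:, 0], arr[:, 1]
    if unit in ("nm", "nanometer"):
        axis = nm_to_cm1(axis)
    elif unit not in ("cm-1", "cm^-1", "wavenumber"):
        raise ValueError(f"{path}: unknown axis unit {unit!r}")
    order = np.argsort(axis)
    axis, values = axis[order], values[order]
    if np.any(np.diff(axis) <= 0):
        raise ValueError(f"{path}: axis not strictly monotonic after conversion")
    return Spectrum(axis=axis, values=values, domain_tag=domain, meta={"source": str(path)})


def write_spectrum(spectrum: Spectrum, path, unit: str = "cm-1") -> None:
    """Write a spectrum as two-column text (full double precision)."""
    axis = spectrum.axis
    if unit == "nm":
        axis = nm_to_cm1(axis)  # involution: cm-1 -> nm
    elif unit != "cm-1":
        raise ValueError("unit must be 'cm-1' or 'nm'")
    with open(path, "w") as fh:
        fh.write(f"# axis: {unit}\n")
        fh.write(f"# domain: {spectrum.domain_tag}\n")
        for k, v in spectrum.meta.items():
            if isinstance(v, (str, int, float, bool)):
                fh.write(f"# meta {k}: {v}\n")
        for x, y in zip(axis, spectrum.values):
            fh.write(f"{float(x)!r} {float(y)!r}\n")


def write_tamap(ta: TAMap, path) -> None:
    """Write a TA map to HDF5 (/delays fs, /wavenumbers cm-1, /dA mOD)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("delays", data=ta.delays)
        f.create_dataset("wavenumbers", data=ta.axis)
        f.create_dataset("dA", data=ta.dA)
        f.attrs["polarization"] = ta.polarization
        for k, v in ta.meta.items():
            if v is None:
                continue
            if isinstance(v, (str, int, float, bool, np.integer, np.floating)):
                f.attrs[k] = v


def read_tamap(path) -> TAMap:
    """Read an HDF5 TA-map container (lossless round trip)."""
    with h5py.File(path, "r") as f:
        for ds in ("delays", "wavenumbers", "dA"):
            if ds not in f:
                raise ValueError(f"{path}: missing dataset /{ds}")
        meta = {k: (v.item() if hasattr(v, "item") else v) for k, v in f.attrs.items()}
        pol = meta.pop("polarization", "magic")
        return TAMap(
            delays=f["delays"][...],
            axis=f["wavenumbers"][...],
            dA=f["dA"][...],
            polarization=pol,
            meta=meta,
        )


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def fixture_path(name: str) -> Path:
    """Path of a packaged YAML fixture (e.g. ``chl_a_acetone_B``)."""
    if not name.endswith(".yaml"):
        name = name + ".yaml"
    ref = importlib.resources.files("qband") / "fixtures" / name
    return Path(str(ref))
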