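"""Coupled-surface wavepacket dynamics on nested 2D model potentials.

Five electronic states (S0, Q_y, Q_x, B_x, B_y) share identical-curvature
2D harmonic potentials in two dimensionless normal-mode coordinates
(default mode frequencies 1489 and 1639 cm^-1), vertically offset by their
Franck-Condon energies — the "nested potentials" picture with negligible
curve displacement.  Inter-state couplings are explicit diabatic matrix
elements; by default they are linear in the first (strongest-coupling) mode
coordinate, the standard linear-vibronic-coupling stand-in for nonadiabatic
coupling.  A constant inter-state coupling on exactly nested surfaces
commutes with the nuclear Hamiltonian, so it can only produce detuned Rabi
oscillations with amplitude 4V^2/(4V^2 + Delta^2) and no net inter-band
transfer; coordinate-dependent couplings are what allow the vibrational
manifold to absorb the electronic energy gap.

Propagation is second-order split-operator on an FFT grid: half-step
potential-matrix propagators (exact per-point 5x5 exponentials), full-step
kinetic phase in momentum space.  Populations are reported in the per-point
adiabatic basis by default (what transient spectroscopy observes), with the
diabatic basis available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import AU_FIELD_GV_CM, CM1_TO_EV, HARTREE_EV, HBAR_EV_FS

__all__ = [
    "STATES",
    "CouplingSpec",
    "PumpPulse",
    "QDConfig",
    "Hamiltonian",
    "Wavefunction",
    "PopulationTrace",
    "build_model",
    "delta_excitation",
    "propagate",
    "apply_pulse",
    "toggle_coupling",
]

STATES = ("S0", "Q_y", "Q_x", "B_x", "B_y")
_BANDS = {"B": ("B_x", "B_y"), "Q": ("Q_x", "Q_y")}


@dataclass(frozen=True)
class CouplingSpec:
    """One inter-state diabatic coupling.

    ``shape``: "constant" (value, eV), "linear" (value * q_mode, eV per
    unit coordinate) or "gaussian" (value * exp(-(q_mode-center)^2/2w^2),
    optionally times a second Gaussian in the other mode when ``center2``
    is given).  A coupling localized away from the Franck-Condon point
    reaches the high vibrational levels that conserve energy across an
    electronic gap on displacement-free nested surfaces, while leaving the
    adiabatic FC-point gaps untouched.  ``enabled`` implements reversible
    coupling toggles.
    """

    value: float
    shape: str = "linear"
    mode: int = 0
    center: float = 0.0
    width: float = 1.0
    center2: float | None = None
    width2: float = 1.0
    enabled: bool = True

    def __post_init__(self):
        if self.shape not in ("constant", "linear", "gaussian"):
            raise ValueError("shape must be constant, linear or gaussian")
        if self.shape == "gaussian" and (self.width <= 0 or self.width2 <= 0):
            raise ValueError("gaussian coupling widths must be > 0")

    def profile(self, q_modes):
        if not self.enabled:
            return 0.0 * q_modes[0]
        if self.shape == "constant":
            return self.value * np.ones_like(q_modes[0])
        q = q_modes[self.mode]
        if self.shape == "linear":
            return self.value * q
        out = self.value * np.exp(-0.5 * ((q - self.center) / self.width) ** 2)
        if self.center2 is not None:
            q_other = q_modes[1 - self.mode]
            out = out * np.exp(-0.5 * ((q_other - self.center2) / self.width2) ** 2)
        return out


@dataclass(frozen=True)
class PumpPulse:
    """Gaussian-envelope semiclassical pump pulse.

    ``peak_field`` in GV/cm, ``fwhm`` in fs, carrier energy ``omega0`` in
    eV; ``transition_dipoles`` maps excited-state names to ground-to-state
    transition dipole moments in atomic units.
    """

    peak_field: float = 0.0026
    fwhm: float = 20.0
    omega0: float = 3.60
    t_center: float = 40.0
    transition_dipoles: tuple = ()

    def field(self, t):
        """E(t) in GV/cm (real carrier-resolved field)."""
        env = self.peak_field * np.exp(
            -4.0 * np.log(2.0) * ((np.asarray(t, float) - self.t_center) / self.fwhm) ** 2
        )
        return env * np.cos(self.omega0 / HBAR_EV_FS * (np.asarray(t, float) - self.t_center))

    def dipole_matrix(self) -> np.ndarray:
        mu = np.zeros((len(STATES), len(STATES)))
        for state, val in dict(self.transition_dipoles).items():
            j = STATES.index(state)
            mu[0, j] = mu[j, 0] = float(val)
        return mu


#: off-origin seam of the calibrated nonadiabatic-coupling stand-in
_SEAM = dict(shape="gaussian", mode=0, center=2.0, width=0.7, center2=1.0, width2=1.0)


def _default_couplings():
    # frozen calibration: see scripts/calibrate_qd.py and docs/methods.md
    return (
        (("B_x", "B_y"), CouplingSpec(0.030, "constant")),
        (("Q_x", "Q_y"), CouplingSpec(0.110, "linear", mode=1)),
        (("B_x", "Q_x"), CouplingSpec(1.400, **_SEAM)),
        (("B_y", "Q_x"), CouplingSpec(1.400, **_SEAM)),
        (("B_x", "Q_y"), CouplingSpec(0.014, **_SEAM)),
        (("B_y", "Q_y"), CouplingSpec(0.014, **_SEAM)),
    )


def _default_energies():
    # Q_x diabatic offset calibrated so the *adiabatic* Q_x - Q_y gap at
    # the FC point is 0.225 eV exactly under the default couplings
    return (("S0", 0.0), ("Q_y", 1.940), ("Q_x", 2.165291), ("B_x", 3.500), ("B_y", 3.600))


@dataclass(frozen=True)
class QDConfig:
    """Model + propagation parameters (energies eV, times fs)."""

    mode_freqs_cm1: tuple = (1489.0, 1639.0)
    n_points: tuple = (64, 64)
    extent: float = 6.0
    state_energies: tuple = field(default_factory=_default_energies)
    couplings: tuple = field(default_factory=_default_couplings)
    #: per-state vibrational frequency scale (nested wells, slightly
    #: different curvature); 1.0 = the reference (ground-state) frequency
    freq_scales: tuple = (("S0", 1.0), ("Q_y", 1.0), ("Q_x", 1.0), ("B_x", 1.0), ("B_y", 1.0))
    #: per-state equilibrium displacement along mode 1 (dimensionless);
    #: states omitted here sit at the reference origin
    displacements: tuple = ()
    dt: float = 0.1
    t_final: float = 500.0

    def __post_init__(self):
        if any(n % 2 for n in self.n_points):
            raise ValueError("grid sizes must be even for FFT propagation")
        names = [s for s, _ in self.state_energies]
        if list(names) != list(STATES):
            raise ValueError(f"state_energies must cover {STATES} in order")
        object.__setattr__(
            self,
            "couplings",
            tuple((tuple(sorted(pair)), spec) for pair, spec in self.couplings),
        )

    @property
    def energies(self) -> dict:
        return dict(self.state_energies)

    @property
    def mode_freqs_ev(self) -> np.ndarray:
        return np.asarray(self.mode_freqs_cm1, dtype=float) * CM1_TO_EV

    def coupling(self, a: str, b: str) -> CouplingSpec | None:
        key = tuple(sorted((a, b)))
        for pair, spec in self.couplings:
            if pair == key:
                return spec
        return None


def _expand_pair(pair) -> list:
    """Expand band shorthand: ("B", "Q_x") -> [(B_x, Q_x), (B_y, Q_x)]."""
    if isinstance(pair, str):
        pair = tuple(pair.split("/"))
    a, b = pair
    left = _BANDS.get(a, (a,))
    right = _BANDS.get(b, (b,))
    out = [tuple(sorted((x, y))) for x in left for y in right if x != y]
    for x in [s for p in out for s in p]:
        if x not in STATES:
            raise ValueError(f"unknown state {x!r}")
    return out


def toggle_coupling(config: QDConfig, pair, off: bool = True) -> QDConfig:
    """Return a config with the named coupling(s) disabled (or re-enabled).

    ``pair`` may name states ("B_x", "Q_x"), bands ("B", "Q_x") or use the
    string form "B/Q_x".  Toggling off and back on restores the original
    config exactly.
    """
    keys = set(_expand_pair(pair))
    hit = False
    new = []
    for p, spec in config.couplings:
        if p in keys:
            new.append((p, replace(spec, enabled=not off)))
            hit = True
        else:
            new.append((p, spec))
    if not hit:
        raise ValueError(f"no coupling defined for pair {pair!r}")
    return replace(config, couplings=tuple(new))


# -- model construction ---------------------------------------------------------


class Hamiltonian:
    """Grid representation: harmonic scalar + electronic matrix + kinetic."""

    def __init__(self, config: QDConfig):
        self.config = config
        n1, n2 = config.n_points
        L = config.extent
        ground_sd = np.sqrt(0.5)  # |phi0|^2 width of the dimensionless mode
        if L < 5 * ground_sd:
            raise ValueError("grid extent must cover >= 5 coordinate sd of the ground state")
        self.q1 = np.linspace(-L, L, n1, endpoint=False)
        self.q2 = np.linspace(-L, L, n2, endpoint=False)
        self.dq = (self.q1[1] - self.q1[0], self.q2[1] - self.q2[0])
        self.dV = self.dq[0] * self.dq[1]
        Q1, Q2 = np.meshgrid(self.q1, self.q2, indexing="ij")
        self.grid_shape = (n1, n2)
        w = config.mode_freqs_ev
        self.harm = 0.5 * (w[0] * Q1**2 + w[1] * Q2**2)  # common to all states

        ns = len(STATES)
        scales = dict(config.freq_scales)
        shifts = dict(config.displacements)
        C = np.zeros(self.grid_shape + (ns, ns))
        for i, (name, e) in enumerate(config.state_energies):
            C[..., i, i] = e
            s = scales.get(name, 1.0)
            if s != 1.0:
                # curvature deviation from the reference well
                C[..., i, i] += (s**2 - 1.0) * self.harm
            d = shifts.get(name, 0.0)
            if d:
                # equal-curvature well displaced along mode 1; E00 kept at
                # the state energy (the vertical FC energy is E + w1 d^2/2)
                C[..., i, i] += w[0] * (0.5 * d * d - d * Q1) * s**2
        for (a, b), spec in config.couplings:
            i, j = STATES.index(a), STATES.index(b)
            prof = spec.profile((Q1, Q2))
            C[..., i, j] += prof
            C[..., j, i] += prof
        self.C = C

        flat = C.reshape(-1, ns, ns)
        self.adiab_energies, self.adiab_vectors = np.linalg.eigh(flat)
        self.adiab_energies = self.adiab_energies.reshape(self.grid_shape + (ns,))
        # add the common harmonic part to get total adiabatic surfaces
        self._flatC = flat

        p1 = 2.0 * np.pi * np.fft.fftfreq(n1, self.dq[0])
        p2 = 2.0 * np.pi * np.fft.fftfreq(n2, self.dq[1])
        P1, P2 = np.meshgrid(p1, p2, indexing="ij")
        self.kin = 0.5 * (w[0] * P1**2 + w[1] * P2**2)

    # cached propagator pieces keyed by dt
    def _half_potential_propagator(self, dt: float) -> np.ndarray:
        key = ("U_half", dt)
        cache = getattr(self, "_cache", {})
        if key not in cache:
            w, v = np.linalg.eigh(self._flatC)
            phase = np.exp(-1j * w * dt / (2.0 * HBAR_EV_FS))
            U = np.einsum("nik,nk,njk->nij", v, phase, v)
            U *= np.exp(-1j * self.harm.reshape(-1, 1, 1) * dt / (2.0 * HBAR_EV_FS))
            cache[key] = U
            self._cache = cache
        return cache[key]

    def _kinetic_phase(self, dt: float) -> np.ndarray:
        key = ("K", dt)
        cache = getattr(self, "_cache", {})
        if key not in cache:
            cache[key] = np.exp(-1j * self.kin * dt / HBAR_EV_FS)
            self._cache = cache
        return cache[key]

    def adiabatic_gap(self, a: str, b: str, at=(0.0, 0.0)) -> float:
        """Adiabatic energy gap between two surfaces at a grid point (eV).

        Surfaces are indexed by matching the adiabatic state at ``at`` to
        the diabatic state of maximal overlap there.
        """
        i1 = int(np.argmin(np.abs(self.q1 - at[0])))
        i2 = int(np.argmin(np.abs(self.q2 - at[1])))
        n = i1 * self.grid_shape[1] + i2
        vecs = self.adiab_vectors[n]  # (state, surface)
        surf = {s: int(np.argmax(np.abs(vecs[STATES.index(s), :]))) for s in (a, b)}
        e = self.adiab_energies.reshape(-1, len(STATES))[n]
        return float(abs(e[surf[a]] - e[surf[b]]))

    def ground_gaussian(self) -> np.ndarray:
        Q1, Q2 = np.meshgrid(self.q1, self.q2, indexing="ij")
        phi = np.exp(-0.5 * (Q1**2 + Q2**2))
        return phi / np.sqrt(np.sum(np.abs(phi) ** 2) * self.dV)


def build_model(config: QDConfig) -> Hamiltonian:
    """Construct the grid Hamiltonian from a configuration."""
    return Hamiltonian(config)


# -- wavefunctions and observables ----------------------------------------------


@dataclass
class Wavefunction:
    """Per-state complex amplitudes on the 2D coordinate grid."""

    amps: np.ndarray  # (n_states, n1, n2) complex
    hamiltonian: Hamiltonian

    def norm(self) -> float:
        return float(np.sum(np.abs(self.amps) ** 2) * self.hamiltonian.dV)

    def populations(self, basis: str = "diabatic") -> np.ndarray:
        H = self.hamiltonian
        ns = len(STATES)
        flat = self.amps.reshape(ns, -1)
        if basis == "diabatic":
            return np.sum(np.abs(flat) ** 2, axis=1) * H.dV
        if basis == "adiabatic":
            ad = np.einsum("nsi,sn->in", H.adiab_vectors, flat)
            return np.sum(np.abs(ad) ** 2, axis=1) * H.dV
        raise ValueError("basis must be 'diabatic' or 'adiabatic'")

    def energy(self) -> float:
        """Total energy expectation <T> + <V> in eV."""
        H = self.hamiltonian
        psi_p = np.fft.fftn(self.amps, axes=(1, 2))
        norm_p = np.sum(np.abs(psi_p) ** 2)
        t = float(np.sum(H.kin[None] * np.abs(psi_p) ** 2) / norm_p) if norm_p else 0.0
        flat = self.amps.reshape(len(STATES), -1)
        v_el = np.einsum("sn,nst,tn->", flat.conj(), H._flatC, flat).real * H.dV
        v_h = float(np.sum(H.harm[None] * np.abs(self.amps) ** 2) * H.dV)
        return t * self.norm() + float(v_el) + v_h


def delta_excitation(H: Hamiltonian, state: str = "B_y") -> Wavefunction:
    """Vertical (delta-pulse) promotion of the ground wavepacket."""
    amps = np.zeros((len(STATES),) + H.grid_shape, dtype=complex)
    amps[STATES.index(state)] = H.ground_gaussian()
    return Wavefunction(amps=amps, hamiltonian=H)


@dataclass
class PopulationTrace:
    """State populations versus time, plus conservation diagnostics."""

    times: np.ndarray
    populations: np.ndarray  # (n_states, n_times)
    basis: str = "adiabatic"
    norms: np.ndarray | None = None
    energies: np.ndarray | None = None

    def pop(self, state: str) -> np.ndarray:
        return self.populations[STATES.index(state)]

    def band(self, band: str) -> np.ndarray:
        return sum(self.pop(s) for s in _BANDS[band])

    def one_over_e_time(self, band: str = "B") -> float:
        """First time the band population drops below 1/e of its initial value.

        Returns +inf if it never does within the simulated window.
        """
        p = self.band(band)
        target = p[0] / np.e
        below = np.nonzero(p < target)[0]
        if below.size == 0:
            return np.inf
        i = below[0]
        if i == 0:
            return float(self.times[0])
        # linear interpolation to the crossing
        t0, t1 = self.times[i - 1], self.times[i]
        p0, p1 = p[i - 1], p[i]
        return float(t0 + (p0 - target) / (p0 - p1) * (t1 - t0))


def propagate(
    H: Hamiltonian,
    psi0: Wavefunction,
    dt: float | None = None,
    t_final: float | None = None,
    store_every: int = 10,
    basis: str = "adiabatic",
    pulse: PumpPulse | None = None,
) -> tuple[PopulationTrace, Wavefunction]:
    """Split-operator propagation; returns (trace, final wavefunction).

    Norm is checked every stored frame; drift beyond 1e-6 raises a
    stability error naming the step size and grid.  With ``pulse`` given, a
    semiclassical dipole interaction -mu E(t) is active (extra symmetric
    splitting with the constant dipole-pattern matrix).
    """
    cfg = H.config
    dt = cfg.dt if dt is None else dt
    t_final = cfg.t_final if t_final is None else t_final
    n_steps = int(round(t_final / dt))
    ns = len(STATES)
    n_grid = H.grid_shape[0] * H.grid_shape[1]

    U_half = H._half_potential_propagator(dt)
    K_phase = H._kinetic_phase(dt)

    mu = None
    if pulse is not None:
        m = pulse.dipole_matrix()
        if not np.any(m):
            pulse = None
        else:
            mw, mv = np.linalg.eigh(m)
            mu = (mw, mv)
            if all(
                abs(pulse.omega0 - abs(e - dict(cfg.state_energies)["S0"])) > 1.0
                for s, e in cfg.state_energies
                if s != "S0"
            ):
                warnings.warn("pulse carrier detuned by > 1 eV from every transition")

    psi = psi0.amps.reshape(ns, n_grid).copy()
    wf = Wavefunction(psi.reshape(ns, *H.grid_shape), H)

    times = [0.0]
    pops = [wf.populations(basis)]
    norms = [wf.norm()]
    energies = [wf.energy()]
    norm0 = norms[0]

    def apply_dipole_half(psi, t_mid):
        w, v = mu
        # field (GV/cm) -> interaction energy (eV) per unit dipole (au)
        e_ev = pulse.field(t_mid) / AU_FIELD_GV_CM * HARTREE_EV
        phase = np.exp(1j * e_ev * w * dt / (2.0 * HBAR_EV_FS))  # -(-mu E)
        U = (v * phase) @ v.T.conj()
        return U @ psi

    for step in range(1, n_steps + 1):
        t_mid = (step - 0.5) * dt
        if mu is not None:
            psi = apply_dipole_half(psi, t_mid)
        psi = np.einsum("nij,jn->in", U_half, psi)
        grid = np.fft.fftn(psi.reshape(ns, *H.grid_shape), axes=(1, 2))
        grid *= K_phase[None]
        psi = np.fft.ifftn(grid, axes=(1, 2)).reshape(ns, n_grid)
        psi = np.einsum("nij,jn->in", U_half, psi)
        if mu is not None:
            psi = apply_dipole_half(psi, t_mid)

        if step % store_every == 0 or step == n_steps:
            wf = Wavefunction(psi.reshape(ns, *H.grid_shape), H)
            times.append(step * dt)
            pops.append(wf.populations(basis))
            norms.append(wf.norm())
            energies.append(wf.energy())
            if abs(norms[-1] - norm0) > 1e-6 * max(norm0, 1.0):
                raise RuntimeError(
                    f"norm drift {abs(norms[-1]-norm0):.2e} at t={step*dt:.1f} fs: "
                    f"reduce dt={dt} or enlarge the {H.grid_shape} grid"
                )

    trace = PopulationTrace(
        times=np.asarray(times),
        populations=np.asarray(pops).T,
        basis=basis,
        norms=np.asarray(norms),
        energies=np.asarray(energies),
    )
    return trace, Wavefunction(psi.reshape(ns, *H.grid_shape), H)


def apply_pulse(
    H: Hamiltonian,
    pulse: PumpPulse,
    dt: float = 0.05,
    basis: str = "diabatic",
) -> tuple[Wavefunction, PopulationTrace]:
    """Excite from the nuclear/electronic ground state with an explicit pulse.

    Propagates from t = 0 to t = 2 * pulse.t_center with the semiclassical
    dipole interaction active and returns the wavefunction at the pulse end
    together with the population trace (excited-state populations after the
    pulse are the physically meaningful output).
    """
    amps = np.zeros((len(STATES),) + H.grid_shape, dtype=complex)
    amps[0] = H.ground_gaussian()
    psi0 = Wavefunction(amps, H)
    trace, wf = propagate(
        H,
        psi0,
        dt=dt,
        t_final=2.0 * pulse.t_center,
        store_every=max(int(round(1.0 / dt)), 1),
        basis=basis,
        pulse=pulse,
    )
    return wf, trace
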