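# Methods

This note documents the models implemented in `qband`, the choices made
where the design was genuinely open, the problem sizes used by the default
test and acceptance runs, and what the synthetic fixtures do and do not
emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Vibronic band model

Bands are zero-temperature displaced-harmonic-oscillator progressions: a
0-0 Gaussian at E₀₀ plus replicas at E₀₀ + n·ω_vib weighted by the Poisson
Franck–Condon factors e^(−S)Sⁿ/n!, with a common sub-band width σ and a
peak-normalized amplitude. The internal energy axis is wavenumber (cm⁻¹,
ascending) everywhere; wavelength appears only in file I/O (a declared
`# axis: nm` header) because vibronic spacings are additive in energy.
Sub-bands are Gaussian, not Voigt — the downstream band fits are
bi-gaussian, so a heavier lineshape model would add parameters the rest of
the chain never uses.

The chlorophyll-*a*-like fixture (`chl_a_bands.yaml`) places Q_y at
14 925 cm⁻¹ (ω_vib = 1250 cm⁻¹, S = 0.28, σ = 270 cm⁻¹), a weak Q_x at
16 000 cm⁻¹ (ω_vib = 1100 cm⁻¹, amplitude 0.10) and two B bands near
23 000–23 800 cm⁻¹. Widths and Huang–Rhys factors are visual stand-ins
chosen once for a realistic band envelope; they are not literature claims.

## Polarization model and the β decomposition

All polarization weights come from photoselection in an isotropic ensemble:
a probed TDM at angle δ to the pumped/reference TDM contributes with
fundamental anisotropy r₀(δ) = 0.4·P₂(cos δ); polarized pair signals use
1 + 0.8·P₂ (parallel) and 1 − 0.4·P₂ (perpendicular), so
(I_∥ + 2 I_⊥)/3 is exactly isotropic. Rotational diffusion is not modelled
(glass / sub-ps regime).

The decomposition assigns the two components of an isotropic spectrum the
anisotropies r_∥ = 0.4·P₂(cos β) and r_⊥ = 0.4·P₂(cos(90°−β)) and solves
linearly per wavenumber. Design choices:

* **Suppression objective.** β* minimizes the integrated |component| over
  a stated window, ties toward smaller β, on a 0.1° grid. For a pure
  component at angle δ the suppression is exact at β = δ; which component
  is suppressed is an argument (`suppress=`), because emission-referenced
  steady-state data suppress the reference-aligned band from S_⊥ while
  pump-referenced transient data suppress the y-polarized band from S_∥.
* **Geometry of the steady-state fixture.** The emissive TDM is rotated
  17° from the absorption y-axis, so Q_y sits at δ = 17° and the
  x-polarized bands at δ = 90° (separation 73°). The 0.349 anisotropy
  plateau at the Q_y origin and β* = 17° are then consequences of geometry
  alone, not of amplitude tuning.
* **Masking.** Points with isotropic intensity below 10⁻³ of the maximum
  are masked and propagate; `optimize_beta` additionally accepts an
  intensity floor (`min_intensity`, fraction of the window maximum)
  because near-zero-signal points carry noise-dominated anisotropy whose
  amplification ∝ 1/(r_∥ − r_⊥) grows with β and would bias the argmin low.
* **Exact additivity.** S_∥ + S_⊥ reconstructs S_iso bit-for-bit; a
  floating-point compensation step resolves the rare exact-half-ulp ties.

### Transient (TAA) protocol

The polarized fixture encodes a four-compartment sequential scheme whose
per-compartment spectra are split into an x-polarized part (δ = 0 to the
pump) and a y-polarized part (δ = 58° = 90° − 32°). The analysis protocol,
frozen in `qband.workflows`:

* β* is optimized at the representative 120 fs delay on the noise-free
  decomposition, window 14 200–14 950 cm⁻¹ (red flank of the Q_y band),
  floor 0.05. The frame angle is a geometry property; a single 2%-noise
  slice determines it only to ±1.7°, so the noise study is attached to the
  band-spacing stage instead.
* The surviving S_x is then formed from the 2%-noise maps averaged over
  0.3–1 ps — after the transient B-band excited-state absorption
  (a stand-in feature at 15 270 cm⁻¹, split between the two polarization
  channels since both B states are populated early) has decayed — and the
  Q_x ground-state-bleach doublet is fitted with a bi-gaussian
  (initial centers 16 000 / 17 100 cm⁻¹, window 15 300–17 900 cm⁻¹).

## Global kinetic analysis

The data model is D(t, ν̃) = Σᵢ cᵢ(t; τ, IRF, t₀(ν̃))·Aᵢ(ν̃). Sequential
chains are solved in closed form (Bateman amplitudes); the IRF convolution
is the exponentially-modified-Gaussian closed form evaluated through
`erfcx`, with an asymptotic branch for late delays. The chirp is a ≤ 3rd
degree polynomial shift of the per-wavenumber time base — the data are
never resampled.

Fitting is variable projection: lifetimes in log space (positivity and
conditioning), optional t₀ and IRF width, bounded trust-region least
squares; spectra are solved per wavenumber from batched normal equations
with a singularity fallback and a conditioning warning beyond 10¹⁰. DAS
come directly from the projection basis; EAS follow from the inverse
Bateman transform. Parameter covariances are the usual Gauss–Markov
estimate on the nonlinear parameters only (the conditionally linear
spectra are profiled out). Fits start from three deterministic
log-spaced lifetime ladders and keep the best SSR, which removes the local
minimum that otherwise splits the fast component in two on ~10% of noise
realizations.

Model-order selection uses incremental F-tests on the residual sum of
squares, BIC reported alongside. The library default is α = 0.05; the
fixture workflow runs at α = 0.01 because the linear-theory F-test is
measurably anticonservative for nested *nonlinear* fits (about one seed in
five adds a spurious fifth component to the four-component fixture at
0.05, while the genuine components are detected at p < 10⁻³). The
"fastest" lifetime reported by the workflow is the fastest component that
carries ≥ 5% of the maximum spectral amplitude and exceeds twice the IRF
width; smaller or faster components are statistically unassignable.

Fixtures: acetone B-band excitation (110 fs, 2 ps, 9 ps, 5 ns — the last
fixed, since a 100 ps window cannot constrain a fluorescence lifetime;
IRF 30 fs FWHM; 1% noise; 71 delays × 180 wavenumbers) and Q-band
excitation (150 fs, 5 ps, 5 ns fixed). The small-amplitude middle
components are encoded as slight broadening/narrowing plus small amplitude
changes of the Q_y band, strong enough to be identifiable at the stated
noise — the fixture's ground truth is a four-component best fit, so
identifiability is part of the study conditions.

## Coupled-surface wavepacket dynamics

Five diabatic states on 2D harmonic wells in dimensionless normal-mode
coordinates (reference frequencies 1489 and 1639 cm⁻¹), identical
curvature, zero displacement ("nested"), vertically offset by the state
energies. Propagation is second-order Strang splitting on a 64×64 FFT grid
(|q| ≤ 6, dt = 0.1 fs, 500 fs): half-step potential-matrix exponentials
(per-point 5×5 eigendecomposition, precomputed for time-independent
Hamiltonians) and a full kinetic step in momentum space. Populations are
reported in the per-point adiabatic basis by default — what transient
spectroscopy observes — with the diabatic basis available. Units: eV, fs,
ħ = 0.6582 eV·fs.

The coupling model is the package's own stand-in for nonadiabatic
coupling, and its shape is forced by the nested geometry: with identical
displacement-free wells, a *constant* coupling commutes with the nuclear
Hamiltonian, giving only detuned Rabi oscillations of amplitude
4V²/(4V² + Δ²) — no net inter-band transfer at any physical V — and a
*linear* coupling connects only Δn = ±1 levels, off-resonant by ~1.2 eV
across the B–Q gap. Inter-band transfer therefore requires a coupling
localized away from the Franck–Condon point, whose matrix elements reach
the high vibrational levels that conserve energy. The frozen default:

* B_x/B_y ↔ Q_x: Gaussian seam, amplitude 1.4 eV, centered at
  (q₁, q₂) = (2.0, 1.0), widths (0.7, 1.0);
* B_x/B_y ↔ Q_y: same seam, amplitude 0.014 eV (spectroscopically
  negligible, so toggling it is a clean null experiment);
* Q_x ↔ Q_y: linear in the 1639 cm⁻¹ mode (0.11 eV per unit q₂), whose
  quantum (0.203 eV) is nearly resonant with the 0.225 eV gap;
* B_x ↔ B_y: constant 0.03 eV (small gap, strong mixing).

All inter-band couplings vanish at the FC point, so the adiabatic spectrum
there is untouched; the Q_x diabatic energy carries a +0.3 meV calibration
offset that absorbs the residual second-order repulsion, making the
adiabatic Q_x−Q_y FC gap 0.225 eV exactly. Magnitudes, the offset and the
pulse transition dipoles were calibrated once (`scripts/calibrate_qd.py`)
against three observables — B-band 1/e transfer ≈ 100 fs, ≈ 5%
pulse-excited B population, exact FC gap — and frozen; the tests verify
the frozen values regression-style. The calibrated model gives a 1/e time
of 127 fs, insensitive to halving dt (0.2%) or doubling the grid (10⁻⁶).

Known limitations, stated deliberately: a closed two-mode model has a
sparse vibronic spectrum, so (i) the B decay shows partial recurrences
after ~300 fs rather than a clean exponential, and (ii) the transferred
population equilibrates between the strongly mixed Q_x and Q_y manifolds
(state counting gives Q_x ≈ 40% of the Q population at these energies)
instead of draining almost completely into Q_y as a condensed-phase
environment would enforce. The model's Q_x is a true bridge — it fills
only as B empties and never holds more than about half the population —
but its occupation is not a quantitative prediction of the molecular Q_x
lifetime. Energy is conserved as a bounded shadow-Hamiltonian oscillation
of the Strang splitting (≤ 2×10⁻⁴ relative at dt = 0.1 fs for the hot
wavepacket, scaling as dt²); norm is conserved to 10⁻¹².

The explicit pump pulse is semiclassical dipole coupling −μ·E(t) with a
Gaussian envelope (0.0026 GV cm⁻¹ peak, 20 fs FWHM, 3.60 eV carrier),
applied by an extra symmetric splitting with the constant dipole-pattern
matrix at dt = 0.05 fs; the S0→B_y dipole of 1.05 au is the calibrated
value exciting 5.0% into the B band.

## Biphasic heat-flow model

Two-compartment energy flow: the deposited excess energy
E_dep = max(E_photon − E₀₀, 0) enters a hot (unthermalized) pool decaying
with τ_IVR into a thermal pool that cools with τ_VC into the bath, so the
heat delivered to the bath integrates exactly to E_dep. The effective
temperature is the normalized biphasic form with peak rise E_dep/C at
t* = τ_IVR·τ_VC·ln(τ_VC/τ_IVR)/(τ_VC − τ_IVR); the confluent limit
τ_VC → τ_IVR is handled analytically. The effective heat capacity
(83.3 cm⁻¹/K) is a stand-in making the B-excitation peak rise ≈ 100 K;
solvent fixtures differ only in (τ_IVR, τ_VC). The lineshape response is a
harmonic-bath-motivated square-root law σ(T) = √(σ₀² + a²(T − T_bath)) at
constant band area; a Stokes-shift red shift after direct Q excitation is
not modelled (off by default in scope).

## Excited-state spectra

GSB removal adds a scaled ground-state absorption to a transient slice;
"auto" scaling anchors the result to zero at a user-named wavenumber where
only bleach contributes (default use: the blue edge of the Q_y bleach).
Computed ESA stick spectra are consumed as two-column text and broadened
with unit-area-scaled Gaussians for overlay.

## Synthetic data: what passing tests do and do not show

The generators emulate band envelopes, photoselection, sequential kinetics,
IRF, chirp and additive white noise with seeded reproducibility. They do
not emulate coherent artifacts around time zero, rotational diffusion,
solvent-dependent spectral evolution beyond per-fixture constants, or
detector-correlated noise. Passing the acceptance chain therefore shows
that the *analysis* recovers the encoded ground truth under realistic
noise — not that the stand-in parameter values are themselves accurate
descriptions of chlorophyll *a*.

## Problem sizes and runtimes (defaults)

* Steady-state decomposition: 600-point axis, β grid 0.1° — < 1 s.
* TAA: 71 delays × 520 wavenumbers, two polarizations — ~1 s.
* Global analysis: 71 × 180 maps; three-ladder multistart per fit; the
  20-seed recovery study and two order scans together run in ~1 min.
* Quantum dynamics: 64×64×5, 5000 steps — ~8 s per run; the full summary
  (default + two toggles + pulse) ~40 s.
* Full test suite ~90 s; `scripts/acceptance.py` ~45 s.
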