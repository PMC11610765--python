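# qband

Polarization-resolved spectroscopy and relaxation dynamics of
chlorophyll-type chromophores.

Chlorophyll *a* has two band systems (B/Soret in the blue, Q in the red),
each split into two transitions with nearly — but not exactly —
perpendicular transition dipole moments (TDMs): B_x/B_y and Q_x/Q_y. The
weak Q_x transition overlaps Q_y and its vibronic sidebands, which has kept
both its spectral position and its excited-state lifetime controversial.
`qband` implements, end to end and on synthetic data with known ground
truth, the analysis chain used to untangle this system:

1. **Rotated-frame ("β") decomposition of polarization data.** An isotropic
   spectrum S_iso with anisotropy trace r(ν̃) is split into two
   polarization-associated components. The frame is rotated by β from the
   reference TDM; the components carry anisotropies
   r_∥ = 0.4·P₂(cos β) and r_⊥ = 0.4·P₂(cos(90°−β)), and

       S_∥ = S_iso (r − r_⊥)/(r_∥ − r_⊥),  S_⊥ = S_iso − S_∥.

   Non-orthogonal TDM pairs (separation θ = 90° − β) are thereby separated
   cleanly; β is found by suppressing one component over a stated spectral
   window. Applied to steady-state excitation anisotropy this isolates the
   Q_x spectrum (β ≈ 17°, θ ≈ 73°); applied to transient-absorption
   anisotropy (TAA) it isolates the Q_x ground-state bleach, whose two
   bands are ~1100 cm⁻¹ apart (bi-gaussian fit).

2. **Global kinetic analysis of ΔA(t, ν̃) maps.** Sequential compartment
   models convolved with a Gaussian IRF (exponentially modified Gaussian
   closed form, optional probe chirp) are fitted by variable projection:
   only lifetimes (in log space), time zero and IRF width are iterated,
   while all spectra are solved linearly at each step. Evolution- and
   decay-associated spectra (EAS/DAS) are linked by the exact Bateman
   transform; model order is chosen by nested F-tests with BIC reported.

3. **Coupled-surface wavepacket dynamics.** Five electronic states
   (S0, Q_y, Q_x, B_x, B_y) on nested 2D harmonic surfaces (modes at 1489
   and 1639 cm⁻¹), with explicit diabatic couplings standing in for the
   nonadiabatic coupling, are propagated by a second-order split-operator
   scheme on an FFT grid. The frozen default model has an adiabatic
   Q_x−Q_y gap of exactly 0.225 eV at the Franck–Condon point, transfers
   the B-band population to the Q band with a 1/e time of ≈ 127 fs through
   the Q_x bridge, and an explicit 20 fs / 3.60 eV pump pulse excites ≈ 5%
   into the B band.

4. **Biphasic heat dissipation.** Excess excitation energy E_dep heats an
   effective molecular temperature
   T_m(t) = T_bath + (E_dep/C)·k·(e^(−t/τ_VC) − e^(−t/τ_IVR)), rising with
   intramolecular vibrational redistribution (τ_IVR ≈ 1 ps) and cooling
   into the solvation shell (τ_VC ≈ 7–9 ps), which drives transient
   broadening-then-narrowing of the Q_y band at constant band area.

A synthetic-data module generates every input the chain consumes
(steady-state spectra and anisotropies, polarized / magic-angle TA maps
from sequential schemes with IRF, chirp and seeded noise), so all stages
are testable without downloads.

## Worked example

```python
import numpy as np
from qband import workflows

ss = workflows.steady_state_analysis()
print(f"beta* = {ss['beta_star']:.1f} deg, theta = {ss['theta_deg']:.1f} deg,"
      f" r(Q_y peak) = {ss['r_at_qy_peak']:.3f}")

taa = workflows.taa_analysis(seed=7)
print(f"TAA beta* = {taa['beta_star']:.1f} deg,"
      f" Q_x spacing = {taa['spacing_cm1']:.0f} cm^-1")

fit = workflows.global_analysis("chl_a_acetone_B", seed=1)
print(f"fast lifetime = {fit['fast_lifetime_fs']:.0f} fs")
```

prints

```
beta* = 17.1 deg, theta = 72.9 deg, r(Q_y peak) = 0.348
TAA beta* = 31.9 deg, Q_x spacing = 1097 cm^-1
fast lifetime = 110 fs
```

i.e. the frame rotation that suppresses the y-polarized contribution of
the steady-state excitation spectrum is 17° (TDM separation 73°, matching
the 0.35 anisotropy plateau of the Q_y origin), the transient decomposition
needs 32° and leaves a Q_x bleach doublet spaced by ≈ 1100 cm⁻¹, and the
fastest kinetic component of the B-band-excited map — the B→Q transfer —
comes back at ≈ 110 fs.

The same steps are available as a CLI (`qband simulate | decompose |
globalfit | qd | thermal | esas`), e.g.

```bash
qband thermal --solvent acetone --band B --out tm.csv
# peak T_m = 393.0 K -> tm.csv
qband qd --out qd_populations.csv
# B-band 1/e time: 126.9 fs -> qd_populations.csv
```

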