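# Biphasic heat-flow fixtures per solvent. Only the two timescales differ
# between solvents; the effective heat capacity is a stand-in chosen so
# B-band excitation peaks ~100 K above the bath.
version: 1
E_00_cm1: 14925.0          # Q_y origin (~670 nm)
T_bath_K: 293.0
heat_capacity_cm1_per_K: 83.3
excitation:
  B: {E_photon_cm1: 23256.0}   # ~430 nm
  Q: {E_photon_cm1: 15385.0}   # ~650 nm
solvents:
  acetone: {tau_ivr_ps: 1.0, tau_vc_ps: 8.0}
  ethanol: {tau_ivr_ps: 1.0, tau_vc_ps: 9.0}
  benzonitrile: {tau_ivr_ps: 1.0, tau_vc_ps: 7.0}
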