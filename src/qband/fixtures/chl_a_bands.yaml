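# Chlorophyll-a-like steady-state band system (isopropanol glass stand-in).
# TDM angles are relative to the emissive TDM. The emission TDM is rotated
# 17 deg from the absorption y-axis (vibronic frame rotation), so the Q_y
# absorption band sits at 17 deg and the x-polarized bands at 90 deg:
# Q_x/Q_y TDM separation = 73 deg, and the Q_y anisotropy plateau is
# 0.4*P2(cos 17 deg) = 0.349. Band shapes are visual stand-ins, not claims.
version: 1
axis_cm1: {start: 13500.0, stop: 27000.0, num: 600}
bands:
  - name: Q_y
    E00: 14925.0        # 0-0 at ~670 nm
    omega_vib: 1250.0
    huang_rhys: 0.28
    sigma: 270.0
    tdm_angle: 17.0
    amplitude: 1.0
    n_quanta: 3
  - name: Q_x
    E00: 16000.0        # ~625 nm; weak, overlapping Q_y sidebands
    omega_vib: 1100.0   # vibronic spacing recovered by the bi-gaussian fit
    huang_rhys: 0.55
    sigma: 330.0
    tdm_angle: 90.0
    amplitude: 0.10
    n_quanta: 2
  - name: B_x
    E00: 22990.0        # ~435 nm
    omega_vib: 1200.0
    huang_rhys: 0.40
    sigma: 700.0
    tdm_angle: 90.0
    amplitude: 1.3
    n_quanta: 2
  - name: B_y
    E00: 23810.0        # ~420 nm
    omega_vib: 1200.0
    huang_rhys: 0.40
    sigma: 700.0
    tdm_angle: 17.0
    amplitude: 1.3
    n_quanta: 2
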