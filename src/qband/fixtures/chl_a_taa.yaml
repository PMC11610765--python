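# Polarized TA (TAA) fixture: chlorophyll a in acetone, B-band excitation,
# parallel + perpendicular pump-probe pairs. The same four-compartment
# sequential scheme as the magic-angle B fixture, but each compartment's
# spectrum is split into an x-polarized part (TDM parallel to the pumped
# B_x TDM, angle 0) and a y-polarized part. The y-polarized TDM is at
# 90 - 32 = 58 deg from the pump, so a frame rotation of beta = 32 deg
# removes the Q_y band from the pump-parallel component S_x, leaving the
# Q_x GSB doublet (0-0 at 16000, 0-1 at 17100: spacing 1100 cm^-1).
version: 1
excitation_band: B
solvent: acetone
scheme:
  topology: sequential
  lifetimes_fs: [110.0, 2000.0, 9000.0, 5.0e+6]
  fixed: [false, false, false, true]
instrument:
  irf_fwhm_fs: 30.0
  t0_fs: 0.0
  chirp_coeffs: [0.0]
axis_cm1: {start: 14000.0, stop: 24500.0, num: 520}
delays_fs:
  linear: {start: -100.0, stop: 580.0, step: 20.0}
  log: {start: 700.0, stop: 5000.0, num: 12}
noise_sd: 0.02
pump_geometry:
  x_tdm_angle: 0.0    # probed TDM parallel to the pumped B_x TDM
  y_tdm_angle: 58.0   # y-polarized transitions: 90 deg - beta, beta = 32 deg
species_x:   # x-polarized spectral parts, one per compartment
  - name: B_excited
    features:
      - {center: 23000.0, sigma: 600.0, amplitude: -1.00}   # B_x GSB
      - {center: 15270.0, sigma: 200.0, amplitude: 0.08}    # early B ESA (~655 nm), x part
      - {center: 16000.0, sigma: 300.0, amplitude: -0.15}   # Q_x GSB 0-0
      - {center: 17100.0, sigma: 300.0, amplitude: -0.12}   # Q_x GSB 0-1
  - name: Qy_hot
    features:
      - {center: 23000.0, sigma: 600.0, amplitude: -1.00}
      - {center: 16000.0, sigma: 300.0, amplitude: -0.15}
      - {center: 17100.0, sigma: 300.0, amplitude: -0.12}
  - name: Qy_warm
    features:
      - {center: 23000.0, sigma: 600.0, amplitude: -1.00}
      - {center: 16000.0, sigma: 300.0, amplitude: -0.15}
      - {center: 17100.0, sigma: 300.0, amplitude: -0.12}
  - name: Qy_relaxed
    features:
      - {center: 23000.0, sigma: 600.0, amplitude: -1.00}
      - {center: 16000.0, sigma: 300.0, amplitude: -0.15}
      - {center: 17100.0, sigma: 300.0, amplitude: -0.12}
species_y:   # y-polarized spectral parts, one per compartment
  - name: B_excited
    features:
      - {center: 14925.0, sigma: 280.0, amplitude: -0.30}   # immediate Q_y GSB
      - {center: 15270.0, sigma: 200.0, amplitude: 0.07}    # early B ESA, y part
      - {center: 16175.0, sigma: 380.0, amplitude: -0.08}
      - {center: 23810.0, sigma: 600.0, amplitude: -0.40}   # B_y GSB
  - name: Qy_hot
    features:
      - {center: 14925.0, sigma: 310.0, amplitude: -1.00}   # Q_y GSB + SE
      - {center: 16175.0, sigma: 380.0, amplitude: -0.25}
      - {center: 23810.0, sigma: 600.0, amplitude: -0.40}
  - name: Qy_warm
    features:
      - {center: 14925.0, sigma: 295.0, amplitude: -1.02}
      - {center: 16175.0, sigma: 380.0, amplitude: -0.24}
      - {center: 23810.0, sigma: 600.0, amplitude: -0.40}
  - name: Qy_relaxed
    features:
      - {center: 14925.0, sigma: 285.0, amplitude: -1.04}
      - {center: 16175.0, sigma: 380.0, amplitude: -0.24}
      - {center: 23810.0, sigma: 600.0, amplitude: -0.40}
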