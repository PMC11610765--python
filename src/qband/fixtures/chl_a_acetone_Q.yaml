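# Magic-angle TA fixture: chlorophyll a in acetone, direct Q-band
# excitation. Three sequential compartments: a fast component without
# population-transfer signatures (~150 fs), a small structural/IVR
# component (~5 ps), and the fixed 5 ns excited-state lifetime.
version: 1
excitation_band: Q
solvent: acetone
scheme:
  topology: sequential
  lifetimes_fs: [150.0, 5000.0, 5.0e+6]
  fixed: [false, false, true]
instrument:
  irf_fwhm_fs: 30.0
  t0_fs: 0.0
  chirp_coeffs: [0.0]
axis_cm1: {start: 14000.0, stop: 24500.0, num: 180}
delays_fs:
  linear: {start: -100.0, stop: 580.0, step: 20.0}
  log: {start: 700.0, stop: 95000.0, num: 40}
noise_sd: 0.01
species:
  - name: Qy_hot
    features:
      - {center: 14925.0, sigma: 330.0, amplitude: -1.00}
      - {center: 16175.0, sigma: 400.0, amplitude: -0.25}
      - {center: 23000.0, sigma: 600.0, amplitude: -0.50}
      - {center: 19000.0, sigma: 1500.0, amplitude: 0.25}
  - name: Qy_warm
    features:
      - {center: 14925.0, sigma: 303.0, amplitude: -1.03}
      - {center: 16175.0, sigma: 400.0, amplitude: -0.24}
      - {center: 23000.0, sigma: 600.0, amplitude: -0.50}
      - {center: 19000.0, sigma: 1500.0, amplitude: 0.25}
  - name: Qy_relaxed
    features:
      - {center: 14925.0, sigma: 288.0, amplitude: -1.06}
      - {center: 16175.0, sigma: 400.0, amplitude: -0.23}
      - {center: 23000.0, sigma: 600.0, amplitude: -0.50}
      - {center: 19000.0, sigma: 1500.0, amplitude: 0.25}
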