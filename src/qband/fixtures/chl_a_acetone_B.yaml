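# Magic-angle TA fixture: chlorophyll a in acetone, B-band excitation.
# Four sequential compartments: B->Q transfer (~110 fs), a small-amplitude
# IVR component (~2 ps, slight Q_y broadening), vibrational cooling
# (~9 ps, Q_y narrowing + amplitude growth), and the excited-state
# lifetime (5 ns, held fixed: a 100 ps window cannot constrain it).
# Species spectra are Gaussian-feature stand-ins; delta-A sign convention:
# GSB/SE negative, ESA positive.
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
axis_cm1: {start: 14000.0, stop: 24500.0, num: 180}
delays_fs:
  linear: {start: -100.0, stop: 580.0, step: 20.0}
  log: {start: 700.0, stop: 95000.0, num: 40}
noise_sd: 0.01
species:
  - name: B_excited
    features:
      - {center: 23000.0, sigma: 600.0, amplitude: -1.00}   # B GSB
      - {center: 14925.0, sigma: 280.0, amplitude: -0.15}   # Q_y GSB, small at t=0
      - {center: 18500.0, sigma: 2000.0, amplitude: 0.35}   # broad B ESA
  - name: Qy_hot
    features:
      - {center: 14925.0, sigma: 345.0, amplitude: -0.96}   # hot (broadened) Q_y GSB/SE
      - {center: 16175.0, sigma: 420.0, amplitude: -0.30}   # hot vibronic sideband
      - {center: 23000.0, sigma: 600.0, amplitude: -0.55}   # persistent B GSB
      - {center: 19000.0, sigma: 1500.0, amplitude: 0.25}   # Q_y ESA
  - name: Qy_warm
    features:
      - {center: 14925.0, sigma: 298.0, amplitude: -1.05}
      - {center: 16175.0, sigma: 400.0, amplitude: -0.21}
      - {center: 23000.0, sigma: 600.0, amplitude: -0.55}
      - {center: 19000.0, sigma: 1500.0, amplitude: 0.25}
  - name: Qy_relaxed
    features:
      - {center: 14925.0, sigma: 275.0, amplitude: -1.08}
      - {center: 16175.0, sigma: 400.0, amplitude: -0.23}
      - {center: 23000.0, sigma: 600.0, amplitude: -0.55}
      - {center: 19000.0, sigma: 1500.0, amplitude: 0.25}
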