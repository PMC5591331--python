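# stepwave

Gait event detection from a single lower-back IMU, built around
single-scale continuous-wavelet-transform (CWT) differentiation of the
anterior–posterior (AP) acceleration.

The package provides:

- **Treadmill pipeline** (`stepwave.detect_hs_to`): detrend → 10 Hz
  zero-phase Butterworth low-pass → cumulative integration →
  CWT(gaus1) at a scale chosen from the dominant step frequency
  (`a = Fc / (Fa·Δ)`); local minima are heel strikes (HS). A second
  differentiation with CWT(gaus2) yields toe-offs (TO) from local
  maxima. Extrema are kept only above 40% of the mean candidate
  magnitude, and HS/TO alternation is enforced.
- **Home-like variant** (`stepwave.detect_steps_homelike`): turning
  periods are detected from the integrated yaw rate (excursion > 90°,
  duration 0.5–10 s); step detection then uses a gaus2 wavelet inside
  turns and a db2 wavelet outside, emitting context-labeled STEP events.
- **Turn detection** (`stepwave.detect_turns`, `stepwave.yaw_angle`).
- **Validation statistics** (`stepwave.metrics`): tolerance-capped
  optimal one-to-one event matching, contingency-table metrics
  (sensitivity, specificity, accuracy, PPV, NPV, Cohen's kappa),
  Bland–Altman limits of agreement, ICC(2,1).
- **Synthetic generator** (`stepwave.simulate_treadmill`,
  `stepwave.simulate_homelike`): cadence-locked harmonic AP waveforms
  with per-step ground truth, heel-strike transients, noise, tremor
  tones, scripted turns and idle gaps — so the whole pipeline is
  testable without any recorded data.

The CWT itself (gaus1/gaus2 closed forms, db2 via cascade refinement)
is implemented in-house; no wavelet library is required.

## CLI

```sh
# synthesize a 120 s treadmill-like recording with ground truth
stepwave simulate --mode treadmill --seed 1 --out rec.csv --truth-events truth.csv

# detect HS/TO events (writes events + a JSON run manifest)
stepwave detect rec.csv --out events.csv

# compare against the reference at the 0.3 s tolerance
stepwave validate events.csv truth.csv --event-type HS

# home-like: scripted turns, turn detection, context-labeled steps
stepwave simulate --mode homelike --seed 2 --config sim.yaml --out hl.csv
stepwave turns hl.csv --out turns.json
stepwave detect hl.csv --mode homelike --out steps.csv

# score a printed contingency table directly
stepwave validate --counts 3257 227 361 1083
```

Exit codes: 0 ok, 1 data/format error, 2 usage error. Recordings are
CSV with columns `time_s,acc_ap,acc_ml,acc_v,gyr_ap,gyr_ml,gyr_yaw`
(column map, units and sampling rate configurable via
`RecordingDialect`); events are CSV `time_s,type,context` or JSON.

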