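# tiltpress

Analysis of tilt-table experiments that record craniospinal, arterial,
venous, and abdominal pressures simultaneously — the setting of
shunt-design studies in large-animal models, where the pressure difference
between the proximal (intraventricular) and distal (venous or peritoneal)
end of a CSF shunt depends on posture.

The package covers the full chain from raw multi-channel waveforms to
cohort statistics:

- **Preprocessing** — anti-aliased decimation (1 kHz → 100 Hz working
  rate), z-score spike rejection at σ_crit = 3 with per-step statistics,
  and mean-trace extraction with a 4th-order zero-phase (forward/backward)
  Butterworth lowpass at 0.1 Hz.
- **Tilt statistics** — per-step 10-min arithmetic means, deltas from the
  first 0° baseline, Pearson correlation of cohort step means with tilt
  angle (strong |r| ≥ 0.7, mild 0.3 < |r| < 0.7, weak |r| ≤ 0.3), paired
  dependent t-tests, and OLS regression of deltas on angle.
- **Pulse analysis** — cardiac beat detection (peak/trough alternation) and
  per-step mean pulse pressure (peak-to-trough), with respiratory
  modulation deliberately retained.
- **Transfer functions** — for each subject and tilt step, the bin-by-bin
  FFT ratio `H(f) = Y(f)/X(f)` from the carotid arterial input (cABP) to
  each output channel over a rectangular window, smoothed along
  log-frequency with a zero-phase filter using Gustafsson's
  initial-condition method, averaged across subjects in dB with a
  pointwise Student-t 95% CI, and reduced to resonant peaks, notches, and
  the roll-off slope (OLS of magnitude vs log₁₀ f, dB/decade).
- **Hydrostatics** — the trigonometric column predictor
  `h = d·sin(θ)` and `ΔP = h·ρ·0.73556 mmHg/cmH₂O` between any sensor and
  the ICP reference.
- **Synthetic cohorts** — a seeded generator producing 11-channel
  recordings with exact ground truth (step means, hydrostatic slopes,
  pulse amplitudes, analytic compartment frequency responses), used by the
  test suite so every estimator has a recoverable target.

## Worked example

```python
import numpy as np
from tiltpress import (
    SensorGeometry, hydrostatic_predict,
    default_cohort_config, generate_cohort,
    analyze_cohort, AnalysisConfig,
    cohort_transfer_functions, find_peaks_and_notches, fit_rolloff,
)

# 1. hydrostatic prediction for the ITP sensor 70 cm from the ICP sensor
pred = hydrostatic_predict(SensorGeometry(horizontal_dist_to_icp=70.0), angle=13.0)
print(f"hydrostatic column at 13 deg: {pred.column_height:.1f} cm "
      f"-> {pred.pressure_offset:.1f} mmHg")

# 2. simulate a 6-subject cohort (200 Hz, 60 s steps) and run the statistics
cfg = default_cohort_config(seed=42)
recordings, truth = generate_cohort(cfg)
results = analyze_cohort(recordings, AnalysisConfig(settle_time_s=20.0))
corr = results["correlations"]
mean_corr = corr[corr.statistic == "mean"].set_index("channel")
for ch in ("cABP", "ICP", "ITP", "IVP"):
    row = mean_corr.loc[ch]
    print(f"{ch:5s} r = {row.r:+.2f} ({row.strength_class})")

# 3. transfer functions from cABP and their spectral features
# (TF estimation needs broadband input excitation; the TF-validation
# configuration provides it)
from tiltpress.synthetic_data import tf_validation_config
tf_recordings, tf_truth = generate_cohort(tf_validation_config(seed=42))
ctfs = cohort_transfer_functions(tf_recordings, steps=("0_1",))
feats = find_peaks_and_notches(ctfs[("ICP", "0_1")])
roll = fit_rolloff(ctfs[("ICP", "0_1")], min_span_decades=0.1)
peaks = ", ".join(f"{f:.1f} Hz (+{h:.1f} dB)" for f, h in feats.peaks)
print(f"cABP->ICP resonant peaks: {peaks}")
print(f"cABP->ICP roll-off: {roll.rolloff_db_per_decade:.1f} dB/decade "
      f"over {roll.rolloff_band[0]:.1f}-{roll.rolloff_band[1]:.1f} Hz")
```

Output:

```
hydrostatic column at 13 deg: 15.7 cm -> 11.6 mmHg
cABP  r = -1.00 (strong)
ICP   r = -1.00 (strong)
ITP   r = +1.00 (strong)
IVP   r = +1.00 (strong)
cABP->ICP resonant peaks: 4.3 Hz (+11.3 dB), 11.6 Hz (+5.4 dB)
cABP->ICP roll-off: -17.1 dB/decade over 17.3-24.0 Hz
```

The first line is the fluid-column geometry: a 70 cm horizontal sensor
separation tilted to 13° spans a 15.7 cm vertical column, i.e. 11.6 mmHg of
hydrostatic offset at unit CSF density. The correlation block recovers the
channel-specific signs the generator imposed (arterial and intracranial
pressures fall with head-up tilt; intrathecal and intravesical pressures
rise). The spectral block recovers the two compartment resonances the
cohort was generated with (4.2 and 11.5 Hz) and a roll-off near the
first-order decay of the simulated cascade over the recorded fit band.

## Command line

```bash
tiltpress simulate --config cohort.yaml --out data/ --seed 1
tiltpress analyze  --in data/ --out results/ --settle-time 60
tiltpress tf       --in data/ --out results/
tiltpress report   --in data/ --out results/
```

`simulate` writes one HDF5 file per subject plus `ground_truth.json`;
`analyze` writes step summaries, correlations, paired tests, and the
regression table; `tf` writes long-format cohort transfer functions and a
feature table.

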