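# Methods

## Setting

A tilt-table protocol exposes an anesthetized quadruped to a symmetric
sequence of body angles — 0°, +5°, +10°, +13°, +10°, +5°, 0°, −5°, −10°,
−13°, −10°, −5°, 0°, each plateau held for 10 minutes — while eleven
pressures are recorded at 1 kHz: carotid and femoral arterial (cABP, fABP),
intracranial and intrathecal (ICP, ITP), central and jugular venous (CVP,
JVP), four intra-abdominal quadrants (IAPcr/cd/ds/ve), and intravesical
(IVP). Positive angles are head-over-body. The package analyzes three
aspects of such recordings: per-step mean pressures and their relation to
angle, per-beat pulse pressures, and frequency-domain transfer functions
from the arterial input to every other compartment.

## Preprocessing

Working-rate reduction decimates each channel by an integer factor after a
zero-phase 8th-order Butterworth anti-alias lowpass at 0.4× the target rate
(default 100 Hz). Spike artifacts are rejected by a single z-score pass at
σ_crit = 3; statistics are computed **per tilt step** so that hydrostatic
mean shifts between steps do not inflate the SD and mask spikes (the
windowing is a package choice; an iterative re-estimation pass is
deliberately not performed). Rejected samples are replaced by linear
interpolation between retained neighbours rather than deleted, because the
spectral stages require a uniform sample grid. The mean trace is the
4th-order forward/backward Butterworth lowpass at 0.1 Hz, with reflective
padding of three filter time constants to suppress edge transients; the
forward/backward pass doubles the effective order and cancels the phase
response.

Degenerate inputs: a zero-variance series cannot be z-scored and is passed
through unchanged with a flag; `np.ptp` (not a floating-point SD) decides
degeneracy.

## Step statistics

Step means are arithmetic means of the mean trace over each plateau,
excluding a configurable settling interval at the start of each step
(default 60 s at full scale; "once pressures had stabilized" has no printed
number, so it is a parameter). Deltas are taken against the first 0°
baseline. Cohort statistics average across subjects *within* each step
first; the Pearson correlation is then computed between the 13 per-step
cohort values and the 13 step angles (repeated angles stay separate
points; collapsing them is available as a flag). p-values use the exact
two-sided t transform with n−2 degrees of freedom. Strength classes:
strong |r| ≥ 0.7, mild 0.3 < |r| < 0.7, weak |r| ≤ 0.3, with the boundary
values belonging to strong and weak respectively. Paired dependent t-tests
are computed for every consecutive step pair and every step against
baseline; no multiple-testing correction is applied by default (a Holm
option exists). Degenerate pairings report their limits (identical pairs:
t = 0, p = 1; constant nonzero offset: t = ±∞, p = 0).

The hydrostatic predictor is pure trigonometry: a sensor a horizontal
distance d from the ICP transducer spans a vertical column h = d·sin(θ) at
tilt angle θ, giving ΔP = h·ρ·0.73556 mmHg per cmH₂O. Values are exact and
rounded only at presentation; with d = 70.0 cm and θ = 13° this yields
15.7 cm and 11.6 mmHg.

## Pulse pressure

Pulse pressure is the per-beat peak-to-trough difference on the cleaned
working-rate signal *without* the 0.1 Hz lowpass (which would destroy the
pulse), averaged over each step. The cardiac rate is estimated once from
the arterial input (largest Welch periodogram peak in 0.8–4 Hz after
bandpassing; a peak below 5× the in-band median power is flagged as
unreliable) and reused for all channels of that subject — the venous and
abdominal channels are too weakly pulsatile to trust their own estimates,
and all compartments share one cardiac driver. Peak picking runs on the
signal detrended at half the heart rate (so step transients cannot
masquerade as beats) with minimum separation 0.6/HR and prominence 0.25×
the inter-quartile amplitude (a global IQR; a running window adds
complexity without changing any tested contract). Amplitudes are read from
the signal minus its 0.1 Hz mean trace: this removes the tilt-induced
baseline drift within a beat, keeps respiratory modulation inside the
measured amplitudes (as in the raw waveforms), makes the extraction
invariant to constant offsets and to re-adding the mean trace, and
guarantees non-negative amplitudes by construction. Troughs are the minima
between consecutive peaks, enforcing alternation.

## Transfer functions

The estimator is the most literal one: the one-sided FFT of a rectangular,
mean-removed window (default the full step; no zero padding, so frequency
resolution is 1/duration), divided bin by bin, output over input. Bins
where the input magnitude falls below a relative floor (default 10⁻⁶ of
the input maximum) are masked — a ratio with no input power estimates
nothing. The DC bin is always excluded.

A single-window bin ratio is intrinsically noisy (several dB per bin, from
windowing leakage alone). Smoothing therefore does two things: raw bins
are first *averaged* into cells of a uniform log₂-frequency grid (default
48 points/octave), which shrinks the per-cell noise by the square root of
the cell population — at high frequency each cell holds many raw bins —
and the cell curve is then filtered forward/backward with a 2nd-order
Butterworth using Gustafsson's initial-condition method, so edges carry no
transient and a constant passes unchanged. The smoothing bandwidth
(default 1/12 octave) is gentle enough that a 10 dB resonance with damping
0.05 at 4.2 Hz loses under 1 dB of height. Masked cells are bridged by
interpolation and re-masked afterwards.

Subject TFs are averaged pointwise in dB (a geometric mean of linear
magnitudes — CIs are symmetric in the plotted dB domain) with a Student-t
95% interval per bin. Features are extracted from the cohort mean:
resonant peaks and notches are local extrema within the analysis band
(default 0.5–30 Hz) with at least 3 dB of prominence; the roll-off is the
OLS slope of mean dB versus log₁₀ f over a recorded fit band, by default
[1.5× the highest detected peak, 0.8× the band top]. The default span
requirement of half a decade applies to calibration-style fits; scaled
configurations whose band top is 30 Hz cannot span half a decade above an
11.5 Hz resonance, so recovery tests pass an explicit relaxed span, and
every reported slope records the band actually used so it is auditable.
Only the 0° baseline and ±13° extremes get TFs by default; other steps are
available via a parameter. Phase is retained in the raw complex ratio but
no phase features are extracted. A Welch cross-spectral estimator exists
behind a flag for comparison; it is never the default.

## Synthetic cohorts

Each subject's channels share one cardiac source: a sum of n harmonics
with 1/k amplitudes and sign-aligned phases (a sharp-upstroke,
arterial-like pulse), normalized to zero mean and unit peak-to-trough
*before* an optional white broadband excitation floor is added — the pulse
height, not the noise extremes, defines the unit. Each channel passes the
source through its compartment cascade: second-order "bell" sections
(unity gain at DC and at high frequency, peak gain g at the resonance,
implemented as H(s) = (s² + 2ζgω₀s + ω₀²)/(s² + 2ζω₀s + ω₀²)), optional
anti-resonant notches of the same form, and a first-order-per-order
lowpass whose corner (default 12 Hz) sits just above the second resonance,
so the cascade's final asymptote is −20 dB/decade per lowpass order.
Filtering is multiplicative in the frequency domain (rfft × analytic
response), which makes the recorded spectral ground truth exact rather
than a discretization.

On top of the scaled pulse the generator adds the hydrostatic mean profile
(baseline + slope × angle, with an exponential settling transient at each
step change, default time constant 30 s at full scale), an additive
respiratory sinusoid at the ventilator rate (12–15/min band enforced,
default 14), Gaussian sensor noise, and sparse spike artifacts of
amplitude 6–12× the noise SD — removable by the σ = 3 rule by
construction. Between-subject variability multiplies baselines and slopes
by Gaussian factors truncated at ±3 SD, preserving every slope's sign so
correlation-sign recovery stays well-posed. An optional linear within-step
drift knob exists and defaults to off. All randomness derives from one
`SeedSequence`; identical configurations are bit-identical.

Default channel parameters are at the scale of an ovine cohort: baselines
from ~5 mmHg (JVP) to ~80 mmHg (cABP), pulse amplitudes 1.2–26 mmHg, and
hydrostatic slopes equal to the per-channel +13° shift divided by 13°,
signed per compartment (arterial, intracranial, jugular, cranial/dorsal
abdominal negative; intrathecal, central venous, caudal abdominal,
intravesical positive). Sensor noise defaults to 5% of each channel's
pulse amplitude; the dorsal abdominal channel carries an 8 Hz notch
(shallower on the ventral and vesical channels).

What the generator does **not** emulate: baroreflex or autoregulatory
feedback (shifts are prescribed, not regulated), heart-rate variability,
beat morphology change with posture, ruminal content shifts, or any
mechanistic abdominal heterogeneity — channels differ only by their signed
slopes and cascades. Passing recovery tests therefore demonstrates
estimator correctness on signals with known structure, not robustness to
every behaviour of real animal data.

## Study conditions used by the tests

Full acquisition scale (1 kHz, 10-min steps, ~7.8 M samples per channel)
is supported but not exercised end to end; the suite runs the same
pipeline at a scaled configuration the package treats as its reference
test condition: 6 subjects, 200 Hz, 60 s steps (13 × 60 s = 780 s per
subject), 84 bpm cardiac fundamental, 14 breaths/min, settling time
constant 3 s with 20 s excluded from step means, 10% between-subject
variability. The noise-free step-mean round trip (< 0.01 mmHg) is checked
at full-length 600 s steps for one subject, because the zero-phase
filter's symmetric smear at step boundaries is diluted by window length.

Two dedicated validation configurations fix the remaining free choices:

- **TF validation** — all outputs share bells at 4.2 Hz (ζ = 0.08, +10 dB)
  and 11.5 Hz (ζ = 0.10, +8 dB) over a first-order 12 Hz decay; sensor
  noise 5% of pulse amplitude; the source carries harmonics to the 21st
  and a 50% broadband excitation floor. The floor is an identifiability
  requirement, not a tuning knob: a bin-ratio transfer function is only
  defined at frequencies the input excites, and without broadband input
  power the band between cardiac harmonics estimates nothing. Recovery is
  asserted as: cohort-median peak locations within 2 feature-grid bins
  (grid spacing f·(2^{1/48}−1), about 1.5% of f) of the analytic truth,
  and the across-channel mean roll-off within 3 dB/decade of the OLS slope
  of the analytic response over the identical fit band (the truth is the
  band-local analytic slope, not the f→∞ asymptote, because the fit band
  sits only ~1.5–2× above the corner).
- **Statistics validation** — cohort-scale signed slopes with sensor noise
  fixed at 1 mmHg on every channel; recovery is the sign pattern of r on
  all 11 channels and a "strong" classification wherever the full-range
  shift |slope|·13° reaches 5 mmHg.

## Numerical choices

- Zero-phase filtering uses second-order sections throughout (a 4th-order
  lowpass at 0.001 of Nyquist is ill-conditioned in transfer-function
  form).
- Interpolation of rejected samples extends the nearest retained value at
  the series edges.
- `fit_rolloff` requires ≥ 20 valid bins; `smooth_tf` requires ≥ 10
  unmasked bins.
- CSV waveform round trips write floats as `%.17g` and read with
  pandas' round-trip float parser, so values survive exactly.
- Tie-breaks: when several detected peaks could match a truth peak,
  recovery tests match the nearest by frequency.

## Known limitations

- The bin-ratio TF estimator has no coherence weighting; at frequencies
  where channel noise dominates the excited output the magnitude flattens
  toward the noise-floor ratio, which biases roll-off fits upward when the
  fit band extends into noise-dominated territory. The broadband
  excitation level of the TF-validation cohort keeps this bias within the
  asserted tolerance; on real data, fit bands should be chosen with the
  recorded band audits in hand.
- Beat detection assumes a dominant cardiac fundamental; severely
  arrhythmic signals would need a different detector.
- The deposited-data loader accepts only the documented open formats
  (HDF5/CSV layouts described in `io_formats`); no vendor format is read.
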