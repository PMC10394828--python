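"""Cardiac beat detection and per-step pulse pressures.

Pulse pressure is the per-beat peak-to-trough difference, averaged over each
tilt step. Beats are detected on the cleaned working-rate signal *without*
the 0.1 Hz mean-trace lowpass (which would destroy the pulses); respiratory
modulation is deliberately left in, so beat amplitudes fluctuate with the
ventilation cycle just as the raw waveforms do.

Weakly pulsatile venous/abdominal channels reuse the cardiac rate estimated
from the arterial input of the same subject (the compartments share one
cardiac driver), rather than trusting their own rate estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import mean_trace

DEFAULT_HR_BAND = (0.8, 4.0)
DEFAULT_PROMINENCE_FRAC = 0.25
DEFAULT_MIN_SEPARATION_FRAC = 0.6


class HeartRateNotFound(ValueError):
    """No periodogram peak rose reliably above the noise floor."""


class BeatDetectionError(ValueError):
    """Fewer than three beats were found."""


@dataclass
class BeatSeries:
    """Detected beats: alternating peaks and troughs with amplitudes.

    ``amplitudes[i]`` is the pressure at ``peak_indices[i + 1]`` minus the
    preceding trough ``trough_indices[i]``; amplitudes are non-negative by
    construction (each trough is the minimum between its flanking peaks).
    """

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    amplitudes: np.ndarray
    estimated_heart_rate: float  # Hz

    def __post_init__(self) -> None:
        p = np.asarray(self.peak_indices)
        t = np.asarray(self.trough_indices)
        if t.size != p.size - 1 or self.amplitudes.size != t.size:
            raise ValueError("troughs/amplitudes must interleave the peaks")
        if p.size >= 2:
            inter = np.stack([p[:-1], t]).T.ravel()
            if np.any(np.diff(np.concatenate([inter, p[-1:]])) <= 0):
                raise ValueError("peaks and troughs must strictly alternate")
        if np.any(self.amplitudes < 0):
            raise ValueError("beat amplitudes must be non-negative")

    @property
    def amplitude_peak_indices(self) -> np.ndarray:
        """Peak index each amplitude is attributed to (the peak ending the beat)."""
        return np.asarray(self.peak_indices)[1:]


def estimate_heart_rate(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_HR_BAND,
    min_peak_ratio: float = 5.0,
) -> float:
    """Cardiac fundamental from the largest in-band Welch periodogram peak.

    The signal is band-passed to ``band`` first. If the winning peak does
    not exceed ``min_peak_ratio`` times the in-band median power, the series
    is considered rateless (e.g. white noise) and
    :class:`HeartRateNotFound` is raised so the caller can supply a rate.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 10 * fs:
        raise ValueError("need at least 10 s of signal")
    lo, hi = band
    sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    xb = signal.sosfiltfilt(sos, x - x.mean())
    nperseg = min(x.size, int(30 * fs))
    freq, pxx = signal.welch(xb, fs=fs, nperseg=nperseg)
    sel = (freq >= lo) & (freq <= hi)
    if not np.any(sel):
        raise ValueError("band contains no spectral bins")
    f_band, p_band = freq[sel], pxx[sel]
    i = int(np.argmax(p_band))
    floor = float(np.median(p_band))
    if floor <= 0 or p_band[i] < min_peak_ratio * floor:
        raise HeartRateNotFound(
            f"in-band peak only {p_band[i] / max(floor, 1e-300):.1f}x the "
            f"median power (need {min_peak_ratio}x)"
        )
    return float(f_band[i])


def detect_beats(
    x: np.ndarray,
    fs: float,
    heart_rate: float,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    min_separation_frac: float = DEFAULT_MIN_SEPARATION_FRAC,
) -> BeatSeries:
    """Locate systolic peaks and the troughs between them.

    Peaks are local maxima separated by at least
    ``min_separation_frac / heart_rate`` seconds with a prominence of at
    least ``prominence_frac`` times the inter-quartile amplitude of the
    detrended signal; each trough is the minimum between consecutive peaks,
    enforcing alternation. Two different trend removals are at work:

    * peak *picking* happens on the signal lowpass-detrended at half the
      heart rate, so step changes in mean pressure cannot masquerade as
      beats;
    * amplitudes are *read* from the signal minus its 0.1 Hz mean trace,
      which removes the tilt-induced baseline drift within a beat but
      deliberately keeps respiratory modulation inside the measured
      amplitudes.
    """
    x = np.asarray(x, dtype=np.float64)
    if heart_rate <= 0:
        raise ValueError("heart_rate must be > 0")
    trend_cut = min(0.5 * heart_rate, 0.45 * fs)
    trend = mean_trace(x, fs, cutoff=trend_cut, order=2)
    detrended = x - trend
    q75, q25 = np.percentile(detrended, [75, 25])
    scale = q75 - q25
    distance = max(1, int(min_separation_frac * fs / heart_rate))
    peaks, _ = signal.find_peaks(
        detrended, distance=distance, prominence=prominence_frac * scale
    )
    if peaks.size < 3:
        raise BeatDetectionError(f"only {peaks.size} beats found (need >= 3)")
    read = x - mean_trace(x, fs, cutoff=min(0.1, 0.45 * fs))
    w = max(1, int(0.2 * fs / heart_rate))  # systolic refinement window
    troughs = np.empty(peaks.size - 1, dtype=np.intp)
    amplitudes = np.empty(peaks.size - 1)
    for i in range(peaks.size - 1):
        lo, hi = peaks[i] + 1, peaks[i + 1]
        troughs[i] = lo + int(np.argmin(read[lo:hi]))
        p = peaks[i + 1]
        crest = read[max(0, p - w) : min(read.size, p + w + 1)].max()
        amplitudes[i] = crest - read[troughs[i]]
    span = (peaks[-1] - peaks[0]) / fs
    return BeatSeries(
        peak_indices=peaks,
        trough_indices=troughs,
        amplitudes=amplitudes,
        estimated_heart_rate=float((peaks.size - 1) / span),
    )


def step_pulse_pressure(beats: BeatSeries, sample_range: tuple[int, int]) -> float:
    """Mean beat amplitude over one step.

    Averages the amplitudes whose closing peak falls inside
    ``[start, stop)``; returns NaN when the step contains no complete beat.
    """
    start, stop = sample_range
    peaks = beats.amplitude_peak_indices
    sel = (peaks >= start) & (peaks < stop)
    if not np.any(sel):
        return float("nan")
    return float(np.asarray(beats.amplitudes)[sel].mean())
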