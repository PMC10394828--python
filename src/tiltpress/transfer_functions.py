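"""Arterial-input transfer functions: FFT ratios, smoothing, cohort
averages, and spectral features.

For each subject and tilt step the transfer function (TF) from the carotid
arterial input to an output channel is the bin-by-bin ratio of the two
one-sided FFTs over a rectangular window with the mean removed — the most
literal frequency-domain estimator. Bins where the input magnitude falls
below a relative floor are masked (a ratio with no input power in the
denominator estimates nothing).

The raw ratio is then smoothed along log-frequency with a zero-phase
lowpass using Gustafsson's initial-condition scheme, which suppresses edge
transients at both ends of the band while preserving a constant exactly.
Subject TFs are averaged in dB (a geometric mean of magnitudes) with a
pointwise Student-t 95% confidence interval.

Feature extraction reduces a cohort TF to resonant peaks, notches, and the
asymptotic roll-off: an ordinary least-squares slope of magnitude against
log10 frequency in dB/decade over a recorded fit band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy import stats as sps

from .io_formats import TF_INPUT_CHANNEL, Recording
from .tilt_statistics import segment_steps

DEFAULT_WINDOW_S = 600.0
DEFAULT_FLOOR = 1e-6
DEFAULT_SMOOTH_BANDWIDTH_OCTAVES = 1.0 / 12.0
DEFAULT_POINTS_PER_OCTAVE = 48
DEFAULT_BAND_HZ = (0.5, 30.0)
DEFAULT_MIN_PROMINENCE_DB = 3.0
DEFAULT_TF_STEPS = ("0_1", "+13", "-13")


@dataclass
class TransferFunctionEstimate:
    """One subject's TF magnitude for one output channel and tilt step."""

    subject_id: str
    output_channel: str
    step_label: str
    freq: np.ndarray  # Hz, strictly increasing
    magnitude_db: np.ndarray
    mask: np.ndarray  # True where the bin is valid (input above floor)
    input_channel: str = TF_INPUT_CHANNEL
    complex_ratio: np.ndarray | None = None
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=np.float64)
        self.magnitude_db = np.asarray(self.magnitude_db, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(np.diff(self.freq) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not (self.freq.size == self.magnitude_db.size == self.mask.size):
            raise ValueError("freq, magnitude_db, and mask must align")
        if np.any(~np.isfinite(self.magnitude_db[self.mask])):
            raise ValueError("magnitude must be finite on unmasked bins")


@dataclass
class CohortTF:
    """Across-subject mean TF with a pointwise 95% confidence interval."""

    output_channel: str
    step_label: str
    freq: np.ndarray
    mean_db: np.ndarray
    ci_low_db: np.ndarray
    ci_high_db: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        ok = np.isfinite(self.mean_db) & np.isfinite(self.ci_low_db)
        if np.any(self.ci_low_db[ok] > self.mean_db[ok] + 1e-9) or np.any(
            self.mean_db[ok] > self.ci_high_db[ok] + 1e-9
        ):
            raise ValueError("CI must bracket the mean pointwise")


@dataclass
class SpectralFeatures:
    """Resonant peaks, notches, and roll-off of one cohort TF."""

    peaks: list[tuple[float, float]] = field(default_factory=list)  # (Hz, dB prominence)
    notches: list[tuple[float, float]] = field(default_factory=list)  # (Hz, dB depth)
    rolloff_db_per_decade: float | None = None
    rolloff_band: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# spectra and ratios
# ---------------------------------------------------------------------------

def window_spectrum(
    x: np.ndarray, fs: float, duration: float = DEFAULT_WINDOW_S
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT of the first ``duration`` seconds, mean removed.

    A rectangular window without overlap; the frequency resolution is
    ``1/duration`` Hz. Series shorter than the window are rejected — no
    zero padding, which would fake resolution.
    """
    x = np.asarray(x, dtype=np.float64)
    n = int(round(duration * fs))
    if x.size < n:
        raise ValueError(
            f"series of {x.size / fs:.1f} s is shorter than the "
            f"{duration:.0f} s window"
        )
    seg = x[:n]
    spec = np.fft.rfft(seg - seg.mean())
    freq = np.fft.rfftfreq(n, d=1.0 / fs)
    return freq, spec


def tf_ratio(
    out_spec: np.ndarray,
    in_spec: np.ndarray,
    freq: np.ndarray,
    floor: float = DEFAULT_FLOOR,
    subject_id: str = "",
    output_channel: str = "",
    step_label: str = "",
) -> TransferFunctionEstimate:
    """Bin-by-bin output/input spectral ratio with an input-magnitude floor.

    Bins where ``|in| < floor * max|in|`` are masked and excluded from
    smoothing, averaging, and features.
    """
    out_spec = np.asarray(out_spec)
    in_spec = np.asarray(in_spec)
    if out_spec.shape != in_spec.shape:
        raise ValueError("spectra must share one frequency grid")
    mag_in = np.abs(in_spec)
    mask = mag_in >= floor * mag_in.max()
    mask &= np.asarray(freq) > 0  # the DC bin is meaningless after mean removal
    if not np.any(mask):
        raise ValueError("all bins fall below the input floor")
    ratio = np.full(out_spec.shape, np.nan, dtype=complex)
    ratio[mask] = out_spec[mask] / in_spec[mask]
    mag_db = np.full(out_spec.shape, np.nan)
    with np.errstate(divide="ignore"):
        mag_db[mask] = 20.0 * np.log10(np.abs(ratio[mask]))
    mask &= np.isfinite(mag_db)
    return TransferFunctionEstimate(
        subject_id=subject_id,
        output_channel=output_channel,
        step_label=step_label,
        freq=np.asarray(freq, dtype=float),
        magnitude_db=mag_db,
        mask=mask,
        complex_ratio=ratio,
    )


def smooth_tf(
    tf: TransferFunctionEstimate,
    bandwidth_octaves: float = DEFAULT_SMOOTH_BANDWIDTH_OCTAVES,
    points_per_octave: int = DEFAULT_POINTS_PER_OCTAVE,
) -> TransferFunctionEstimate:
    """Zero-phase smoothing of TF magnitude along log-frequency.

    Unmasked bins are reduced onto a uniform log2-frequency grid by
    averaging all linear-grid bins falling inside each log cell (cells the
    mask leaves empty are bridged by interpolation and re-masked
    afterwards), then filtered forward-backward with a 2nd-order
    Butterworth lowpass using Gustafsson's initial-condition method, so a
    constant passes through unchanged out to the very first and last grid
    points. The cutoff along the log axis is ``1/bandwidth_octaves`` cycles
    per octave: magnitude ripple narrower than the bandwidth is removed,
    broader trends are kept. The cell averaging is what turns the noisy
    bin-by-bin ratio into a usable curve — at high frequency each log cell
    averages many raw bins, shrinking the single-window ratio noise by the
    square root of the cell population.
    """
    usable = tf.mask & (tf.freq > 0) & np.isfinite(tf.magnitude_db)
    if usable.sum() < 10:
        raise ValueError("need at least 10 unmasked bins to smooth")
    logf = np.log2(tf.freq[usable])
    y = tf.magnitude_db[usable]
    n = max(2, int(math.floor((logf[-1] - logf[0]) * points_per_octave)) + 1)
    grid = logf[0] + np.arange(n) / points_per_octave
    # average raw bins into log cells centred on the grid points
    edges = np.concatenate([[grid[0] - 0.5 / points_per_octave],
                            grid + 0.5 / points_per_octave])
    cell = np.digitize(logf, edges) - 1
    inside = (cell >= 0) & (cell < n)
    counts = np.bincount(cell[inside], minlength=n)
    sums = np.bincount(cell[inside], weights=y[inside], minlength=n)
    yi = np.empty(n)
    filled = counts > 0
    yi[filled] = sums[filled] / counts[filled]
    if not np.all(filled):  # sparse cells (or masked runs): bridge by interpolation
        yi[~filled] = np.interp(grid[~filled], grid[filled], yi[filled])
    wn = (1.0 / bandwidth_octaves) / (points_per_octave / 2.0)
    if wn < 1.0:
        b, a = signal.butter(2, wn)
        ys = signal.filtfilt(b, a, yi, method="gust")
    else:  # grid too coarse to express the bandwidth; nothing to remove
        ys = yi
    pos = tf.freq > 0
    cover = np.interp(grid, np.log2(tf.freq[pos]), tf.mask[pos].astype(float))
    return TransferFunctionEstimate(
        subject_id=tf.subject_id,
        output_channel=tf.output_channel,
        step_label=tf.step_label,
        freq=np.exp2(grid),
        magnitude_db=ys,
        mask=cover >= 0.5,
        input_channel=tf.input_channel,
        smoothed=True,
    )


def cohort_average(tfs: list[TransferFunctionEstimate]) -> CohortTF:
    """Pointwise dB mean across subjects with a Student-t 95% CI.

    Magnitudes are averaged in dB (a geometric mean of linear magnitudes),
    matching the symmetric CIs of the plotted dB domain. Subjects on
    different grids are interpolated onto the first subject's grid. With a
    single subject the mean is returned and the CI is NaN (flagged by
    ``n_subjects == 1``).
    """
    if not tfs:
        raise ValueError("no transfer functions to average")
    base = tfs[0]
    grid = base.freq
    rows = []
    for tf in tfs:
        y = np.where(tf.mask, tf.magnitude_db, np.nan)
        if tf.freq.shape != grid.shape or not np.allclose(tf.freq, grid):
            ok = np.isfinite(y)
            if ok.sum() < 2:
                raise ValueError(f"subject {tf.subject_id}: too few valid bins")
            yg = np.interp(grid, tf.freq[ok], y[ok],
                           left=np.nan, right=np.nan)
        else:
            yg = y
        rows.append(yg)
    stack = np.vstack(rows)
    n_eff = np.sum(np.isfinite(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(n_eff > 0, stack, np.nan), axis=0)
    n = len(tfs)
    if n >= 2:
        sd = np.nanstd(stack, axis=0, ddof=1)
        half = np.full(grid.shape, np.nan)
        ok = n_eff >= 2
        tcrit = sps.t.ppf(0.975, n_eff[ok] - 1)
        half[ok] = tcrit * sd[ok] / np.sqrt(n_eff[ok])
        lo, hi = mean - half, mean + half
    else:
        lo = hi = np.full(grid.shape, np.nan)
    return CohortTF(
        output_channel=base.output_channel,
        step_label=base.step_label,
        freq=grid,
        mean_db=mean,
        ci_low_db=lo,
        ci_high_db=hi,
        n_subjects=n,
    )


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def find_peaks_and_notches(
    ctf: CohortTF,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    min_prominence: float = DEFAULT_MIN_PROMINENCE_DB,
) -> SpectralFeatures:
    """Resonant peaks (local maxima) and notches (local minima) of the mean
    TF within ``band``, keeping only extrema at least ``min_prominence`` dB
    above/below their surrounding baseline. Sorted by frequency; empty
    lists are a valid result for a monotone response."""
    lo, hi = band
    sel = (ctf.freq >= lo) & (ctf.freq <= hi) & np.isfinite(ctf.mean_db)
    f = ctf.freq[sel]
    y = ctf.mean_db[sel]
    feats = SpectralFeatures()
    if f.size < 3:
        return feats
    pk, props = signal.find_peaks(y, prominence=min_prominence)
    feats.peaks = sorted(zip(f[pk], props["prominences"]))
    nt, nprops = signal.find_peaks(-y, prominence=min_prominence)
    feats.notches = sorted(zip(f[nt], nprops["prominences"]))
    return feats


def fit_rolloff(
    ctf: CohortTF,
    fit_band: tuple[float, float] | None = None,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    min_prominence: float = DEFAULT_MIN_PROMINENCE_DB,
    min_span_decades: float = 0.5,
    min_bins: int = 20,
) -> SpectralFeatures:
    """Asymptotic roll-off: OLS slope of mean dB against log10 frequency.

    With ``fit_band=None`` the band is chosen automatically as
    ``[1.5 x highest detected peak, 0.8 x band max]`` (or the upper half
    decade of the band when no peak exists). The band must span at least
    ``min_span_decades`` with at least ``min_bins`` valid bins; the band
    actually used is recorded in the result so every reported slope is
    auditable.
    """
    if fit_band is None:
        peaks = find_peaks_and_notches(ctf, band, min_prominence).peaks
        hi = 0.8 * band[1]
        lo = 1.5 * max(f for f, _ in peaks) if peaks else hi / 10 ** 0.5
        fit_band = (lo, hi)
    lo, hi = fit_band
    span = math.log10(hi / lo) if hi > lo > 0 else 0.0
    if span < min_span_decades:
        raise ValueError(
            f"fit band [{lo:.3g}, {hi:.3g}] Hz spans {span:.3f} decades; "
            f"need >= {min_span_decades}"
        )
    sel = (ctf.freq >= lo) & (ctf.freq <= hi) & np.isfinite(ctf.mean_db)
    if sel.sum() < min_bins:
        raise ValueError(
            f"only {int(sel.sum())} valid bins in the fit band (need >= {min_bins})"
        )
    res = sps.linregress(np.log10(ctf.freq[sel]), ctf.mean_db[sel])
    return SpectralFeatures(
        rolloff_db_per_decade=float(res.slope), rolloff_band=(float(lo), float(hi))
    )


def extract_features(
    ctf: CohortTF,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    min_prominence: float = DEFAULT_MIN_PROMINENCE_DB,
    fit_band: tuple[float, float] | None = None,
    min_span_decades: float = 0.5,
    min_bins: int = 20,
) -> SpectralFeatures:
    """Peaks, notches, and roll-off of one cohort TF in a single pass."""
    feats = find_peaks_and_notches(ctf, band, min_prominence)
    roll = fit_rolloff(ctf, fit_band, band, min_prominence,
                       min_span_decades, min_bins)
    feats.rolloff_db_per_decade = roll.rolloff_db_per_decade
    feats.rolloff_band = roll.rolloff_band
    return feats


# ---------------------------------------------------------------------------
# pipeline over recordings
# ---------------------------------------------------------------------------

def estimate_step_tfs(
    recording: Recording,
    steps: tuple[str, ...] = DEFAULT_TF_STEPS,
    window_s: float | None = None,
    floor: float = DEFAULT_FLOOR,
    bandwidth_octaves: float = DEFAULT_SMOOTH_BANDWIDTH_OCTAVES,
    points_per_octave: int = DEFAULT_POINTS_PER_OCTAVE,
    input_channel: str = TF_INPUT_CHANNEL,
    smooth: bool = True,
) -> list[TransferFunctionEstimate]:
    """Smoothed TFs from the arterial input to every other channel for the
    requested tilt steps of one recording.

    ``window_s`` defaults to the full step duration. TFs are computed at
    the recording's native rate (no decimation) for maximal spectral
    resolution.
    """
    windows = {w.step.label: w for w in segment_steps(recording, settle_time=0.0)}
    fs = recording.fs
    out: list[TransferFunctionEstimate] = []
    for label in steps:
        if label not in windows:
            raise KeyError(f"step {label!r} not in the protocol")
        w = windows[label]
        dur = window_s if window_s is not None else w.step.duration
        x_in = recording[input_channel].samples[w.start : w.stop]
        freq, in_spec = window_spectrum(x_in, fs, duration=dur)
        for name, ch in recording.channels.items():
            if name == input_channel:
                continue
            _, out_spec = window_spectrum(ch.samples[w.start : w.stop], fs,
                                          duration=dur)
            tf = tf_ratio(out_spec, in_spec, freq, floor=floor,
                          subject_id=recording.subject_id,
                          output_channel=name, step_label=label)
            out.append(
                smooth_tf(tf, bandwidth_octaves, points_per_octave)
                if smooth else tf
            )
    return out


def cohort_transfer_functions(
    recordings: list[Recording], **kwargs
) -> dict[tuple[str, str], CohortTF]:
    """Cohort-averaged TFs keyed by ``(output_channel, step_label)``."""
    per_key: dict[tuple[str, str], list[TransferFunctionEstimate]] = {}
    for rec in recordings:
        for tf in estimate_step_tfs(rec, **kwargs):
            per_key.setdefault((tf.output_channel, tf.step_label), []).append(tf)
    return {key: cohort_average(tfs) for key, tfs in per_key.items()}


def cohort_tf_table(ctfs: dict[tuple[str, str], CohortTF]) -> pd.DataFrame:
    """Long-format frequency table of cohort TFs."""
    frames = []
    for (channel, step), ctf in ctfs.items():
        frames.append(pd.DataFrame(dict(
            output_channel=channel, step=step, freq_hz=ctf.freq,
            mean_db=ctf.mean_db, ci_low_db=ctf.ci_low_db,
            ci_high_db=ctf.ci_high_db,
        )))
    return pd.concat(frames, ignore_index=True)


def features_table(
    features: dict[tuple[str, str], SpectralFeatures]
) -> pd.DataFrame:
    """One row per feature: peaks, notches, roll-off with its fit band."""
    rows = []
    for (channel, step), f in features.items():
        for freq, height in f.peaks:
            rows.append(dict(channel=channel, step=step, feature_type="peak",
                             freq_hz=freq, value=height))
        for freq, depth in f.notches:
            rows.append(dict(channel=channel, step=step, feature_type="notch",
                             freq_hz=freq, value=depth))
        if f.rolloff_db_per_decade is not None:
            rows.append(dict(channel=channel, step=step,
                             feature_type="rolloff_db_per_decade",
                             freq_hz=np.nan, value=f.rolloff_db_per_decade,
                             fit_lo_hz=f.rolloff_band[0],
                             fit_hi_hz=f.rolloff_band[1]))
    return pd.DataFrame(rows)
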