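"""Waveform preprocessing: decimation, z-score artifact rejection, mean trace.

The analysis chain reduces raw pressure waveforms in three steps:

1. anti-aliased decimation of the acquisition-rate signal (1 kHz nominal)
   down to a working rate (100 Hz by default);
2. z-score outlier rejection with a critical threshold of 3 SD, replacing
   rejected samples by linear interpolation so downstream FFTs keep a
   uniform grid;
3. extraction of the slow "mean trace" with a 4th-order zero-phase
   (forward/backward) Butterworth lowpass at 0.1 Hz, removing cardiac and
   respiratory oscillations before step means are taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_formats import PressureChannel

DEFAULT_SIGMA_CRIT = 3.0
DEFAULT_MEAN_CUTOFF_HZ = 0.1
DEFAULT_FILTER_ORDER = 4
DEFAULT_TARGET_FS = 100.0


@dataclass
class CleaningReport:
    """Bookkeeping from one outlier-rejection pass."""

    n_input: int
    n_rejected: int
    rejected_indices: np.ndarray
    sigma_crit: float
    degenerate_sd: bool = False  # True when SD was zero and no test was possible

    def __post_init__(self) -> None:
        self.rejected_indices = np.asarray(self.rejected_indices, dtype=np.intp)
        if self.n_rejected != self.rejected_indices.size:
            raise ValueError("n_rejected must equal len(rejected_indices)")
        if self.n_rejected > self.n_input:
            raise ValueError("cannot reject more samples than provided")


def decimate(channel: PressureChannel, target_fs: float) -> PressureChannel:
    """Reduce a channel to ``target_fs`` with a zero-phase anti-alias lowpass.

    ``target_fs`` must divide the channel's rate exactly; the anti-alias
    cutoff is 0.4 x target_fs and every (fs/target_fs)-th sample is kept, so
    the output has ceil(n/q) samples.
    """
    if target_fs > channel.fs:
        raise ValueError("target_fs must not exceed the channel rate")
    ratio = channel.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(
            f"target_fs={target_fs} does not divide fs={channel.fs} "
            f"(ratio {ratio:.6g} is not an integer)"
        )
    if q == 1:
        return PressureChannel(channel.name, channel.fs, channel.samples.copy(),
                               geometry=channel.geometry)
    sos = signal.butter(8, 0.4 * target_fs, btype="low", fs=channel.fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, channel.samples)
    return PressureChannel(channel.name, target_fs, filtered[::q],
                           geometry=channel.geometry)


def reject_outliers(
    x: np.ndarray, sigma_crit: float = DEFAULT_SIGMA_CRIT
) -> tuple[np.ndarray, CleaningReport]:
    """Replace samples further than ``sigma_crit`` SDs from the mean.

    Statistics are computed once over the full input (no iterative
    re-estimation). Rejected samples are linearly interpolated between the
    nearest retained neighbours; at the edges the nearest retained value is
    extended. Output length always equals input length.

    A zero-variance input is degenerate: nothing is rejected and the report
    flags the degenerate SD.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D series of length >= 3")
    if not sigma_crit > 0:
        raise ValueError("sigma_crit must be > 0")
    mean = x.mean()
    sd = x.std()
    if sd == 0.0:
        report = CleaningReport(x.size, 0, np.empty(0, dtype=np.intp),
                                sigma_crit, degenerate_sd=True)
        return x.copy(), report
    bad = np.abs(x - mean) > sigma_crit * sd
    idx = np.flatnonzero(bad)
    y = x.copy()
    if idx.size:
        good = np.flatnonzero(~bad)
        if good.size == 0:
            raise ValueError("all samples rejected; sigma_crit too small")
        y[idx] = np.interp(idx, good, x[good])
    report = CleaningReport(x.size, int(idx.size), idx, sigma_crit)
    return y, report


def reject_outliers_stepwise(
    x: np.ndarray,
    windows: "list[tuple[int, int]]",
    sigma_crit: float = DEFAULT_SIGMA_CRIT,
) -> tuple[np.ndarray, CleaningReport]:
    """Apply :func:`reject_outliers` independently inside each window.

    Computing the z-score statistics per tilt step keeps hydrostatic mean
    shifts between steps from inflating the SD and masking spikes.
    ``windows`` are contiguous ``(start, stop)`` sample ranges.
    """
    x = np.asarray(x, dtype=np.float64)
    y = x.copy()
    rejected: list[np.ndarray] = []
    sigma = sigma_crit
    degenerate = False
    for start, stop in windows:
        seg, rep = reject_outliers(x[start:stop], sigma_crit)
        y[start:stop] = seg
        rejected.append(rep.rejected_indices + start)
        degenerate |= rep.degenerate_sd
    idx = np.concatenate(rejected) if rejected else np.empty(0, dtype=np.intp)
    report = CleaningReport(x.size, int(idx.size), idx, sigma,
                            degenerate_sd=degenerate)
    return y, report


def mean_trace(
    x: np.ndarray,
    fs: float,
    cutoff: float = DEFAULT_MEAN_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Slow pressure trend via a zero-phase Butterworth lowpass.

    Forward/backward application doubles the effective order and cancels the
    phase response, so slow features are not shifted in time. Edge
    transients are suppressed with reflective padding of at least three
    filter time constants (capped by the series length).
    """
    x = np.asarray(x, dtype=np.float64)
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2)=(0, {fs / 2})")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = min(x.size - 1, int(3 * fs / cutoff))
    return signal.sosfiltfilt(sos, x, padlen=padlen)
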