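"""End-to-end analysis over a cohort of recordings.

Glue over the stage modules: decimate each channel to the working rate,
reject spike artifacts per tilt step, extract the 0.1 Hz mean trace, take
step means and pulse pressures, attach deltas from the first baseline, and
compute angle correlations and paired tests. Transfer functions run
separately on the native-rate signals (see
:mod:`tiltpress.transfer_functions`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess, pulse_analysis, tilt_statistics
from .io_formats import STEP_SUMMARY_COLUMNS, TF_INPUT_CHANNEL, Recording
from .pulse_analysis import BeatDetectionError, HeartRateNotFound


@dataclass
class AnalysisConfig:
    """Tunable parameters of the step-statistics pipeline."""

    target_fs: float = 100.0
    sigma_crit: float = 3.0
    mean_cutoff_hz: float = 0.1
    filter_order: int = 4
    settle_time_s: float = 60.0
    hr_band: tuple[float, float] = (0.8, 4.0)
    prominence_frac: float = 0.25
    min_separation_frac: float = 0.6


def summarize_recording(
    recording: Recording, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Step summary (mean pressure + pulse amplitude per channel x step)
    for one subject, deltas filled relative to the first baseline.

    The cardiac rate is estimated once from the arterial input and reused
    for every channel's beat detection — venous and abdominal channels are
    too weakly pulsatile to trust their own rate estimates, and all
    compartments share one cardiac driver.
    """
    cfg = config or AnalysisConfig()
    cleaned: dict[str, np.ndarray] = {}
    fs = None
    windows = None
    for name, ch in recording.channels.items():
        dec = preprocess.decimate(ch, cfg.target_fs)
        if windows is None:
            fs = dec.fs
            windows = tilt_statistics.segment_steps(
                recording.protocol, fs, settle_time=cfg.settle_time_s
            )
        x, _ = preprocess.reject_outliers_stepwise(
            dec.samples, [(w.start, w.stop) for w in windows], cfg.sigma_crit
        )
        cleaned[name] = x

    try:
        heart_rate = pulse_analysis.estimate_heart_rate(
            cleaned[TF_INPUT_CHANNEL], fs, band=cfg.hr_band
        )
    except (HeartRateNotFound, KeyError):
        heart_rate = None

    rows = []
    for name, x in cleaned.items():
        trace = preprocess.mean_trace(
            x, fs, cutoff=cfg.mean_cutoff_hz, order=cfg.filter_order
        )
        beats = None
        if heart_rate is not None:
            try:
                beats = pulse_analysis.detect_beats(
                    x, fs, heart_rate,
                    prominence_frac=cfg.prominence_frac,
                    min_separation_frac=cfg.min_separation_frac,
                )
            except BeatDetectionError:
                beats = None
        for w in windows:
            pulse = (
                pulse_analysis.step_pulse_pressure(beats, (w.start, w.stop))
                if beats is not None else float("nan")
            )
            rows.append(dict(
                subject_id=recording.subject_id,
                channel=name,
                step_label=w.step.label,
                angle_deg=w.step.angle,
                mean_pressure_mmhg=tilt_statistics.step_mean(trace, w),
                pulse_amplitude_mmhg=pulse,
            ))
    df = pd.DataFrame(rows)
    df = tilt_statistics.deltas_from_baseline(
        df, baseline_label=recording.protocol.baseline_label
    )
    return df[list(STEP_SUMMARY_COLUMNS)]


def summarize_cohort(
    recordings: list[Recording], config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Concatenated step summaries for all subjects."""
    return pd.concat(
        [summarize_recording(r, config) for r in recordings], ignore_index=True
    )


def analyze_cohort(
    recordings: list[Recording], config: AnalysisConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Step summaries, angle correlations (mean and pulse), paired-test
    matrix, and the cohort regression of deltas on angle."""
    summary = summarize_cohort(recordings, config)
    correlations = pd.concat(
        [
            tilt_statistics.correlate_with_angle(summary, "mean"),
            tilt_statistics.correlate_with_angle(summary, "pulse"),
        ],
        ignore_index=True,
    )
    return {
        "step_summary": summary,
        "correlations": correlations,
        "paired_tests": tilt_statistics.paired_test_matrix(summary),
        "regression": tilt_statistics.regress_on_angle(summary),
    }
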