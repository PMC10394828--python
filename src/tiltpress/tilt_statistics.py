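"""Step segmentation, step means, angle correlations, paired tests, and the
trigonometric hydrostatic predictor.

The unit of analysis is the tilt step: each channel's mean pressure is the
arithmetic mean of its 0.1 Hz mean trace over the step plateau (an initial
settling interval is excluded), deltas are taken against the first 0-degree
baseline, and cohort statistics first average across subjects per step
before any correlation or regression is computed, so each step contributes
one cohort value.

Correlation strength follows the conventional thresholds: strong |r| >= 0.7,
mild 0.3 < |r| < 0.7, weak |r| <= 0.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import (
    CORRELATION_COLUMNS,
    Recording,
    SensorGeometry,
    TiltProtocol,
    TiltStep,
)

#: mmHg per cmH2O at unit fluid density.
MMHG_PER_CMH2O = 0.73556

DEFAULT_SETTLE_TIME_S = 60.0
DEFAULT_ALPHA = 0.05

_STAT_COLUMNS = {"mean": "mean_pressure_mmhg", "pulse": "pulse_amplitude_mmhg"}


@dataclass(frozen=True)
class StepWindow:
    """Sample range of one tilt step; the mean is taken from
    ``analysis_start`` (settling excluded) to ``stop``."""

    step: TiltStep
    start: int
    stop: int
    analysis_start: int


@dataclass(frozen=True)
class HydrostaticPrediction:
    """Expected hydrostatic offset between two sensors at a tilt angle."""

    angle: float  # degrees
    column_height: float  # cm, signed with the angle
    pressure_offset: float  # mmHg
    density: float  # g/cm^3


def segment_steps(
    recording_or_protocol: Recording | TiltProtocol,
    fs: float | None = None,
    settle_time: float = DEFAULT_SETTLE_TIME_S,
) -> list[StepWindow]:
    """Contiguous, non-overlapping sample ranges, one per protocol step.

    Ranges exactly tile ``[0, n)``. The first ``settle_time`` seconds of
    each step are flagged as excluded from the step mean ("once pressures
    had stabilized").
    """
    if isinstance(recording_or_protocol, Recording):
        protocol = recording_or_protocol.protocol
        fs = recording_or_protocol.fs
        n = recording_or_protocol.n_samples
    else:
        protocol = recording_or_protocol
        if fs is None:
            raise ValueError("fs is required when passing a bare protocol")
        n = int(round(protocol.duration * fs))
    if settle_time >= min(s.duration for s in protocol.steps):
        raise ValueError("settle_time must be shorter than the shortest step")
    expected = int(round(protocol.duration * fs))
    if expected > n:
        raise ValueError(
            f"protocol duration {protocol.duration} s exceeds recording "
            f"length {n / fs:.1f} s"
        )
    windows: list[StepWindow] = []
    t0 = 0.0
    start = 0
    for i, step in enumerate(protocol.steps):
        t0 += step.duration
        stop = n if i == len(protocol.steps) - 1 else int(round(t0 * fs))
        analysis_start = min(stop - 1, start + int(round(settle_time * fs)))
        windows.append(StepWindow(step, start, stop, analysis_start))
        start = stop
    return windows


def step_mean(trace: np.ndarray, window: StepWindow) -> float:
    """Arithmetic mean of a mean trace over a step's analysis window."""
    trace = np.asarray(trace)
    if window.stop > trace.size:
        raise ValueError("window extends past the end of the trace")
    seg = trace[window.analysis_start : window.stop]
    if seg.size == 0:
        raise ValueError("empty analysis window")
    return float(seg.mean())


def deltas_from_baseline(
    summary: pd.DataFrame,
    baseline_label: str = "0_1",
    value_columns: tuple[str, ...] = ("mean_pressure_mmhg", "pulse_amplitude_mmhg"),
) -> pd.DataFrame:
    """Add delta columns relative to the first baseline step.

    For each subject x channel, ``delta = value(step) - value(baseline)``;
    the baseline's own delta is exactly zero. Raises if any subject x
    channel lacks the baseline step.
    """
    delta_names = {"mean_pressure_mmhg": "delta_mean_mmhg",
                   "pulse_amplitude_mmhg": "delta_pulse_mmhg"}
    out = summary.copy()
    base = summary[summary["step_label"] == baseline_label].set_index(
        ["subject_id", "channel"]
    )
    missing = (
        summary.set_index(["subject_id", "channel"]).index.unique()
        .difference(base.index)
    )
    if len(missing):
        raise ValueError(
            f"baseline step {baseline_label!r} missing for {list(missing)[:5]}"
        )
    for col in value_columns:
        if col not in summary.columns:
            continue
        ref = out.set_index(["subject_id", "channel"]).index.map(base[col])
        out[delta_names.get(col, f"delta_{col}")] = out[col].to_numpy() - np.asarray(ref)
    return out


def classify_strength(r: float) -> str:
    """Strong / mild / weak correlation classes on |r|."""
    if not np.isfinite(r):
        return "undefined"
    a = abs(r)
    if a >= 0.7:
        return "strong"
    if a > 0.3:
        return "mild"
    return "weak"


def correlate_with_angle(
    summary: pd.DataFrame,
    statistic: str = "mean",
    collapse_repeated_angles: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each channel's per-step cohort statistic with
    the tilt angle.

    The statistic is first averaged across subjects within each step, then
    correlated against the step angles (each of the 13 steps is one point;
    with ``collapse_repeated_angles`` repeated visits to an angle are merged
    first). p-values come from the exact two-sided t transform with
    ``n_steps - 2`` degrees of freedom. Zero variance in either vector
    yields an undefined r, reported as NaN.
    """
    col = _STAT_COLUMNS.get(statistic)
    if col is None:
        raise ValueError(f"statistic must be one of {sorted(_STAT_COLUMNS)}")
    rows = []
    for channel, sub in summary.groupby("channel", sort=False):
        per_step = (
            sub.groupby("step_label", sort=False)
            .agg(angle=("angle_deg", "first"), value=(col, "mean"))
            .dropna()
        )
        if collapse_repeated_angles:
            per_step = per_step.groupby("angle", as_index=False).mean()
        if len(per_step) < 3:
            raise ValueError(f"channel {channel}: need >= 3 steps")
        x = per_step["angle"].to_numpy(float)
        y = per_step["value"].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r, p = math.nan, math.nan
        else:
            res = sps.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        rows.append(
            dict(channel=channel, statistic=statistic, r=r, p=p,
                 strength_class=classify_strength(r))
        )
    return pd.DataFrame(rows, columns=list(CORRELATION_COLUMNS))


def paired_test(
    summary: pd.DataFrame,
    step_a: str,
    step_b: str,
    statistic: str = "mean",
    channel: str | None = None,
) -> tuple[float, float]:
    """Paired dependent t-test across subjects between two steps.

    Returns ``(t, p)`` with a two-sided p. Degenerate pairings are reported
    as their limits: identical values give ``(0, 1)``; a constant nonzero
    offset with zero within-pair variance gives ``(+-inf, 0)``.
    """
    col = _STAT_COLUMNS.get(statistic)
    if col is None:
        raise ValueError(f"statistic must be one of {sorted(_STAT_COLUMNS)}")
    sub = summary if channel is None else summary[summary["channel"] == channel]
    a = sub[sub["step_label"] == step_a].set_index("subject_id")[col]
    b = sub[sub["step_label"] == step_b].set_index("subject_id")[col]
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValueError("paired test needs >= 2 subjects present in both steps")
    d = a.loc[common].to_numpy(float) - b.loc[common].to_numpy(float)
    if np.all(d == d[0]):
        if d[0] == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, d[0]), 0.0
    t, p = sps.ttest_rel(a.loc[common], b.loc[common])
    return float(t), float(p)


def paired_test_matrix(
    summary: pd.DataFrame,
    statistic: str = "mean",
    baseline_label: str = "0_1",
    correction: str | None = None,
) -> pd.DataFrame:
    """t/p for every consecutive step pair and every step against baseline.

    ``correction='holm'`` applies a Holm step-down adjustment per channel;
    by default p-values are unadjusted.
    """
    if correction not in (None, "none", "holm"):
        raise ValueError("correction must be None or 'holm'")
    labels: list[str] = list(dict.fromkeys(summary["step_label"]))
    pairs = [(labels[i], labels[i + 1]) for i in range(len(labels) - 1)]
    pairs += [(baseline_label, lab) for lab in labels if lab != baseline_label]
    seen = set()
    pairs = [p for p in pairs if not (p in seen or seen.add(p))]
    rows = []
    for channel in dict.fromkeys(summary["channel"]):
        for a, b in pairs:
            t, p = paired_test(summary, a, b, statistic=statistic, channel=channel)
            rows.append(dict(channel=channel, step_a=a, step_b=b,
                             statistic=statistic, t=t, p=p))
    df = pd.DataFrame(rows)
    if correction == "holm":
        def _holm(p: np.ndarray) -> np.ndarray:
            order = np.argsort(p)
            m = p.size
            adj = np.empty(m)
            running = 0.0
            for rank, i in enumerate(order):
                running = max(running, (m - rank) * p[i])
                adj[i] = min(1.0, running)
            return adj

        df["p_adjusted"] = (
            df.groupby("channel")["p"].transform(lambda s: _holm(s.to_numpy()))
        )
    return df


def regress_on_angle(
    summary: pd.DataFrame, statistic: str = "mean", delta: bool = True
) -> pd.DataFrame:
    """Ordinary least squares of the cohort per-step statistic (or its delta
    from baseline) against tilt angle; slope in mmHg/degree."""
    col = {"mean": "delta_mean_mmhg", "pulse": "delta_pulse_mmhg"}[statistic] \
        if delta else _STAT_COLUMNS[statistic]
    rows = []
    for channel, sub in summary.groupby("channel", sort=False):
        per_step = (
            sub.groupby("step_label", sort=False)
            .agg(angle=("angle_deg", "first"), value=(col, "mean"))
            .dropna()
        )
        res = sps.linregress(per_step["angle"], per_step["value"])
        rows.append(dict(channel=channel, statistic=statistic,
                         slope_mmhg_per_deg=float(res.slope),
                         intercept_mmhg=float(res.intercept),
                         r=float(res.rvalue), p=float(res.pvalue)))
    return pd.DataFrame(rows)


def hydrostatic_predict(
    geometry: SensorGeometry, angle: float, density: float = 1.0
) -> HydrostaticPrediction:
    """Trigonometric hydrostatic column between a sensor and the ICP sensor.

    The vertical column height at tilt angle theta is the horizontal
    sensor separation times sin(theta); the fluid-column pressure is that
    height (in cmH2O at the given density) converted to mmHg. Values are
    exact; rounding happens only at presentation.
    """
    if abs(angle) > 90:
        raise ValueError("|angle| must be <= 90 degrees")
    height = geometry.horizontal_dist_to_icp * math.sin(math.radians(angle))
    offset = height * density * MMHG_PER_CMH2O
    return HydrostaticPrediction(
        angle=float(angle), column_height=height, pressure_offset=offset,
        density=density,
    )
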