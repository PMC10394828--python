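"""Synthetic multi-compartment tilt-test recordings with known ground truth.

The generator emulates the structure of an anesthetized large-animal tilt
experiment: eleven pressure channels driven by one cardiac source per
subject, each channel shaped by its own compartment dynamics (resonant
"bell" sections near 4.2 and 11.5 Hz on top of a lowpass decay, optionally
an anti-resonant notch near 8 Hz), with

* a hydrostatic mean shift proportional to the tilt angle with a
  channel-specific signed slope and an exponential settling transient at
  each step change,
* additive respiratory modulation at the ventilator rate,
* Gaussian sensor noise and sparse spike artifacts, and
* multiplicative between-subject variability on baselines and slopes.

Every stochastic ingredient is seeded, and the generator records the exact
analytic ground truth (per-step means, pulse amplitudes, hydrostatic slopes,
and the compartment cascade's complex frequency response) so that each
downstream estimator has a recoverable target.

Compartment filtering is performed multiplicatively in the frequency domain
(``rfft`` of the source times the analytic response), which makes the
exposed magnitude ground truth exact rather than a discretization of it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .io_formats import (
    CHANNEL_NAMES,
    PressureChannel,
    Recording,
    SensorGeometry,
    TiltProtocol,
    default_protocol,
)

__all__ = [
    "SimChannelSpec",
    "SimCohortConfig",
    "ChannelTruth",
    "GroundTruth",
    "generate_cardiac_source",
    "compartment_response",
    "apply_compartment_filter",
    "synthesize_channel",
    "generate_cohort",
    "angle_profile",
    "default_channel_specs",
    "default_cohort_config",
    "tf_validation_config",
    "stats_validation_config",
]


@dataclass(frozen=True)
class SimChannelSpec:
    """Ground-truth parameters of one simulated pressure channel.

    ``resonances`` are ``(frequency_hz, damping_ratio, gain_db)`` triples
    realized as second-order bell sections with unity gain at DC and at high
    frequency, so the cascade's final asymptote is set by ``lowpass_order``
    alone (-20 dB/decade per order). ``notches`` are
    ``(frequency_hz, damping_ratio, depth_db)`` anti-resonant sections.
    """

    name: str
    baseline_mean: float  # mmHg at 0 degrees
    pulse_amplitude: float  # mmHg peak-to-trough at 0 degrees
    hydro_slope: float  # mmHg per degree of tilt, signed
    resp_depth: float = 0.0  # mmHg amplitude of respiratory modulation
    resonances: tuple[tuple[float, float, float], ...] = ()
    notches: tuple[tuple[float, float, float], ...] = ()
    lowpass_order: int = 0
    lowpass_cutoff_hz: float = 12.0
    noise_sd: float = 0.0  # mmHg
    artifact_rate: float = 0.0  # artifacts per minute

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel name {self.name!r}")
        if self.pulse_amplitude < 0:
            raise ValueError("pulse_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lowpass_order < 0:
            raise ValueError("lowpass_order must be >= 0")
        if self.lowpass_order and self.lowpass_cutoff_hz <= 0:
            raise ValueError("lowpass_cutoff_hz must be > 0")
        for f0, zeta, _ in tuple(self.resonances) + tuple(self.notches):
            if not 0 < zeta < 1:
                raise ValueError(
                    f"damping ratio {zeta} for section at {f0} Hz must lie in (0, 1)"
                )
            if f0 <= 0:
                raise ValueError("section frequencies must be > 0")

    def validate_for_fs(self, fs: float) -> None:
        for f0, _, _ in tuple(self.resonances) + tuple(self.notches):
            if f0 >= fs / 2:
                raise ValueError(
                    f"section frequency {f0} Hz is not below Nyquist ({fs / 2} Hz)"
                )


@dataclass(frozen=True)
class SimCohortConfig:
    """Study conditions for one simulated cohort."""

    n_subjects: int
    fs: float  # Hz
    protocol: TiltProtocol
    heart_rate: float  # Hz
    resp_rate: float  # breaths per minute
    channel_specs: tuple[SimChannelSpec, ...]
    seed: int
    between_subject_sd: float = 0.0  # fractional, on baselines and slopes
    n_harmonics: int = 12
    broadband_frac: float = 0.02  # broadband excitation, fraction of pulse height
    settle_tau_s: float = 30.0  # exponential settling time constant at step changes
    drift_mmhg_per_min: float = 0.0  # optional slow within-step drift, default off

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 12.0 <= self.resp_rate <= 15.0:
            raise ValueError("resp_rate must lie in the ventilated band 12-15 /min")
        top = max(
            (f0 for spec in self.channel_specs for f0, _, _ in
             tuple(spec.resonances) + tuple(spec.notches)),
            default=0.0,
        )
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} Hz must exceed twice the highest section "
                f"frequency ({top} Hz)"
            )
        for spec in self.channel_specs:
            spec.validate_for_fs(self.fs)
        if self.heart_rate * self.n_harmonics >= self.fs / 2:
            raise ValueError("cardiac harmonics would alias; reduce n_harmonics")


@dataclass
class ChannelTruth:
    """Exact generator bookkeeping for one subject's channel."""

    name: str
    baseline_mean: float
    hydro_slope: float
    pulse_amplitude: float
    step_means: dict[str, float]  # label -> baseline + slope * angle, exact
    response: Callable[[np.ndarray], np.ndarray]  # analytic complex H(f)
    norm_const: float  # peak-to-trough of the filtered unit source

    def magnitude_db(self, freq: np.ndarray) -> np.ndarray:
        return 20.0 * np.log10(np.abs(self.response(np.asarray(freq, float))))


@dataclass
class GroundTruth:
    """Cohort-level ground truth: one ChannelTruth per subject x channel."""

    subjects: list[dict[str, ChannelTruth]]

    def tf_magnitude_db(
        self, subject: int, output: str, freq: np.ndarray, input_channel: str = "cABP"
    ) -> np.ndarray:
        """Analytic transfer-function magnitude from ``input_channel`` to
        ``output`` in dB, including the pulse-amplitude scaling the
        synthesized waveforms carry."""
        freq = np.asarray(freq, dtype=float)
        out = self.subjects[subject][output]
        inp = self.subjects[subject][input_channel]
        gain = (out.pulse_amplitude / out.norm_const) / (
            inp.pulse_amplitude / inp.norm_const
        )
        h = out.response(freq) / inp.response(freq)
        return 20.0 * np.log10(gain * np.abs(h))


# ---------------------------------------------------------------------------
# cardiac source
# ---------------------------------------------------------------------------

def generate_cardiac_source(
    heart_rate: float,
    n_harmonics: int,
    fs: float,
    duration: float,
    seed: int,
    broadband_frac: float = 0.0,
) -> np.ndarray:
    """Unitless arterial-like cardiac waveform: zero mean, unit pulse height.

    The deterministic part is a sum of ``n_harmonics`` phase-aligned
    harmonics with 1/k amplitudes, giving the sharp-upstroke sawtooth-like
    morphology of an arterial pulse. ``broadband_frac`` adds a seeded white
    excitation floor (a stand-in for beat-to-beat variability and
    high-frequency hemodynamic turbulence) scaled to that fraction of the
    pulse height; it is what makes frequency-response estimation
    identifiable between cardiac harmonics. The deterministic train is
    normalized to zero mean and peak-to-trough exactly 1 *before* the
    excitation floor is added, so the pulse height — not the noise
    extremes — defines the unit.
    """
    train, noise = _cardiac_components(
        heart_rate, n_harmonics, fs, duration, seed, broadband_frac
    )
    return train + noise


def _cardiac_components(
    heart_rate: float,
    n_harmonics: int,
    fs: float,
    duration: float,
    seed: int,
    broadband_frac: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic unit-pulse-height train and its broadband floor,
    separately (the cohort generator normalizes channels against the
    deterministic part alone)."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    for k in range(1, n_harmonics + 1):
        if heart_rate * k >= fs / 2:
            raise ValueError(
                f"harmonic {k} at {heart_rate * k:g} Hz is not below "
                f"Nyquist ({fs / 2:g} Hz)"
            )
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        # -sin alignment: steep rise, slow decay, like an arterial upstroke
        x -= np.sin(2 * np.pi * k * heart_rate * t) / k
    x -= x.mean()
    x /= x.max() - x.min()
    if broadband_frac > 0:
        rng = np.random.default_rng(seed)
        noise = broadband_frac * rng.standard_normal(n)
        noise -= noise.mean()
    else:
        noise = np.zeros(n)
    return x, noise


# ---------------------------------------------------------------------------
# compartment dynamics
# ---------------------------------------------------------------------------

def _bell(freq: np.ndarray, f0: float, zeta: float, gain_db: float) -> np.ndarray:
    """Second-order resonant section with unity DC and HF gain.

    H(s) = (s^2 + 2 zeta_n w0 s + w0^2) / (s^2 + 2 zeta w0 s + w0^2) with
    zeta_n = zeta * 10^(gain_db/20); |H(j w0)| = 10^(gain_db/20).
    """
    u = freq / f0
    zeta_n = zeta * 10.0 ** (gain_db / 20.0)
    num = (1 - u**2) + 2j * zeta_n * u
    den = (1 - u**2) + 2j * zeta * u
    return num / den


def compartment_response(spec: SimChannelSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Analytic complex frequency response of a channel's filter cascade."""

    def response(freq: np.ndarray) -> np.ndarray:
        freq = np.asarray(freq, dtype=float)
        h = np.ones_like(freq, dtype=complex)
        for f0, zeta, gain_db in spec.resonances:
            h = h * _bell(freq, f0, zeta, gain_db)
        for f0, zeta, depth_db in spec.notches:
            h = h * _bell(freq, f0, zeta, -depth_db)
        if spec.lowpass_order:
            h = h / (1 + 1j * freq / spec.lowpass_cutoff_hz) ** spec.lowpass_order
        return h

    return response


def apply_compartment_filter(
    source: np.ndarray, spec: SimChannelSpec, fs: float
) -> tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """Filter a waveform through the channel's analytic cascade.

    Returns the filtered waveform and the analytic complex response used,
    which serves as spectral ground truth downstream. With no resonant,
    notch, or lowpass sections the source is returned unchanged.
    """
    spec.validate_for_fs(fs)
    response = compartment_response(spec)
    if not spec.resonances and not spec.notches and spec.lowpass_order == 0:
        return np.asarray(source, dtype=np.float64).copy(), response
    x = np.asarray(source, dtype=np.float64)
    freq = np.fft.rfftfreq(x.size, d=1.0 / fs)
    y = np.fft.irfft(np.fft.rfft(x) * response(freq), n=x.size)
    return y, response


# ---------------------------------------------------------------------------
# channel synthesis
# ---------------------------------------------------------------------------

def angle_profile(
    protocol: TiltProtocol, fs: float, settle_tau_s: float = 0.0
) -> np.ndarray:
    """Tilt angle as a function of sample index.

    Piecewise constant per step; with ``settle_tau_s > 0`` each step change
    relaxes exponentially from the previous plateau toward the new one
    (the table moves fast, the pressures settle slowly).
    """
    n = int(round(protocol.duration * fs))
    angle = np.empty(n)
    prev = protocol.steps[0].angle
    start = 0
    for step in protocol.steps:
        stop = min(n, start + int(round(step.duration * fs)))
        m = stop - start
        if settle_tau_s > 0 and prev != step.angle:
            t = np.arange(m) / fs
            angle[start:stop] = step.angle + (prev - step.angle) * np.exp(
                -t / settle_tau_s
            )
        else:
            angle[start:stop] = step.angle
        prev = step.angle
        start = stop
    if start < n:  # guard against rounding shortfall
        angle[start:] = prev
    return angle


def synthesize_channel(
    source: np.ndarray,
    spec: SimChannelSpec,
    protocol: TiltProtocol,
    fs: float,
    resp_rate: float,
    seed: int,
    settle_tau_s: float = 30.0,
    drift_mmhg_per_min: float = 0.0,
    pulse_reference: np.ndarray | None = None,
) -> tuple[PressureChannel, ChannelTruth]:
    """Build one pressure channel from the shared cardiac source.

    channel(t) = baseline + slope * angle(t)              (with settling)
               + pulse_amplitude * filtered source        (unit pulse height)
               + resp_depth * sin(2 pi f_resp t)
               + optional linear drift + noise + sparse spike artifacts

    ``pulse_reference``, when given, is the deterministic cardiac train
    alone; the filtered channel is rescaled so that *its* filtered
    peak-to-trough equals ``pulse_amplitude`` (otherwise the full source is
    used). The recorded ground-truth step means are the exact plateau
    values baseline + slope * angle, settling transient excluded.
    """
    n = int(round(protocol.duration * fs))
    source = np.asarray(source, dtype=np.float64)
    if source.size != n:
        raise ValueError(
            f"source length {source.size} != protocol duration x fs = {n}"
        )
    filtered, response = apply_compartment_filter(source, spec, fs)
    if pulse_reference is not None:
        ref_filtered, _ = apply_compartment_filter(
            np.asarray(pulse_reference, dtype=np.float64), spec, fs
        )
    else:
        ref_filtered = filtered
    norm = float(ref_filtered.max() - ref_filtered.min())
    if norm == 0.0:
        norm = 1.0
    angle = angle_profile(protocol, fs, settle_tau_s)
    x = spec.baseline_mean + spec.hydro_slope * angle
    if spec.pulse_amplitude:
        x = x + spec.pulse_amplitude * (filtered / norm)
    if spec.resp_depth:
        t = np.arange(n) / fs
        x = x + spec.resp_depth * np.sin(2 * np.pi * (resp_rate / 60.0) * t)
    if drift_mmhg_per_min:
        x = x + drift_mmhg_per_min * (np.arange(n) / fs / 60.0)
    rng = np.random.default_rng(seed)
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, size=n)
        if spec.artifact_rate > 0:
            n_art = rng.poisson(spec.artifact_rate * protocol.duration / 60.0)
            if n_art:
                idx = rng.integers(0, n, size=n_art)
                amp = rng.uniform(6.0, 12.0, size=n_art) * spec.noise_sd
                sign = rng.choice([-1.0, 1.0], size=n_art)
                x[idx] += sign * amp
    truth = ChannelTruth(
        name=spec.name,
        baseline_mean=spec.baseline_mean,
        hydro_slope=spec.hydro_slope,
        pulse_amplitude=spec.pulse_amplitude,
        step_means={
            s.label: spec.baseline_mean + spec.hydro_slope * s.angle
            for s in protocol.steps
        },
        response=response,
        norm_const=norm,
    )
    return PressureChannel(name=spec.name, fs=fs, samples=x), truth


def generate_cohort(config: SimCohortConfig) -> tuple[list[Recording], GroundTruth]:
    """Generate ``n_subjects`` recordings sharing one protocol.

    Each subject gets one cardiac source driving all channels. Baseline
    means and hydrostatic slopes receive multiplicative Gaussian
    between-subject variability truncated at +-3 SD, which preserves the
    sign of every slope and keeps correlation-sign recovery well-posed.
    Bit-identical output for identical config (including seed).
    """
    root = np.random.SeedSequence(config.seed)
    subject_seqs = root.spawn(config.n_subjects)
    recordings: list[Recording] = []
    truths: list[dict[str, ChannelTruth]] = []
    for i, seq in enumerate(subject_seqs):
        child = seq.spawn(len(config.channel_specs) + 2)
        rng_subj = np.random.default_rng(child[0])
        train, bb = _cardiac_components(
            config.heart_rate,
            config.n_harmonics,
            config.fs,
            config.protocol.duration,
            seed=int(child[1].generate_state(1)[0] % (2**31)),
            broadband_frac=config.broadband_frac,
        )
        source = train + bb
        channels: dict[str, PressureChannel] = {}
        truth: dict[str, ChannelTruth] = {}
        for j, spec in enumerate(config.channel_specs):
            if config.between_subject_sd > 0:
                mult = rng_subj.normal(1.0, config.between_subject_sd, size=2)
                lim = 3.0 * config.between_subject_sd
                mult = np.clip(mult, 1.0 - lim, 1.0 + lim)
                spec_i = replace(
                    spec,
                    baseline_mean=spec.baseline_mean * mult[0],
                    hydro_slope=spec.hydro_slope * mult[1],
                )
            else:
                spec_i = spec
            ch, ct = synthesize_channel(
                source,
                spec_i,
                config.protocol,
                config.fs,
                config.resp_rate,
                seed=int(child[j + 2].generate_state(1)[0] % (2**31)),
                settle_tau_s=config.settle_tau_s,
                drift_mmhg_per_min=config.drift_mmhg_per_min,
                pulse_reference=train,
            )
            channels[spec.name] = ch
            truth[spec.name] = ct
        recordings.append(
            Recording(subject_id=f"S{i + 1}", channels=channels,
                      protocol=config.protocol)
        )
        truths.append(truth)
    return recordings, GroundTruth(subjects=truths)


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

#: Cohort-scale channel parameters: baseline mean, pulse amplitude, and
#: hydrostatic slope (mmHg per degree; the slope is the +13 degree mean shift
#: divided by 13). Signs reflect the measured channel-specific responses:
#: arterial, intracranial, jugular, cranial/dorsal abdominal pressures fall
#: with head-over-body tilt; intrathecal, central venous, caudal abdominal
#: and intravesical pressures rise.
_TABLE_SCALE = {
    #        mean   amp   slope   resp
    "cABP": (80.4, 18.8, -0.66, 1.0),
    "fABP": (75.5, 26.0, -0.35, 1.0),
    "ICP": (16.8, 2.6, -0.45, 0.4),
    "ITP": (18.2, 3.0, +0.38, 0.4),
    "CVP": (7.6, 3.7, +0.03, 0.8),
    "JVP": (5.1, 1.2, -0.13, 0.3),
    "IAPcr": (15.9, 7.7, -0.36, 1.5),
    "IAPcd": (14.9, 4.6, +0.18, 1.5),
    "IAPds": (12.6, 11.0, -0.48, 1.5),
    "IAPve": (10.0, 6.2, -0.20, 1.5),
    "IVP": (11.4, 1.7, +0.54, 0.5),
}

#: Compartment resonances shared by the craniospinal/venous outputs: bells
#: near 4.2 and 11.5 Hz over a first-order decay.
_DEFAULT_RESONANCES = ((4.2, 0.08, 10.0), (11.5, 0.10, 8.0))


def default_channel_specs(
    noise_frac: float = 0.05, artifact_rate: float = 1.0
) -> tuple[SimChannelSpec, ...]:
    """Cohort-scale specs for all eleven channels.

    ``noise_frac`` sets each channel's sensor noise SD as a fraction of its
    pulse amplitude. The arterial input (cABP) passes the cardiac source
    unfiltered; all other channels carry the resonant-lowpass compartment
    cascade, and the dorsal abdominal channel additionally carries the 8 Hz
    anti-resonant notch (shallower on the ventral and vesical channels).
    """
    notch_by_channel = {
        "IAPds": ((8.0, 0.15, 10.0),),
        "IAPve": ((8.0, 0.15, 5.0),),
        "IVP": ((8.0, 0.15, 5.0),),
    }
    specs = []
    for name, (mean, amp, slope, resp) in _TABLE_SCALE.items():
        filtered = name != "cABP"
        specs.append(
            SimChannelSpec(
                name=name,
                baseline_mean=mean,
                pulse_amplitude=amp,
                hydro_slope=slope,
                resp_depth=resp,
                resonances=_DEFAULT_RESONANCES if filtered else (),
                notches=notch_by_channel.get(name, ()),
                lowpass_order=1 if filtered else 0,
                lowpass_cutoff_hz=12.0,
                noise_sd=noise_frac * amp,
                artifact_rate=artifact_rate,
            )
        )
    return tuple(specs)


def default_cohort_config(
    seed: int,
    n_subjects: int = 6,
    fs: float = 200.0,
    step_duration: float = 60.0,
    **overrides,
) -> SimCohortConfig:
    """Scaled study conditions used throughout the test suite.

    Full acquisition scale (1 kHz, 10-min steps) is configurable but the
    default keeps a whole cohort comfortably inside unit-test budgets:
    200 Hz sampling, 60 s plateaus, 84 bpm cardiac fundamental, 14
    breaths/min ventilation, 10% between-subject variability.
    """
    params = dict(
        n_subjects=n_subjects,
        fs=fs,
        protocol=default_protocol(step_duration),
        heart_rate=1.4,
        resp_rate=14.0,
        channel_specs=default_channel_specs(),
        seed=seed,
        between_subject_sd=0.1,
        n_harmonics=12,
        broadband_frac=0.02,
        settle_tau_s=3.0,
    )
    params.update(overrides)
    return SimCohortConfig(**params)


def tf_validation_config(seed: int, **overrides) -> SimCohortConfig:
    """Cohort configured for transfer-function recovery checks.

    All output channels share the same cascade (bells at 4.2 and 11.5 Hz
    over a first-order 12 Hz decay, no notch) so the cohort average has a
    single known spectral truth, and the cardiac source carries a strong
    broadband excitation floor (50% of pulse height, harmonics up to the
    21st): estimating a frequency response at frequencies the input does
    not excite is not an estimator property worth testing. Sensor noise is
    5% of each channel's pulse amplitude.
    """
    specs = tuple(
        replace(s, notches=(), resonances=_DEFAULT_RESONANCES if s.name != "cABP" else ())
        for s in default_channel_specs(noise_frac=0.05, artifact_rate=0.0)
    )
    params = dict(channel_specs=specs, broadband_frac=0.5, n_harmonics=21,
                  between_subject_sd=0.0)
    params.update(overrides)
    return default_cohort_config(seed, **params)


def stats_validation_config(seed: int, **overrides) -> SimCohortConfig:
    """Cohort configured for correlation-sign recovery checks.

    Hydrostatic slopes keep the cohort-scale channel-specific signs; every
    channel's sensor noise is fixed at 1 mmHg.
    """
    specs = tuple(
        replace(s, noise_sd=1.0) for s in default_channel_specs(artifact_rate=1.0)
    )
    params = dict(channel_specs=specs)
    params.update(overrides)
    return default_cohort_config(seed, **params)
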