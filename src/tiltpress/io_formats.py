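"""Domain types and file I/O for tilt-test pressure recordings.

A recording is a set of simultaneously sampled pressure channels from a
closed set of eleven anatomical sites (carotid/femoral arterial,
intracranial, intrathecal, central/jugular venous, four intra-abdominal
quadrants, and intravesical), together with the tilt protocol — the ordered
sequence of table angles that segments every downstream analysis.

Waveforms are stored in HDF5 (one float64 dataset per channel under
``/channels/<name>`` with ``fs_hz`` / ``units`` attributes and the protocol
serialized as a JSON root attribute) or, for small data, as long-format CSV
(``time_s,channel,value_mmHg``) with a JSON metadata sidecar. Derived tables
are plain CSV for diffability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

#: The closed set of channel names. Downstream sign conventions (hydrostatic
#: slopes, transfer-function input selection) depend on channel identity, so
#: unknown names are errors, never warnings.
CHANNEL_NAMES = (
    "cABP", "fABP", "ICP", "ITP", "CVP", "JVP",
    "IAPcr", "IAPcd", "IAPds", "IAPve", "IVP",
)

#: Designated transfer-function input: the carotid arterial pressure drives
#: all other compartments.
TF_INPUT_CHANNEL = "cABP"

#: Column schema for step-summary tables (one row per subject x channel x step).
STEP_SUMMARY_COLUMNS = (
    "subject_id", "channel", "step_label", "angle_deg",
    "mean_pressure_mmhg", "pulse_amplitude_mmhg",
    "delta_mean_mmhg", "delta_pulse_mmhg",
)

#: Column schema for correlation tables (one row per channel x statistic).
CORRELATION_COLUMNS = ("channel", "statistic", "r", "p", "strength_class")


class FormatError(ValueError):
    """Raised when a file does not conform to the documented layout."""


@dataclass(frozen=True)
class SensorGeometry:
    """Position of a pressure transducer relative to the ICP transducer.

    ``vertical_dist_to_icp`` is positive when the sensor sits below the ICP
    transducer in the prone reference posture.
    """

    horizontal_dist_to_icp: float  # cm
    vertical_dist_to_icp: float = 0.0  # cm, positive = below ICP sensor

    def __post_init__(self) -> None:
        if self.horizontal_dist_to_icp < 0:
            raise ValueError("horizontal_dist_to_icp must be >= 0 cm")


@dataclass(frozen=True)
class TiltStep:
    """One plateau of the tilt protocol.

    Positive angles are head-over-body, negative body-over-head.
    """

    angle: float  # degrees
    duration: float  # seconds
    label: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"step {self.label!r}: duration must be > 0")
        if abs(self.angle) > 90:
            raise ValueError(f"step {self.label!r}: |angle| must be <= 90 deg")


@dataclass(frozen=True)
class TiltProtocol:
    """Ordered angle schedule; the first step must be the 0 degree baseline."""

    steps: tuple[TiltStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("protocol must contain at least one step")
        if self.steps[0].angle != 0.0:
            raise ValueError("first protocol step must be the 0 deg baseline")
        labels = [s.label for s in self.steps]
        if len(set(labels)) != len(labels):
            raise ValueError("step labels must be unique")

    @property
    def duration(self) -> float:
        return float(sum(s.duration for s in self.steps))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.steps)

    @property
    def angles(self) -> np.ndarray:
        return np.array([s.angle for s in self.steps], dtype=float)

    @property
    def baseline_label(self) -> str:
        return self.steps[0].label

    def step(self, label: str) -> TiltStep:
        for s in self.steps:
            if s.label == label:
                return s
        raise KeyError(f"no step labelled {label!r}")

    def to_json(self) -> str:
        return json.dumps([asdict(s) for s in self.steps])

    @classmethod
    def from_json(cls, text: str) -> "TiltProtocol":
        return cls(tuple(TiltStep(**d) for d in json.loads(text)))


def default_protocol(step_duration: float = 600.0) -> TiltProtocol:
    """The standard 13-step tilt sequence.

    0, +5, +10, +13, +10, +5, 0, -5, -10, -13, -10, -5, 0 degrees, each
    plateau held for ``step_duration`` seconds (10 min by default). Repeated
    angles carry ordinal suffixes; the three prone plateaus are labelled
    ``0_1``, ``0_2``, ``0_3``.
    """
    angles = [0, 5, 10, 13, 10, 5, 0, -5, -10, -13, -10, -5, 0]
    labels = [
        "0_1", "+5_1", "+10_1", "+13", "+10_2", "+5_2", "0_2",
        "-5_1", "-10_1", "-13", "-10_2", "-5_2", "0_3",
    ]
    steps = tuple(
        TiltStep(angle=float(a), duration=float(step_duration), label=lab)
        for a, lab in zip(angles, labels)
    )
    return TiltProtocol(steps)


@dataclass
class PressureChannel:
    """One named pressure signal in mmHg with its sampling rate."""

    name: str
    fs: float  # Hz
    samples: np.ndarray  # mmHg
    geometry: SensorGeometry | None = None

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ValueError(
                f"unknown channel name {self.name!r}; expected one of {CHANNEL_NAMES}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Recording:
    """All channels of one subject plus the tilt protocol that segments them."""

    subject_id: str
    channels: dict[str, PressureChannel]
    protocol: TiltProtocol

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("recording has no channels")
        lengths = {c.n_samples for c in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"channels differ in length: {sorted(lengths)}")
        rates = {c.fs for c in self.channels.values()}
        if len(rates) != 1:
            raise ValueError(f"channels differ in sampling rate: {sorted(rates)}")
        n = lengths.pop()
        fs = rates.pop()
        expected = self.protocol.duration * fs
        if abs(n - expected) > 1.0:
            raise ValueError(
                f"recording length {n} samples does not match protocol duration "
                f"{self.protocol.duration} s at fs={fs} Hz ({expected:.0f} samples)"
            )

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).n_samples

    def __getitem__(self, name: str) -> PressureChannel:
        return self.channels[name]


# ---------------------------------------------------------------------------
# waveform I/O
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a recording to HDF5 in the documented layout."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = recording.subject_id
        f.attrs["protocol"] = recording.protocol.to_json()
        grp = f.create_group("channels")
        for name, ch in recording.channels.items():
            ds = grp.create_dataset(name, data=ch.samples, dtype="float64")
            ds.attrs["fs_hz"] = ch.fs
            ds.attrs["units"] = "mmHg"
            if ch.geometry is not None:
                ds.attrs["horizontal_dist_to_icp_cm"] = ch.geometry.horizontal_dist_to_icp
                ds.attrs["vertical_dist_to_icp_cm"] = ch.geometry.vertical_dist_to_icp
    return path


def _read_recording_hdf5(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        if "protocol" not in f.attrs:
            raise FormatError(f"{path}: missing 'protocol' root attribute")
        protocol = TiltProtocol.from_json(f.attrs["protocol"])
        subject_id = str(f.attrs.get("subject_id", path.stem))
        if "channels" not in f:
            raise FormatError(f"{path}: missing '/channels' group")
        channels: dict[str, PressureChannel] = {}
        for name, ds in f["channels"].items():
            if name not in CHANNEL_NAMES:
                raise FormatError(f"{path}: unknown channel name {name!r}")
            if "fs_hz" not in ds.attrs:
                raise FormatError(f"{path}: channel {name!r} missing 'fs_hz' attribute")
            geometry = None
            if "horizontal_dist_to_icp_cm" in ds.attrs:
                geometry = SensorGeometry(
                    horizontal_dist_to_icp=float(ds.attrs["horizontal_dist_to_icp_cm"]),
                    vertical_dist_to_icp=float(ds.attrs.get("vertical_dist_to_icp_cm", 0.0)),
                )
            channels[name] = PressureChannel(
                name=name, fs=float(ds.attrs["fs_hz"]), samples=ds[()],
                geometry=geometry,
            )
    return Recording(subject_id=subject_id, channels=channels, protocol=protocol)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_recording_csv(recording: Recording, path: str | Path) -> Path:
    """Write a recording as long-format CSV plus a JSON metadata sidecar.

    Intended for small (test-scale) recordings; waveform storage at full
    acquisition rates should use HDF5.
    """
    path = Path(path)
    fs = recording.fs
    n = recording.n_samples
    t = np.arange(n) / fs
    frames = []
    for name, ch in recording.channels.items():
        frames.append(pd.DataFrame(
            {"time_s": t, "channel": name, "value_mmHg": ch.samples}
        ))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")
    meta = {
        "subject_id": recording.subject_id,
        "fs_hz": fs,
        "n_samples": n,
        "protocol": json.loads(recording.protocol.to_json()),
        "geometry": {
            name: asdict(ch.geometry)
            for name, ch in recording.channels.items()
            if ch.geometry is not None
        },
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _read_recording_csv(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"{path}: metadata sidecar {sidecar.name} not found")
    meta = json.loads(sidecar.read_text())
    fs = float(meta["fs_hz"])
    n_expected = int(meta["n_samples"])
    protocol = TiltProtocol(tuple(TiltStep(**d) for d in meta["protocol"]))
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "channel", "value_mmHg"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    channels: dict[str, PressureChannel] = {}
    for name, sub in df.groupby("channel", sort=False):
        if name not in CHANNEL_NAMES:
            raise FormatError(f"{path}: unknown channel name {name!r}")
        values = sub.sort_values("time_s")["value_mmHg"].to_numpy()
        if values.size != n_expected:
            raise FormatError(
                f"{path}: channel {name!r} has {values.size} samples, "
                f"sidecar declares {n_expected} (truncated file?)"
            )
        geo = meta.get("geometry", {}).get(name)
        channels[name] = PressureChannel(
            name=str(name), fs=fs, samples=values,
            geometry=SensorGeometry(**geo) if geo else None,
        )
    return Recording(subject_id=str(meta["subject_id"]), channels=channels,
                     protocol=protocol)


def read_recording(path: str | Path) -> Recording:
    """Read a recording from HDF5 (``.h5``/``.hdf5``) or CSV (``.csv``)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_recording_hdf5(path)
    if path.suffix.lower() == ".csv":
        return _read_recording_csv(path)
    raise FormatError(f"{path}: unrecognized extension {path.suffix!r}")


# ---------------------------------------------------------------------------
# result tables and run manifest
# ---------------------------------------------------------------------------

def write_results(
    out_dir: str | Path,
    *,
    step_summary: pd.DataFrame | None = None,
    correlations: pd.DataFrame | None = None,
    tf_table: pd.DataFrame | None = None,
    features: pd.DataFrame | None = None,
    manifest: Mapping | None = None,
) -> dict[str, Path]:
    """Write result tables as CSV plus a JSON run manifest.

    Returns a mapping from logical table name to the written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    tables = {
        "step_summary": step_summary,
        "correlations": correlations,
        "transfer_functions": tf_table,
        "spectral_features": features,
    }
    for name, df in tables.items():
        if df is not None:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            written[name] = p
    if manifest is not None:
        p = out / "manifest.json"
        p.write_text(json.dumps(dict(manifest), indent=1, default=str))
        written["manifest"] = p
    return written


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
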