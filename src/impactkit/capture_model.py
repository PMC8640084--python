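"""Capture data model and on-disk session format.

A *capture* is one threshold-triggered, windowed multi-sensor recording from
an instrumented mouthguard: three triaxial linear accelerometers (nominally
3,200 Hz, ±200 g, 12-bit) plus a triaxial gyroscope (nominally 800 Hz,
±2,000 dps, 16-bit), together with trigger metadata and an optional
video-review label.  Every other stage of the pipeline consumes or produces
these types.

On disk a *session* of captures is stored as a single self-describing JSON
file (``*.captures.json``): a header carrying device / calibration /
label-vocabulary information followed by per-capture records with columnar
sample blocks.  Samples are stored in physical units (g, dps), not raw ADC
counts; quantisation is the simulator's job.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SENSOR_IDS",
    "ACCELEROMETER_SENSORS",
    "LABELS",
    "SUBLABELS",
    "SensorStream",
    "Capture",
    "CalibrationSet",
    "CaptureFormatError",
    "CaptureValidationError",
    "validate_capture",
    "read_capture_file",
    "write_capture_file",
    "accelerometer_stream",
    "gyro_stream",
]

# ---------------------------------------------------------------------------
# Sensor constants (hardware reference configuration)
# ---------------------------------------------------------------------------

SENSOR_IDS = ("left_acc", "centre_acc", "right_acc", "gyro")
ACCELEROMETER_SENSORS = ("left_acc", "centre_acc", "right_acc")

ACC_NOMINAL_RATE_HZ = 3200.0
GYRO_NOMINAL_RATE_HZ = 800.0
ACC_RANGE_G = 200.0
GYRO_RANGE_DPS = 2000.0
ACC_BIT_DEPTH = 12
GYRO_BIT_DEPTH = 16

DEFAULT_LEAD_IN_MS = 20.0
DEFAULT_TAIL_MS = 80.0

LABELS = ("hit", "non_hit", "unlabelled")
SUBLABELS = (
    "hit",
    "biting",
    "chewing",
    "drinking",
    "insertion",
    "removal",
    "in_hand",
    "in_sock",
    "yelling",
    "no_footage",
    "unknown",
    "none",
)

_FORMAT_NAME = "impactkit-captures"
_FORMAT_VERSION = 1


class CaptureFormatError(ValueError):
    """Raised when a capture file does not conform to the session dialect."""


class CaptureValidationError(ValueError):
    """Raised when a capture violates a type invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SensorStream:
    """One sensor's triaxial time series.

    Parameters
    ----------
    sensor_id
        One of :data:`SENSOR_IDS`.
    samples
        Array of shape ``(3, n)`` holding the x/y/z channels, in g for
        accelerometers and degrees-per-second for the gyroscope.
    nominal_rate, actual_rate
        Design and realised sampling rates in Hz.  The actual rate may
        deviate from nominal because of per-device oscillator variation.
    range_limit
        Full-scale magnitude (±) of the sensor.
    bit_depth
        ADC resolution over ``[-range_limit, +range_limit]``.
    """

    sensor_id: str
    samples: np.ndarray
    nominal_rate: float
    actual_rate: float
    range_limit: float
    bit_depth: int

    def __post_init__(self) -> None:
        # Ragged channels are kept as-is so that validate_capture can report
        # them as a violation instead of the constructor raising.
        try:
            arr = np.asarray(self.samples, dtype=np.float64)
        except (ValueError, TypeError):
            arr = None
        if arr is not None and arr.ndim == 2 and arr.shape[0] == 3:
            self.samples = arr

    @property
    def is_well_formed(self) -> bool:
        return (
            isinstance(self.samples, np.ndarray)
            and self.samples.dtype == np.float64
            and self.samples.ndim == 2
            and self.samples.shape[0] == 3
        )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.actual_rate

    def copy(self) -> "SensorStream":
        return replace(self, samples=self.samples.copy())


@dataclass
class Capture:
    """One triggered mouthguard event: four sensor streams plus metadata.

    ``trigger_index`` is 0-based on the *left accelerometer* stream at its
    actual rate — the onboard trigger thresholds the Euclidean norm of that
    sensor.  ``lead_in_ms``/``tail_ms`` record the window geometry (20 ms
    before the first threshold crossing, 80 ms after the last).
    """

    capture_id: str
    device_id: str
    streams: dict[str, SensorStream]
    trigger_index: int
    lead_in_ms: float = DEFAULT_LEAD_IN_MS
    tail_ms: float = DEFAULT_TAIL_MS
    label: str = "unlabelled"
    sublabel: str = "none"
    session_id: str = ""

    def stream(self, sensor_id: str) -> SensorStream:
        return self.streams[sensor_id]

    def copy(self) -> "Capture":
        return replace(
            self, streams={k: s.copy() for k, s in self.streams.items()}
        )


@dataclass
class CalibrationSet:
    """Per-sensor 3x3 rotation matrices mapping device axes to cardinal axes.

    The matrices are treated as given inputs (they come from a per-device
    factory calibration); this package only checks that each is a proper
    rotation (orthonormal, determinant +1) and applies it.
    """

    matrices: dict[str, np.ndarray]
    orthonormal_tol: float = 1e-9

    def __post_init__(self) -> None:
        self.matrices = {
            k: np.asarray(m, dtype=np.float64) for k, m in self.matrices.items()
        }

    def matrix(self, sensor_id: str) -> np.ndarray:
        return self.matrices[sensor_id]

    def violations(self) -> list[str]:
        out = []
        for sensor_id, m in self.matrices.items():
            if m.shape != (3, 3):
                out.append(f"{sensor_id}: matrix shape {m.shape} != (3, 3)")
                continue
            if not np.allclose(m.T @ m, np.eye(3), atol=self.orthonormal_tol):
                out.append(f"{sensor_id}: matrix is not orthonormal")
            elif np.linalg.det(m) < 0:
                out.append(f"{sensor_id}: matrix is a reflection (det < 0)")
        return out

    @classmethod
    def identity(cls) -> "CalibrationSet":
        return cls({sid: np.eye(3) for sid in SENSOR_IDS})


def accelerometer_stream(
    sensor_id: str, samples: np.ndarray, actual_rate: float | None = None
) -> SensorStream:
    """Convenience constructor for an accelerometer stream with the
    reference hardware constants."""
    return SensorStream(
        sensor_id=sensor_id,
        samples=samples,
        nominal_rate=ACC_NOMINAL_RATE_HZ,
        actual_rate=ACC_NOMINAL_RATE_HZ if actual_rate is None else actual_rate,
        range_limit=ACC_RANGE_G,
        bit_depth=ACC_BIT_DEPTH,
    )


def gyro_stream(samples: np.ndarray, actual_rate: float | None = None) -> SensorStream:
    """Convenience constructor for the gyroscope stream."""
    return SensorStream(
        sensor_id="gyro",
        samples=samples,
        nominal_rate=GYRO_NOMINAL_RATE_HZ,
        actual_rate=GYRO_NOMINAL_RATE_HZ if actual_rate is None else actual_rate,
        range_limit=GYRO_RANGE_DPS,
        bit_depth=GYRO_BIT_DEPTH,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_capture(c: Capture) -> list[str]:
    """Check every type invariant of ``c``.

    Returns a list of human-readable violation descriptions, each naming the
    offending field and rule; an empty list means the capture is valid.
    Violations are returned, never raised.
    """
    v: list[str] = []
    missing = [sid for sid in SENSOR_IDS if sid not in c.streams]
    if missing:
        v.append(f"streams: missing sensor(s) {missing}")
    extra = [sid for sid in c.streams if sid not in SENSOR_IDS]
    if extra:
        v.append(f"streams: unknown sensor id(s) {extra}")
    for sid, s in c.streams.items():
        if s.sensor_id != sid:
            v.append(f"streams[{sid}]: sensor_id mismatch ({s.sensor_id})")
        if not s.is_well_formed:
            lengths = [np.size(ch) for ch in s.samples] if len(s.samples) else []
            v.append(
                f"streams[{sid}].samples: three equal-length channels "
                f"required (got lengths {lengths})"
            )
            continue
        if s.n_samples < 1:
            v.append(f"streams[{sid}].samples: channels must have length >= 1")
        if not np.all(np.isfinite(s.samples)):
            v.append(f"streams[{sid}].samples: non-finite values")
        elif np.any(np.abs(s.samples) > s.range_limit * (1 + 1e-12)):
            peak = float(np.max(np.abs(s.samples)))
            v.append(
                f"streams[{sid}].samples: |sample| {peak:g} exceeds "
                f"range_limit ±{s.range_limit:g}"
            )
        if not (s.actual_rate > 0):
            v.append(f"streams[{sid}].actual_rate: must be > 0")
    if c.label not in LABELS:
        v.append(f"label: {c.label!r} not in {LABELS}")
    if c.sublabel not in SUBLABELS:
        v.append(f"sublabel: {c.sublabel!r} not in {SUBLABELS}")
    if c.label == "hit" and c.sublabel != "hit":
        v.append("sublabel: must be 'hit' when label is 'hit'")
    if c.lead_in_ms < 0 or c.tail_ms < 0:
        v.append("lead_in_ms/tail_ms: must be non-negative")
    left = c.streams.get("left_acc")
    if left is not None and left.is_well_formed:
        if not (0 <= c.trigger_index < max(left.n_samples, 1)):
            v.append(
                f"trigger_index: {c.trigger_index} outside left_acc stream "
                f"of length {left.n_samples}"
            )
    return v


def _validate_or_raise(c: Capture) -> None:
    violations = validate_capture(c)
    if violations:
        raise CaptureValidationError(
            f"capture {c.capture_id!r}: " + "; ".join(violations)
        )


# ---------------------------------------------------------------------------
# Session file I/O (the `.captures.json` dialect)
# ---------------------------------------------------------------------------


def _stream_to_record(s: SensorStream) -> dict:
    return {
        "sensor_id": s.sensor_id,
        "nominal_rate": s.nominal_rate,
        "actual_rate": s.actual_rate,
        "range_limit": s.range_limit,
        "bit_depth": s.bit_depth,
        "x": s.samples[0].tolist(),
        "y": s.samples[1].tolist(),
        "z": s.samples[2].tolist(),
    }


def _stream_from_record(rec: Mapping, where: str) -> SensorStream:
    try:
        chans = [rec["x"], rec["y"], rec["z"]]
        lengths = {len(c) for c in chans}
        if len(lengths) != 1:
            raise CaptureFormatError(
                f"{where}: channel lengths differ ({[len(c) for c in chans]})"
            )
        return SensorStream(
            sensor_id=rec["sensor_id"],
            samples=np.array(chans, dtype=np.float64),
            nominal_rate=float(rec["nominal_rate"]),
            actual_rate=float(rec["actual_rate"]),
            range_limit=float(rec["range_limit"]),
            bit_depth=int(rec["bit_depth"]),
        )
    except KeyError as e:
        raise CaptureFormatError(f"{where}: missing field {e.args[0]!r}") from e


def _capture_to_record(c: Capture) -> dict:
    return {
        "capture_id": c.capture_id,
        "device_id": c.device_id,
        "session_id": c.session_id,
        "trigger_index": int(c.trigger_index),
        "lead_in_ms": c.lead_in_ms,
        "tail_ms": c.tail_ms,
        "label": c.label,
        "sublabel": c.sublabel,
        "streams": {sid: _stream_to_record(c.streams[sid]) for sid in SENSOR_IDS},
    }


def _capture_from_record(rec: Mapping, index: int) -> Capture:
    where = f"capture record {index}"
    try:
        cid = rec["capture_id"]
        streams = {
            sid: _stream_from_record(srec, f"{where} ({cid}) stream {sid!r}")
            for sid, srec in rec["streams"].items()
        }
        return Capture(
            capture_id=cid,
            device_id=rec["device_id"],
            session_id=rec.get("session_id", ""),
            streams=streams,
            trigger_index=int(rec["trigger_index"]),
            lead_in_ms=float(rec["lead_in_ms"]),
            tail_ms=float(rec["tail_ms"]),
            label=rec["label"],
            sublabel=rec["sublabel"],
        )
    except KeyError as e:
        raise CaptureFormatError(f"{where}: missing field {e.args[0]!r}") from e


def write_capture_file(
    captures: Sequence[Capture],
    path,
    calibration: CalibrationSet | None = None,
    header_extra: Mapping | None = None,
):
    """Write a session of captures to ``path`` in the JSON session dialect.

    Metadata round-trips bit-exactly and sample values are written with full
    ``repr`` precision, so ``read_capture_file(write_capture_file(x)) == x``.
    """
    captures = list(captures)
    if not captures:
        raise ValueError("write_capture_file: capture sequence is empty")
    for c in captures:
        _validate_or_raise(c)
    header: dict = {
        "devices": sorted({c.device_id for c in captures}),
        "label_vocabulary": {"labels": list(LABELS), "sublabels": list(SUBLABELS)},
    }
    if calibration is not None:
        header["calibration"] = {
            sid: m.tolist() for sid, m in calibration.matrices.items()
        }
    if header_extra:
        header.update(dict(header_extra))
    doc = {
        "format": _FORMAT_NAME,
        "version": _FORMAT_VERSION,
        "header": header,
        "captures": [_capture_to_record(c) for c in captures],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return path


def read_capture_file(path, validate: bool = True):
    """Read a session file written by :func:`write_capture_file`.

    Returns ``(captures, calibration_or_None)``.  Malformed files raise
    :class:`CaptureFormatError` naming the offending record; invariant
    violations raise :class:`CaptureValidationError` naming the capture.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise CaptureFormatError(f"{path}: invalid JSON at line {e.lineno}") from e
    if not isinstance(doc, dict) or doc.get("format") != _FORMAT_NAME:
        raise CaptureFormatError(f"{path}: not an {_FORMAT_NAME} file")
    if doc.get("version") != _FORMAT_VERSION:
        raise CaptureFormatError(
            f"{path}: unsupported version {doc.get('version')!r}"
        )
    captures = [
        _capture_from_record(rec, i) for i, rec in enumerate(doc.get("captures", []))
    ]
    if validate:
        for c in captures:
            _validate_or_raise(c)
    cal = None
    cal_rec = doc.get("header", {}).get("calibration")
    if cal_rec is not None:
        cal = CalibrationSet({sid: np.array(m) for sid, m in cal_rec.items()})
    return captures, cal
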