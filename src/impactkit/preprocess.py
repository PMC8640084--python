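"""Signal conditioning: axis alignment, resampling, triage, trigger emulation.

The pipeline's conditioning stage mirrors what happens between the raw
mouthguard recording and feature extraction:

* the onboard *trigger* thresholds the raw Euclidean norm of the left
  accelerometer at 10 g and stores a window from 20 ms before the first
  crossing to 80 ms after the last (crossings closer than the 80 ms tail
  merge into one capture);
* every channel is rotated into the cardinal-axis frame using the per-device
  calibration matrices and resampled to a common 3,200 Hz with a polyphase
  filter (gyroscope upsampled from 800 Hz; jittered accelerometer rates
  corrected via a rational-ratio approximation);
* offline *triage* low-pass filters the left-accelerometer norm at 300 Hz
  with a causal second-order Butterworth filter and re-applies the 10 g
  threshold, discarding vocalisation and other high-frequency-only captures.

"Non-phase corrected" filtering is implemented as a single causal pass
(:func:`scipy.signal.lfilter`), i.e. *not* forward-backward zero-phase
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .capture_model import (
    SENSOR_IDS,
    CalibrationSet,
    Capture,
    SensorStream,
)

__all__ = [
    "TARGET_RATE_HZ",
    "TriageConfig",
    "TriggerConfig",
    "ProcessedCapture",
    "SIGNAL_NAMES",
    "align_axes",
    "resample_to_common_rate",
    "euclidean_norm",
    "butterworth_lowpass",
    "emulate_onboard_trigger",
    "process_capture",
    "triage_capture",
]

TARGET_RATE_HZ = 3200.0

#: Canonical order of the 12 aligned signals (sensor-major, x/y/z within).
SIGNAL_NAMES = tuple(f"{sid}_{ax}" for sid in SENSOR_IDS for ax in ("x", "y", "z"))


@dataclass(frozen=True)
class TriageConfig:
    """Offline triage filter: 300 Hz causal second-order Butterworth low-pass
    on the left-accelerometer norm, followed by a 10 g threshold."""

    cutoff_hz: float = 300.0
    filter_order: int = 2
    threshold_g: float = 10.0
    phase_corrected: bool = False


@dataclass(frozen=True)
class TriggerConfig:
    """Onboard capture trigger: raw left-accelerometer norm >= 10 g, with a
    20 ms lead-in before the first crossing and an 80 ms tail after the
    last."""

    threshold_g: float = 10.0
    lead_in_ms: float = 20.0
    tail_ms: float = 80.0


@dataclass
class ProcessedCapture:
    """A capture after alignment and resampling: 12 cardinal-frame channels
    at exactly 3,200 Hz plus the left-accelerometer norm and triage verdict."""

    capture_id: str
    signals: np.ndarray  # shape (12, n), ordered as SIGNAL_NAMES
    rate: float
    left_norm: np.ndarray  # raw (unfiltered) norm of the left accelerometer
    triage_passed: bool
    label: str = "unlabelled"
    sublabel: str = "none"
    session_id: str = ""

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def align_axes(c: Capture, cal: CalibrationSet) -> Capture:
    """Rotate every sensor's triaxial samples into the cardinal-axis frame.

    Each sensor's ``(3, n)`` block is left-multiplied by its calibration
    rotation.  Rotations preserve per-sample norms, which downstream triage
    relies on.
    """
    bad = cal.violations()
    if bad:
        raise ValueError("align_axes: invalid calibration: " + "; ".join(bad))
    missing = [sid for sid in c.streams if sid not in cal.matrices]
    if missing:
        raise ValueError(f"align_axes: calibration missing sensors {missing}")
    out = c.copy()
    for sid, s in out.streams.items():
        s.samples = cal.matrix(sid) @ s.samples
    return out


def resample_to_common_rate(
    s: SensorStream, target_rate: float = TARGET_RATE_HZ, max_denominator: int = 1000
) -> SensorStream:
    """Resample a stream to ``target_rate`` using polyphase filtering.

    The rate ratio is approximated by a rational number with denominator
    bounded by ``max_denominator`` and the stream passed through
    :func:`scipy.signal.resample_poly` (Kaiser-windowed polyphase filter).
    A stream already at the target rate passes through untouched.
    """
    if not np.all(np.isfinite(s.samples)):
        raise ValueError(f"{s.sensor_id}: non-finite samples cannot be resampled")
    if s.actual_rate <= 0:
        raise ValueError(f"{s.sensor_id}: actual_rate must be > 0")
    if s.actual_rate == target_rate:
        return s.copy()
    ratio = Fraction(target_rate / s.actual_rate).limit_denominator(max_denominator)
    up, down = ratio.numerator, ratio.denominator
    resampled = sps.resample_poly(s.samples, up, down, axis=1)
    return replace(s, samples=resampled, actual_rate=target_rate)


def euclidean_norm(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Element-wise Euclidean norm sqrt(x^2 + y^2 + z^2) of three channels."""
    x, y, z = (np.asarray(a, dtype=np.float64) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError(
            f"euclidean_norm: channel shapes differ: {x.shape}, {y.shape}, {z.shape}"
        )
    return np.sqrt(x * x + y * y + z * z)


def butterworth_lowpass(
    series: np.ndarray, rate: float, cfg: TriageConfig = TriageConfig()
) -> np.ndarray:
    """Low-pass filter a series with the triage Butterworth filter.

    Causal single-pass by default (``cfg.phase_corrected=False``); output has
    the same length as the input.
    """
    if cfg.cutoff_hz >= rate / 2:
        raise ValueError(
            f"butterworth_lowpass: cutoff {cfg.cutoff_hz} Hz >= Nyquist "
            f"{rate / 2} Hz"
        )
    b, a = sps.butter(cfg.filter_order, cfg.cutoff_hz, btype="low", fs=rate)
    series = np.asarray(series, dtype=np.float64)
    if cfg.phase_corrected:
        return sps.filtfilt(b, a, series, axis=-1)
    return sps.lfilter(b, a, series, axis=-1)


# ---------------------------------------------------------------------------
# Trigger emulation
# ---------------------------------------------------------------------------


def _trigger_groups(trigger_idx: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Group trigger sample indices: crossings separated by less than
    ``merge_gap`` samples belong to the same capture.  Returns (first, last)
    pairs."""
    groups: list[tuple[int, int]] = []
    start = prev = int(trigger_idx[0])
    for t in trigger_idx[1:]:
        t = int(t)
        if t - prev < merge_gap:
            prev = t
        else:
            groups.append((start, prev))
            start = prev = t
    groups.append((start, prev))
    return groups


def emulate_onboard_trigger(
    streams: Mapping[str, SensorStream],
    cfg: TriggerConfig = TriggerConfig(),
    capture_id_prefix: str = "capture",
    device_id: str = "device-0",
    session_id: str = "",
    label: str = "unlabelled",
    sublabel: str = "none",
) -> list[Capture]:
    """Emulate the mouthguard's onboard capture logic on continuous streams.

    Trigger samples are those where the *raw* left-accelerometer norm is at
    or above the threshold.  A capture spans ``[first - lead_in, last +
    tail]``; triggers separated by less than the tail merge into a single
    capture.  Windows are clipped to the stream bounds and every sensor is
    excerpted over the same time span (converted to its own sampling rate).
    Returns an empty list when the threshold is never reached.
    """
    if "left_acc" not in streams:
        raise ValueError("emulate_onboard_trigger: left_acc stream required")
    left = streams["left_acc"]
    norm = euclidean_norm(*left.samples)
    crossings = np.flatnonzero(norm >= cfg.threshold_g)
    if crossings.size == 0:
        return []
    rate = left.actual_rate
    lead = int(round(cfg.lead_in_ms * 1e-3 * rate))
    tail = int(round(cfg.tail_ms * 1e-3 * rate))
    captures = []
    for k, (first, last) in enumerate(_trigger_groups(crossings, tail)):
        start = max(first - lead, 0)
        stop = min(last + tail, left.n_samples)  # half-open [start, stop)
        windowed: dict[str, SensorStream] = {}
        for sid, s in streams.items():
            scale = s.actual_rate / rate
            s0 = max(int(round(start * scale)), 0)
            s1 = min(int(round(stop * scale)), s.n_samples)
            s1 = max(s1, s0 + 1)
            windowed[sid] = replace(s, samples=s.samples[:, s0:s1].copy())
        captures.append(
            Capture(
                capture_id=f"{capture_id_prefix}-{k:02d}",
                device_id=device_id,
                session_id=session_id,
                streams=windowed,
                trigger_index=first - start,
                lead_in_ms=cfg.lead_in_ms,
                tail_ms=cfg.tail_ms,
                label=label,
                sublabel=sublabel,
            )
        )
    return captures


# ---------------------------------------------------------------------------
# Full capture conditioning
# ---------------------------------------------------------------------------


def process_capture(
    c: Capture,
    cal: CalibrationSet | None = None,
    triage: TriageConfig = TriageConfig(),
) -> ProcessedCapture:
    """Align, resample to 3,200 Hz, compute the left norm and triage verdict.

    All 12 channels are trimmed to the shortest post-resampling length so the
    capture is a rectangular signal block.
    """
    aligned = align_axes(c, cal) if cal is not None else c
    resampled = {
        sid: resample_to_common_rate(s, TARGET_RATE_HZ)
        for sid, s in aligned.streams.items()
    }
    n = min(s.n_samples for s in resampled.values())
    block = np.vstack([resampled[sid].samples[:, :n] for sid in SENSOR_IDS])
    left = resampled["left_acc"].samples[:, :n]
    norm = euclidean_norm(*left)
    p = ProcessedCapture(
        capture_id=c.capture_id,
        signals=block,
        rate=TARGET_RATE_HZ,
        left_norm=norm,
        triage_passed=False,
        label=c.label,
        sublabel=c.sublabel,
        session_id=c.session_id,
    )
    p.triage_passed = triage_capture(p, triage)
    return p


def triage_capture(p: ProcessedCapture, cfg: TriageConfig = TriageConfig()) -> bool:
    """True iff the 300 Hz-low-passed left-accelerometer norm reaches the
    10 g triage threshold somewhere in the capture."""
    if p.rate != TARGET_RATE_HZ:
        raise ValueError("triage_capture: capture must be at 3,200 Hz")
    filtered = butterworth_lowpass(p.left_norm, p.rate, cfg)
    return bool(np.max(filtered) >= cfg.threshold_g)
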