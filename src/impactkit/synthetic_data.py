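"""Synthetic mouthguard capture corpora.

The study data behind this pipeline (proprietary match captures from an
instrumented mouthguard) are not public, so this module generates labelled
corpora with the statistical structure the pipeline assumes:

* **impact** ("hit") — an exponentially damped sinusoid on the linear
  channels, dominant frequency 20–150 Hz, with a kinematically coupled
  rotational pulse on the gyroscope;
* **chewing** — a train of low-frequency bursts plus a weak >300 Hz
  mouthguard-deformation ripple; passes triage, labelled non-hit;
* **yelling** — narrowband vocalisation above 300 Hz that can exceed the
  10 g trigger raw but falls below 10 g once low-passed at 300 Hz, so
  triage removes it;
* **handling** — irregular broadband spikes (mouthguard in hand), non-hit.

Each event is sampled per sensor at a jittered actual rate, clipped to the
sensor range and quantised to its bit depth (12-bit over ±200 g for the
accelerometers, 16-bit over ±2,000 dps for the gyroscope).  The onboard
trigger from :mod:`impactkit.preprocess` then windows the continuous streams
into captures (20 ms lead-in, 80 ms tail), exactly as the hardware would.

Reproducibility: one seed per corpus; each capture derives its own random
stream from ``(seed, capture_counter)`` via :class:`numpy.random.SeedSequence`,
so corpora are identical across runs regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .capture_model import (
    ACC_BIT_DEPTH,
    ACC_NOMINAL_RATE_HZ,
    ACC_RANGE_G,
    ACCELEROMETER_SENSORS,
    GYRO_BIT_DEPTH,
    GYRO_NOMINAL_RATE_HZ,
    GYRO_RANGE_DPS,
    CalibrationSet,
    Capture,
    SensorStream,
)
from .preprocess import TriggerConfig, emulate_onboard_trigger

__all__ = [
    "EVENT_CLASSES",
    "SimConfig",
    "EventTruth",
    "simulate_event",
    "simulate_capture",
    "generate_corpus",
    "random_rotation",
]

EVENT_CLASSES = ("impact", "chewing", "yelling", "handling")

#: sublabel assigned to each non-impact event class
_SUBLABEL = {
    "impact": "hit",
    "chewing": "chewing",
    "yelling": "yelling",
    "handling": "in_hand",
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic corpus.

    Defaults emulate the reference dataset: roughly a 10:1 non-hit:hit
    imbalance (hit fraction ~0.115), impact amplitudes 10–150 g with
    dominant frequency 20–150 Hz, ±1 % sampling-rate jitter, and a
    designated single-session holdout share.
    """

    n_captures: int = 1000
    hit_fraction: float = 0.115
    impact_amplitude_range: tuple[float, float] = (10.0, 150.0)
    impact_frequency_range: tuple[float, float] = (20.0, 150.0)
    artifact_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)  # chewing, yelling, handling
    rate_jitter: float = 0.01
    noise_sd: float = 0.2  # g (accelerometers); scaled for the gyro
    seed: int = 0
    duration_s: float = 0.35
    onset_s: float = 0.12
    gyro_coupling_dps_per_g: float = 8.0
    holdout_fraction: float = 0.1
    session_id: str = "session-1"
    holdout_session_id: str = "holdout-session"
    rotate_device_frame: bool = True

    def validate(self) -> None:
        if self.n_captures < 1:
            raise ValueError("n_captures must be >= 1")
        if not (0.0 < self.hit_fraction <= 1.0):
            raise ValueError("hit_fraction must be in (0, 1]")
        if abs(sum(self.artifact_mix) - 1.0) > 1e-12:
            raise ValueError("artifact_mix probabilities must sum to 1")
        for lo, hi in (self.impact_amplitude_range, self.impact_frequency_range):
            if not (0 < lo < hi):
                raise ValueError("ranges must be non-degenerate and positive")
        if self.rate_jitter < 0 or self.noise_sd < 0:
            raise ValueError("rate_jitter and noise_sd must be >= 0")


@dataclass
class EventTruth:
    """Ground truth describing one simulated event (for testing and triage
    audits, not visible to the classifier)."""

    event_class: str
    peak_linear_acc: float  # g
    dominant_freq: float  # Hz
    onset_time: float  # s

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.peak_linear_acc < 0 or self.dominant_freq <= 0:
            raise ValueError("peak_linear_acc >= 0 and dominant_freq > 0 required")


# ---------------------------------------------------------------------------
# Waveform primitives (continuous-time, evaluated at each sensor's clock)
# ---------------------------------------------------------------------------


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def _impact_waveform(t, truth: EventTruth):
    """Exponentially damped sinusoid; amplitude halves every two cycles so
    several oscillations survive the 300 Hz triage filter's settling time."""
    tau = np.maximum(t - truth.onset_time, 0.0)
    active = t >= truth.onset_time
    lam = truth.dominant_freq * math.log(2) / 2.0
    return np.where(
        active,
        truth.peak_linear_acc
        * np.exp(-lam * tau)
        * np.sin(2 * math.pi * truth.dominant_freq * tau),
        0.0,
    )


def _burst_train(t, truth: EventTruth, rng: np.random.Generator):
    """Chewing: 3–6 Hann-windowed low-frequency bursts."""
    n_bursts = int(rng.integers(3, 7))
    width = rng.uniform(0.06, 0.12)
    spacing = rng.uniform(0.3, 0.6) * width + width
    out = np.zeros_like(t)
    for k in range(n_bursts):
        centre = truth.onset_time + width / 2 + k * spacing
        phase = (t - centre) / width
        env = np.where(np.abs(phase) <= 0.5, np.cos(math.pi * phase) ** 2, 0.0)
        out += env * np.sin(2 * math.pi * truth.dominant_freq * (t - centre))
    return truth.peak_linear_acc * out


def _yell_waveform(t, truth: EventTruth, ripple: bool = False):
    """Narrowband >300 Hz vocalisation under a Hann envelope."""
    width = 0.15
    centre = truth.onset_time + width / 2
    phase = (t - centre) / width
    env = np.where(np.abs(phase) <= 0.5, np.cos(math.pi * phase) ** 2, 0.0)
    return truth.peak_linear_acc * env * np.sin(2 * math.pi * truth.dominant_freq * t)


def _spike_train(t, truth: EventTruth, rng: np.random.Generator):
    """Handling: 2–5 irregular half-sine spikes, a few ms wide."""
    n_spikes = int(rng.integers(2, 6))
    out = np.zeros_like(t)
    for k in range(n_spikes):
        width = rng.uniform(0.003, 0.006)
        centre = truth.onset_time + rng.uniform(0.0, 0.12)
        amp = truth.peak_linear_acc * rng.uniform(0.5, 1.0)
        phase = (t - centre) / width
        out += np.where(
            np.abs(phase) <= 0.5, amp * np.cos(math.pi * phase), 0.0
        ) * rng.choice([-1.0, 1.0])
    # guarantee the nominal peak appears at least once
    width = rng.uniform(0.003, 0.006)
    phase = (t - (truth.onset_time + 0.01)) / width
    out += np.where(np.abs(phase) <= 0.5, truth.peak_linear_acc * np.cos(math.pi * phase), 0.0)
    return out


def _quantize(x: np.ndarray, range_limit: float, bit_depth: int) -> np.ndarray:
    """Clip to the sensor range and snap to the ADC grid
    (step = range / 2**(bit_depth - 1))."""
    step = range_limit / (2 ** (bit_depth - 1))
    clipped = np.clip(x, -range_limit, range_limit)
    return np.round(clipped / step) * step


# ---------------------------------------------------------------------------
# Event and capture simulation
# ---------------------------------------------------------------------------


def draw_event_truth(
    event_class: str, cfg: SimConfig, rng: np.random.Generator
) -> EventTruth:
    """Draw the ground-truth parameters for one event of the given class."""
    if event_class == "impact":
        lo, hi = cfg.impact_amplitude_range
        flo, fhi = cfg.impact_frequency_range
        amp, freq = rng.uniform(lo, hi), rng.uniform(flo, fhi)
    elif event_class == "chewing":
        amp, freq = rng.uniform(11.0, 25.0), rng.uniform(25.0, 80.0)
    elif event_class == "yelling":
        # Raw peak above the 10 g trigger, but the rectified-envelope DC
        # (~0.64 x peak) stays under 10 g after the 300 Hz triage filter.
        amp, freq = rng.uniform(10.5, 13.0), rng.uniform(400.0, 700.0)
    elif event_class == "handling":
        amp, freq = rng.uniform(15.0, 60.0), rng.uniform(160.0, 330.0)
    else:
        raise ValueError(f"unknown event class {event_class!r}")
    return EventTruth(event_class, float(amp), float(freq), cfg.onset_s)


def simulate_event(
    truth: EventTruth, cfg: SimConfig, rng: np.random.Generator
) -> dict[str, SensorStream]:
    """Render one event as continuous streams for all four sensors.

    The source motion is a single 3-vector waveform along a random direction;
    the three accelerometers see it with mild position-dependent gain, the
    gyroscope sees a coupled rotational pulse (strong for impacts, weak for
    artifacts).  Channels are noise-corrupted, clipped and quantised.
    """
    cfg.validate()
    direction = _unit_vector(rng)
    gyro_axis = _unit_vector(rng)
    sensor_gain = {sid: rng.uniform(0.9, 1.1) for sid in ACCELEROMETER_SENSORS}

    # Rotational coupling: head impacts, chewing (jaw rotation) and
    # mouthguard handling (hand rotation) all drive the gyro at comparable
    # magnitude per g of linear signal; vocalisation barely does.
    if truth.event_class == "impact":
        scalar = _impact_waveform
        gyro_scale, ripple_amp = cfg.gyro_coupling_dps_per_g, 0.0
    elif truth.event_class == "chewing":
        scalar = lambda t, tr: _burst_train(t, tr, rng)
        gyro_scale, ripple_amp = 0.75 * cfg.gyro_coupling_dps_per_g, 0.15
    elif truth.event_class == "yelling":
        scalar = _yell_waveform
        gyro_scale, ripple_amp = 0.1, 0.0
    elif truth.event_class == "handling":
        scalar = lambda t, tr: _spike_train(t, tr, rng)
        gyro_scale, ripple_amp = cfg.gyro_coupling_dps_per_g, 0.0
    else:
        raise ValueError(f"unknown event class {truth.event_class!r}")

    # per-event deformation-ripple frequency (mouthguard resonance varies
    # with bite position)
    ripple_freq = rng.uniform(350.0, 600.0)
    streams: dict[str, SensorStream] = {}
    # Freeze the scalar waveform on a common fine clock so per-sensor
    # renderings are samplings of the same motion, not re-draws.
    jitter = lambda: 1.0 + rng.uniform(-cfg.rate_jitter, cfg.rate_jitter)
    for sid in ACCELEROMETER_SENSORS:
        rate = ACC_NOMINAL_RATE_HZ * jitter()
        n = int(round(cfg.duration_s * rate))
        t = np.arange(n) / rate
        w = scalar(t, truth) * sensor_gain[sid]
        if ripple_amp > 0:
            env = np.abs(w) / max(truth.peak_linear_acc, 1e-12)
            w = w + ripple_amp * truth.peak_linear_acc * env * np.sin(
                2 * math.pi * ripple_freq * t
            )
        xyz = direction[:, None] * w[None, :]
        if cfg.noise_sd > 0:
            xyz = xyz + rng.normal(0.0, cfg.noise_sd, size=xyz.shape)
        streams[sid] = SensorStream(
            sid,
            _quantize(xyz, ACC_RANGE_G, ACC_BIT_DEPTH),
            ACC_NOMINAL_RATE_HZ,
            rate,
            ACC_RANGE_G,
            ACC_BIT_DEPTH,
        )

    rate = GYRO_NOMINAL_RATE_HZ * jitter()
    n = int(round(cfg.duration_s * rate))
    t = np.arange(n) / rate
    w = scalar(t, truth) * gyro_scale
    xyz = gyro_axis[:, None] * w[None, :]
    if cfg.noise_sd > 0:
        xyz = xyz + rng.normal(0.0, cfg.noise_sd * 2.0, size=xyz.shape)
    streams["gyro"] = SensorStream(
        "gyro",
        _quantize(xyz, GYRO_RANGE_DPS, GYRO_BIT_DEPTH),
        GYRO_NOMINAL_RATE_HZ,
        rate,
        GYRO_RANGE_DPS,
        GYRO_BIT_DEPTH,
    )
    return streams


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def simulate_capture(
    truth: EventTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
    capture_id: str = "capture",
    device_id: str = "device-0",
    session_id: str = "",
    device_rotation: np.ndarray | None = None,
) -> Capture | None:
    """Render an event and window it through the onboard trigger.

    Returns the first triggered capture, or ``None`` if the event never
    crosses the 10 g threshold (the hardware would simply record nothing).
    If ``device_rotation`` is given, all channels are rotated *out of* the
    cardinal frame into the device frame; the inverse is what the
    calibration matrices later undo.
    """
    streams = simulate_event(truth, cfg, rng)
    if device_rotation is not None:
        for s in streams.values():
            s.samples = device_rotation.T @ s.samples
    captures = emulate_onboard_trigger(
        streams,
        TriggerConfig(),
        capture_id_prefix=capture_id,
        device_id=device_id,
        session_id=session_id,
        label="hit" if truth.event_class == "impact" else "non_hit",
        sublabel=_SUBLABEL[truth.event_class],
    )
    return captures[0] if captures else None


def generate_corpus(
    cfg: SimConfig,
) -> tuple[list[Capture], list[EventTruth], dict[str, CalibrationSet]]:
    """Generate a labelled corpus of triggered captures.

    Returns ``(captures, truths, calibrations)`` with one
    :class:`EventTruth` per capture and a per-device
    :class:`CalibrationSet` mapping the device frame back to cardinal axes.
    Sub-threshold draws are redrawn within the same event class so the class
    mix stays at the configured probabilities.  Fully reproducible from
    ``cfg.seed``.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    class_rng = np.random.default_rng(root.spawn(1)[0])
    device_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xD0)))
    rotation = random_rotation(device_rng) if cfg.rotate_device_frame else None
    device_id = "device-0"
    calibrations = {
        device_id: CalibrationSet(
            {sid: (rotation if rotation is not None else np.eye(3)).copy()
             for sid in ("left_acc", "centre_acc", "right_acc", "gyro")}
        )
    }

    artifact_classes = ("chewing", "yelling", "handling")
    n_holdout = int(round(cfg.holdout_fraction * cfg.n_captures))
    captures: list[Capture] = []
    truths: list[EventTruth] = []
    for i in range(cfg.n_captures):
        if class_rng.uniform() < cfg.hit_fraction:
            event_class = "impact"
        else:
            event_class = artifact_classes[
                class_rng.choice(3, p=np.asarray(cfg.artifact_mix))
            ]
        session = (
            cfg.holdout_session_id if i >= cfg.n_captures - n_holdout else cfg.session_id
        )
        cap = None
        for attempt in range(20):
            rng_i = np.random.default_rng(
                np.random.SeedSequence((cfg.seed, 1, i, attempt))
            )
            truth = draw_event_truth(event_class, cfg, rng_i)
            cap = simulate_capture(
                truth,
                cfg,
                rng_i,
                capture_id=f"sim-{i:05d}",
                device_id=device_id,
                session_id=session,
                device_rotation=rotation,
            )
            if cap is not None:
                break
        if cap is None:
            raise RuntimeError(
                f"event {i} ({event_class}) failed to trigger after 20 draws"
            )
        captures.append(cap)
        truths.append(truth)
    return captures, truths, calibrations
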