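"""Shared fixtures: small synthetic corpora and canned captures."""

from __future__ import annotations

import numpy as np
import pytest

import impactkit as ik
from impactkit.capture_model import (
    ACC_NOMINAL_RATE_HZ,
    GYRO_NOMINAL_RATE_HZ,
    Capture,
    accelerometer_stream,
    gyro_stream,
)


def make_capture(
    n_acc: int = 320,
    n_gyro: int = 80,
    amplitude: float = 0.0,
    capture_id: str = "cap-0",
    label: str = "unlabelled",
    sublabel: str = "none",
    seed: int = 0,
) -> Capture:
    """A structurally valid capture with optional white-noise content."""
    rng = np.random.default_rng(seed)
    streams = {
        sid: accelerometer_stream(sid, amplitude * rng.standard_normal((3, n_acc)))
        for sid in ("left_acc", "centre_acc", "right_acc")
    }
    streams["gyro"] = gyro_stream(amplitude * rng.standard_normal((3, n_gyro)))
    return Capture(
        capture_id=capture_id,
        device_id="dev-0",
        streams=streams,
        trigger_index=64,
        label=label,
        sublabel=sublabel,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A 150-capture corpus at the reference class mix (seeded)."""
    cfg = ik.SimConfig(n_captures=150, seed=42)
    captures, truths, calibrations = ik.generate_corpus(cfg)
    return cfg, captures, truths, calibrations


@pytest.fixture(scope="session")
def processed_corpus(small_corpus):
    cfg, captures, truths, calibrations = small_corpus
    cal = calibrations[captures[0].device_id]
    processed = [ik.process_capture(c, cal) for c in captures]
    return cfg, processed, truths


@pytest.fixture(scope="session")
def trained_toy_pipeline():
    """A small but fully trained pipeline run shared across model-level
    tests (500 captures, scaled search)."""
    from impactkit.pipeline import PipelineConfig, run_pipeline

    cfg = PipelineConfig.synthetic_study(seed=11, n_captures=500)
    return run_pipeline(cfg)
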