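"""Feature generation: random convolutional kernels and binned Welch PSD.

Two feature families are computed per aligned signal (12 signals: 3
accelerometers x 3 axes + 3 gyroscope axes):

* **kernel** — random convolutional kernels in the ROCKET style: length
  drawn from {7, 9, 11}, Gaussian weights mean-centred, bias uniform on
  [-1, 1], dyadic dilation bounded so the receptive field fits the capture,
  optional zero padding.  Each signal is z-scored to its own mean/SD, then
  per kernel two aggregates are emitted: the maximum of the convolution
  output and the proportion of positive values (ppv).
* **psd** — Welch power spectral density (reference configuration: 256-sample
  Hann segments, 50 % overlap, FFT zero-padded to 512 points so the 6.25 Hz
  grid populates every bin), averaged within 10-Hz bins spanning
  (10 Hz, Nyquist] — the DC bin is excluded — and natural-log transformed.
  At 3,200 Hz this yields 159 bins per signal, 1,908 across 12 signals.

All features are standardised to the mean and standard deviation of the
*training* rows only (population SD, zero-SD columns guarded by epsilon).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import SIGNAL_NAMES, TARGET_RATE_HZ, ProcessedCapture

__all__ = [
    "KernelSpec",
    "FeatureName",
    "FeatureConfig",
    "StandardizationModel",
    "generate_kernels",
    "apply_kernels",
    "welch_psd_features",
    "psd_bin_edges",
    "assemble_feature_matrix",
    "fit_standardizer",
    "apply_standardizer",
    "parse_feature_name",
]

logger = logging.getLogger(__name__)

_KERNEL_LENGTHS = (7, 9, 11)
_LOG_FLOOR = 1e-30
_ZSCORE_EPS = 1e-12


@dataclass(frozen=True)
class KernelSpec:
    """One random convolutional kernel (reproducible from (seed, kernel_id))."""

    kernel_id: int
    length: int
    weights: tuple[float, ...]
    bias: float
    dilation: int
    padding: bool
    seed: int

    def __post_init__(self):
        if len(self.weights) != self.length:
            raise ValueError("weights length must equal kernel length")


@dataclass(frozen=True)
class FeatureName:
    """Parsed feature column name.

    ``family`` is ``psd`` or ``kernel``; ``signal_id`` one of the 12 aligned
    signals.  For psd features ``detail`` is the bin's lower edge in Hz; for
    kernel features it is ``(kernel_id, stat)`` with stat ``max`` or ``ppv``.
    """

    family: str
    signal_id: str
    detail: object

    def __str__(self) -> str:
        if self.family == "psd":
            return f"psd|{self.signal_id}|{int(self.detail):04d}"
        kid, stat = self.detail
        return f"kernel|{self.signal_id}|k{kid:03d}|{stat}"


def parse_feature_name(name: str) -> FeatureName:
    parts = name.split("|")
    try:
        if parts[0] == "psd" and len(parts) == 3:
            return FeatureName("psd", parts[1], int(parts[2]))
        if parts[0] == "kernel" and len(parts) == 4 and parts[3] in ("max", "ppv"):
            return FeatureName("kernel", parts[1], (int(parts[2][1:]), parts[3]))
    except (ValueError, IndexError):
        pass
    raise ValueError(f"unparseable feature name: {name!r}")


@dataclass(frozen=True)
class FeatureConfig:
    """Reference feature-extraction configuration."""

    n_kernels: int = 300
    kernel_seed: int = 0
    bin_width_hz: float = 10.0
    welch_nperseg: int = 256
    welch_overlap: float = 0.5
    welch_nfft: int = 512
    kernel_input_length: int = 320

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Random convolutional kernels
# ---------------------------------------------------------------------------


def generate_kernels(
    n_kernels: int, seed: int, input_length: int = 320
) -> list[KernelSpec]:
    """Draw ``n_kernels`` random kernels, reproducibly from ``seed``.

    Weights ~ N(0,1) then mean-centred; bias ~ U[-1,1]; dilation ``2**a``
    with ``a`` uniform on [0, log2((input_length-1)/(length-1))] so the
    dilated receptive field fits an ``input_length``-sample capture; padding
    ~ Bernoulli(0.5).
    """
    if n_kernels < 1:
        raise ValueError("n_kernels must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF417)))
    kernels = []
    for kid in range(n_kernels):
        length = int(rng.choice(_KERNEL_LENGTHS))
        w = rng.standard_normal(length)
        w = w - w.mean()
        bias = float(rng.uniform(-1.0, 1.0))
        max_exp = math.log2((input_length - 1) / (length - 1))
        dilation = int(2 ** math.floor(rng.uniform(0.0, max_exp)))
        padding = bool(rng.integers(0, 2))
        kernels.append(
            KernelSpec(kid, length, tuple(w.tolist()), bias, dilation, padding, seed)
        )
    return kernels


def _zscore_rows(signals: np.ndarray) -> np.ndarray:
    mu = signals.mean(axis=-1, keepdims=True)
    sd = signals.std(axis=-1, keepdims=True)
    return (signals - mu) / np.maximum(sd, _ZSCORE_EPS)


def _convolve_batch(z: np.ndarray, k: KernelSpec) -> np.ndarray:
    """Dilated convolution with bias of a batch of z-scored signals.

    ``z`` has shape ``(m, n)``; returns ``(m, n_out)`` where ``n_out``
    depends on padding.  With padding the signal is zero-padded by
    ``(length-1)//2 * dilation`` on both sides (output length ~= input
    length); without, only fully supported positions are evaluated.
    """
    receptive = (k.length - 1) * k.dilation
    if k.padding:
        pad = ((k.length - 1) // 2) * k.dilation
        z = np.pad(z, ((0, 0), (pad, pad)))
    n = z.shape[-1]
    n_out = n - receptive
    if n_out < 1:
        # edge-clipped captures can be shorter than the kernel's receptive
        # field; zero-extend so the kernel has one valid position
        z = np.pad(z, ((0, 0), (0, receptive + 1 - n)))
        n_out = 1
    out = np.full(z.shape[:-1] + (n_out,), k.bias)
    for j, w in enumerate(k.weights):
        out += w * z[..., j * k.dilation : j * k.dilation + n_out]
    return out


def apply_kernels(
    signal: np.ndarray, kernels: Sequence[KernelSpec], zscore: bool = True
) -> np.ndarray:
    """Kernel aggregate features of one signal: ``[max_0, ppv_0, max_1, ...]``.

    The signal is z-scored to its own mean and SD (epsilon-guarded for
    constant signals) before convolution; per kernel the maximum output
    value and the proportion of outputs > 0 are returned.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1 or signal.size < 2:
        raise ValueError("apply_kernels: 1-D signal of length >= 2 required")
    if not np.all(np.isfinite(signal)):
        raise ValueError("apply_kernels: non-finite signal")
    z = _zscore_rows(signal[None, :]) if zscore else signal[None, :]
    out = np.empty(2 * len(kernels))
    for i, k in enumerate(kernels):
        conv = _convolve_batch(z, k)
        out[2 * i] = conv.max()
        out[2 * i + 1] = (conv > 0).mean()
    return out


# ---------------------------------------------------------------------------
# Binned Welch PSD
# ---------------------------------------------------------------------------


def psd_bin_edges(rate: float = TARGET_RATE_HZ, bin_width: float = 10.0) -> np.ndarray:
    """Bin edges spanning (bin_width, Nyquist]; the DC bin is excluded."""
    nyquist = rate / 2.0
    n_bins = int(math.floor(nyquist / bin_width)) - 1
    return bin_width * (1 + np.arange(n_bins + 1))


def welch_psd_features(
    signal: np.ndarray,
    rate: float = TARGET_RATE_HZ,
    bin_width: float = 10.0,
    nperseg: int = 256,
    overlap: float = 0.5,
    nfft: int = 512,
) -> np.ndarray:
    """Natural-log of the mean Welch PSD within each 10-Hz bin.

    Bins cover (10, Nyquist] Hz labelled by lower edge — 159 values per
    signal at 3,200 Hz.  Signals shorter than one Welch segment fall back to
    a single-segment periodogram (logged).
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("welch_psd_features: 1-D signal required")
    if signal.size < nperseg:
        logger.warning(
            "signal length %d < Welch segment %d; using single-segment periodogram",
            signal.size,
            nperseg,
        )
        nperseg = signal.size
    freqs, psd = sps.welch(
        signal,
        fs=rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        nfft=max(nfft, nperseg),
    )
    edges = psd_bin_edges(rate, bin_width)
    out = np.empty(len(edges) - 1)
    for i in range(len(edges) - 1):
        mask = (freqs > edges[i]) & (freqs <= edges[i + 1])
        mean_power = psd[mask].mean() if mask.any() else 0.0
        out[i] = math.log(max(mean_power, _LOG_FLOOR))
    return out


# ---------------------------------------------------------------------------
# Feature matrix assembly and standardisation
# ---------------------------------------------------------------------------


def feature_column_names(
    kernels: Sequence[KernelSpec], rate: float = TARGET_RATE_HZ, bin_width: float = 10.0
) -> list[str]:
    """Deterministic column order: all psd features (signal-major, ascending
    bin), then all kernel features (signal-major, kernel-major, max before
    ppv)."""
    edges = psd_bin_edges(rate, bin_width)
    names = [
        str(FeatureName("psd", sig, int(lo)))
        for sig in SIGNAL_NAMES
        for lo in edges[:-1]
    ]
    names += [
        str(FeatureName("kernel", sig, (k.kernel_id, stat)))
        for sig in SIGNAL_NAMES
        for k in kernels
        for stat in ("max", "ppv")
    ]
    return names


def assemble_feature_matrix(
    captures: Sequence[ProcessedCapture],
    kernels: Sequence[KernelSpec],
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Build the captures x features matrix for triage-passed captures.

    One shared kernel set is applied to every signal.  Kernel convolutions
    are vectorised across captures per (kernel, signal) pair; captures of
    unequal length are truncated to the shortest for the kernel family
    (PSD features use each capture's full signal).
    """
    captures = list(captures)
    if not captures:
        raise ValueError("assemble_feature_matrix: no captures")
    rates = {c.rate for c in captures}
    if rates != {TARGET_RATE_HZ}:
        raise ValueError(f"assemble_feature_matrix: mixed or wrong rates {rates}")
    not_triaged = [c.capture_id for c in captures if not c.triage_passed]
    if not_triaged:
        raise ValueError(
            f"assemble_feature_matrix: captures failed triage: {not_triaged[:5]}"
        )

    n_cap = len(captures)
    edges = psd_bin_edges(TARGET_RATE_HZ, config.bin_width_hz)
    n_psd = len(edges) - 1

    psd_block = np.empty((n_cap, len(SIGNAL_NAMES) * n_psd))
    for i, c in enumerate(captures):
        for j in range(len(SIGNAL_NAMES)):
            psd_block[i, j * n_psd : (j + 1) * n_psd] = welch_psd_features(
                c.signals[j],
                TARGET_RATE_HZ,
                config.bin_width_hz,
                config.welch_nperseg,
                config.welch_overlap,
                config.welch_nfft,
            )

    # kernel features: z-score once, then batch-convolve per (signal, kernel)
    n_min = min(c.n_samples for c in captures)
    stacked = np.stack([c.signals[:, :n_min] for c in captures])  # (cap, 12, n)
    z = _zscore_rows(stacked)
    n_kfeat = 2 * len(kernels)
    kernel_block = np.empty((n_cap, len(SIGNAL_NAMES) * n_kfeat))
    for j in range(len(SIGNAL_NAMES)):
        zj = z[:, j, :]
        for ki, k in enumerate(kernels):
            conv = _convolve_batch(zj, k)
            col = j * n_kfeat + 2 * ki
            kernel_block[:, col] = conv.max(axis=-1)
            kernel_block[:, col + 1] = (conv > 0).mean(axis=-1)

    matrix = pd.DataFrame(
        np.hstack([psd_block, kernel_block]),
        index=[c.capture_id for c in captures],
        columns=feature_column_names(kernels, TARGET_RATE_HZ, config.bin_width_hz),
    )
    matrix.attrs["config_hash"] = config.config_hash()
    if matrix.isna().any().any():
        raise AssertionError("feature matrix contains missing values")
    return matrix


@dataclass
class StandardizationModel:
    """Per-feature training-set mean/SD (population convention)."""

    mean: pd.Series
    sd: pd.Series
    epsilon: float = _ZSCORE_EPS


def fit_standardizer(
    m: pd.DataFrame, train_indices: Sequence[int]
) -> StandardizationModel:
    """Estimate per-column mean and population SD from the training rows only."""
    train_indices = np.asarray(train_indices)
    if train_indices.size < 2:
        raise ValueError("fit_standardizer: need >= 2 training rows")
    train = m.iloc[train_indices]
    return StandardizationModel(mean=train.mean(axis=0), sd=train.std(axis=0, ddof=0))


def apply_standardizer(model: StandardizationModel, m: pd.DataFrame) -> pd.DataFrame:
    """Transform to ``(x - mean) / max(sd, epsilon)`` per column.

    Columns with zero training SD map to all zeros.  Unknown columns raise.
    """
    unknown = [c for c in m.columns if c not in model.mean.index]
    if unknown:
        raise ValueError(f"apply_standardizer: unknown columns {unknown[:5]}")
    denom = model.sd.clip(lower=model.epsilon)
    out = (m - model.mean[m.columns]) / denom[m.columns]
    zero_sd = model.sd[m.columns] < model.epsilon
    if zero_sd.any():
        out.loc[:, zero_sd[zero_sd].index] = 0.0
    out.attrs = dict(m.attrs)
    return out
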