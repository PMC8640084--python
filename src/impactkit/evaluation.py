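"""Confusion-matrix metrics and bootstrap confidence intervals.

Metrics follow the usual binary-classification definitions with *hit* as the
positive class:

* ``TP% = 100 * tp / (tp + fn)`` (sensitivity as a percentage of true hits)
* ``TN% = 100 * tn / (tn + fp)``
* ``precision = tp / (tp + fp)``; ``F1`` the harmonic mean of precision and
  sensitivity; ``MCC`` the Matthews correlation coefficient.

Degenerate denominators (for example a subset with no positives) yield 0 and
set a flag rather than raising.  Confidence intervals are percentile
bootstrap: (truth, prediction) pairs resampled with replacement, uniformly,
10,000 times by default, interval at the 2.5/97.5 percentiles.

Reported tables print rates to two decimals using *truncation* (229/238 =
96.218... prints as 96.21); serialized reports retain full precision.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "METRIC_NAMES",
    "confusion_counts",
    "compute_metrics",
    "bootstrap_ci",
    "evaluate_model",
    "truncate2",
]

METRIC_NAMES = ("tp_pct", "tn_pct", "f1", "sensitivity", "precision", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name}: labels must be binary (0/1)")
    return a.astype(int)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Exact confusion counts with hit (1) as the positive class."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"confusion_counts: length mismatch {y_true.shape} vs {y_pred.shape}"
        )
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def compute_metrics(c: ConfusionCounts) -> dict:
    """All scalar metrics for one confusion table.

    Returns a mapping with the six metrics plus a ``degenerate`` list naming
    metrics whose denominator was zero (reported as 0 by convention).
    """
    degenerate: list[str] = []
    sens, d = _safe_div(c.tp, c.tp + c.fn)
    if d:
        degenerate.append("sensitivity")
    spec, d = _safe_div(c.tn, c.tn + c.fp)
    if d:
        degenerate.append("tn_pct")
    prec, d = _safe_div(c.tp, c.tp + c.fp)
    if d:
        degenerate.append("precision")
    f1, d = _safe_div(2 * prec * sens, prec + sens)
    if d:
        degenerate.append("f1")
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc, d = _safe_div(c.tp * c.tn - c.fp * c.fn, mcc_den)
    if d:
        degenerate.append("mcc")
    return {
        "tp_pct": 100.0 * sens,
        "tn_pct": 100.0 * spec,
        "f1": f1,
        "sensitivity": sens,
        "precision": prec,
        "mcc": mcc,
        "degenerate": sorted(set(degenerate) | ({"tp_pct"} if "sensitivity" in degenerate else set())),
    }


def truncate2(x: float) -> float:
    """Two-decimal truncation used for printed tables (96.218 -> 96.21)."""
    return math.floor(x * 100.0) / 100.0


# ---------------------------------------------------------------------------
# Vectorised metric kernels for the bootstrap
# ---------------------------------------------------------------------------


def _metrics_from_count_arrays(tp, tn, fp, fn) -> dict[str, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        spec = np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1), 0.0)
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        f1_den = prec + sens
        f1 = np.where(f1_den > 0, 2 * prec * sens / np.maximum(f1_den, 1e-300), 0.0)
        mcc_den = np.sqrt(
            (tp + fp).astype(float) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        mcc = np.where(mcc_den > 0, (tp * tn - fp * fn) / np.maximum(mcc_den, 1e-300), 0.0)
    return {
        "tp_pct": 100.0 * sens,
        "tn_pct": 100.0 * spec,
        "f1": f1,
        "sensitivity": sens,
        "precision": prec,
        "mcc": mcc,
    }


def bootstrap_ci(
    y_true,
    y_pred,
    metric: str = "tp_pct",
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    chunk: int = 1000,
) -> tuple[float, float]:
    """Percentile bootstrap CI for one metric.

    (truth, prediction) pairs are resampled with replacement, uniformly;
    the metric is evaluated on each resample (degenerate resamples use the
    0-convention) and the interval taken at the ``(1-level)/2`` and
    ``1-(1-level)/2`` percentiles.  Deterministic given ``seed``.
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    n = y_true.size
    if n < 1:
        raise ValueError("bootstrap_ci: need at least one observation")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB007)))
    # classify each pair once; a resample's counts are sums of pair types
    is_tp = (y_true == 1) & (y_pred == 1)
    is_tn = (y_true == 0) & (y_pred == 0)
    is_fp = (y_true == 0) & (y_pred == 1)
    vals = np.empty(n_boot)
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        tp = is_tp[idx].sum(axis=1)
        tn = is_tn[idx].sum(axis=1)
        fp = is_fp[idx].sum(axis=1)
        fn = n - tp - tn - fp
        vals[done : done + m] = _metrics_from_count_arrays(tp, tn, fp, fn)[metric]
        done += m
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Full evaluation report
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-subset metrics with bootstrap CIs.

    ``subsets`` maps subset name to a block::

        {"n_pos": int, "n_neg": int,
         "metrics": {name: {"point": x, "ci": [lo, hi]}},
         "flags": [...]}
    """

    subsets: dict
    n_boot: int
    ci_seed: int

    def to_dict(self) -> dict:
        return {"subsets": self.subsets, "n_boot": self.n_boot, "ci_seed": self.ci_seed}

    @classmethod
    def from_dict(cls, d: Mapping) -> "EvalReport":
        return cls(subsets=dict(d["subsets"]), n_boot=d["n_boot"], ci_seed=d["ci_seed"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EvalReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def point(self, subset: str, metric: str) -> float:
        return self.subsets[subset]["metrics"][metric]["point"]

    def ci(self, subset: str, metric: str) -> tuple[float, float]:
        lo, hi = self.subsets[subset]["metrics"][metric]["ci"]
        return lo, hi

    def format_table(self) -> str:
        """Text table of hits / non-hits / TP% / TN% / F1 with 95% CIs,
        two-decimal truncated."""
        lines = [
            f"{'Subset':<12}{'Hits':>8}{'Non-hits':>10}"
            f"{'TP% (95% CI)':>24}{'TN% (95% CI)':>24}{'F1 (95% CI)':>22}"
        ]
        for name, block in self.subsets.items():
            m = block["metrics"]

            def cell(metric, scale_f="{:.2f}"):
                p = truncate2(m[metric]["point"])
                lo, hi = m[metric]["ci"]
                return f"{p:.2f} ({truncate2(lo):.2f}-{truncate2(hi):.2f})"

            lines.append(
                f"{name:<12}{block['n_pos']:>8}{block['n_neg']:>10}"
                f"{cell('tp_pct'):>24}{cell('tn_pct'):>24}{cell('f1'):>22}"
            )
        return "\n".join(lines)


def evaluate_model(
    model,
    X: pd.DataFrame,
    bundle,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_metrics: Sequence[str] = METRIC_NAMES,
) -> EvalReport:
    """Score a fitted model on every bundle subset with bootstrap CIs.

    Subsets with no positives (the *rest* set by construction) report
    positive-class metrics as 0 with a flag.  Empty subsets are omitted
    with a warning.
    """
    blocks: dict[str, dict] = {}
    for name, idx in bundle.subsets.items():
        if idx.size == 0:
            warnings.warn(f"evaluate_model: subset {name!r} is empty; omitted")
            continue
        y_true = bundle.y[idx]
        y_pred = model.predict(X.iloc[idx].to_numpy())
        c = confusion_counts(y_true, y_pred)
        metrics = compute_metrics(c)
        flags = [f"no-{'positives' if c.positives == 0 else 'negatives'}"] if (
            c.positives == 0 or c.negatives == 0
        ) else []
        block = {
            "n_pos": c.positives,
            "n_neg": c.negatives,
            "counts": {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn},
            "metrics": {},
            "flags": flags + metrics["degenerate"],
        }
        for metric in METRIC_NAMES:
            entry = {"point": metrics[metric]}
            if metric in ci_metrics:
                entry["ci"] = list(
                    bootstrap_ci(y_true, y_pred, metric, n_boot=n_boot, seed=seed)
                )
            block["metrics"][metric] = entry
        blocks[name] = block
    return EvalReport(subsets=blocks, n_boot=n_boot, ci_seed=seed)
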