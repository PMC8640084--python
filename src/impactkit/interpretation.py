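"""Attribution of the tuned tree ensemble: ranking and grouped summaries.

Per-observation additive feature attributions are computed with the tree
ensemble's native TreeSHAP implementation (``Booster.predict(...,
pred_contribs=True)``), which guarantees additivity: per observation the
attributions plus the base value equal the model's margin output.  This
module owns only ranking (top-k by mean |attribution|), grouping by feature
family / sensor / frequency band, and serialization — the attribution
algorithm itself is the library's.

Positive attribution values indicate contribution toward the positive (hit)
label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost

from .capture_model import SENSOR_IDS
from .features import parse_feature_name

__all__ = [
    "AttributionSummary",
    "attribution_summary",
    "aggregate_attributions",
    "FREQ_BAND_SPLIT_HZ",
]

#: Split between the "low" and "high" spectral attribution bands.
FREQ_BAND_SPLIT_HZ = 150.0

GROUPINGS = ("family", "sensor", "frequency_band")


@dataclass
class AttributionSummary:
    """Per-feature attributions over one dataset.

    ``values`` holds the signed per-observation attribution matrix
    (observations x features); ``mean_abs`` its column-wise mean absolute
    value, sorted descending; ``top`` the first ``k`` of that ranking.
    """

    feature_names: list[str]
    values: np.ndarray
    base_values: np.ndarray
    mean_abs: pd.Series
    top: pd.Series
    k: int

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "top": {str(n): float(v) for n, v in self.top.items()},
            "mean_abs": {str(n): float(v) for n, v in self.mean_abs.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _booster_of(model) -> xgboost.Booster:
    inner = getattr(model, "model", model)  # unwrap TunedModel
    if isinstance(inner, xgboost.Booster):
        return inner
    if isinstance(inner, xgboost.XGBModel):
        return inner.get_booster()
    raise TypeError(
        "attribution_summary: model must be an XGBoost tree ensemble, "
        f"got {type(inner).__name__}"
    )


def attribution_summary(
    model, X: pd.DataFrame, indices: Sequence[int] | None = None, k: int = 50
) -> AttributionSummary:
    """Additive attributions of a tree ensemble over selected observations.

    ``indices`` are positional rows of ``X`` (default: all rows — the
    caller conventionally passes the validation subset).  Returns signed
    per-observation values, the mean-|attribution| ranking and its top
    ``k`` (the full ranking when ``k`` exceeds the feature count).
    """
    booster = _booster_of(model)
    rows = X if indices is None else X.iloc[np.asarray(indices)]
    if len(rows) == 0:
        raise ValueError("attribution_summary: no observations selected")
    dmat = xgboost.DMatrix(rows.to_numpy())
    contribs = booster.predict(dmat, pred_contribs=True)
    values, base = contribs[:, :-1], contribs[:, -1]
    mean_abs = (
        pd.Series(np.abs(values).mean(axis=0), index=list(X.columns))
        .sort_values(ascending=False, kind="mergesort")
    )
    return AttributionSummary(
        feature_names=list(X.columns),
        values=values,
        base_values=base,
        mean_abs=mean_abs,
        top=mean_abs.iloc[: min(k, len(mean_abs))],
        k=k,
    )


def _group_key(name: str, grouping: str) -> str | None:
    f = parse_feature_name(name)
    if grouping == "family":
        return f.family
    if grouping == "sensor":
        return f.signal_id.rsplit("_", 1)[0]
    if grouping == "frequency_band":
        if f.family != "psd":
            return None
        return (
            f"<{FREQ_BAND_SPLIT_HZ:.0f} Hz"
            if float(f.detail) < FREQ_BAND_SPLIT_HZ
            else f">={FREQ_BAND_SPLIT_HZ:.0f} Hz"
        )
    raise ValueError(f"unknown grouping {grouping!r}; choose from {GROUPINGS}")


def aggregate_attributions(s: AttributionSummary, grouping: str) -> pd.Series:
    """Sum of mean |attribution| per group, sorted descending.

    Groupings: ``family`` (psd vs kernel), ``sensor`` (the four physical
    sensors), ``frequency_band`` (psd features only, split at 150 Hz).
    Each feature belongs to exactly one group; group sums therefore add up
    to the total mass of their members.
    """
    keys = {}
    for name in s.mean_abs.index:
        key = _group_key(name, grouping)
        if key is not None:
            keys.setdefault(key, []).append(name)
    agg = pd.Series(
        {key: float(s.mean_abs[names].sum()) for key, names in keys.items()}
    )
    return agg.sort_values(ascending=False)
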