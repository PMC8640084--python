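"""Dataset construction, baseline classifier sweep and tuned gradient boosting.

Dataset construction mirrors the study design:

* the corpus is split into *Set 1* (all sessions but one) and a *holdout*
  set (every capture from one designated session, never used for training
  or selection);
* Set 1 is balanced by downsampling the non-hit majority to the hit
  minority with uniform pseudorandom sampling;
* the balanced set is split, stratified by class, into 70 % training /
  15 % validation / 15 % test;
* the *rest* set is the non-hit captures excluded by balancing — it probes
  real-world specificity under the natural ~10:1 imbalance.

Classifier selection fits a roster of untuned algorithms on the training
subset, scores TP% / TN% on the validation subset and picks the algorithm
with the highest mean of TP% and TN%, breaking ties by the smallest
|TP% - TN%| and then roster order.  The gradient-boosted tree ensemble
(XGBoost) is then tuned by randomized search (50 candidates, stratified
5-fold CV) maximising the Matthews correlation coefficient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint, uniform
from sklearn.base import clone
from sklearn.metrics import make_scorer, matthews_corrcoef
from sklearn.model_selection import (
    GridSearchCV,
    ParameterSampler,
    StratifiedKFold,
)
from xgboost import XGBClassifier

__all__ = [
    "DatasetBundle",
    "SweepResult",
    "TunedModel",
    "balance_by_downsampling",
    "split_dataset",
    "build_dataset_bundle",
    "default_roster",
    "baseline_sweep",
    "select_estimator",
    "tune_estimator",
    "DEFAULT_PARAM_SPACE",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Balancing and splitting
# ---------------------------------------------------------------------------


def balance_by_downsampling(labels: Sequence[int], seed: int) -> np.ndarray:
    """Balance a binary label vector by downsampling the majority class.

    Every minority-class index is retained; majority-class indices are
    sampled uniformly without replacement down to the minority count.
    Returns sorted positional indices of size ``2 * minority_count``.
    """
    y = np.asarray(labels).astype(int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("balance_by_downsampling: both classes must be present")
    minority, majority = (pos, neg) if pos.size <= neg.size else (neg, pos)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xBA1)))
    kept_majority = rng.choice(majority, size=minority.size, replace=False)
    return np.sort(np.concatenate([minority, kept_majority]))


@dataclass
class DatasetBundle:
    """Index sets (positions into the feature matrix / label vector) for the
    five evaluation subsets, plus the labels and split seed."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    rest: np.ndarray
    holdout: np.ndarray
    y: np.ndarray
    seed: int

    def subset(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def subsets(self) -> dict[str, np.ndarray]:
        return {
            "train": self.train,
            "validation": self.validation,
            "test": self.test,
            "rest": self.rest,
            "holdout": self.holdout,
        }


def split_dataset(
    balanced_indices: Sequence[int],
    labels: Sequence[int],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    rest_indices: Sequence[int] | None = None,
    holdout_indices: Sequence[int] | None = None,
) -> DatasetBundle:
    """Stratified train/validation/test split of the balanced indices.

    Per class, the training subset gets ``floor(train_fraction * n)``
    indices; the remainder is divided between validation and test with any
    odd index going to validation.  ``rest_indices`` (majority-class
    captures excluded by balancing) and ``holdout_indices`` (a held-out
    session) pass through into the bundle.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    balanced = np.asarray(balanced_indices)
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x59117)))
    train_parts, val_parts, test_parts = [], [], []
    for cls in (1, 0):
        cls_idx = balanced[y[balanced] == cls]
        n = cls_idx.size
        n_train = int(math.floor(fractions[0] * n))
        rem = n - n_train
        n_val = int(math.ceil(rem / 2)) if fractions[1] > 0 else 0
        n_val = min(n_val, rem)
        n_test = rem - n_val
        if fractions[1] > 0 and fractions[2] > 0 and (n_train == 0 or n_val == 0 or n_test == 0):
            raise ValueError(
                f"split_dataset: class {cls} too small ({n}) for three "
                "non-empty parts"
            )
        perm = rng.permutation(cls_idx)
        train_parts.append(perm[:n_train])
        val_parts.append(perm[n_train : n_train + n_val])
        test_parts.append(perm[n_train + n_val :])
    empty = np.array([], dtype=int)
    return DatasetBundle(
        train=np.sort(np.concatenate(train_parts)),
        validation=np.sort(np.concatenate(val_parts)),
        test=np.sort(np.concatenate(test_parts)),
        rest=np.sort(np.asarray(rest_indices)) if rest_indices is not None and len(rest_indices) else empty,
        holdout=np.sort(np.asarray(holdout_indices)) if holdout_indices is not None and len(holdout_indices) else empty,
        y=y,
        seed=seed,
    )


def build_dataset_bundle(
    labels: Sequence[int],
    session_ids: Sequence[str],
    holdout_session: str,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> DatasetBundle:
    """Full study-design bundle: session holdout, balancing, stratified split.

    The holdout is every capture whose session matches ``holdout_session``
    (never selected randomly); balancing and splitting operate on the
    remaining Set 1 captures.
    """
    y = np.asarray(labels).astype(int)
    sessions = np.asarray(session_ids)
    holdout = np.flatnonzero(sessions == holdout_session)
    set1 = np.flatnonzero(sessions != holdout_session)
    y_set1_mask = np.zeros(y.size, dtype=bool)
    y_set1_mask[set1] = True
    # balance within Set 1 only
    balanced_local = balance_by_downsampling(y[set1], seed)
    balanced = set1[balanced_local]
    rest = np.setdiff1d(set1[y[set1] == 0], balanced)
    return split_dataset(
        balanced, y, fractions, seed, rest_indices=rest, holdout_indices=holdout
    )


# ---------------------------------------------------------------------------
# Untuned baseline sweep and selection
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Per-algorithm untuned TP% / TN% on the evaluation subset."""

    table: pd.DataFrame  # index: algorithm, columns: tp_pct, tn_pct, diff, failed
    roster_order: tuple[str, ...]

    def successful(self) -> pd.DataFrame:
        return self.table[~self.table["failed"]]


def default_roster(seed: int = 0, compact: bool = True) -> list[tuple[str, object]]:
    """Classifier roster for the untuned sweep.

    ``compact=True`` (the pipeline default) is a representative fast subset;
    ``compact=False`` enumerates the bulk of the library's classifiers plus
    the gradient-boosted ensembles.  The roster is configurable because
    library inventories drift between releases.
    """
    from sklearn.discriminant_analysis import (
        LinearDiscriminantAnalysis,
        QuadraticDiscriminantAnalysis,
    )
    from sklearn.dummy import DummyClassifier
    from sklearn.ensemble import (
        AdaBoostClassifier,
        BaggingClassifier,
        ExtraTreesClassifier,
        GradientBoostingClassifier,
        HistGradientBoostingClassifier,
        RandomForestClassifier,
    )
    from sklearn.linear_model import (
        LogisticRegression,
        PassiveAggressiveClassifier,
        Perceptron,
        RidgeClassifier,
        SGDClassifier,
    )
    from sklearn.naive_bayes import BernoulliNB, GaussianNB
    from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
    from sklearn.svm import LinearSVC, SVC
    from sklearn.tree import DecisionTreeClassifier, ExtraTreeClassifier

    xgb = (
        "xgb_classifier",
        XGBClassifier(
            tree_method="hist", max_bin=64, n_jobs=1, random_state=seed,
            eval_metric="logloss",
        ),
    )
    compact_roster = [
        ("logistic_regression", LogisticRegression(max_iter=2000, random_state=seed)),
        ("ridge_classifier", RidgeClassifier(random_state=seed)),
        ("gaussian_nb", GaussianNB()),
        ("k_neighbors", KNeighborsClassifier()),
        ("decision_tree", DecisionTreeClassifier(random_state=seed)),
        ("random_forest", RandomForestClassifier(random_state=seed, n_jobs=1)),
        ("extra_trees", ExtraTreesClassifier(random_state=seed, n_jobs=1)),
        (
            "hist_gradient_boosting",
            HistGradientBoostingClassifier(random_state=seed),
        ),
        xgb,
    ]
    if compact:
        return compact_roster
    extra = [
        ("dummy", DummyClassifier(strategy="stratified", random_state=seed)),
        ("bernoulli_nb", BernoulliNB()),
        ("nearest_centroid", NearestCentroid()),
        ("perceptron", Perceptron(random_state=seed)),
        (
            "passive_aggressive",
            PassiveAggressiveClassifier(random_state=seed),
        ),
        ("sgd_classifier", SGDClassifier(random_state=seed)),
        ("linear_svc", LinearSVC(random_state=seed)),
        ("svc", SVC(random_state=seed)),
        ("linear_discriminant", LinearDiscriminantAnalysis()),
        ("quadratic_discriminant", QuadraticDiscriminantAnalysis()),
        ("extra_tree", ExtraTreeClassifier(random_state=seed)),
        ("adaboost", AdaBoostClassifier(random_state=seed)),
        ("bagging", BaggingClassifier(random_state=seed)),
        ("gradient_boosting", GradientBoostingClassifier(random_state=seed)),
    ]
    return compact_roster + extra


def _tp_tn_pct(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    pos = y_true == 1
    neg = y_true == 0
    tp_pct = 100.0 * np.mean(y_pred[pos] == 1) if pos.any() else 0.0
    tn_pct = 100.0 * np.mean(y_pred[neg] == 0) if neg.any() else 0.0
    return float(tp_pct), float(tn_pct)


def baseline_sweep(
    X: pd.DataFrame,
    bundle: DatasetBundle,
    roster: Sequence[tuple[str, object]],
    eval_subset: str = "validation",
) -> SweepResult:
    """Fit each untuned roster algorithm on the training subset and score
    TP% / TN% on ``eval_subset``.

    An algorithm that raises is recorded as a failed entry and the sweep
    continues.
    """
    if not roster:
        raise ValueError("baseline_sweep: empty roster")
    Xtr = X.iloc[bundle.train].to_numpy()
    ytr = bundle.y[bundle.train]
    ev = bundle.subset(eval_subset)
    Xev = X.iloc[ev].to_numpy()
    yev = bundle.y[ev]
    rows = []
    for name, est in roster:
        try:
            fitted = clone(est).fit(Xtr, ytr)
            tp, tn = _tp_tn_pct(yev, np.asarray(fitted.predict(Xev)).astype(int))
            rows.append((name, tp, tn, abs(tp - tn), False))
        except Exception as e:  # failure is data, not fatal
            logger.warning("baseline_sweep: %s failed: %s", name, e)
            rows.append((name, np.nan, np.nan, np.nan, True))
    table = pd.DataFrame(
        rows, columns=["algorithm", "tp_pct", "tn_pct", "diff", "failed"]
    ).set_index("algorithm")
    return SweepResult(table=table, roster_order=tuple(n for n, _ in roster))


def select_estimator(sweep: SweepResult) -> str:
    """Pick the algorithm with the highest mean of TP% and TN%; ties broken
    by smallest |TP% - TN%|, then roster order."""
    ok = sweep.successful()
    if ok.empty:
        raise ValueError("select_estimator: no successful sweep entries")
    order = {name: i for i, name in enumerate(sweep.roster_order)}
    ranked = sorted(
        ok.itertuples(),
        key=lambda r: (-(r.tp_pct + r.tn_pct) / 2.0, r.diff, order[r.Index]),
    )
    winner = ranked[0].Index
    logger.info("select_estimator: chose %s", winner)
    return winner


# ---------------------------------------------------------------------------
# Randomized hyperparameter tuning (MCC objective)
# ---------------------------------------------------------------------------

#: Declared search space for the gradient-boosted tree ensemble.
DEFAULT_PARAM_SPACE = {
    "n_estimators": randint(50, 1001),
    "max_depth": randint(2, 11),
    "learning_rate": loguniform(0.01, 0.3),
    "subsample": uniform(0.5, 0.5),
    "colsample_bytree": uniform(0.5, 0.5),
    "min_child_weight": randint(1, 11),
}


@dataclass
class TunedModel:
    """Tuned gradient-boosted tree ensemble with its search provenance."""

    algorithm_id: str
    params: dict
    model: XGBClassifier
    cv_mcc: float
    seed: int
    n_candidates: int
    folds: int

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.model.predict(np.asarray(X))).astype(int)


def tune_estimator(
    X: pd.DataFrame,
    bundle: DatasetBundle,
    n_candidates: int = 50,
    folds: int = 5,
    seed: int = 0,
    param_space: dict | None = None,
) -> TunedModel:
    """Randomized hyperparameter search for XGBoost maximising CV MCC.

    ``n_candidates`` random draws from the declared space are scored by
    stratified ``folds``-fold cross-validation on the training subset
    (``n_candidates * folds`` CV fits plus one refit on the full training
    subset).
    """
    Xtr = X.iloc[bundle.train].to_numpy()
    ytr = bundle.y[bundle.train]
    if np.unique(ytr).size < 2:
        raise ValueError("tune_estimator: training subset has a single class")
    counts = np.bincount(ytr)
    if counts.min() < folds:
        raise ValueError(
            f"tune_estimator: cannot stratify {folds} folds with class "
            f"counts {counts.tolist()}"
        )
    # max_bin=64: with a few hundred training rows and thousands of
    # features, split scanning is bin-bound; 64 quantile bins lose nothing
    # at this sample size.
    base = XGBClassifier(
        tree_method="hist", max_bin=64, n_jobs=1, random_state=seed,
        eval_metric="logloss",
    )
    # The first candidate is the library-default configuration, the rest are
    # random draws; the tuned model can therefore never score below the
    # untuned default on the same folds, and the fit count stays
    # n_candidates * folds (+1 refit).
    sampler = ParameterSampler(
        param_space or DEFAULT_PARAM_SPACE,
        n_iter=max(n_candidates - 1, 0),
        random_state=seed,
    )
    candidates: list[dict] = [{}] + list(sampler)
    search = GridSearchCV(
        base,
        param_grid=[{k: [v] for k, v in c.items()} for c in candidates],
        scoring=make_scorer(matthews_corrcoef),
        cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed),
        refit=True,
        n_jobs=1,
    )
    search.fit(Xtr, ytr)
    logger.info(
        "tune_estimator: %d candidates x %d folds = %d CV fits; best CV MCC %.4f",
        n_candidates,
        folds,
        n_candidates * folds,
        search.best_score_,
    )
    return TunedModel(
        algorithm_id="xgb_classifier",
        params={k: (v.item() if hasattr(v, "item") else v) for k, v in search.best_params_.items()},
        model=search.best_estimator_,
        cv_mcc=float(search.best_score_),
        seed=seed,
        n_candidates=n_candidates,
        folds=folds,
    )
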