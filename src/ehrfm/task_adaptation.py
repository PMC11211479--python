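"""Supervised task heads on top of frozen features.

Two feature routes feed the heads: a conventional count-based
featurization (per-code occurrence counts over the observation window
plus age and sex) for the boosted-tree baseline, and frozen
foundation-model representations for L2-regularized logistic probes.
Hyperparameters are always selected on the task validation fold by log
loss; test labels never influence any choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.preprocessing import StandardScaler

from .cohort_tasks import CohortExample
from .timeline_store import MINUTES_PER_DAY, PatientTimeline


@dataclass
class FeatureMatrix:
    ids: list[str]
    X: np.ndarray | sparse.spmatrix
    kind: str  # "count" | "fm"
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.ids):
            raise ValueError("row count does not match example ids")


class CountFeaturizer:
    """Code-count features over the pre-prediction-time history.

    The code space is frozen on the fitting fold (the task training set);
    codes first seen elsewhere are ignored.  Raw counts, no time binning,
    no ontology rollup; age at prediction time (days) and a sex indicator
    are appended as dense columns.
    """

    def __init__(self) -> None:
        self.codes: list[str] | None = None

    def fit(self, examples: Sequence[CohortExample], timelines: Sequence[PatientTimeline]):
        seen: set[str] = set()
        by_id = {tl.patient_id: tl for tl in timelines}
        for ex in examples:
            tl = by_id[ex.patient_id]
            for e in tl.events:
                if e.time < ex.prediction_time:
                    seen.add(e.code)
        self.codes = sorted(seen)
        return self

    def transform(
        self, examples: Sequence[CohortExample], timelines: Sequence[PatientTimeline]
    ) -> FeatureMatrix:
        if self.codes is None:
            raise RuntimeError("featurizer not fitted")
        col = {c: j for j, c in enumerate(self.codes)}
        by_id = {tl.patient_id: tl for tl in timelines}
        rows, cols, vals = [], [], []
        demo = np.zeros((len(examples), 2))
        ids = []
        for i, ex in enumerate(examples):
            tl = by_id[ex.patient_id]
            ids.append(f"{ex.patient_id}:{ex.task}:{ex.prediction_time}")
            for e in tl.events:
                if e.time >= ex.prediction_time:
                    continue  # features never see data at/after prediction time
                j = col.get(e.code)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    vals.append(1.0)
            demo[i, 0] = (ex.prediction_time - tl.birth_date) / MINUTES_PER_DAY
            demo[i, 1] = 1.0 if tl.sex == "M" else 0.0
        counts = sparse.coo_matrix(
            (vals, (rows, cols)), shape=(len(examples), len(self.codes))
        ).tocsr()
        X = sparse.hstack([counts, sparse.csr_matrix(demo)]).tocsr()
        names = list(self.codes) + ["age_days", "sex_male"]
        return FeatureMatrix(ids, X, "count", names)


def count_featurize(
    examples: Sequence[CohortExample],
    timelines: Sequence[PatientTimeline],
    fit_examples: Sequence[CohortExample] | None = None,
) -> FeatureMatrix:
    """Convenience wrapper: fit the code space on ``fit_examples``
    (default: ``examples`` themselves) and transform ``examples``."""
    fz = CountFeaturizer().fit(fit_examples if fit_examples is not None else examples, timelines)
    return fz.transform(examples, timelines)


# ---------------------------------------------------------------------------
# Heads


@dataclass
class FittedHead:
    kind: str  # "gbm" | "linear" | "constant"
    model: object
    hyperparameters: dict
    valid_log_loss: float
    flagged: str = ""


DEFAULT_GBM_GRID = tuple(
    {"learning_rate": lr, "num_leaves": nl, "boosting_type": bt}
    for lr in (0.1, 0.03)
    for nl in (15, 31)
    for bt in ("gbdt", "dart")
)

DEFAULT_C_GRID = (1e-2, 1e-1, 1.0, 10.0)


def _as_dense(X):
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def fit_gbm_head(
    X_train, y_train, X_valid, y_valid,
    grid: Sequence[dict] = DEFAULT_GBM_GRID,
    seed: int = 0,
    max_rounds: int = 500,
) -> FittedHead:
    """Gradient-boosted tree head with grid search on validation log loss.

    The boosting variant (standard vs dart) is part of the grid — the
    "optimization algorithm" axis.  Standard boosting uses early-stopped
    rounds up to ``max_rounds``; dart uses a fixed 100 rounds (it has no
    meaningful early stopping).
    """
    import lightgbm as lgb

    y_train = np.asarray(y_train, dtype=int)
    y_valid = np.asarray(y_valid, dtype=int)
    if len(y_train) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y_train)) < 2:
        rate = float(np.clip(y_train.mean(), 1e-6, 1 - 1e-6))
        return FittedHead("constant", rate, {}, float("nan"), flagged="single-class train")

    best = None
    for hp in grid:
        params = dict(
            objective="binary", verbosity=-1, seed=seed, deterministic=True,
            num_threads=1, min_child_samples=2, min_data_in_bin=1,
            learning_rate=hp["learning_rate"], num_leaves=hp["num_leaves"],
            boosting_type=hp["boosting_type"],
        )
        n_rounds = 100 if hp["boosting_type"] == "dart" else max_rounds
        callbacks = []
        valid_sets = None
        if hp["boosting_type"] != "dart" and len(np.unique(y_valid)) >= 2:
            valid_sets = [lgb.Dataset(_to_lgb(X_valid), label=y_valid)]
            callbacks = [lgb.early_stopping(25, verbose=False)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            booster = lgb.train(
                params, lgb.Dataset(_to_lgb(X_train), label=y_train),
                num_boost_round=n_rounds, valid_sets=valid_sets, callbacks=callbacks,
            )
        pv = np.clip(booster.predict(_to_lgb(X_valid)), 1e-12, 1 - 1e-12)
        vloss = log_loss(y_valid, pv, labels=[0, 1])
        if best is None or vloss < best[0]:
            best = (vloss, hp, booster)
    vloss, hp, booster = best
    return FittedHead("gbm", booster, dict(hp), float(vloss))


def _to_lgb(X):
    return X if sparse.issparse(X) else np.asarray(X, dtype=float)


def fit_linear_head(
    X_train, y_train, X_valid, y_valid,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
) -> FittedHead:
    """L2 logistic regression (lbfgs) probe tuned by validation log loss."""
    X_train = _as_dense(X_train)
    X_valid = _as_dense(X_valid)
    if not np.all(np.isfinite(X_train)) or not np.all(np.isfinite(X_valid)):
        raise ValueError("non-finite features")
    y_train = np.asarray(y_train, dtype=int)
    y_valid = np.asarray(y_valid, dtype=int)
    if len(y_train) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y_train)) < 2:
        rate = float(np.clip(y_train.mean(), 1e-6, 1 - 1e-6))
        return FittedHead("constant", rate, {}, float("nan"), flagged="single-class train")

    scaler = StandardScaler().fit(X_train)
    Xt, Xv = scaler.transform(X_train), scaler.transform(X_valid)
    best = None
    for C in c_grid:
        # default penalty is L2; spelled via C only to stay warning-free
        clf = LogisticRegression(
            C=C, solver="lbfgs", max_iter=2000, random_state=seed
        ).fit(Xt, y_train)
        pv = np.clip(clf.predict_proba(Xv)[:, 1], 1e-12, 1 - 1e-12)
        vloss = log_loss(y_valid, pv, labels=[0, 1])
        if best is None or vloss < best[0]:
            best = (vloss, C, clf)
    vloss, C, clf = best
    return FittedHead("linear", (scaler, clf), {"C": C}, float(vloss))


def predict_proba(head: FittedHead, X) -> np.ndarray:
    """Predicted event probability per row, in [0, 1]."""
    if head.kind == "constant":
        n = X.shape[0]
        return np.full(n, float(head.model))
    if head.kind == "gbm":
        p = head.model.predict(_to_lgb(X))
        return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    if head.kind == "linear":
        scaler, clf = head.model
        Xd = scaler.transform(_as_dense(X))
        if Xd.shape[1] != clf.coef_.shape[1]:
            raise ValueError("feature dimension mismatch")
        return clf.predict_proba(Xd)[:, 1]
    raise ValueError(f"unknown head kind {head.kind!r}")
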