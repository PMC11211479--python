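"""Evaluation metrics and bootstrap inference.

AUROC is the probability a random positive outranks a random negative
(ties counted one half), computed from rank statistics.  Calibration is
quantile-bin expected calibration error (ECE).  For heads trained on
class-balanced few-shot draws, predicted risks are first mapped back to
the deployment prevalence ``b'`` by the prior correction

    p' = p / (p + (1 - p) * (1 - b') / b')

which is the Bayes-odds adjustment from a balanced training prior to the
true outcome rate.  Model comparisons use a hierarchical bootstrap that
resamples tasks (outcomes) with replacement and then patients with
replacement within each resampled task; two-tailed p-values are twice
the smaller tail proportion of bootstrap differences around zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence
import warnings

import numpy as np
from scipy.stats import rankdata


class UndefinedMetricError(ValueError):
    """Metric is undefined (e.g. AUROC with a single class)."""


@dataclass
class PredictionSet:
    """Aligned predicted risks and binary labels for one (model, task)."""

    ids: Sequence[str]
    p: np.ndarray
    y: np.ndarray
    task: str = ""
    model: str = ""

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.p.shape != self.y.shape:
            raise ValueError("p and y length mismatch")
        if not np.all(np.isfinite(self.p)):
            raise ValueError("non-finite predicted risks")


def auroc(p: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney AUROC with ties counted half.

    Equals exhaustive positive–negative pair counting exactly (midranks
    distribute tied pairs evenly).
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes")
    r = rankdata(p)
    u = r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def prior_correct(p: np.ndarray | float, b_prime: float) -> np.ndarray | float:
    """Map balanced-prior risks back to outcome rate ``b_prime``.

    Fixed points at 0 and 1; the identity when ``b_prime`` is 0.5;
    strictly increasing in ``p``.
    """
    if not (0.0 < b_prime < 1.0):
        raise ValueError("outcome rate must be in (0, 1)")
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("predicted risks must be in [0, 1]")
    out = arr / (arr + (1.0 - arr) * (1.0 - b_prime) / b_prime)
    return float(out) if np.isscalar(p) else out


def ece_quantile(p: np.ndarray, y: np.ndarray, bins: int = 10) -> float:
    """Expected calibration error over predicted-risk quantile bins.

    Bins are formed from quantiles of ``p``; duplicate bin edges (heavily
    tied risks) are merged, and the fully degenerate single-bin case
    reduces to ``|mean(p) - prevalence|``.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(p)
    if n == 0:
        raise ValueError("empty prediction set")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, bins + 1)))
    if len(edges) <= 2:
        return float(abs(p.mean() - y.mean()))
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    total = 0.0
    for b in range(len(edges) - 1):
        mask = idx == b
        nb = int(mask.sum())
        if nb == 0:
            continue
        total += (nb / n) * abs(p[mask].mean() - y[mask].mean())
    return float(total)


def _metric_or_nan(fn: Callable, p: np.ndarray, y: np.ndarray) -> float:
    try:
        return fn(p, y)
    except UndefinedMetricError:
        return float("nan")


@dataclass
class ComparisonResult:
    """Model A − model B metric difference with hierarchical bootstrap CI."""

    metric: str
    per_task: dict[str, float]
    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    replicates: int

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "per_task": self.per_task,
            "mean_diff": self.mean_diff,
            "ci": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "replicates": self.replicates,
        }


def hierarchical_bootstrap_diff(
    preds_a: Mapping[str, PredictionSet],
    preds_b: Mapping[str, PredictionSet],
    metric: Callable[[np.ndarray, np.ndarray], float] = auroc,
    n_replicates: int = 1000,
    seed: int = 0,
    nesting: str = "tasks-patients",
    metric_name: str = "auroc",
) -> ComparisonResult:
    """Bootstrap the across-task mean metric difference between two models.

    Each replicate resamples tasks with replacement, then patients with
    replacement within each resampled task (the same patient draw is used
    for both models, preserving pairing).  With ``nesting="patients"``
    the task level is held fixed.  The two-tailed p-value is twice the
    smaller tail proportion of replicate differences relative to zero,
    with exact zeros counted half in each tail, capped at 1.
    """
    if n_replicates < 100:
        warnings.warn("fewer than 100 bootstrap replicates; CI will be unstable")
    tasks = sorted(preds_a)
    if set(preds_b) != set(tasks):
        raise ValueError("models evaluated on different task sets")
    for t in tasks:
        if len(preds_a[t].p) != len(preds_b[t].p):
            raise ValueError(f"task {t}: example sets differ between models")
    rng = np.random.default_rng(seed)

    per_task = {
        t: _metric_or_nan(metric, preds_a[t].p, preds_a[t].y)
        - _metric_or_nan(metric, preds_b[t].p, preds_b[t].y)
        for t in tasks
    }
    point = float(np.nanmean(list(per_task.values())))

    n_tasks = len(tasks)
    diffs = np.empty(n_replicates)
    for r in range(n_replicates):
        if nesting == "tasks-patients" and n_tasks > 1:
            chosen = [tasks[i] for i in rng.integers(0, n_tasks, size=n_tasks)]
        else:
            chosen = tasks
        vals = []
        for t in chosen:
            n = len(preds_a[t].p)
            idx = rng.integers(0, n, size=n)
            da = _metric_or_nan(metric, preds_a[t].p[idx], preds_a[t].y[idx])
            db = _metric_or_nan(metric, preds_b[t].p[idx], preds_b[t].y[idx])
            vals.append(da - db)
        finite = [v for v in vals if np.isfinite(v)]
        diffs[r] = float(np.mean(finite)) if finite else np.nan
    diffs = diffs[np.isfinite(diffs)]
    if len(diffs) == 0:
        raise UndefinedMetricError("all bootstrap replicates undefined")

    lo, hi = np.percentile(diffs, [2.5, 97.5])
    left = float(np.mean(diffs < 0) + 0.5 * np.mean(diffs == 0))
    right = float(np.mean(diffs > 0) + 0.5 * np.mean(diffs == 0))
    p_two = min(1.0, 2.0 * min(left, right))
    return ComparisonResult(
        metric=metric_name,
        per_task=per_task,
        mean_diff=point,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p_two,
        replicates=len(diffs),
    )
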