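"""Metrics: AUROC rank statistic, prior correction, quantile ECE, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrfm.eval_stats import (
    PredictionSet,
    UndefinedMetricError,
    auroc,
    ece_quantile,
    hierarchical_bootstrap_diff,
    prior_correct,
)


def brute_force_auroc(p, y):
    """O(n^2) positive-negative pair counting with half-credit ties."""
    p = np.asarray(p, float)
    pos = p[np.asarray(y) == 1]
    neg = p[np.asarray(y) == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def test_auroc_basics():
    assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert auroc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == 0.5
    assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75
    with pytest.raises(UndefinedMetricError):
        auroc([0.1, 0.2], [1, 1])


def test_auroc_equals_pair_counting_oracle():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n = int(rng.integers(4, 51))
        y = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
        if y.sum() in (0, n):
            continue
        p = np.round(rng.random(n), 2)  # coarse grid → plenty of ties
        assert abs(auroc(p, y) - brute_force_auroc(p, y)) < 1e-12


def test_prior_correct_closed_form_and_fixed_points():
    grid = np.linspace(0.05, 0.95, 10)
    for b in np.linspace(0.05, 0.95, 10):
        for p in grid:
            direct = p * b / (p * b + (1 - p) * (1 - b))
            assert abs(prior_correct(p, b) - direct) < 1e-12
    assert prior_correct(0.0, 0.2) == 0.0 and prior_correct(1.0, 0.2) == 1.0
    assert np.allclose(prior_correct(grid, 0.5), grid)
    assert abs(prior_correct(0.5, 0.1) - 0.1) < 1e-12
    assert abs(prior_correct(0.8, 0.25) - 0.2 / 0.35) < 1e-12
    with pytest.raises(ValueError):
        prior_correct(0.5, 0.0)


def test_prior_correct_strictly_increasing_and_invertible():
    p = np.linspace(0.01, 0.99, 50)
    out = prior_correct(p, 0.07)
    assert np.all(np.diff(out) > 0)
    # applying the correction backwards (swap the roles of the priors)
    back = out * 0.5 / 0.07 / (out * 0.5 / 0.07 + (1 - out) * 0.5 / 0.93)
    assert np.allclose(back, p, atol=1e-12)


def test_ece_worked_example_and_degenerate_cases():
    p = np.array([0.2, 0.2, 0.8, 0.8])
    y = np.array([0, 1, 1, 1])
    assert abs(ece_quantile(p, y, bins=2) - 0.25) < 1e-12
    # constant predictor at the prevalence is perfectly calibrated
    yy = (np.arange(100) < 30).astype(int)
    assert ece_quantile(np.full(100, 0.3), yy) == 0.0
    # perfect 0/1 predictions
    assert ece_quantile(yy.astype(float), yy) == 0.0
    # order invariance and boundedness
    rng = np.random.default_rng(1)
    pr = rng.random(200)
    yr = (rng.random(200) < 0.4).astype(int)
    perm = rng.permutation(200)
    assert abs(ece_quantile(pr, yr) - ece_quantile(pr[perm], yr[perm])) < 1e-12
    assert 0.0 <= ece_quantile(pr, yr) <= 1.0


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    p=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=40),
    b=st.floats(0.01, 0.99),
)
def test_prior_correct_properties(p, b):
    """Range-preserving, monotone, and exactly invertible."""
    arr = np.asarray(p)
    out = prior_correct(arr, b)
    assert np.all((out >= 0) & (out <= 1))
    order = np.argsort(arr)
    assert np.all(np.diff(out[order]) >= -1e-15)
    # undo: correct back toward a balanced prior
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = out / np.maximum(1 - out, 1e-300) * (1 - b) / b
        back = odds / (1 + odds)
    assert np.allclose(back, arr, atol=1e-9)


def _pred(ids, p, y, task=""):
    return PredictionSet(ids, np.asarray(p, float), np.asarray(y, int), task)


def test_bootstrap_identical_models_p_one():
    rng = np.random.default_rng(0)
    preds = {}
    for t in range(3):
        y = (rng.random(80) < 0.4).astype(int)
        p = np.clip(0.4 + 0.3 * y + rng.normal(0, 0.2, 80), 0, 1)
        preds[f"t{t}"] = _pred([str(i) for i in range(80)], p, y)
    r = hierarchical_bootstrap_diff(preds, preds, n_replicates=300, seed=1)
    assert r.mean_diff == 0.0 and r.p_value == 1.0
    assert r.ci_low <= 0.0 <= r.ci_high


def test_bootstrap_detects_large_gap():
    rng = np.random.default_rng(2)
    A, B = {}, {}
    for t in range(4):
        y = (rng.random(400) < 0.4).astype(int)
        sa = 1.2 * y + rng.normal(0, 1, 400)
        sb = rng.normal(0, 1, 400)
        ids = [str(i) for i in range(400)]
        A[f"t{t}"] = _pred(ids, 1 / (1 + np.exp(-sa)), y)
        B[f"t{t}"] = _pred(ids, 1 / (1 + np.exp(-sb)), y)
    r = hierarchical_bootstrap_diff(A, B, n_replicates=400, seed=3)
    assert r.mean_diff > 0.2 and r.p_value < 0.05
    assert r.ci_low <= r.mean_diff <= r.ci_high


def test_bootstrap_requires_matched_tasks():
    rng = np.random.default_rng(4)
    y = (rng.random(50) < 0.5).astype(int)
    ps = _pred([str(i) for i in range(50)], rng.random(50), y)
    with pytest.raises(ValueError):
        hierarchical_bootstrap_diff({"a": ps}, {"b": ps}, n_replicates=200)


def test_bootstrap_flat_nesting_variant_runs():
    rng = np.random.default_rng(5)
    y = (rng.random(120) < 0.3).astype(int)
    ids = [str(i) for i in range(120)]
    A = {"t": _pred(ids, np.clip(0.3 + 0.4 * y + rng.normal(0, 0.3, 120), 0, 1), y)}
    B = {"t": _pred(ids, np.clip(0.3 + 0.1 * y + rng.normal(0, 0.3, 120), 0, 1), y)}
    r1 = hierarchical_bootstrap_diff(A, B, n_replicates=300, seed=6, nesting="patients")
    r2 = hierarchical_bootstrap_diff(A, B, n_replicates=300, seed=6)
    # single task: the two nestings coincide
    assert r1.mean_diff == r2.mean_diff
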