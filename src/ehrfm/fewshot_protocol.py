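"""Label-efficiency (k-shot) experiment protocol.

For each task and each ``k`` in an ascending powers-of-two grid, draw
``k`` training examples with balanced classes — ``k/2`` positives and
``k/2`` negatives when enough positives exist; otherwise all ``k_p``
available positives plus negatives filling the draw to ``k`` total —
retrain the task head from scratch with the standard tuning procedure,
and evaluate on the untouched validation and test folds.  The validation
set is never subsampled.  Sampling, training, and evaluation are
repeated for a fixed number of iterations and averaged.

To keep pretraining from silently seeing few-shot task examples, the
protocol removes every task-training patient from the pretraining corpus
(:func:`exclude_task_patients_from_pretraining`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .eval_stats import UndefinedMetricError, auroc, ece_quantile, prior_correct

DEFAULT_K_GRID = (2, 4, 8, 16, 32, 64, 128, 256, 512, 1024)


@dataclass
class FewShotDesign:
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    iterations: int = 20
    seed: int = 0
    #: fill with negatives to total k when positives run short (the
    #: alternative reading fills to k/2 negatives only)
    total_fill: bool = True

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if any(b <= a for a, b in zip(self.k_grid, self.k_grid[1:])):
            raise ValueError("k grid must be ascending")


@dataclass
class FewShotDraw:
    k: int
    iteration: int
    indices: np.ndarray
    n_pos: int
    n_neg: int
    flagged: str = ""


def derive_seed(global_seed: int, *parts) -> int:
    """Deterministic per-cell seed from (task, k, iteration, ...)."""
    h = hashlib.sha256(repr((global_seed,) + parts).encode()).digest()
    return int.from_bytes(h[:4], "big") % (1 << 31)


def sample_few_shot(
    labels: np.ndarray,
    k: int,
    seed: int,
    iteration: int = 0,
    total_fill: bool = True,
) -> FewShotDraw:
    """Draw a balanced k-shot training set without replacement."""
    labels = np.asarray(labels, dtype=int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("pool must contain both classes")
    rng = np.random.default_rng(seed)
    flagged = ""
    if k >= len(labels):
        idx = np.arange(len(labels))
        flagged = "pool smaller than k; using the whole pool"
        return FewShotDraw(k, iteration, idx, len(pos), len(neg), flagged)
    half = k // 2
    n_pos = min(half, len(pos))
    n_neg = (k - n_pos) if (total_fill and n_pos < half) else k - half
    if n_neg > len(neg):
        n_neg = len(neg)
        flagged = "not enough negatives to fill the draw"
    take_pos = rng.choice(pos, size=n_pos, replace=False)
    take_neg = rng.choice(neg, size=n_neg, replace=False)
    idx = np.concatenate([take_pos, take_neg])
    return FewShotDraw(k, iteration, idx, n_pos, n_neg, flagged)


def exclude_task_patients_from_pretraining(
    corpus_patient_ids: Sequence[str], task_train_patient_ids: Sequence[str]
) -> list[str]:
    """Remove task-training patients from a pretraining corpus id list."""
    drop = set(task_train_patient_ids)
    return [p for p in corpus_patient_ids if p not in drop]


@dataclass
class FewShotCell:
    model: str
    task: str
    k: int
    auroc_mean: float
    ece_mean: float
    auroc_per_iter: list[float] = field(default_factory=list)
    ece_per_iter: list[float] = field(default_factory=list)
    n_missing: int = 0


def run_fewshot_experiment(
    arms: Mapping[str, dict],
    design: FewShotDesign,
) -> list[FewShotCell]:
    """Run the full (model × task × k × iteration) grid.

    ``arms`` maps a model name to per-task data:
    ``{task: {"X_train", "y_train", "X_valid", "y_valid", "X_test",
    "y_test", "fit": callable(X_tr, y_tr, X_va, y_va, seed) -> head,
    "predict": callable(head, X) -> p}}``.  ECE is computed on
    prior-corrected risks using the task training-pool outcome rate, the
    correction for balanced sampling.  Per-cell seeds derive
    deterministically from (seed, task, k, iteration).
    """
    cells: list[FewShotCell] = []
    for model_name, tasks in sorted(arms.items()):
        for task_name, d in sorted(tasks.items()):
            y_pool = np.asarray(d["y_train"], dtype=int)
            b_prime = float(np.clip(y_pool.mean(), 1e-6, 1 - 1e-6))
            for k in design.k_grid:
                aurocs, eces, missing = [], [], 0
                for it in range(design.iterations):
                    s = derive_seed(design.seed, task_name, k, it)
                    draw = sample_few_shot(
                        y_pool, k, s, iteration=it, total_fill=design.total_fill
                    )
                    idx = draw.indices
                    if len(np.unique(y_pool[idx])) < 2:
                        missing += 1
                        continue
                    head = d["fit"](
                        d["X_train"][idx], y_pool[idx], d["X_valid"], d["y_valid"], s
                    )
                    p_test = d["predict"](head, d["X_test"])
                    y_test = np.asarray(d["y_test"], dtype=int)
                    try:
                        aurocs.append(auroc(p_test, y_test))
                    except UndefinedMetricError:
                        missing += 1
                        continue
                    eces.append(ece_quantile(prior_correct(p_test, b_prime), y_test))
                cells.append(
                    FewShotCell(
                        model=model_name, task=task_name, k=k,
                        auroc_mean=float(np.mean(aurocs)) if aurocs else float("nan"),
                        ece_mean=float(np.mean(eces)) if eces else float("nan"),
                        auroc_per_iter=aurocs, ece_per_iter=eces, n_missing=missing,
                    )
                )
    return cells


def cells_to_frame(cells: Sequence[FewShotCell]):
    import pandas as pd

    rows = []
    for c in cells:
        for it, (a, e) in enumerate(zip(c.auroc_per_iter, c.ece_per_iter)):
            rows.append(
                {"model": c.model, "task": c.task, "k": c.k, "iteration": it,
                 "auroc": a, "ece_corrected": e}
            )
    return pd.DataFrame(rows, columns=["model", "task", "k", "iteration", "auroc", "ece_corrected"])
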