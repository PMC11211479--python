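"""End-to-end experiment orchestration on two-site synthetic data.

Three experiment families, mirroring a cross-hospital foundation-model
adaptability study at desk scale:

* **overall** — per-task AUROC/ECE of a count-featurized GBM, a locally
  pretrained foundation model (FM), the other site's FM used
  off-the-shelf, and the external FM after continued pretraining on the
  evaluation site; hierarchical-bootstrap comparisons between arms.
* **few-shot** — the balanced k-shot protocol with task-train patients
  excluded from continued pretraining.
* **subsample** — AUROC as a function of the pretraining patient
  fraction, continued pretraining vs pretraining from scratch.

A deliberate population split keeps a configurable fraction of patients
out of the supervised cohorts entirely (``cohort_fraction``): pretraining
corpora are larger than task cohorts, as in real hospital data, which
keeps the few-shot pretraining-exclusion rule from emptying the corpus.
Every pretraining corpus is drawn from global *train*-fold patients
only; :func:`audit_leakage` verifies that no test patient ever reaches a
pretraining corpus or tuning step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import synthetic_ehr as synth
from .cohort_tasks import (
    TASKS,
    CohortExample,
    SplitAssignment,
    build_inpatient_cohort,
    derive_task_splits,
    label_task,
    make_global_splits,
)
from .eval_stats import (
    ComparisonResult,
    PredictionSet,
    auroc,
    ece_quantile,
    hierarchical_bootstrap_diff,
)
from .fewshot_protocol import (
    FewShotDesign,
    cells_to_frame,
    exclude_task_patients_from_pretraining,
    run_fewshot_experiment,
)
from .fm_core import (
    FMCheckpoint,
    FMConfig,
    build_vocabulary,
    continue_pretrain,
    example_histories,
    extract_representations,
    pretrain,
)
from .task_adaptation import (
    DEFAULT_GBM_GRID,
    CountFeaturizer,
    fit_gbm_head,
    fit_linear_head,
    predict_proba,
)
from .timeline_store import PatientTimeline


@dataclass
class ExperimentPlan:
    seed: int = 0
    synth_config: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    fm_config: FMConfig = field(default_factory=FMConfig)
    vocab_size: int = 512
    #: fraction of patients eligible for supervised cohorts; the rest
    #: exist only in pretraining corpora
    cohort_fraction: float = 0.5
    subsample_fractions: tuple[float, ...] = (0.001, 0.01, 0.1, 0.4, 0.8)
    fewshot: FewShotDesign = field(default_factory=FewShotDesign)
    bootstrap_replicates: int = 1000
    gbm_grid: tuple = DEFAULT_GBM_GRID
    gbm_max_rounds: int = 150
    out_dir: str | None = None


def default_benchmark_plan(seed: int = 0) -> ExperimentPlan:
    """The default two-site synthetic benchmark (desk scale, one CPU)."""
    cfg = synth.SynthConfig(seed=seed)
    # the external provider site pretrains on a larger population than the
    # evaluation site, as with shared hospital foundation models
    cfg.sites[0].n_patients = 5000
    cfg.sites[1].n_patients = 2000
    fm = FMConfig(
        n_layers=2, hidden=64, n_heads=4, window=32, max_seq_len=48,
        batch_sequences=12, max_steps=300, patience=150, eval_every=25,
        lr_candidates=(1e-3,), val_chunk_budget=96, seed=seed,
    )
    return ExperimentPlan(
        seed=seed, synth_config=cfg, fm_config=fm,
        subsample_fractions=(0.05, 0.2, 0.8),
        fewshot=FewShotDesign(k_grid=(2, 4, 8, 16, 32, 64), iterations=5, seed=seed),
    )


# ---------------------------------------------------------------------------
# Site preparation


@dataclass
class SiteData:
    site_id: str
    timelines: list[PatientTimeline]
    split: SplitAssignment
    cohort_patients: set[str]
    examples: dict[str, list[CohortExample]]  # task -> all labeled examples
    folds: dict[str, dict[str, list[CohortExample]]]  # task -> fold -> examples
    pretrain_train: list[PatientTimeline]
    pretrain_valid: list[PatientTimeline]

    def by_id(self) -> dict[str, PatientTimeline]:
        return {tl.patient_id: tl for tl in self.timelines}


def prepare_site(plan: ExperimentPlan, site_id: str) -> SiteData:
    timelines = synth.generate_site_population(plan.synth_config, site_id)
    ids = sorted(tl.patient_id for tl in timelines)
    split = make_global_splits(ids, seed=plan.seed)
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 101]))
    n_cohort = int(round(plan.cohort_fraction * len(ids)))
    cohort_patients = set(rng.permutation(ids)[:n_cohort]) if n_cohort < len(ids) else set(ids)

    site_prof = plan.synth_config.site(site_id)
    cohort_tls = [tl for tl in timelines if tl.patient_id in cohort_patients]
    cohort = build_inpatient_cohort(cohort_tls, site_prof.min_age_days, seed=plan.seed)
    examples, folds = {}, {}
    for name, spec in TASKS.items():
        ex = label_task(cohort, spec, cohort_tls)
        examples[name] = ex
        folds[name] = derive_task_splits(ex, split)

    train_ids = set(split.patients("train"))
    valid_ids = set(split.patients("valid"))
    return SiteData(
        site_id=site_id,
        timelines=timelines,
        split=split,
        cohort_patients=cohort_patients,
        examples=examples,
        folds=folds,
        pretrain_train=[tl for tl in timelines if tl.patient_id in train_ids],
        pretrain_valid=[tl for tl in timelines if tl.patient_id in valid_ids],
    )


# ---------------------------------------------------------------------------
# Arm evaluation


def _rep_features(
    ckpt: FMCheckpoint, site: SiteData, fold_examples: Mapping[str, Sequence[CohortExample]]
) -> dict[str, np.ndarray]:
    """Frozen representations per fold, cached over (patient, time) pairs."""
    all_ex = [ex for fold in ("train", "valid", "test") for ex in fold_examples[fold]]
    keys = [(ex.patient_id, ex.prediction_time) for ex in all_ex]
    uniq = sorted(set(keys))
    pos = {k: i for i, k in enumerate(uniq)}
    proxy = [
        CohortExample(pid, 0, "", pt, 0) for pid, pt in uniq
    ]
    hists = example_histories(proxy, site.timelines, ckpt.vocab)
    reps = extract_representations(ckpt, hists)
    out = {}
    i = 0
    for fold in ("train", "valid", "test"):
        n = len(fold_examples[fold])
        rows = [pos[(ex.patient_id, ex.prediction_time)] for ex in fold_examples[fold]]
        out[fold] = reps[rows] if rows else np.zeros((0, reps.shape[1]))
        i += n
    return out


def evaluate_arms_on_site(
    plan: ExperimentPlan,
    site: SiteData,
    fm_arms: Mapping[str, FMCheckpoint],
    include_gbm: bool = True,
) -> tuple[pd.DataFrame, dict[str, dict[str, PredictionSet]]]:
    """Fit heads and score every arm on each task's test fold."""
    rows = []
    preds: dict[str, dict[str, PredictionSet]] = {name: {} for name in fm_arms}
    if include_gbm:
        preds["gbm"] = {}
    rep_cache = {name: {} for name in fm_arms}

    for task in sorted(TASKS):
        folds = site.folds[task]
        y = {f: np.array([ex.label for ex in folds[f]]) for f in ("train", "valid", "test")}
        if min(len(v) for v in y.values()) == 0 or any(
            len(np.unique(v)) < 2 for v in (y["train"], y["test"])
        ):
            continue  # task not evaluable at this scale

        if include_gbm:
            fz = CountFeaturizer().fit(folds["train"], site.timelines)
            Xc = {f: fz.transform(folds[f], site.timelines).X for f in ("train", "valid", "test")}
            head = fit_gbm_head(
                Xc["train"], y["train"], Xc["valid"], y["valid"],
                grid=plan.gbm_grid, seed=plan.seed, max_rounds=plan.gbm_max_rounds,
            )
            p = predict_proba(head, Xc["test"])
            preds["gbm"][task] = PredictionSet(
                [ex.patient_id for ex in folds["test"]], p, y["test"], task, "gbm"
            )

        for name, ckpt in fm_arms.items():
            reps = _rep_features(ckpt, site, folds)
            rep_cache[name][task] = reps
            head = fit_linear_head(
                reps["train"], y["train"], reps["valid"], y["valid"], seed=plan.seed
            )
            p = predict_proba(head, reps["test"])
            preds[name][task] = PredictionSet(
                [ex.patient_id for ex in folds["test"]], p, y["test"], task, name
            )

    for name, by_task in preds.items():
        for task, ps in by_task.items():
            rows.append(
                {
                    "site": site.site_id, "model": name, "task": task,
                    "auroc": auroc(ps.p, ps.y), "ece": ece_quantile(ps.p, ps.y),
                    "n_test": len(ps.y), "prevalence": float(ps.y.mean()),
                }
            )
    metrics = pd.DataFrame(
        rows, columns=["site", "model", "task", "auroc", "ece", "n_test", "prevalence"]
    ).sort_values(["site", "model", "task"]).reset_index(drop=True)
    return metrics, preds


# ---------------------------------------------------------------------------
# Experiment families


@dataclass
class OverallResult:
    metrics: pd.DataFrame
    comparisons: dict[str, ComparisonResult]
    preds: dict[str, dict[str, dict[str, PredictionSet]]]  # site -> arm -> task
    checkpoints: dict[str, FMCheckpoint]
    sites: dict[str, SiteData]


def train_base_checkpoints(
    plan: ExperimentPlan,
    site_a: SiteData,
    site_b: SiteData,
    include: tuple[str, ...] = ("fm_a", "fm_b", "fm_a_plus_b", "fm_b_plus_a"),
) -> dict[str, FMCheckpoint]:
    """From-scratch FMs per site plus both continued-pretraining arms."""
    cfg = plan.fm_config
    ckpts: dict[str, FMCheckpoint] = {}
    vocab_a = build_vocabulary(site_a.pretrain_train, plan.vocab_size)
    vocab_b = build_vocabulary(site_b.pretrain_train, plan.vocab_size)
    ckpts["fm_a"] = pretrain(
        site_a.pretrain_train, site_a.pretrain_valid, vocab_a, cfg, plan.seed, site="A"
    )
    ckpts["fm_b"] = pretrain(
        site_b.pretrain_train, site_b.pretrain_valid, vocab_b, cfg, plan.seed, site="B"
    )
    if "fm_a_plus_b" in include:
        ckpts["fm_a_plus_b"] = continue_pretrain(
            ckpts["fm_a"], site_b.pretrain_train, site_b.pretrain_valid, cfg, plan.seed, site="B"
        )
    if "fm_b_plus_a" in include:
        ckpts["fm_b_plus_a"] = continue_pretrain(
            ckpts["fm_b"], site_a.pretrain_train, site_a.pretrain_valid, cfg, plan.seed, site="A"
        )
    for name, ck in ckpts.items():
        ck.provenance["train_patient_ids"] = [
            tl.patient_id
            for tl in (site_a if name in ("fm_a", "fm_b_plus_a") else site_b).pretrain_train
        ]
    return ckpts


def run_overall_experiment(
    plan: ExperimentPlan, evaluate_sites: tuple[str, ...] = ("A", "B")
) -> OverallResult:
    site_a = prepare_site(plan, plan.synth_config.sites[0].site_id)
    site_b = prepare_site(plan, plan.synth_config.sites[1].site_id)
    include = ["fm_a", "fm_b"]
    if site_b.site_id in evaluate_sites or not evaluate_sites:
        include.append("fm_a_plus_b")
    if site_a.site_id in evaluate_sites or not evaluate_sites:
        include.append("fm_b_plus_a")
    ckpts = train_base_checkpoints(plan, site_a, site_b, include=tuple(include))

    all_metrics = []
    all_preds: dict[str, dict] = {}
    comparisons: dict[str, ComparisonResult] = {}
    site_map = {site_a.site_id: site_a, site_b.site_id: site_b}
    for sid in evaluate_sites:
        site = site_map[sid]
        if sid == site_a.site_id:
            arms = {
                "fm_local": ckpts["fm_a"],
                "fm_external": ckpts["fm_b"],
                "fm_external_continued": ckpts["fm_b_plus_a"],
            }
        else:
            arms = {
                "fm_local": ckpts["fm_b"],
                "fm_external": ckpts["fm_a"],
                "fm_external_continued": ckpts["fm_a_plus_b"],
            }
        metrics, preds = evaluate_arms_on_site(plan, site, arms)
        all_metrics.append(metrics)
        all_preds[sid] = preds
        common = [
            t for t in preds["gbm"]
            if all(t in preds[a] for a in ("fm_local", "fm_external", "fm_external_continued"))
        ]
        for arm in ("fm_local", "fm_external", "fm_external_continued"):
            for metric_fn, mname in ((auroc, "auroc"), (ece_quantile, "ece")):
                comparisons[f"{sid}:{arm}-vs-gbm:{mname}"] = hierarchical_bootstrap_diff(
                    {t: preds[arm][t] for t in common},
                    {t: preds["gbm"][t] for t in common},
                    metric=metric_fn, metric_name=mname,
                    n_replicates=plan.bootstrap_replicates, seed=plan.seed,
                )
        for arm in ("fm_external", "fm_external_continued"):
            comparisons[f"{sid}:{arm}-vs-fm_local:auroc"] = hierarchical_bootstrap_diff(
                {t: preds[arm][t] for t in common},
                {t: preds["fm_local"][t] for t in common},
                n_replicates=plan.bootstrap_replicates, seed=plan.seed,
            )
    return OverallResult(
        metrics=pd.concat(all_metrics, ignore_index=True) if all_metrics else pd.DataFrame(),
        comparisons=comparisons, preds=all_preds, checkpoints=ckpts,
        sites=site_map,
    )


def subsample_patients(
    timelines: Sequence[PatientTimeline], fraction: float, seed: int
) -> list[PatientTimeline]:
    """Seeded patient-level subsample (the unit of sample-efficiency claims)."""
    ids = sorted(tl.patient_id for tl in timelines)
    n = int(round(fraction * len(ids)))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    keep = set(rng.permutation(ids)[:n])
    return [tl for tl in timelines if tl.patient_id in keep]


def run_subsample_experiment(
    plan: ExperimentPlan,
    overall: OverallResult | None = None,
    eval_site: str | None = None,
    include_scratch: bool = True,
) -> pd.DataFrame:
    """AUROC-vs-pretraining-fraction curves, continued vs from-scratch."""
    if overall is None:
        overall = run_overall_experiment(plan, evaluate_sites=())
    eval_site = eval_site or plan.synth_config.sites[1].site_id
    site = overall.sites[eval_site]
    external = overall.checkpoints[
        "fm_a" if eval_site == plan.synth_config.sites[1].site_id else "fm_b"
    ]
    cfg = plan.fm_config
    rows = []
    for frac in plan.subsample_fractions:
        sub = subsample_patients(site.pretrain_train, frac, plan.seed)
        if len(sub) < 10:
            rows.append({"fraction": frac, "model": "skipped", "mean_auroc": np.nan,
                         "n_patients": len(sub)})
            continue
        arms: dict[str, FMCheckpoint] = {}
        cont = continue_pretrain(external, sub, site.pretrain_valid, cfg, plan.seed,
                                 site=eval_site)
        cont.provenance["train_patient_ids"] = [tl.patient_id for tl in sub]
        arms["continued"] = cont
        if include_scratch:
            vocab = build_vocabulary(sub, plan.vocab_size)
            scr = pretrain(sub, site.pretrain_valid, vocab, cfg, plan.seed, site=eval_site)
            scr.provenance["train_patient_ids"] = [tl.patient_id for tl in sub]
            arms["scratch"] = scr
        metrics, _ = evaluate_arms_on_site(plan, site, arms, include_gbm=False)
        for model in arms:
            m = metrics[metrics.model == model]
            rows.append({"fraction": frac, "model": model,
                         "mean_auroc": float(m.auroc.mean()), "n_patients": len(sub)})
    return pd.DataFrame(rows, columns=["fraction", "model", "mean_auroc", "n_patients"])


def run_fewshot_site(
    plan: ExperimentPlan,
    overall: OverallResult,
    eval_site: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Few-shot grid at one site: count-GBM vs external-FM probes.

    Continued pretraining for this experiment excludes every patient who
    contributes a task-training example, so pretraining never sees the
    task-train pool.
    """
    eval_site = eval_site or plan.synth_config.sites[1].site_id
    site = overall.sites[eval_site]
    external = overall.checkpoints[
        "fm_a" if eval_site == plan.synth_config.sites[1].site_id else "fm_b"
    ]
    task_train_patients = sorted(
        {ex.patient_id for task in site.folds for ex in site.folds[task]["train"]}
    )
    keep_ids = exclude_task_patients_from_pretraining(
        [tl.patient_id for tl in site.pretrain_train], task_train_patients
    )
    if not keep_ids:
        raise ValueError("pretraining corpus empty after task-train exclusion")
    keep = set(keep_ids)
    reduced = [tl for tl in site.pretrain_train if tl.patient_id in keep]
    continued = continue_pretrain(
        external, reduced, site.pretrain_valid, plan.fm_config, plan.seed, site=eval_site
    )
    continued.provenance["train_patient_ids"] = keep_ids
    continued.provenance["fewshot_exclusion"] = True

    fewshot_gbm_grid = tuple(
        {"learning_rate": 0.1, "num_leaves": 15, "boosting_type": bt}
        for bt in ("gbdt", "dart")
    )
    arms: dict[str, dict] = {"gbm": {}, "fm_external": {}, "fm_external_continued": {}}
    for task in sorted(TASKS):
        folds = site.folds[task]
        y = {f: np.array([ex.label for ex in folds[f]]) for f in ("train", "valid", "test")}
        if (
            min(len(v) for v in y.values()) == 0
            or y["train"].sum() == 0 or y["train"].sum() == len(y["train"])
            or len(np.unique(y["test"])) < 2
        ):
            continue
        fz = CountFeaturizer().fit(folds["train"], site.timelines)
        Xc = {f: fz.transform(folds[f], site.timelines).X for f in ("train", "valid", "test")}
        arms["gbm"][task] = {
            "X_train": Xc["train"], "y_train": y["train"],
            "X_valid": Xc["valid"], "y_valid": y["valid"],
            "X_test": Xc["test"], "y_test": y["test"],
            "fit": lambda Xt, yt, Xv, yv, s, _g=fewshot_gbm_grid: fit_gbm_head(
                Xt, yt, Xv, yv, grid=_g, seed=s, max_rounds=100
            ),
            "predict": predict_proba,
        }
        for arm_name, ckpt in (("fm_external", external), ("fm_external_continued", continued)):
            reps = _rep_features(ckpt, site, folds)
            arms[arm_name][task] = {
                "X_train": reps["train"], "y_train": y["train"],
                "X_valid": reps["valid"], "y_valid": y["valid"],
                "X_test": reps["test"], "y_test": y["test"],
                "fit": lambda Xt, yt, Xv, yv, s: fit_linear_head(Xt, yt, Xv, yv, seed=s),
                "predict": predict_proba,
            }
    cells = run_fewshot_experiment(arms, plan.fewshot)
    return cells_to_frame(cells), {"continued_checkpoint": continued, "cells": cells}


def run_benchmark_seed(seed: int, include_scratch: bool = False) -> dict:
    """One full pass of the default benchmark at a given seed.

    Evaluates the transfer direction A→B (external FM, continued
    pretraining, local FM, count-GBM on site B), the few-shot grid, and
    the continued-pretraining subsample curve.  Returns a summary dict
    with the across-task mean AUROCs, the few-shot table, the subsample
    curve, and the leakage-audit findings.
    """
    plan = default_benchmark_plan(seed)
    overall = run_overall_experiment(plan, evaluate_sites=("B",))
    means = (
        overall.metrics.groupby("model")[["auroc", "ece"]].mean().to_dict(orient="index")
    )
    fs, info = run_fewshot_site(plan, overall)
    fs_mean = fs.groupby(["model", "k"]).auroc.mean()
    sub = run_subsample_experiment(plan, overall, include_scratch=include_scratch)
    violations = audit_leakage(overall, [info["continued_checkpoint"]])
    return {
        "plan": plan,
        "overall": overall,
        "mean_metrics": means,
        "fewshot": fs,
        "fewshot_mean_auroc": {k: float(v) for k, v in fs_mean.items()},
        "subsample": sub,
        "violations": violations,
    }


# ---------------------------------------------------------------------------
# Leakage audit


def audit_leakage(overall: OverallResult, extra_checkpoints: Sequence[FMCheckpoint] = ()) -> list[str]:
    """Return a list of leakage violations (empty = clean).

    Checks that no test-fold patient of either site appears in any
    checkpoint's pretraining corpus, and that task folds are disjoint by
    patient and consistent with the global folds.
    """
    violations: list[str] = []
    test_ids = {
        sid: set(site.split.patients("test")) for sid, site in overall.sites.items()
    }
    all_test = set().union(*test_ids.values()) if test_ids else set()
    ckpts = list(overall.checkpoints.values()) + list(extra_checkpoints)
    for ck in ckpts:
        ids = set(ck.provenance.get("train_patient_ids", []))
        bad = ids & all_test
        if bad:
            violations.append(
                f"checkpoint {ck.provenance.get('kind')}@{ck.provenance.get('site')}: "
                f"{len(bad)} test patients in pretraining corpus"
            )
    for sid, site in overall.sites.items():
        for task, folds in site.folds.items():
            pats = {f: {ex.patient_id for ex in folds[f]} for f in folds}
            for f1, f2 in (("train", "valid"), ("train", "test"), ("valid", "test")):
                if pats[f1] & pats[f2]:
                    violations.append(f"{sid}/{task}: folds {f1} and {f2} share patients")
            for f in folds:
                glob = set(site.split.patients(f))
                if not pats[f] <= glob:
                    violations.append(f"{sid}/{task}: {f} examples outside global fold")
    return violations


# ---------------------------------------------------------------------------
# Reporting


def _render_plots(results_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fs_path = results_dir / "fewshot_results.csv"
    if fs_path.exists():
        df = pd.read_csv(fs_path)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for model, g in df.groupby("model"):
            curve = g.groupby("k").auroc.mean()
            ax.plot(curve.index, curve.values, marker="o", label=model)
        ax.set_xscale("log", base=2)
        ax.set_xlabel("training examples (k)")
        ax.set_ylabel("mean AUROC")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(results_dir / "fewshot_auroc.png", dpi=120)
        plt.close(fig)
    sub_path = results_dir / "subsample_results.csv"
    if sub_path.exists():
        df = pd.read_csv(sub_path)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for model, g in df.groupby("model"):
            g = g.dropna(subset=["mean_auroc"]).sort_values("fraction")
            if len(g):
                ax.plot(g.fraction, g.mean_auroc, marker="o", label=model)
        ax.set_xlabel("pretraining patient fraction")
        ax.set_ylabel("mean AUROC")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(results_dir / "subsample_auroc.png", dpi=120)
        plt.close(fig)


def report(results_dir: str | Path, plots: bool = False) -> str:
    """Render a deterministic markdown summary of saved result tables.

    ``plots=True`` additionally writes AUROC-vs-k and AUROC-vs-fraction
    figures next to the tables (the markdown itself stays byte-stable).
    """
    results_dir = Path(results_dir)
    if plots:
        _render_plots(results_dir)
    lines = ["# Experiment summary", ""]
    metrics_path = results_dir / "overall_metrics.csv"
    if metrics_path.exists():
        df = pd.read_csv(metrics_path)
        lines.append("## Overall per-task metrics")
        lines.append("")
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        means = df.groupby(["site", "model"])[["auroc", "ece"]].mean().reset_index()
        lines.append("## Across-task means")
        lines.append("")
        lines.append(means.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        lines.append("")
    comp_path = results_dir / "comparisons.json"
    if comp_path.exists():
        comps = json.loads(comp_path.read_text())
        lines.append("## Model comparisons (hierarchical bootstrap)")
        lines.append("")
        for key in sorted(comps):
            c = comps[key]
            lines.append(
                f"- {key}: diff {c['mean_diff']:+.4f} "
                f"[{c['ci'][0]:+.4f}, {c['ci'][1]:+.4f}], p = {c['p_value']:.4f}"
            )
        lines.append("")
    for name, title in (
        ("fewshot_results.csv", "Few-shot mean AUROC by k"),
        ("subsample_results.csv", "Pretraining-subsample curves"),
    ):
        p = results_dir / name
        if p.exists():
            df = pd.read_csv(p)
            lines.append(f"## {title}")
            lines.append("")
            if name.startswith("fewshot"):
                pivot = df.groupby(["model", "k"]).auroc.mean().reset_index()
                lines.append(pivot.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
            else:
                lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
            lines.append("")
    text = "\n".join(lines)
    (results_dir / "report.md").write_text(text)
    return text
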