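"""Pipeline integration at micro scale: determinism, consistency, audit."""

import json

import numpy as np
import pytest

from ehrfm import synthetic_ehr as synth
from ehrfm.experiments import (
    ExperimentPlan,
    audit_leakage,
    prepare_site,
    report,
    run_fewshot_site,
    run_overall_experiment,
    run_subsample_experiment,
)
from ehrfm.fewshot_protocol import FewShotDesign
from ehrfm.fm_core import FMConfig


def micro_plan(seed=0, fractions=(0.5, 1.0)):
    cfg = synth.SynthConfig(seed=seed)
    for s in cfg.sites:
        s.n_patients = 220
    fm = FMConfig(
        n_layers=1, hidden=16, n_heads=2, window=8, max_seq_len=24,
        batch_sequences=8, max_steps=60, patience=40, eval_every=20,
        lr_candidates=(3e-3,), val_chunk_budget=32, seed=seed,
    )
    return ExperimentPlan(
        seed=seed, synth_config=cfg, fm_config=fm, cohort_fraction=0.6,
        subsample_fractions=fractions,
        fewshot=FewShotDesign(k_grid=(2, 8), iterations=2, seed=seed),
        bootstrap_replicates=200, gbm_max_rounds=40,
    )


@pytest.fixture(scope="module")
def micro_run():
    plan = micro_plan()
    overall = run_overall_experiment(plan, evaluate_sites=("B",))
    return plan, overall


def test_overall_produces_metrics_for_every_arm(micro_run):
    plan, overall = micro_run
    models = set(overall.metrics.model)
    assert models == {"gbm", "fm_local", "fm_external", "fm_external_continued"}
    assert overall.metrics.auroc.between(0, 1).all()
    assert overall.metrics.ece.between(0, 1).all()
    for key, c in overall.comparisons.items():
        assert 0 <= c.p_value <= 1
        assert c.ci_low <= c.ci_high


def test_pipeline_is_deterministic(micro_run):
    plan, overall = micro_run
    again = run_overall_experiment(micro_plan(), evaluate_sites=("B",))
    assert overall.metrics.equals(again.metrics)
    for k in overall.comparisons:
        assert overall.comparisons[k].mean_diff == again.comparisons[k].mean_diff
        assert overall.comparisons[k].p_value == again.comparisons[k].p_value


def test_subsample_full_fraction_matches_local_fm(micro_run):
    plan, overall = micro_run
    sub = run_subsample_experiment(plan, overall, include_scratch=True)
    full_scratch = sub[(sub.model == "scratch") & (sub.fraction == 1.0)]
    local = overall.metrics[overall.metrics.model == "fm_local"]
    assert np.isclose(float(full_scratch.mean_auroc.iloc[0]), float(local.auroc.mean()))


def test_fewshot_and_leakage_audit(micro_run):
    plan, overall = micro_run
    fs, info = run_fewshot_site(plan, overall)
    assert set(fs.columns) == {"model", "task", "k", "iteration", "auroc", "ece_corrected"}
    assert fs.k.isin(plan.fewshot.k_grid).all()
    violations = audit_leakage(overall, [info["continued_checkpoint"]])
    assert violations == []
    # the few-shot continuation corpus excludes task-train patients
    excl = set(info["continued_checkpoint"].provenance["train_patient_ids"])
    site = overall.sites["B"]
    task_train = {ex.patient_id for t in site.folds for ex in site.folds[t]["train"]}
    assert not excl & task_train


def test_audit_catches_planted_leak(micro_run):
    plan, overall = micro_run
    ck = overall.checkpoints["fm_b"]
    tainted = list(ck.provenance["train_patient_ids"])
    ck_backup = tainted.copy()
    test_patient = overall.sites["B"].split.patients("test")[0]
    ck.provenance["train_patient_ids"] = tainted + [test_patient]
    try:
        assert audit_leakage(overall) != []
    finally:
        ck.provenance["train_patient_ids"] = ck_backup


def test_report_renders_deterministically(tmp_path, micro_run):
    plan, overall = micro_run
    overall.metrics.to_csv(tmp_path / "overall_metrics.csv", index=False)
    (tmp_path / "comparisons.json").write_text(
        json.dumps({k: c.to_dict() for k, c in overall.comparisons.items()}, sort_keys=True)
    )
    r1 = report(tmp_path)
    r2 = report(tmp_path)
    assert r1 == r2
    assert "Across-task means" in r1
    empty = tmp_path / "empty"
    empty.mkdir()
    assert "# Experiment summary" in report(empty)


def test_report_optional_plots(tmp_path):
    import pandas as pd

    pd.DataFrame(
        {"model": ["gbm", "gbm", "fm", "fm"], "task": ["t"] * 4,
         "k": [2, 4, 2, 4], "iteration": [0] * 4,
         "auroc": [0.5, 0.55, 0.6, 0.7], "ece_corrected": [0.1] * 4}
    ).to_csv(tmp_path / "fewshot_results.csv", index=False)
    report(tmp_path, plots=True)
    assert (tmp_path / "fewshot_auroc.png").stat().st_size > 0


def test_prepare_site_pretraining_only_from_train_fold():
    plan = micro_plan(seed=3, fractions=(0.5,))
    site = prepare_site(plan, "A")
    train_ids = set(site.split.patients("train"))
    assert {tl.patient_id for tl in site.pretrain_train} <= train_ids
    valid_ids = set(site.split.patients("valid"))
    assert {tl.patient_id for tl in site.pretrain_valid} <= valid_ids
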