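"""Synthetic two-site generator: determinism, shift, and closed forms."""

import numpy as np
import pytest

from ehrfm import synthetic_ehr as S
from ehrfm.cohort_tasks import TASKS, build_inpatient_cohort, label_task


@pytest.fixture(scope="module")
def small_config():
    cfg = S.SynthConfig(seed=21)
    for s in cfg.sites:
        s.n_patients = 300
    return cfg


def test_same_seed_identical_population(small_config):
    a1 = S.generate_site_population(small_config, "A")
    a2 = S.generate_site_population(small_config, "A")
    assert len(a1) == len(a2)
    for x, y in zip(a1, a2):
        assert x.patient_id == y.patient_id and x.birth_date == y.birth_date
        assert [(e.code, e.time, e.value) for e in x.events] == [
            (e.code, e.time, e.value) for e in y.events
        ]


def test_single_state_zero_death_hazard_means_no_mortality():
    cfg = S.SynthConfig(seed=5)
    lat = cfg.latent
    lat.n_states = 1
    lat.transition = np.array([[1.0]])
    lat.discharge_hazard = np.array([0.4])
    lat.death_hazard = np.array([0.0])
    lat.event_rate = np.array([3.0])
    lat.lab_measure_prob = lat.lab_measure_prob[:1]
    lat.lab_mean = lat.lab_mean[:1]
    lat.lab_sd = lat.lab_sd[:1]
    lat.readmission_prob = np.array([0.05])
    for s in cfg.sites:
        s.n_patients = 200
        s.initial_dist = np.array([1.0])
    tls = S.generate_site_population(cfg, "A")
    assert all(a.death_time is None for t in tls for a in t.admissions)
    assert S.analytic_prevalences(cfg, "A")["mortality"] == 0.0


def test_invalid_probability_vector_rejected():
    cfg = S.SynthConfig()
    cfg.sites[0].initial_dist = np.array([0.5, 0.5, 0.5, 0.5])
    with pytest.raises(S.ConfigError):
        cfg.validate()


def test_every_patient_has_an_admission(small_config):
    tls = S.generate_site_population(small_config, "B")
    assert all(len(t.admissions) >= 1 for t in tls)


def test_learnability_entropy_gap(small_config):
    """Next-code conditional entropy given the latent state is strictly
    below the unigram entropy — pretraining has signal by construction."""
    for site in ("A", "B"):
        h_uni, h_cond = S.code_entropies(small_config, site)
        assert h_cond < h_uni - 0.1


def test_site_shift_tv_distance_and_overlap(small_config):
    mA = S.site_marginal(small_config, "A")
    mB = S.site_marginal(small_config, "B")
    assert S.total_variation(mA, mB) > 0.1
    shared = set(mA) & set(mB)
    assert len(shared) / len(mA) >= 0.8
    # two identical profiles give identical marginals
    assert S.total_variation(mA, mA) == 0.0


def test_analytic_prevalence_tracks_empirical(small_config):
    """Per-admission label rates agree with the Markov closed forms
    (loose 3-sigma screen at module scale; the tight binomial-interval
    check over >=5000 admissions runs in the acceptance suite)."""
    tls = S.generate_site_population(small_config, "A")
    ana = S.analytic_prevalences(small_config, "A")
    cohort = build_inpatient_cohort(tls, 0.0, seed=0, one_per_patient=False)
    for name in ("mortality", "long_los", "hypoglycemia"):
        ex = label_task(cohort, TASKS[name], tls)
        emp = np.mean([e.label for e in ex])
        sd = np.sqrt(ana[name] * (1 - ana[name]) / len(ex))
        assert abs(emp - ana[name]) < 3.5 * sd + 1e-9


def test_summarize_corpus(small_config):
    tls = S.generate_site_population(small_config, "A")
    summary = S.summarize_corpus(tls)
    site = summary["sites"]["A"]
    assert site["n_patients"] == 300
    marg = site["code_marginal"]
    assert abs(sum(marg.values()) - 1.0) < 1e-9
    assert site["events_per_patient"] > 10
    # single-patient, single-code corpus has a degenerate marginal
    from ehrfm.timeline_store import CodedEvent, PatientTimeline

    one = PatientTimeline(
        "q", 0, "F", "Z", events=[CodedEvent("DX/1", t * 1440) for t in range(1, 4)]
    )
    s2 = S.summarize_corpus([one])
    assert s2["sites"]["Z"]["code_marginal"] == {"DX/1": 1.0}


def test_yaml_config_roundtrip(small_config):
    text = S.config_to_yaml(small_config)
    back = S.config_from_yaml(text)
    assert back.seed == small_config.seed
    assert [s.site_id for s in back.sites] == ["A", "B"]
    assert np.allclose(back.latent.transition, small_config.latent.transition)
    assert back.sites[1].reverse_semantics is True
    tls1 = S.generate_site_population(small_config, "A")
    tls2 = S.generate_site_population(back, "A")
    assert [t.patient_id for t in tls1] == [t.patient_id for t in tls2]
    assert sum(len(t.events) for t in tls1) == sum(len(t.events) for t in tls2)
    with pytest.raises(S.ConfigError):
        S.config_from_yaml(text.replace("freq_tilt", "freq_wibble"))


def test_markov_corpus_entropies_closed_form():
    P = np.array([[0.9, 0.1], [0.2, 0.8]])
    pi = S.markov_stationary(P)
    h1, hc = S.markov_entropies(P)
    # stationary distribution of this chain is (2/3, 1/3)
    assert np.allclose(pi, [2 / 3, 1 / 3])
    expect_h1 = -(2 / 3 * np.log(2 / 3) + 1 / 3 * np.log(1 / 3))
    expect_hc = 2 / 3 * -(0.9 * np.log(0.9) + 0.1 * np.log(0.1)) + 1 / 3 * -(
        0.2 * np.log(0.2) + 0.8 * np.log(0.8)
    )
    assert abs(h1 - expect_h1) < 1e-12 and abs(hc - expect_hc) < 1e-12
    seqs = S.markov_token_corpus(50, 40, P, seed=3)
    assert len(seqs) == 50 and all(len(s) == 40 for s in seqs)
    # empirical transition frequency roughly matches the chain
    from collections import Counter

    c = Counter((a, b) for s in seqs for a, b in zip(s, s[1:]))
    p01 = c[("M/0", "M/1")] / (c[("M/0", "M/0")] + c[("M/0", "M/1")])
    assert abs(p01 - 0.1) < 0.03
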