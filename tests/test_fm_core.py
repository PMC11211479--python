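"""Vocabulary, tokenizer, and the miniature next-code transformer."""

import numpy as np
import pytest

from ehrfm import synthetic_ehr as S
from ehrfm._nn import TinyCausalLM
from ehrfm.fm_core import (
    FMConfig,
    FMCheckpoint,
    Vocabulary,
    VocabularyMismatchError,
    build_vocabulary,
    continue_pretrain,
    corpus_loss,
    example_histories,
    extract_representations,
    pretrain,
    tokenize,
)
from ehrfm.timeline_store import CodedEvent, PatientTimeline


def seq_timelines(seqs, start=0, site="X"):
    out = []
    for i, s in enumerate(seqs):
        events = [CodedEvent(c, 1_000_000 + 10 * j) for j, c in enumerate(s)]
        out.append(PatientTimeline(f"p{start + i}", 0, "M", site, events, []))
    return out


TINY = FMConfig(
    n_layers=1, hidden=16, n_heads=2, window=8, max_seq_len=16,
    batch_sequences=8, max_steps=120, patience=60, eval_every=20,
    lr_candidates=(3e-3,), val_chunk_budget=32,
)


# ---------------------------------------------------------------------------
# Vocabulary / tokenizer


def test_vocabulary_ranking_and_ties():
    tls = seq_timelines([["A"] * 5 + ["B"] * 3 + ["C"] * 3 + ["D"]])
    vocab = build_vocabulary(tls, 3)
    assert vocab.codes == ["A", "B", "C"]  # tie B/C broken lexicographically
    full = build_vocabulary(tls, 99)
    assert full.codes == ["A", "B", "C", "D"]
    with pytest.raises(ValueError):
        build_vocabulary(tls, 0)


def test_tokenize_drops_oov_and_preserves_order():
    tls = seq_timelines([["A", "Z", "B", "Q", "A"]])
    vocab = build_vocabulary(seq_timelines([["A", "A", "B"]]), 10)
    tt = tokenize(tls[0], vocab)
    assert len(tt.tokens) == 3 and tt.dropped == 2
    assert [vocab.codes[t] for t in tt.tokens] == ["A", "B", "A"]
    none = tokenize(seq_timelines([["Z", "Q"]])[0], vocab)
    assert none.tokens == [] and none.dropped == 2


def test_vocabulary_text_roundtrip():
    v = Vocabulary(["A", "B"], [10, 5])
    assert Vocabulary.from_lines(v.to_lines()) == v


# ---------------------------------------------------------------------------
# Transformer mechanics


def test_gradients_match_finite_differences():
    rng = np.random.default_rng(0)
    m = TinyCausalLM(vocab_size=9, hidden=12, n_layers=2, n_heads=3, max_len=8, window=3, seed=1)
    ids = rng.integers(0, 9, size=(3, 7))
    lengths = np.array([7, 5, 2])
    loss, grads = m.loss_and_grads(ids, lengths)
    eps = 1e-5
    for key in m.params:
        flat = m.params[key].reshape(-1)
        for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp = m.loss(ids, lengths)
            flat[i] = orig - eps
            lm = m.loss(ids, lengths)
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[key].reshape(-1)[i]
            assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), key


def test_causality_future_tokens_do_not_leak():
    """Perturbing tokens after position t never changes the hidden state
    at t (causal local attention)."""
    m = TinyCausalLM(vocab_size=12, hidden=16, n_layers=2, n_heads=2, max_len=10, window=4, seed=2)
    rng = np.random.default_rng(3)
    ids = rng.integers(0, 12, size=(1, 10))
    h1 = m.hidden_states(ids)
    for t in (0, 4, 8):
        mutated = ids.copy()
        mutated[0, t + 1 :] = (mutated[0, t + 1 :] + 5) % 12
        h2 = m.hidden_states(mutated)
        assert np.allclose(h1[0, : t + 1], h2[0, : t + 1], atol=1e-12)


def test_local_window_limits_receptive_field():
    """With window w, the hidden state at t ignores tokens before t-w+1
    in a single attention layer."""
    m = TinyCausalLM(vocab_size=12, hidden=16, n_layers=1, n_heads=2, max_len=12, window=3, seed=4)
    rng = np.random.default_rng(5)
    ids = rng.integers(0, 12, size=(1, 12))
    h1 = m.hidden_states(ids)
    mutated = ids.copy()
    mutated[0, :5] = (mutated[0, :5] + 3) % 12  # far outside the window of t=11
    h2 = m.hidden_states(mutated)
    assert np.allclose(h1[0, 11], h2[0, 11], atol=1e-12)
    assert not np.allclose(h1[0, 5], h2[0, 5])


# ---------------------------------------------------------------------------
# Pretraining oracles


def test_single_code_corpus_converges_to_zero_entropy():
    tls = seq_timelines([["A"] * 16 for _ in range(30)])
    vocab = build_vocabulary(tls, 4)
    ck = pretrain(tls[:25], tls[25:], vocab, TINY, seed=0)
    assert ck.provenance["val_loss"] <= 0.01


def test_unigram_corpus_converges_to_unigram_entropy():
    rng = np.random.default_rng(7)
    p = np.array([0.3, 0.25, 0.15, 0.1, 0.08, 0.06, 0.04, 0.02])
    h = float(-(p * np.log(p)).sum())
    seqs = [
        [f"C{j}" for j in rng.choice(8, size=16, p=p)] for _ in range(320)
    ]
    tls = seq_timelines(seqs)
    cfg = FMConfig(
        n_layers=1, hidden=16, n_heads=2, window=8, max_seq_len=16,
        batch_sequences=16, max_steps=400, patience=200, eval_every=25,
        lr_candidates=(3e-3,), val_chunk_budget=64,
    )
    ck = pretrain(tls[:280], tls[280:], vocab=build_vocabulary(tls, 8), config=cfg, seed=0)
    assert abs(ck.provenance["val_loss"] - h) < 0.05


def test_zero_patience_continuation_returns_parent_unchanged():
    tls = seq_timelines([["A", "B"] * 8 for _ in range(20)])
    vocab = build_vocabulary(tls, 4)
    parent = pretrain(tls[:16], tls[16:], vocab, TINY, seed=0)
    import dataclasses

    frozen = dataclasses.replace(TINY, patience=0)
    child = continue_pretrain(parent, tls[:16], tls[16:], frozen, seed=1)
    for k in parent.params:
        assert np.array_equal(parent.params[k], child.params[k])
    assert child.provenance["continued_from"] == parent.provenance["site"]


def test_continuation_on_own_corpus_does_not_get_worse():
    tls = seq_timelines([["A", "B", "C", "A", "B", "C"] * 2 for _ in range(40)])
    vocab = build_vocabulary(tls, 4)
    parent = pretrain(tls[:32], tls[32:], vocab, TINY, seed=0)
    child = continue_pretrain(parent, tls[:32], tls[32:], TINY, seed=0)
    assert child.provenance["val_loss"] <= parent.provenance["val_loss"] + 0.01


def test_continuation_rejects_foreign_vocabulary():
    tls = seq_timelines([["A", "B"] * 8 for _ in range(12)])
    parent = pretrain(tls[:10], tls[10:], build_vocabulary(tls, 4), TINY, seed=0)
    other = Vocabulary(["X", "Y"], [2, 1])
    with pytest.raises(VocabularyMismatchError):
        continue_pretrain(parent, tls[:10], tls[10:], TINY, seed=0, vocab=other)


def test_cross_site_continuation_improves_shifted_corpus_loss():
    """Continuing a site-A model on a shifted site-B corpus lowers its
    site-B held-out loss."""
    P_a = np.array([[0.8, 0.1, 0.05, 0.05],
                    [0.1, 0.8, 0.05, 0.05],
                    [0.05, 0.05, 0.8, 0.1],
                    [0.05, 0.05, 0.1, 0.8]])
    P_b = np.array([[0.1, 0.8, 0.05, 0.05],
                    [0.8, 0.1, 0.05, 0.05],
                    [0.05, 0.05, 0.1, 0.8],
                    [0.05, 0.05, 0.8, 0.1]])
    tls_a = seq_timelines([s for s in S.markov_token_corpus(160, 16, P_a, seed=1)])
    tls_b = seq_timelines([s for s in S.markov_token_corpus(160, 16, P_b, seed=2)], start=500)
    vocab = build_vocabulary(tls_a, 8)
    cfg = FMConfig(
        n_layers=1, hidden=16, n_heads=2, window=8, max_seq_len=16,
        batch_sequences=16, max_steps=300, patience=150, eval_every=25,
        lr_candidates=(3e-3,), val_chunk_budget=64,
    )
    parent = pretrain(tls_a[:140], tls_a[140:], vocab, cfg, seed=0, site="A")
    loss_before = corpus_loss(parent, tls_b[140:])
    child = continue_pretrain(parent, tls_b[:140], tls_b[140:], cfg, seed=0, site="B")
    loss_after = corpus_loss(child, tls_b[140:])
    assert loss_after < loss_before


# ---------------------------------------------------------------------------
# Representations


def test_representation_determinism_and_slicing_contract():
    tls = seq_timelines([["A", "B", "C", "A"] * 4 for _ in range(20)])
    vocab = build_vocabulary(tls, 8)
    ck = pretrain(tls[:16], tls[16:], vocab, TINY, seed=0)
    hists = [[0, 1, 2], [0, 1, 2], [0, 1, 2, 2]]
    reps = extract_representations(ck, hists)
    assert np.array_equal(reps[0], reps[1])  # identical histories
    assert not np.allclose(reps[0], reps[2])
    # empty history → zero-history embedding
    reps2 = extract_representations(ck, [[]])
    assert np.array_equal(reps2[0], np.zeros(ck.config.hidden))


def test_example_histories_slice_at_prediction_time():
    from ehrfm.cohort_tasks import CohortExample

    tl = seq_timelines([["A", "B", "C", "D"]])[0]  # events at t=1e6 + 0,10,20,30
    vocab = build_vocabulary([tl], 8)
    ex_before = CohortExample(tl.patient_id, 0, "t", 1_000_020, 0)
    ex_all = CohortExample(tl.patient_id, 0, "t", 2_000_000, 0)
    hists = example_histories([ex_before, ex_all], [tl], vocab)
    assert len(hists[0]) == 2 and len(hists[1]) == 4
    # an event at/after prediction time never reaches the model input
    tl.events.append(CodedEvent("A", 1_000_020))
    tl.events.sort(key=lambda e: e.time)
    hists2 = example_histories([ex_before], [tl], vocab)
    assert len(hists2[0]) == 2


def test_checkpoint_save_load_roundtrip(tmp_path):
    tls = seq_timelines([["A", "B"] * 8 for _ in range(12)])
    ck = pretrain(tls[:10], tls[10:], build_vocabulary(tls, 4), TINY, seed=0)
    ck.save(tmp_path / "ckpt")
    back = FMCheckpoint.load(tmp_path / "ckpt")
    assert back.vocab == ck.vocab
    for k in ck.params:
        assert np.array_equal(back.params[k], ck.params[k])
    assert back.provenance["kind"] == "from_scratch"
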