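"""Miniature foundation model over coded patient timelines.

A frequency-ranked code vocabulary with out-of-vocabulary *drop*
semantics feeds a small decoder-only transformer (:mod:`ehrfm._nn`)
trained autoregressively to predict the next clinical code.  The model
is used strictly as a frozen encoder downstream: task heads see the
final-layer hidden state at the last token of the history sliced at the
prediction time, never gradients.

Pretraining supports both from-scratch training and *continued
pretraining* — restarting optimization from a parent checkpoint on a new
site's corpus while inheriting the parent's vocabulary (codes the parent
never saw remain out-of-vocabulary, as when moving a shared model to a
new hospital).  The learning rate is selected from a candidate grid by
validation loss; early stopping halts when validation loss has not
improved for a configured number of optimizer steps.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import Adam, TinyCausalLM, pad_batch
from .timeline_store import PatientTimeline


class VocabularyMismatchError(ValueError):
    """Continued pretraining attempted with a different vocabulary."""


@dataclass
class Vocabulary:
    """Frequency-ranked code → token map; unknown codes are dropped."""

    codes: list[str]
    counts: list[int]

    def __post_init__(self) -> None:
        self.index = {c: i for i, c in enumerate(self.codes)}

    def __len__(self) -> int:
        return len(self.codes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Vocabulary) and self.codes == other.codes

    def to_lines(self) -> str:
        return "\n".join(
            f"{c}\t{r}\t{n}" for r, (c, n) in enumerate(zip(self.codes, self.counts))
        )

    @classmethod
    def from_lines(cls, text: str) -> "Vocabulary":
        codes, counts = [], []
        for line in text.strip().splitlines():
            c, _, n = line.split("\t")
            codes.append(c)
            counts.append(int(n))
        return cls(codes, counts)


def build_vocabulary(timelines: Sequence[PatientTimeline], k: int) -> Vocabulary:
    """Top-``k`` codes by corpus frequency; ties broken lexicographically."""
    if k < 1:
        raise ValueError("vocabulary size must be at least 1")
    counts: dict[str, int] = {}
    for tl in timelines:
        for e in tl.events:
            counts[e.code] = counts.get(e.code, 0) + 1
    if not counts:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return Vocabulary([c for c, _ in ranked], [n for _, n in ranked])


@dataclass
class TokenizedTimeline:
    tokens: list[int]
    times: list[int]
    dropped: int


def tokenize(timeline: PatientTimeline, vocab: Vocabulary) -> TokenizedTimeline:
    """Map events to token indices, dropping out-of-vocabulary codes."""
    tokens, times, dropped = [], [], 0
    for e in timeline.events:
        idx = vocab.index.get(e.code)
        if idx is None:
            dropped += 1
        else:
            tokens.append(idx)
            times.append(e.time)
    return TokenizedTimeline(tokens, times, dropped)


@dataclass
class FMConfig:
    """Architecture and optimization settings (tiny desk-scale defaults).

    ``patience`` counts optimizer steps without validation improvement,
    and a "step" is one optimizer update on a batch of
    ``batch_sequences`` chunks of up to ``max_seq_len`` tokens (a fixed
    token budget).
    """

    n_layers: int = 2
    hidden: int = 64
    n_heads: int = 4
    window: int = 64  # local attention span, in tokens
    max_seq_len: int = 64
    batch_sequences: int = 16
    max_steps: int = 1500
    patience: int = 500
    eval_every: int = 25
    lr_candidates: tuple[float, ...] = (1e-3, 3e-4, 1e-4)
    val_chunk_budget: int = 256
    pooling: str = "last"  # or "mean"
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_layers", "hidden", "n_heads", "window", "max_seq_len",
                     "batch_sequences", "max_steps", "eval_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.patience >= self.max_steps and self.patience != 0:
            # patience larger than the step budget just disables early stop
            pass


@dataclass
class FMCheckpoint:
    params: dict[str, np.ndarray]
    vocab: Vocabulary
    config: FMConfig
    provenance: dict = field(default_factory=dict)

    def model(self) -> TinyCausalLM:
        c = self.config
        return TinyCausalLM(
            vocab_size=len(self.vocab), hidden=c.hidden, n_layers=c.n_layers,
            n_heads=c.n_heads, max_len=c.max_seq_len, window=c.window,
            params=self.params,
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "params.npz", **self.params)
        (path / "vocabulary.tsv").write_text(self.vocab.to_lines() + "\n")
        manifest = {"config": asdict(self.config), "provenance": self.provenance}
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "FMCheckpoint":
        path = Path(path)
        with np.load(path / "params.npz") as z:
            params = {k: z[k] for k in z.files}
        vocab = Vocabulary.from_lines((path / "vocabulary.tsv").read_text())
        manifest = json.loads((path / "manifest.json").read_text())
        cfg_d = manifest["config"]
        cfg_d["lr_candidates"] = tuple(cfg_d["lr_candidates"])
        return cls(params, vocab, FMConfig(**cfg_d), manifest["provenance"])


# ---------------------------------------------------------------------------
# Training


def _chunks(token_lists: Sequence[list[int]], max_len: int) -> list[list[int]]:
    out = []
    for toks in token_lists:
        for i in range(0, len(toks), max_len):
            chunk = toks[i : i + max_len]
            if len(chunk) >= 2:  # need at least one supervised position
                out.append(chunk)
    return out


def _corpus_chunks(
    timelines: Sequence[PatientTimeline], vocab: Vocabulary, max_len: int
) -> list[list[int]]:
    return _chunks([tokenize(tl, vocab).tokens for tl in timelines], max_len)


def _eval_chunks(model: TinyCausalLM, chunks: list[list[int]], batch: int) -> float:
    """Token-weighted mean next-token loss over a chunk list."""
    tot, n = 0.0, 0
    order = sorted(range(len(chunks)), key=lambda i: len(chunks[i]))
    for i in range(0, len(order), batch):
        group = [chunks[j] for j in order[i : i + batch]]
        ids, lengths = pad_batch(group)
        w = int((lengths - 1).sum())
        tot += model.loss(ids, lengths) * w
        n += w
    return tot / max(1, n)


def _train_once(
    chunks: list[list[int]],
    val_chunks: list[list[int]],
    config: FMConfig,
    lr: float,
    seed: int,
    init_params: dict[str, np.ndarray] | None,
    vocab_size: int,
) -> tuple[dict[str, np.ndarray], float, int]:
    """One training run at a fixed learning rate; returns best state."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, int(lr * 1e8) % (1 << 30)]))
    model = TinyCausalLM(
        vocab_size=vocab_size, hidden=config.hidden, n_layers=config.n_layers,
        n_heads=config.n_heads, max_len=config.max_seq_len, window=config.window,
        seed=seed,
        params=copy.deepcopy(init_params) if init_params is not None else None,
    )
    val_sel = val_chunks[: config.val_chunk_budget]
    best_loss = _eval_chunks(model, val_sel, config.batch_sequences)
    best_params = copy.deepcopy(model.params)
    best_step = 0
    if config.patience == 0:
        return best_params, best_loss, 0

    opt = Adam(model.params, lr=lr)
    step = 0
    while step < config.max_steps:
        idx = rng.integers(0, len(chunks), size=min(config.batch_sequences, len(chunks)))
        ids, lengths = pad_batch([chunks[i] for i in idx])
        loss, grads = model.loss_and_grads(ids, lengths)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at step {step}")
        opt.step(model.params, grads)
        step += 1
        if step % config.eval_every == 0 or step == config.max_steps:
            vloss = _eval_chunks(model, val_sel, config.batch_sequences)
            if vloss < best_loss - 1e-6:
                best_loss = vloss
                best_params = copy.deepcopy(model.params)
                best_step = step
            if step - best_step >= config.patience:
                break
    return best_params, best_loss, best_step


def pretrain(
    train_timelines: Sequence[PatientTimeline],
    valid_timelines: Sequence[PatientTimeline],
    vocab: Vocabulary,
    config: FMConfig,
    seed: int = 0,
    site: str = "",
) -> FMCheckpoint:
    """Pretrain a model from scratch with the next-code objective."""
    config.validate()
    chunks = _corpus_chunks(train_timelines, vocab, config.max_seq_len)
    if not chunks:
        raise ValueError("empty pretraining corpus after tokenization")
    val_chunks = _corpus_chunks(valid_timelines, vocab, config.max_seq_len) or chunks[:64]
    results = []
    for lr in config.lr_candidates:
        params, vloss, step = _train_once(
            chunks, val_chunks, config, lr, seed, None, len(vocab)
        )
        results.append((vloss, lr, params, step))
    vloss, lr, params, step = min(results, key=lambda r: r[0])
    prov = {
        "kind": "from_scratch", "site": site, "learning_rate": lr,
        "best_step": step, "val_loss": vloss, "seed": seed,
        "n_train_patients": len(train_timelines),
    }
    return FMCheckpoint(params, vocab, config, prov)


def continue_pretrain(
    parent: FMCheckpoint,
    train_timelines: Sequence[PatientTimeline],
    valid_timelines: Sequence[PatientTimeline],
    config: FMConfig | None = None,
    seed: int = 0,
    site: str = "",
    vocab: Vocabulary | None = None,
) -> FMCheckpoint:
    """Resume the next-code objective from a parent checkpoint.

    The parent's vocabulary is inherited, never rebuilt: the new corpus
    is tokenized with it, and codes unknown to the parent stay dropped.
    """
    if vocab is not None and vocab != parent.vocab:
        raise VocabularyMismatchError("continued pretraining must reuse the parent vocabulary")
    config = config or parent.config
    config.validate()
    if config.hidden != parent.config.hidden or config.n_layers != parent.config.n_layers:
        raise VocabularyMismatchError("architecture must match the parent checkpoint")
    chunks = _corpus_chunks(train_timelines, parent.vocab, config.max_seq_len)
    if not chunks:
        raise ValueError("empty continuation corpus after tokenization")
    val_chunks = _corpus_chunks(valid_timelines, parent.vocab, config.max_seq_len) or chunks[:64]
    results = []
    for lr in config.lr_candidates:
        params, vloss, step = _train_once(
            chunks, val_chunks, config, lr, seed, parent.params, len(parent.vocab)
        )
        results.append((vloss, lr, params, step))
    vloss, lr, params, step = min(results, key=lambda r: r[0])
    prov = {
        "kind": "continued", "site": site, "learning_rate": lr,
        "best_step": step, "val_loss": vloss, "seed": seed,
        "continued_from": parent.provenance.get("site", "?"),
        "parent_kind": parent.provenance.get("kind", "?"),
        "n_train_patients": len(train_timelines),
    }
    return FMCheckpoint(params, parent.vocab, config, prov)


def corpus_loss(
    checkpoint: FMCheckpoint, timelines: Sequence[PatientTimeline]
) -> float:
    """Next-code loss of a frozen checkpoint on a held-out corpus."""
    chunks = _corpus_chunks(timelines, checkpoint.vocab, checkpoint.config.max_seq_len)
    if not chunks:
        raise ValueError("no tokens to evaluate")
    return _eval_chunks(checkpoint.model(), chunks, checkpoint.config.batch_sequences)


# ---------------------------------------------------------------------------
# Representation extraction


def extract_representations(
    checkpoint: FMCheckpoint,
    histories: Sequence[Sequence[int]],
    batch: int = 256,
) -> np.ndarray:
    """Frozen encoder features for pre-tokenized, pre-sliced histories.

    Each history is truncated to its most recent ``max_seq_len`` tokens.
    The representation is the final-LayerNorm hidden state at the last
    token (or the mean over tokens with ``pooling="mean"``); an empty
    history maps to the zero vector.
    """
    model = checkpoint.model()
    cfg = checkpoint.config
    n = len(histories)
    out = np.zeros((n, cfg.hidden))
    trunc = [list(h)[-cfg.max_seq_len :] for h in histories]
    nonempty = [i for i in range(n) if len(trunc[i]) > 0]
    nonempty.sort(key=lambda i: len(trunc[i]))
    for i0 in range(0, len(nonempty), batch):
        group = nonempty[i0 : i0 + batch]
        ids, lengths = pad_batch([trunc[i] for i in group])
        hs = model.hidden_states(ids)
        for row, i in enumerate(group):
            L = int(lengths[row])
            if cfg.pooling == "mean":
                out[i] = hs[row, :L].mean(axis=0)
            else:
                out[i] = hs[row, L - 1]
    return out


def example_histories(
    examples,
    timelines: Sequence[PatientTimeline],
    vocab: Vocabulary,
) -> list[list[int]]:
    """Tokenized observation windows for cohort examples.

    The history for an example is every event strictly before its
    prediction time, tokenized with ``vocab``.  Identical
    (patient, prediction time) pairs share work via a cache.
    """
    by_id = {tl.patient_id: tl for tl in timelines}
    tok_cache: dict[str, TokenizedTimeline] = {}
    out = []
    for ex in examples:
        tt = tok_cache.get(ex.patient_id)
        if tt is None:
            tt = tokenize(by_id[ex.patient_id], vocab)
            tok_cache[ex.patient_id] = tt
        # binary search over the (sorted) token times for the slice point
        times = tt.times
        lo, hi = 0, len(times)
        while lo < hi:
            mid = (lo + hi) // 2
            if times[mid] < ex.prediction_time:
                lo = mid + 1
            else:
                hi = mid
        out.append(tt.tokens[:lo])
    return out
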