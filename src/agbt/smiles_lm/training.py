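"""Encoder training stages and fingerprint extraction.

Three stages mirror the fingerprint pipeline: self-supervised
pre-training on an unlabeled SMILES corpus, self-supervised fine-tuning
on task SMILES (mask/keep corruption only), and supervised fine-tuning
that attaches one head per task to the leading-symbol vector and trains
jointly over all labeled datasets (missing labels masked out of the
loss).  Fingerprints are the top-layer vector at the <s> position.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ..chem_io import LabeledDataset
from .encoder import Adam, EncoderConfig, TransformerEncoder, masked_lm_loss
from .masking import MaskingPolicy, apply_masking
from .tokenizer import PAD, Vocabulary, build_vocab, tokenize

STAGES = ("pretrained", "ssl_finetuned", "sl_finetuned")


def _corpus_digest(corpus: Sequence[str]) -> str:
    h = hashlib.sha256()
    for s in corpus:
        h.update(s.encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


@dataclass
class EncoderState:
    """Trained encoder checkpoint: parameters, vocabulary, config, provenance."""

    encoder: TransformerEncoder
    vocab: Vocabulary
    stage: str
    seed: int
    corpus_digest: str
    history: list[float] = field(default_factory=list)

    @property
    def cfg(self) -> EncoderConfig:
        return self.encoder.cfg

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "config": self.cfg.to_dict(),
            "vocabulary": list(self.vocab.symbols),
            "stage": self.stage,
            "seed": self.seed,
            "corpus_digest": self.corpus_digest,
            "history": self.history,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        np.savez(path / "params.npz", **self.encoder.params)

    @classmethod
    def load(cls, path: str | Path) -> "EncoderState":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        vocab = Vocabulary(tuple(manifest["vocabulary"]))
        cfg = EncoderConfig(**manifest["config"])
        with np.load(path / "params.npz") as blob:
            params = {k: blob[k] for k in blob.files}
        encoder = TransformerEncoder(len(vocab), cfg, params=params)
        return cls(encoder, vocab, manifest["stage"], manifest["seed"],
                   manifest["corpus_digest"], list(manifest["history"]))


@dataclass
class BTFingerprint:
    """Leading-symbol latent vector (length = embed_dim)."""

    values: np.ndarray
    flavor: str  # "bt" or "bt_s"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fingerprint contains non-finite values")


def _encode_batch(sequences, vocab: Vocabulary, policy: MaskingPolicy | None,
                  rng_seeds=None):
    """Pad a list of TokenSequence to a common length; optionally corrupt."""
    pad_id = vocab.index[PAD]
    T = max(len(s) for s in sequences)
    B = len(sequences)
    ids = np.full((B, T), pad_id, dtype=np.int64)
    pad_mask = np.zeros((B, T), dtype=bool)
    target_ids = np.zeros((B, T), dtype=np.int64)
    target_mask = np.zeros((B, T), dtype=bool)
    for b, seq in enumerate(sequences):
        if policy is None:
            corrupted, targets = seq, {}
        else:
            corrupted, targets = apply_masking(seq, policy, int(rng_seeds[b]), vocab)
        enc = vocab.encode(corrupted.tokens)
        ids[b, :len(enc)] = enc
        pad_mask[b, :len(enc)] = True
        unk = vocab.index["<unk>"]
        for pos, sym in targets.items():
            target_ids[b, pos] = vocab.index.get(sym, unk)
            target_mask[b, pos] = True
    return ids, pad_mask, target_ids, target_mask


def _run_mlm_training(state: EncoderState, corpus: Sequence[str],
                      policy: MaskingPolicy, epochs: int, lr: float,
                      batch: int, seed: int) -> list[float]:
    sequences = [tokenize(s, max_len=state.cfg.max_len) for s in corpus]
    order_rng = np.random.default_rng(seed)
    dropout_rng = np.random.default_rng(seed + 1)
    opt = Adam(state.encoder.params, lr=lr)
    history = []
    n = len(sequences)
    for epoch in range(epochs):
        order = order_rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            seeds = order_rng.integers(0, 2 ** 31, size=len(idx))
            ids, pad_mask, tgt_ids, tgt_mask = _encode_batch(
                [sequences[i] for i in idx], state.vocab, policy, seeds)
            loss, grads, n_tgt = masked_lm_loss(
                state.encoder, ids, pad_mask, tgt_ids, tgt_mask,
                train=True, dropout_rng=dropout_rng)
            if grads is not None:
                opt.step(grads)
                total += loss * n_tgt
                count += n_tgt
        history.append(total / max(count, 1))
    return history


def masked_loss_on_corpus(state: EncoderState, corpus: Sequence[str],
                          policy: MaskingPolicy, seed: int = 0) -> float:
    """Mean masked cross-entropy of the current parameters on a corpus."""
    sequences = [tokenize(s, max_len=state.cfg.max_len) for s in corpus]
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31, size=len(sequences))
    ids, pad_mask, tgt_ids, tgt_mask = _encode_batch(sequences, state.vocab, policy, seeds)
    loss, _, _ = masked_lm_loss(state.encoder, ids, pad_mask, tgt_ids, tgt_mask)
    return loss


def masked_recovery_accuracy(state: EncoderState, corpus: Sequence[str],
                             policy: MaskingPolicy, seed: int = 0) -> float:
    """Top-1 accuracy of recovering the original symbols at selected positions."""
    sequences = [tokenize(s, max_len=state.cfg.max_len) for s in corpus]
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31, size=len(sequences))
    ids, pad_mask, tgt_ids, tgt_mask = _encode_batch(sequences, state.vocab, policy, seeds)
    hidden, _ = state.encoder.forward(ids, pad_mask)
    pred = state.encoder.logits(hidden).argmax(-1)
    if not tgt_mask.any():
        return 0.0
    return float((pred[tgt_mask] == tgt_ids[tgt_mask]).mean())


def pretrain(corpus: Sequence[str], cfg: EncoderConfig | None = None,
             policy: MaskingPolicy | None = None, epochs: int = 20,
             lr: float = 1e-3, batch: int = 32,
             vocab: Vocabulary | None = None) -> EncoderState:
    """Self-supervised pre-training on an unlabeled SMILES corpus."""
    if not corpus:
        raise ValueError("pretraining corpus is empty")
    cfg = cfg or EncoderConfig.test_scale()
    policy = policy or MaskingPolicy.pretraining()
    vocab = vocab or build_vocab(corpus, max_len=cfg.max_len)
    encoder = TransformerEncoder(len(vocab), cfg)
    state = EncoderState(encoder, vocab, "pretrained", cfg.seed, _corpus_digest(corpus))
    state.history = _run_mlm_training(state, corpus, policy, epochs, lr, batch, cfg.seed)
    return state


def finetune_ssl(state: EncoderState, task_smiles: Sequence[str],
                 policy: MaskingPolicy | None = None, epochs: int = 5,
                 lr: float = 1e-3, batch: int = 32) -> EncoderState:
    """Self-supervised fine-tuning on task SMILES (mask/keep only)."""
    if state.stage != "pretrained":
        raise ValueError(f"finetune_ssl requires a pretrained state, got {state.stage!r}")
    policy = policy or MaskingPolicy.ssl_finetuning()
    if "random" in policy.allowed_ops or policy.op_probs[1] > 0:
        raise ValueError("random-changing operation is forbidden in SSL fine-tuning")
    params = {k: v.copy() for k, v in state.encoder.params.items()}
    encoder = TransformerEncoder(len(state.vocab), state.cfg, params=params)
    new = EncoderState(encoder, state.vocab, "ssl_finetuned", state.seed,
                       _corpus_digest(task_smiles), list(state.history))
    if epochs > 0:
        new.history += _run_mlm_training(new, task_smiles, policy, epochs, lr,
                                         batch, state.seed + 1000)
    return new


def finetune_supervised(state: EncoderState, datasets: Sequence[LabeledDataset],
                        epochs: int = 5, lr: float = 1e-3,
                        batch: int = 32) -> EncoderState:
    """Supervised fine-tuning on labeled datasets; heads are discarded after.

    One linear head per task reads the leading-symbol vector; regression
    tasks use squared error, classification tasks logistic loss; missing
    labels are masked out.  All datasets are trained jointly.
    """
    if state.stage not in ("pretrained", "ssl_finetuned"):
        raise ValueError(f"cannot supervise-finetune from stage {state.stage!r}")
    if not datasets or all(not d.labels for d in datasets):
        raise ValueError("supervised fine-tuning requires at least one labeled dataset")
    # Flatten: one row per molecule, per-task value/mask columns.
    tasks: list[tuple[str, str]] = []  # (task name, type)
    rows: list[tuple[str, np.ndarray, np.ndarray]] = []  # (smiles, values, mask)
    for d in datasets:
        if not d.labels:
            raise ValueError("dataset with no labels")
        for t in d.labels:
            tasks.append((t, d.task_types.get(t, "regression")))
    task_index = {name: i for i, (name, _) in enumerate(tasks)}
    K = len(tasks)
    for d in datasets:
        values_by_task = {t: d.label_vector(t) for t in d.labels}
        for i, mol in enumerate(d.molecules):
            vals = np.zeros(K)
            mask = np.zeros(K, dtype=bool)
            for t, (v, m) in values_by_task.items():
                if m[i]:
                    vals[task_index[t]] = v[i]
                    mask[task_index[t]] = True
            if mol.smiles is None:
                raise ValueError(f"molecule {mol.id!r} lacks a SMILES string")
            rows.append((mol.smiles, vals, mask))

    params = {k: v.copy() for k, v in state.encoder.params.items()}
    encoder = TransformerEncoder(len(state.vocab), state.cfg, params=params)
    new = EncoderState(encoder, state.vocab, "sl_finetuned", state.seed,
                       state.corpus_digest, list(state.history))
    if epochs == 0:
        return new

    D = state.cfg.embed_dim
    rng = np.random.default_rng(state.seed + 2000)
    heads = {"head_w": rng.normal(0, np.sqrt(1.0 / D), size=(D, K)),
             "head_b": np.zeros(K)}
    all_params = {**encoder.params, **heads}
    opt = Adam(all_params, lr=lr)
    sequences = [tokenize(s, max_len=state.cfg.max_len) for s, _, _ in rows]
    Y = np.vstack([v for _, v, _ in rows])
    M = np.vstack([m for _, _, m in rows])
    is_clf = np.array([t == "classification" for _, t in tasks])
    dropout_rng = np.random.default_rng(state.seed + 2001)
    n = len(rows)
    for epoch in range(epochs):
        order = rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            ids, pad_mask, _, _ = _encode_batch([sequences[i] for i in idx],
                                                state.vocab, None)
            hidden, cache = encoder.forward(ids, pad_mask, train=True,
                                            dropout_rng=dropout_rng)
            lead = hidden[:, 0, :]                      # (b, D)
            pred = lead @ heads["head_w"] + heads["head_b"]
            y, m = Y[idx], M[idx]
            n_lab = int(m.sum())
            if n_lab == 0:
                continue
            # squared error for regression, logistic loss for classification
            dpred = np.zeros_like(pred)
            reg = m & ~is_clf
            clf = m & is_clf
            loss = 0.0
            if reg.any():
                err = pred[reg] - y[reg]
                loss += float((err ** 2).sum())
                dpred[reg] = 2.0 * err
            if clf.any():
                z = pred[clf]
                loss += float((np.logaddexp(0.0, z) - y[clf] * z).sum())
                dpred[clf] = 1.0 / (1.0 + np.exp(-z)) - y[clf]
            loss /= n_lab
            dpred /= n_lab
            grads = {"head_w": lead.T @ dpred, "head_b": dpred.sum(0)}
            d_hidden = np.zeros_like(hidden)
            d_hidden[:, 0, :] = dpred @ heads["head_w"].T
            grads.update(encoder.backward(d_hidden, cache))
            opt.step(grads)
            total += loss * n_lab
            count += n_lab
        new.history.append(total / max(count, 1))
    return new


def extract_btfp(state: EncoderState, smiles: str) -> BTFingerprint:
    """Fingerprint of one molecule: top-layer vector at the <s> symbol.

    Deterministic (no corruption, no dropout); a pure function of
    (state, canonical SMILES).
    """
    seq = tokenize(smiles, max_len=state.cfg.max_len)
    ids, pad_mask, _, _ = _encode_batch([seq], state.vocab, None)
    hidden, _ = state.encoder.forward(ids, pad_mask)
    flavor = "bt_s" if state.stage == "sl_finetuned" else "bt"
    return BTFingerprint(hidden[0, 0, :].copy(), flavor)


def bt_feature_matrix(state: EncoderState, smiles_by_id: Sequence[tuple[str, str]]):
    """BT fingerprints for (id, smiles) pairs as a pandas DataFrame."""
    import pandas as pd

    sequences = [tokenize(s, max_len=state.cfg.max_len) for _, s in smiles_by_id]
    rows = []
    for start in range(0, len(sequences), 64):
        chunk = sequences[start:start + 64]
        ids, pad_mask, _, _ = _encode_batch(chunk, state.vocab, None)
        hidden, _ = state.encoder.forward(ids, pad_mask)
        rows.append(hidden[:, 0, :])
    values = np.vstack(rows)
    names = [f"BT::{i:04d}" for i in range(state.cfg.embed_dim)]
    return pd.DataFrame(values, index=[i for i, _ in smiles_by_id], columns=names)
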