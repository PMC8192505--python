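"""Symbol corruption for masked-language-model training.

A fraction of the non-special symbols is selected independently; each
selected symbol is masked, replaced by a random vocabulary symbol, or
kept unchanged.  Pre-training allows all three operations; the
self-supervised fine-tuning stage allows only mask and keep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tokenizer import MASK, SPECIALS, TokenSequence, Vocabulary

OPS = ("mask", "random", "keep")


@dataclass(frozen=True)
class MaskingPolicy:
    """Selection rate and operation mix for symbol corruption."""

    select_rate: float = 0.15
    op_probs: tuple[float, float, float] = (0.8, 0.1, 0.1)  # (mask, random, keep)
    allowed_ops: frozenset[str] = frozenset(OPS)

    def __post_init__(self) -> None:
        if not 0.0 <= self.select_rate <= 1.0:
            raise ValueError("select_rate must be in [0, 1]")
        probs = np.asarray(self.op_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("op_probs must be three non-negative numbers summing to 1")
        if not self.allowed_ops <= set(OPS):
            raise ValueError(f"allowed_ops must be a subset of {OPS}")
        for op, p in zip(OPS, probs):
            if op not in self.allowed_ops and p > 0:
                raise ValueError(f"operation {op!r} is disallowed but has probability {p}")

    @staticmethod
    def pretraining() -> "MaskingPolicy":
        return MaskingPolicy()

    @staticmethod
    def ssl_finetuning() -> "MaskingPolicy":
        return MaskingPolicy(op_probs=(0.8, 0.0, 0.2), allowed_ops=frozenset({"mask", "keep"}))


def apply_masking(seq: TokenSequence, policy: MaskingPolicy, rng_seed: int,
                  vocab: Vocabulary | None = None) -> tuple[TokenSequence, dict[int, str]]:
    """Corrupt a token sequence; return it with a position -> original map.

    Special symbols are never selected.  Targets are recorded for every
    selected position, including keep/random ones, as in standard
    masked-LM objectives.  ``vocab`` is required when the random
    operation has positive probability.
    """
    if policy.op_probs[1] > 0 and vocab is None:
        raise ValueError("random-change operation requires a vocabulary")
    rng = np.random.default_rng(rng_seed)
    tokens = list(seq.tokens)
    targets: dict[int, str] = {}
    for pos, tok in enumerate(tokens):
        if tok in SPECIALS:
            continue
        if rng.random() >= policy.select_rate:
            continue
        targets[pos] = tok
        op = OPS[rng.choice(3, p=policy.op_probs)]
        if op == "mask":
            tokens[pos] = MASK
        elif op == "random":
            tokens[pos] = vocab.regular_symbols[rng.integers(len(vocab.regular_symbols))]
    return TokenSequence(tuple(tokens)), targets
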