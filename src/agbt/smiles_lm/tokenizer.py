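"""SMILES symbol tokenizer and vocabulary.

Greedy longest-match over the SMILES token classes: bracket atoms
``[...]`` as one symbol, the two-letter halogens Cl/Br, single-letter
organic-subset atoms, aromatic atoms, bond symbols, ring-closure digits
(including ``%NN``), parentheses and the dot.  Concatenating the
non-special tokens reproduces the input exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

BOS = "<s>"
EOS = "</s>"
PAD = "<pad>"
MASK = "<mask>"
UNK = "<unk>"
SPECIALS = (BOS, EOS, PAD, MASK, UNK)

DEFAULT_MAX_LEN = 256

_TOKEN_RE = re.compile(
    r"\[[^\]]*\]"        # bracket atom, one symbol
    r"|Cl|Br"            # two-letter halogens
    r"|[BCNOPSFI]"       # single-letter organic atoms
    r"|[bcnops]"         # aromatic atoms
    r"|%\d{2}"           # two-digit ring closure
    r"|[0-9]"            # ring closure digit
    r"|[-=#$:/\\()."     # bonds, branches, dot
    r"+]"
)


class TokenizationError(ValueError):
    pass


@dataclass(frozen=True)
class TokenSequence:
    """Token list wrapped with leading <s> and trailing </s>."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) < 2 or self.tokens[0] != BOS or self.tokens[-1] != EOS:
            raise ValueError("token sequence must start with <s> and end with </s>")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def body(self) -> tuple[str, ...]:
        """Tokens without the wrapping specials."""
        return self.tokens[1:-1]


def tokenize(smiles: str, max_len: int = DEFAULT_MAX_LEN) -> TokenSequence:
    """Split a SMILES string into symbols and wrap with <s>/</s>.

    Raises ``TokenizationError`` on an unknown character (with its
    position) or when the wrapped sequence exceeds ``max_len``.
    """
    if not smiles:
        raise TokenizationError("empty SMILES string")
    tokens: list[str] = []
    pos = 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenizationError(
                f"unknown character {smiles[pos]!r} at position {pos} in {smiles!r}"
            )
        tokens.append(m.group())
        pos = m.end()
    if len(tokens) + 2 > max_len:
        raise TokenizationError(
            f"sequence too long: {len(tokens)} symbols + specials exceed {max_len}"
        )
    return TokenSequence((BOS, *tokens, EOS))


def detokenize(seq: TokenSequence) -> str:
    """Concatenate non-special tokens; inverse of ``tokenize``."""
    return "".join(t for t in seq.tokens if t not in SPECIALS)


@dataclass
class Vocabulary:
    """Bijective symbol <-> integer-id mapping with reserved special ids."""

    symbols: tuple[str, ...]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if tuple(self.symbols[: len(SPECIALS)]) != SPECIALS:
            raise ValueError("vocabulary must start with the special symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("vocabulary symbols must be unique")
        self.index = {s: i for i, s in enumerate(self.symbols)}

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.index

    def encode(self, tokens) -> list[int]:
        unk = self.index[UNK]
        return [self.index.get(t, unk) for t in tokens]

    def decode(self, ids) -> list[str]:
        return [self.symbols[i] for i in ids]

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset(range(len(SPECIALS)))

    @property
    def regular_symbols(self) -> tuple[str, ...]:
        return self.symbols[len(SPECIALS):]


def build_vocab(corpus, max_len: int = DEFAULT_MAX_LEN) -> Vocabulary:
    """Specials + sorted unique tokens of the corpus; order-invariant."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    seen: set[str] = set()
    for lineno, smiles in enumerate(corpus):
        try:
            seen.update(tokenize(smiles, max_len=max_len).body)
        except TokenizationError as exc:
            raise TokenizationError(f"line {lineno}: {exc}") from None
    return Vocabulary((*SPECIALS, *sorted(seen)))
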