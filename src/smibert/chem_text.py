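"""SMILES tokenization and vocabulary management.

SMILES strings are tokenized with a single regular expression whose
alternatives are, in order: the two-letter element symbols that must never be
split (``Si``, ``Mg``, ``Ca``, ``Fe``, ``As``, ``Al``, ``Cl``, ``Br``), a
character class covering ring-bond digits, branch/charge punctuation, bond
symbols, atom-map ``@``, bracket atoms and the organic-subset element letters
(aromatic forms included), and finally the two directional-bond characters.
Alternation is ordered, so the two-letter symbols win over the single-letter
class ("Cl" is one token, never "C","l").

The character class contains ``=`` and ``:`` — the double-bond and
aromatic-bond/atom-map separators. Some renderings of this vocabulary print
these two as a single ligature glyph; they are two distinct SMILES characters
and are treated as such here.

The vocabulary is a fixed bijection between token strings and contiguous
integer ids: first every token the regex can match, then the special tokens
``[MASK]`` and ``[PAD]``, then ``n_task_tokens`` reserved task tokens
``[T0]``, ``[T1]``, ... whose encoder outputs feed per-task prediction heads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "TOKEN_PATTERN",
    "TokenizationError",
    "TokenSequence",
    "Vocabulary",
    "tokenize",
    "build_vocabulary",
    "encode",
    "decode",
]

# Ordered alternation: multi-character element symbols first, then the
# single-character class, then escaped directional bonds.
TOKEN_PATTERN = (
    r"(Si|Mg|Ca|Fe|As|Al|Cl|Br"
    r"|[#%\)\(\+\-0123456789=:@CBFIHONPS\[\]icosn]"
    r"|/|\\)"
)
_TOKEN_RE = re.compile(TOKEN_PATTERN)

#: Two-letter element symbols that are always a single token.
MULTI_CHAR_TOKENS = ("Si", "Mg", "Ca", "Fe", "As", "Al", "Cl", "Br")

#: Single characters of the class, in the order they appear in the pattern.
_SINGLE_CHAR_TOKENS = tuple("#%)(+-0123456789=:@CBFIHONPS[]icosn") + ("/", "\\")

MASK_TOKEN = "[MASK]"
PAD_TOKEN = "[PAD]"


class TokenizationError(ValueError):
    """A character of the SMILES string is matched by no token alternative."""

    def __init__(self, smiles: str, position: int):
        self.smiles = smiles
        self.position = position
        super().__init__(
            f"cannot tokenize character {smiles[position]!r} at position "
            f"{position} of {smiles!r}"
        )


@dataclass(frozen=True)
class TokenSequence:
    """An ordered token list together with the SMILES it came from."""

    tokens: tuple[str, ...]
    source_smiles: str

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def tokenize(smiles: str) -> TokenSequence:
    """Tokenize a SMILES string.

    Scans left to right taking the leftmost-longest alternative at each
    position. Every character must be consumed by some alternative;
    silently dropping characters would desynchronize tokens from labels,
    so an unmatched character raises :class:`TokenizationError`.
    """
    if not smiles:
        raise ValueError("cannot tokenize an empty SMILES string")
    tokens: list[str] = []
    pos = 0
    n = len(smiles)
    while pos < n:
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenizationError(smiles, pos)
        tokens.append(m.group(0))
        pos = m.end()
    return TokenSequence(tokens=tuple(tokens), source_smiles=smiles)


@dataclass(frozen=True)
class Vocabulary:
    """Bijection between token strings and contiguous integer ids."""

    token_to_id: dict[str, int]
    id_to_token: tuple[str, ...]
    n_task_tokens: int
    special_tokens: tuple[str, str] = (MASK_TOKEN, PAD_TOKEN)
    _task_ids: frozenset[int] = field(default=frozenset(), repr=False)

    def __len__(self) -> int:
        return len(self.id_to_token)

    @property
    def size(self) -> int:
        """Vocabulary size V (number of embedding rows)."""
        return len(self.id_to_token)

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK_TOKEN]

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD_TOKEN]

    def task_id(self, t: int) -> int:
        """Id of task token ``[T{t}]``."""
        if not 0 <= t < self.n_task_tokens:
            raise IndexError(
                f"task token index {t} out of range [0, {self.n_task_tokens})"
            )
        return self.token_to_id[f"[T{t}]"]

    @property
    def chemical_ids(self) -> tuple[int, ...]:
        """Ids of ordinary (non-special, non-task) tokens."""
        n_chem = self.size - 2 - self.n_task_tokens
        return tuple(range(n_chem))

    def is_special(self, token_id: int) -> bool:
        return token_id >= self.size - 2 - self.n_task_tokens

    def save(self, path) -> None:
        """Write one token per line; the line number (from 0) is the id."""
        with open(path, "w") as fh:
            for tok in self.id_to_token:
                fh.write(tok + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            toks = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        n_task = sum(1 for t in toks if re.fullmatch(r"\[T\d+\]", t))
        return cls(
            token_to_id={t: i for i, t in enumerate(toks)},
            id_to_token=tuple(toks),
            n_task_tokens=n_task,
        )


def build_vocabulary(n_task_tokens: int = 1000) -> Vocabulary:
    """Build the deterministic vocabulary.

    Order: the eight two-letter element symbols, the single-character
    alternatives in pattern order, then ``[MASK]``, ``[PAD]``, then the
    task tokens ``[T0]`` ... ``[T{n_task_tokens-1}]``. The same argument
    always produces identical id assignments.
    """
    if n_task_tokens < 1:
        raise ValueError("n_task_tokens must be >= 1")
    toks = list(MULTI_CHAR_TOKENS) + list(_SINGLE_CHAR_TOKENS)
    toks += [MASK_TOKEN, PAD_TOKEN]
    toks += [f"[T{i}]" for i in range(n_task_tokens)]
    return Vocabulary(
        token_to_id={t: i for i, t in enumerate(toks)},
        id_to_token=tuple(toks),
        n_task_tokens=n_task_tokens,
    )


def encode(seq: TokenSequence | list[str] | tuple[str, ...], vocab: Vocabulary) -> list[int]:
    """Map token strings to ids; unknown tokens raise ``KeyError`` by name."""
    tokens = seq.tokens if isinstance(seq, TokenSequence) else seq
    try:
        return [vocab.token_to_id[t] for t in tokens]
    except KeyError as exc:
        raise KeyError(f"token {exc.args[0]!r} not in vocabulary") from None


def decode(ids, vocab: Vocabulary, strip_pad: bool = False) -> list[str]:
    """Map ids back to token strings, optionally stripping trailing [PAD]s."""
    ids = list(ids)
    if strip_pad:
        while ids and ids[-1] == vocab.pad_id:
            ids.pop()
    try:
        return [vocab.id_to_token[i] for i in ids]
    except IndexError:
        bad = next(i for i in ids if not 0 <= i < vocab.size)
        raise KeyError(f"id {bad} not in vocabulary") from None
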