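"""Vocabulary construction over tokenized dialogue corpora.

Tokenization is pluggable: the default splits on whitespace, which is
exact for the synthetic token-stream corpora this package generates. A
morphological analyzer (e.g. for Japanese) can be passed as any callable
``str -> list[str]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

logger = logging.getLogger(__name__)

PAD = "<pad>"
UNK = "<unk>"

Tokenizer = Callable[[str], list[str]]


def whitespace_tokenizer(text: str) -> list[str]:
    return text.split()


@dataclass(frozen=True)
class Vocabulary:
    """Dense token -> index map with PAD at 0 and UNK at 1."""

    token_to_index: dict[str, int]
    min_count: int

    @property
    def size(self) -> int:
        return len(self.token_to_index)

    def encode(self, tokens: Iterable[str]) -> list[int]:
        unk = self.token_to_index[UNK]
        return [self.token_to_index.get(t, unk) for t in tokens]

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index


def build_vocabulary(
    dialogues,
    min_count: int = 1,
    tokenizer: Tokenizer = whitespace_tokenizer,
) -> Vocabulary:
    """Count tokens across all turns and keep those with frequency >=
    min_count. Deterministic: tokens are indexed by (descending
    frequency, lexicographic) order after PAD=0 and UNK=1.
    """
    dialogues = list(dialogues)
    if not dialogues:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    if min_count < 1:
        logger.warning("min_count %d < 1; treating as 1", min_count)
        min_count = 1
    counts: dict[str, int] = {}
    for dlg in dialogues:
        for turn in dlg.turns:
            for tok in tokenizer(turn.text):
                counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    mapping = {PAD: 0, UNK: 1}
    for tok in kept:
        mapping[tok] = len(mapping)
    return Vocabulary(token_to_index=mapping, min_count=min_count)
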