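"""WordPiece-style text tokenization for cardiology reports.

Reports are lower-cased, whitespace/punctuation split, and encoded with a
greedy longest-match-first subword scheme over a vocabulary trained on the
report corpus: all single characters (word-initial and ``##``-continuation
forms) are always present so any in-alphabet string can be encoded, and the
most frequent whole words fill the remaining slots up to the requested size.
Sequences are padded/truncated to a fixed length N_L (default 64).
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass

import numpy as np

PAD, UNK, MASK = "[PAD]", "[UNK]", "[MASK]"
SPECIAL_TOKENS = (PAD, UNK, MASK)
PAD_ID, UNK_ID, MASK_ID = 0, 1, 2

DEFAULT_N_L = 64
DEFAULT_VOCAB_SIZE = 2048

_WORD_RE = re.compile(r"[a-z0-9]+|[^\sa-z0-9]")


def _pretokenize(text: str) -> list[str]:
    return _WORD_RE.findall(text.lower())


@dataclass
class Vocabulary:
    """Token <-> id bijection with reserved PAD/UNK/MASK ids."""

    token_to_id: dict[str, int]

    def __post_init__(self):
        for tok, want in zip(SPECIAL_TOKENS, (PAD_ID, UNK_ID, MASK_ID)):
            if self.token_to_id.get(tok) != want:
                raise ValueError(f"special token {tok} must have id {want}")
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}
        if len(self.id_to_token) != len(self.token_to_id):
            raise ValueError("token ids must be unique")

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.token_to_id, fh, indent=0)

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            return cls({t: int(i) for t, i in json.load(fh).items()})

    # -- encoding ---------------------------------------------------------
    def _encode_word(self, word: str) -> list[int]:
        """Greedy longest-match-first subword split of one word."""
        ids: list[int] = []
        start = 0
        while start < len(word):
            end = len(word)
            match = None
            while end > start:
                piece = word[start:end]
                if start > 0:
                    piece = "##" + piece
                if piece in self.token_to_id:
                    match = self.token_to_id[piece]
                    break
                end -= 1
            if match is None:
                ids.append(UNK_ID)
                start += 1
            else:
                ids.append(match)
                start = end
        return ids

    def encode(self, text: str) -> list[int]:
        ids: list[int] = []
        for word in _pretokenize(text):
            ids.extend(self._encode_word(word))
        return ids

    def decode(self, ids) -> str:
        words: list[str] = []
        for i in ids:
            tok = self.id_to_token.get(int(i), UNK)
            if tok == PAD:
                continue
            if tok.startswith("##") and words:
                words[-1] += tok[2:]
            else:
                words.append(tok)
        return " ".join(words)


def fit_vocabulary(corpus: list[str], size: int = DEFAULT_VOCAB_SIZE) -> Vocabulary:
    """Train a subword vocabulary on a report corpus.

    Deterministic given (corpus, size): character units first (guaranteeing
    total coverage of the corpus alphabet), then whole words by descending
    frequency with lexicographic tie-break.
    """
    if not corpus:
        raise ValueError("cannot fit a vocabulary on an empty corpus")
    if size <= len(SPECIAL_TOKENS):
        raise ValueError(f"vocabulary size must exceed {len(SPECIAL_TOKENS)}")
    word_counts: Counter[str] = Counter()
    alphabet: set[str] = set()
    for doc in corpus:
        for w in _pretokenize(doc):
            word_counts[w] += 1
            alphabet.update(w)
    tokens: list[str] = list(SPECIAL_TOKENS)
    for ch in sorted(alphabet):
        tokens.append(ch)
        tokens.append("##" + ch)
    for word, _ in sorted(word_counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if len(tokens) >= size:
            break
        if word not in tokens[len(SPECIAL_TOKENS):] and len(word) > 1:
            tokens.append(word)
    return Vocabulary({t: i for i, t in enumerate(tokens[:max(size, len(tokens))])})


@dataclass
class TextTokenIds:
    """Fixed-length id sequence: non-pad prefix followed by PAD suffix."""

    ids: np.ndarray        # (N_L,) int
    pad_mask: np.ndarray   # (N_L,) bool, True where padding

    @property
    def n_tokens(self) -> int:
        return len(self.ids)

    @property
    def n_nonpad(self) -> int:
        return int((~self.pad_mask).sum())


def encode_text(text: str, vocab: Vocabulary, n_l: int = DEFAULT_N_L) -> TextTokenIds:
    """Encode to exactly `n_l` ids; longer sequences are truncated from the
    right, shorter ones padded with PAD."""
    ids = vocab.encode(text)[:n_l]
    n = len(ids)
    out = np.full(n_l, PAD_ID, dtype=np.int64)
    out[:n] = ids
    pad_mask = np.arange(n_l) >= n
    return TextTokenIds(out, pad_mask)


__all__ = [
    "Vocabulary", "TextTokenIds", "fit_vocabulary", "encode_text",
    "PAD_ID", "UNK_ID", "MASK_ID", "DEFAULT_N_L", "DEFAULT_VOCAB_SIZE",
]
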