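"""Deterministic text encoding: tokenize, rank a vocabulary, map to integers.

The scheme is fixed: title and body are concatenated and lowercased; the
top-``size`` (default 5,000) words by raw training-corpus frequency get
indices 1..size; index 0 is reserved for padding and ``size + 1`` for the
single out-of-vocabulary integer; each post becomes the first ``max_len``
(default 300) token indices, end-padded with 0.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import Post

# Maximal runs of letters/digits with internal apostrophes preserved, so
# contractions like "don't" survive as single tokens.
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)*")

PAD_INDEX = 0
DEFAULT_VOCAB_SIZE = 5000
DEFAULT_MAX_LEN = 300


def tokenize(title: str, body: str = "") -> list[str]:
    """Lowercased tokens of title followed by body; punctuation discarded."""
    text = f"{title} {body}".lower().replace("’", "'")
    return _TOKEN_RE.findall(text)


def tokenize_post(post: Post) -> list[str]:
    return tokenize(post.title, post.body)


@dataclass
class Vocabulary:
    """Frequency-ranked word -> integer table with reserved indices.

    ``index`` maps each kept word to 1..n (descending raw frequency, ties
    broken lexicographically); ``oov_index`` (= n + 1) is the single integer
    shared by every word outside the table; 0 is padding.
    """

    index: dict[str, int]
    pad_index: int = PAD_INDEX
    total_tokens: int = 0
    frequencies: dict[str, int] = field(default_factory=dict, repr=False)

    @property
    def size(self) -> int:
        return len(self.index)

    @property
    def oov_index(self) -> int:
        return len(self.index) + 1

    @property
    def n_symbols(self) -> int:
        """Number of distinct integers a sequence can contain (pad..oov)."""
        return len(self.index) + 2

    def lookup(self, word: str) -> int:
        return self.index.get(word, self.oov_index)


@dataclass
class EncodedPost:
    """A post as a fixed-length integer sequence plus its label."""

    post_id: str
    sequence: np.ndarray
    label: str | None = None


def build_vocabulary(
    token_lists: Iterable[Sequence[str]], size: int = DEFAULT_VOCAB_SIZE
) -> Vocabulary:
    """Rank words of a (training) corpus by raw frequency and keep the top ``size``.

    Ties are broken lexicographically, so the table is a pure function of
    the corpus. Build this from the training split only: encoding held-out
    posts must never touch the table.
    """
    counts: Counter[str] = Counter()
    total = 0
    for tokens in token_lists:
        counts.update(tokens)
        total += len(tokens)
    if not counts:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:size]
    index = {word: i + 1 for i, (word, _) in enumerate(ranked)}
    return Vocabulary(index=index, total_tokens=total, frequencies=dict(ranked))


def encode_tokens(
    tokens: Sequence[str], vocab: Vocabulary, max_len: int = DEFAULT_MAX_LEN
) -> np.ndarray:
    """First ``max_len`` token indices, end-padded with the pad index."""
    seq = np.full(max_len, vocab.pad_index, dtype=np.int32)
    kept = tokens[:max_len]
    if kept:
        seq[: len(kept)] = [vocab.lookup(t) for t in kept]
    return seq


def encode(post: Post, vocab: Vocabulary, max_len: int = DEFAULT_MAX_LEN,
           label: str | None = None) -> EncodedPost:
    return EncodedPost(post.post_id, encode_tokens(tokenize_post(post), vocab, max_len), label)


def encode_corpus(
    posts: Sequence[Post], vocab: Vocabulary, max_len: int = DEFAULT_MAX_LEN
) -> np.ndarray:
    """Encode many posts into an (n_posts, max_len) int32 matrix."""
    mat = np.full((len(posts), max_len), vocab.pad_index, dtype=np.int32)
    for i, post in enumerate(posts):
        mat[i] = encode_tokens(tokenize_post(post), vocab, max_len)
    return mat


def oov_rate(posts: Sequence[Post], vocab: Vocabulary) -> float:
    """Fraction of tokens (before truncation) that fall outside the table."""
    total = 0
    oov = 0
    for post in posts:
        for tok in tokenize_post(post):
            total += 1
            if tok not in vocab.index:
                oov += 1
    return oov / total if total else 0.0


def save_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    """Persist as TSV (rank, word, frequency)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["#rank", "word", "frequency"])
        for word, rank in sorted(vocab.index.items(), key=lambda kv: kv[1]):
            w.writerow([rank, word, vocab.frequencies.get(word, 0)])


def load_vocabulary(path: str | Path) -> Vocabulary:
    index: dict[str, int] = {}
    freqs: dict[str, int] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            rank, word, freq = int(row[0]), row[1], int(row[2])
            index[word] = rank
            freqs[word] = freq
    total = sum(freqs.values())
    return Vocabulary(index=index, total_tokens=total, frequencies=freqs)
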