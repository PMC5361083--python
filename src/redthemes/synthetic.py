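"""Synthetic Reddit-like corpora with controllable theme structure.

The generator emulates the statistical skeleton the downstream analysis
relies on, without any linguistic realism: each disorder theme is a Zipf
word distribution over its own vocabulary, pairs of themes can share a
configurable fraction of their vocabularies (mimicking, e.g., the shared
language of opiate-addiction and alcoholism communities), every post mixes
theme words with a common background distribution, and a control stream of
pure-background posts is written by a configurable fraction of the same
authors, time-shifted so the 180-day index-date filter has a known
pass/fail structure.

Word "types" are opaque alphanumeric strings (``bpdw0012``, ``sh0809w0003``,
``bgw0457``) chosen to survive the downstream tokenizer unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import LabeledCorpus
from .corpus_io import CONTROL_LABEL, Post, load_theme_map

# Fixed 2-year posting window (2014-01-01 .. 2015-12-31 UTC).
WINDOW_START = 1388534400
WINDOW_DAYS = 730
SECONDS_PER_DAY = 86400

CONTROL_SUBREDDITS = (
    "AskReddit", "funny", "gaming", "movies", "Music", "pics",
    "todayilearned", "worldnews", "books", "sports", "technology", "food",
)

# Per-author post count: numpy's geometric (support >= 1, mean 2 at p=0.5).
_AUTHOR_GEOM_P = 0.5
# Negative-binomial document length: heavy-tailed like real posts.
_LENGTH_DISPERSION = 2.0
_MIN_LENGTH = 5
_ZIPF_EXPONENT = 1.3
_TITLE_TOKENS = 5


@dataclass(frozen=True)
class ThemeSpec:
    """One synthetic theme: posts drawn from its own word distribution."""

    name: str
    n_posts: int = 1000
    vocab_size: int = 350
    mean_length: float = 120.0
    subreddits: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_posts <= 0 or self.vocab_size <= 0 or self.mean_length <= 0:
            raise ValueError(f"theme {self.name!r}: counts must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of a synthetic corpus.

    ``overlap`` is a symmetric K x K matrix with unit diagonal; entry (i, j)
    is the fraction of the two themes' vocabularies they share.
    ``background_mix`` is the per-token probability that a theme post emits
    a background word instead of a theme word. ``author_overlap_fraction``
    is the fraction of control authors who also post in themes (only their
    control posts can survive the index-date filter downstream).
    """

    themes: tuple[ThemeSpec, ...]
    overlap: np.ndarray | None = None
    background_vocab_size: int = 1200
    background_mix: float = 0.3
    n_control_posts: int = 10000
    author_overlap_fraction: float = 1.0
    control_time_offset_days: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.themes)
        if k == 0:
            raise ValueError("at least one theme required")
        if len({t.name for t in self.themes}) != k:
            raise ValueError("theme names must be unique")
        ov = self.overlap
        if ov is None:
            ov = np.eye(k)
        ov = np.asarray(ov, dtype=float)
        if ov.shape != (k, k):
            raise ValueError(f"overlap matrix must be {k}x{k}")
        if not np.allclose(ov, ov.T):
            raise ValueError("overlap matrix must be symmetric")
        if not np.allclose(np.diag(ov), 1.0):
            raise ValueError("overlap matrix must have unit diagonal")
        if (ov < 0).any() or (ov > 1).any():
            raise ValueError("overlap entries must lie in [0, 1]")
        object.__setattr__(self, "overlap", ov)
        for name, val in [
            ("background_mix", self.background_mix),
            ("author_overlap_fraction", self.author_overlap_fraction),
        ]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.background_vocab_size <= 0 or self.n_control_posts < 0:
            raise ValueError("counts must be positive")
        # Shared-vocabulary allocations must fit inside each theme's vocabulary.
        for i, t in enumerate(self.themes):
            alloc = sum(
                self._shared_count(i, j)
                for j in range(k)
                if j != i and ov[i, j] > 0
            )
            if alloc > t.vocab_size:
                raise ValueError(
                    f"theme {t.name!r}: overlap allocations ({alloc}) exceed vocab_size"
                )

    def _shared_count(self, i: int, j: int) -> int:
        vi = self.themes[i].vocab_size
        vj = self.themes[j].vocab_size
        return int(round(self.overlap[i, j] * min(vi, vj)))


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower()) or "theme"


def _zipf_probs(n: int) -> np.ndarray:
    """Zipf weights over word ranks 1..n.

    Theme vocabularies are ordered shared-blocks-first (see
    ``_theme_vocabularies``), so words shared between two themes occupy the
    high-frequency core of both distributions: the common jargon of two
    related communities is their frequent shared language, while the
    distinguishing terms sit in the rarer tail. This is what makes a
    strongly-overlapping theme pair genuinely confusable post-by-post.
    """
    w = 1.0 / np.arange(1, n + 1) ** _ZIPF_EXPONENT
    return w / w.sum()


def _theme_vocabularies(config: GeneratorConfig) -> list[list[str]]:
    k = len(config.themes)
    vocabs: list[list[str]] = [[] for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            n_shared = config._shared_count(i, j)
            if n_shared:
                shared = [f"sh{i:02d}{j:02d}w{w:04d}" for w in range(n_shared)]
                vocabs[i].extend(shared)
                vocabs[j].extend(shared)
    for i, theme in enumerate(config.themes):
        slug = _slug(theme.name)
        n_unique = theme.vocab_size - len(vocabs[i])
        vocabs[i].extend(f"{slug}w{w:04d}" for w in range(n_unique))
    return vocabs


def _lengths(n: int, mean: float, rng: np.random.Generator) -> np.ndarray:
    p = _LENGTH_DISPERSION / (_LENGTH_DISPERSION + mean)
    return np.maximum(rng.negative_binomial(_LENGTH_DISPERSION, p, size=n), _MIN_LENGTH)


def _author_assignment(n_posts: int, prefix: str, rng: np.random.Generator) -> list[str]:
    """Assign posts to authors writing Geometric-many posts each."""
    authors: list[str] = []
    k = 0
    while len(authors) < n_posts:
        count = int(rng.geometric(_AUTHOR_GEOM_P))
        authors.extend([f"{prefix}a{k:06d}"] * count)
        k += 1
    return authors[:n_posts]


def _render(tokens: Sequence[str]) -> tuple[str, str]:
    title = " ".join(tokens[:_TITLE_TOKENS])
    body = " ".join(tokens[_TITLE_TOKENS:])
    return title, body


def generate_corpus(config: GeneratorConfig) -> LabeledCorpus:
    """Draw a corpus (theme posts + control stream) with ground-truth labels.

    Deterministic given ``config.seed``. Theme tokens are an i.i.d. mixture
    of (1 - background_mix) theme-distribution and background_mix
    background-distribution draws; control posts are pure background.
    Control authors in the overlapping fraction are theme authors whose
    control posts sit exactly ``control_time_offset_days`` before their
    earliest theme post; the remainder are fresh authors with uniform
    timestamps (they carry no index date downstream).
    """
    rng = np.random.default_rng(config.seed)
    theme_vocabs = _theme_vocabularies(config)
    background = [f"bgw{w:04d}" for w in range(config.background_vocab_size)]
    bg_probs = _zipf_probs(len(background))
    default_map = load_theme_map()

    posts: list[Post] = []
    labels: list[str] = []
    pid = 0
    earliest_theme_post: dict[str, int] = {}

    window = (WINDOW_START, WINDOW_START + WINDOW_DAYS * SECONDS_PER_DAY)
    for ti, theme in enumerate(config.themes):
        vocab = np.array(theme_vocabs[ti])
        probs = _zipf_probs(len(vocab))
        subs = theme.subreddits
        if subs is None:
            mapped = default_map.subreddits_of(theme.name)
            subs = tuple(mapped) if mapped else (theme.name,)
        lengths = _lengths(theme.n_posts, theme.mean_length, rng)
        authors = _author_assignment(theme.n_posts, f"u{_slug(theme.name)}", rng)
        created = rng.integers(window[0], window[1], size=theme.n_posts)
        sub_choice = rng.integers(0, len(subs), size=theme.n_posts)
        # Bulk-sample all tokens for the theme (as indices into the joint
        # word array, so mixed-length strings never truncate), then slice.
        all_words = np.concatenate([vocab, np.asarray(background)])
        total = int(lengths.sum())
        from_bg = rng.random(total) < config.background_mix
        n_bg = int(from_bg.sum())
        idx = np.empty(total, dtype=np.int64)
        idx[from_bg] = len(vocab) + rng.choice(len(background), size=n_bg, p=bg_probs)
        idx[~from_bg] = rng.choice(len(vocab), size=total - n_bg, p=probs)
        toks = all_words[idx]
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        for n in range(theme.n_posts):
            tokens = toks[offsets[n]: offsets[n + 1]].tolist()
            title, body = _render(tokens)
            author = authors[n]
            ts = int(created[n])
            prev = earliest_theme_post.get(author)
            if prev is None or ts < prev:
                earliest_theme_post[author] = ts
            posts.append(
                Post(
                    post_id=f"p{pid:07d}",
                    author=author,
                    created=ts,
                    subreddit=subs[sub_choice[n]],
                    title=title,
                    body=body,
                )
            )
            labels.append(theme.name)
            pid += 1

    # --- control stream: background-only posts -------------------------------
    n_ctrl = config.n_control_posts
    if n_ctrl:
        ctrl_authors_counts: list[int] = []
        while sum(ctrl_authors_counts) < n_ctrl:
            ctrl_authors_counts.append(int(rng.geometric(_AUTHOR_GEOM_P)))
        n_authors = len(ctrl_authors_counts)
        n_shared_authors = int(round(config.author_overlap_fraction * n_authors))
        theme_author_pool = sorted(earliest_theme_post)
        n_shared_authors = min(n_shared_authors, len(theme_author_pool))
        shared = rng.choice(theme_author_pool, size=n_shared_authors, replace=False)
        names = list(shared) + [f"uca{k:06d}" for k in range(n_authors - n_shared_authors)]
        offset = config.control_time_offset_days * SECONDS_PER_DAY

        lengths = _lengths(n_ctrl, _control_mean_length(config), rng)
        total = int(lengths.sum())
        bg_arr = np.asarray(background)
        toks = bg_arr[rng.choice(len(bg_arr), size=total, p=bg_probs)]
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        sub_choice = rng.integers(0, len(CONTROL_SUBREDDITS), size=n_ctrl)
        uniform_ts = rng.integers(window[0], window[1], size=n_ctrl)
        n = 0
        for author, count in zip(names, ctrl_authors_counts):
            for _ in range(count):
                if n >= n_ctrl:
                    break
                if author in earliest_theme_post:
                    ts = earliest_theme_post[author] - offset
                else:
                    ts = int(uniform_ts[n])
                tokens = toks[offsets[n]: offsets[n + 1]].tolist()
                title, body = _render(tokens)
                posts.append(
                    Post(
                        post_id=f"p{pid:07d}",
                        author=author,
                        created=ts,
                        subreddit=CONTROL_SUBREDDITS[sub_choice[n]],
                        title=title,
                        body=body,
                    )
                )
                labels.append(CONTROL_LABEL)
                pid += 1
                n += 1
    return LabeledCorpus(posts, labels)


def _control_mean_length(config: GeneratorConfig) -> float:
    return float(np.mean([t.mean_length for t in config.themes]))


@dataclass
class CorpusSummary:
    """Descriptive statistics of a labeled corpus (mental vs control sides)."""

    posts_per_subreddit: dict[str, int]
    n_mental_posts: int
    n_control_posts: int
    n_mental_authors: int
    n_control_authors: int
    n_shared_authors: int
    shared_control_author_fraction: float
    shared_mental_author_fraction: float
    mental_posts_by_shared_fraction: float


def corpus_summary(corpus: LabeledCorpus) -> CorpusSummary:
    """Per-subreddit counts and author-overlap statistics.

    The overlap statistics quantify how much of the author pool appears on
    both sides and what share of the mental-health posts the intersection
    authors wrote — on real data both fractions are small (throwaway
    accounts), which is the regime the binary classifier faces.
    """
    if not corpus.posts:
        raise ValueError("corpus is empty")
    per_sub: dict[str, int] = {}
    mental_authors: set[str] = set()
    control_authors: set[str] = set()
    n_mental = n_control = 0
    for post, label in zip(corpus.posts, corpus.labels):
        per_sub[post.subreddit] = per_sub.get(post.subreddit, 0) + 1
        if label == CONTROL_LABEL:
            control_authors.add(post.author)
            n_control += 1
        elif label is not None:
            mental_authors.add(post.author)
            n_mental += 1
    shared = mental_authors & control_authors
    by_shared = sum(
        1
        for post, label in zip(corpus.posts, corpus.labels)
        if label not in (None, CONTROL_LABEL) and post.author in shared
    )
    return CorpusSummary(
        posts_per_subreddit=per_sub,
        n_mental_posts=n_mental,
        n_control_posts=n_control,
        n_mental_authors=len(mental_authors),
        n_control_authors=len(control_authors),
        n_shared_authors=len(shared),
        shared_control_author_fraction=(
            len(shared) / len(control_authors) if control_authors else 0.0
        ),
        shared_mental_author_fraction=(
            len(shared) / len(mental_authors) if mental_authors else 0.0
        ),
        mental_posts_by_shared_fraction=by_shared / n_mental if n_mental else 0.0,
    )


def default_config(seed: int = 0, n_posts_per_theme: int = 1000) -> GeneratorConfig:
    """The standard study conditions: 11 themes, one strongly-overlapping pair.

    Theme names follow the default theme map; the Opiates and
    cripplingalcoholism vocabularies share half their words (both are
    substance-addiction communities with heavily shared language), and every
    post draws 30% of its tokens from the common background.
    """
    theme_map = load_theme_map()
    themes = tuple(
        ThemeSpec(name=name, n_posts=n_posts_per_theme) for name in theme_map.themes
    )
    k = len(themes)
    ov = np.eye(k)
    i = theme_map.themes.index("Opiates")
    j = theme_map.themes.index("cripplingalcoholism")
    ov[i, j] = ov[j, i] = 0.5
    return GeneratorConfig(
        themes=themes,
        overlap=ov,
        n_control_posts=10 * n_posts_per_theme,
        seed=seed,
    )


def ablation_config(seed: int = 0) -> GeneratorConfig:
    """Study conditions for the class-ablation experiment.

    depression is planted as a dominant, broadly comorbid class: 4x the
    posts of any other theme (~29% of the mental posts), a much larger
    vocabulary, and 50% vocabulary overlap with each of five related themes
    (anxiety, borderline, bipolar, self-harm, suicide-risk), on top of the
    standard Opiates/cripplingalcoholism pair. The related themes then
    write mostly in language depression also uses, so their posts are
    systematically drawn into the bigger class; removing it should sharpen
    the remaining classes — the signature the experiment looks for.
    """
    theme_map = load_theme_map()
    themes = tuple(
        ThemeSpec(name=name, n_posts=1600, vocab_size=900)
        if name == "depression"
        else ThemeSpec(name=name, n_posts=400)
        for name in theme_map.themes
    )
    names = theme_map.themes
    k = len(themes)
    ov = np.eye(k)
    pairs = [("Opiates", "cripplingalcoholism", 0.5)] + [
        ("depression", other, 0.5)
        for other in ("Anxiety", "BPD", "bipolar", "selfharm", "SuicideWatch")
    ]
    for a, b, o in pairs:
        i, j = names.index(a), names.index(b)
        ov[i, j] = ov[j, i] = o
    return GeneratorConfig(
        themes=themes, overlap=ov, n_control_posts=0, seed=seed
    )


def sample_planted_docs(
    word_sets: Sequence[Sequence[str]],
    n_docs: int,
    doc_length: int = 30,
    seed: int = 0,
) -> list[list[str]]:
    """Documents each drawn uniformly from ONE of several planted word sets.

    A degenerate topic-model benchmark: with disjoint sets, a fitted topic
    model should recover each set as (at least) one near-pure topic.
    """
    rng = np.random.default_rng(seed)
    docs = []
    for d in range(n_docs):
        ws = word_sets[d % len(word_sets)]
        docs.append([ws[i] for i in rng.integers(0, len(ws), size=doc_length)])
    return docs
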