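"""Cohort construction: subreddit discovery, theme labelling, temporal controls.

The control set is built with an index-date rule borrowed from
case-control epidemiology: an author's *index date* is the timestamp of
their earliest post in any mental-health subreddit, and only their posts in
other subreddits made at least ``window_days`` (default 180) before that
date qualify as controls. This keeps control text clinically distant in
time from the mental-health posting while drawing controls from the same
author pool.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .corpus_io import CONTROL_LABEL, Post, ThemeMap
from .preprocess import tokenize_post

SECONDS_PER_DAY = 86400


@dataclass
class LabeledCorpus:
    """Posts with one label each: a theme name, ``control``, or None (unlabeled)."""

    posts: list[Post]
    labels: list[str | None]

    def __post_init__(self) -> None:
        if len(self.posts) != len(self.labels):
            raise ValueError("labels and posts must have equal length")

    def __len__(self) -> int:
        return len(self.posts)

    def label_counts(self) -> Counter:
        return Counter(l for l in self.labels if l is not None)

    def subset(self, keep: set[str]) -> "LabeledCorpus":
        pairs = [(p, l) for p, l in zip(self.posts, self.labels) if l in keep]
        return LabeledCorpus([p for p, _ in pairs], [l for _, l in pairs])

    def mental(self, theme_map: ThemeMap) -> "LabeledCorpus":
        return self.subset(set(theme_map.themes))


@dataclass
class AuthorIndex:
    """author -> timestamp of that author's earliest mental-health post."""

    index_dates: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_labeled(cls, labeled: LabeledCorpus) -> "AuthorIndex":
        dates: dict[str, int] = {}
        for post, label in zip(labeled.posts, labeled.labels):
            if label is not None and label != CONTROL_LABEL:
                prev = dates.get(post.author)
                if prev is None or post.created < prev:
                    dates[post.author] = post.created
        return cls(dates)


def discover_subreddits(
    posts: list[Post], keywords: list[str], min_posts: int = 1
) -> list[tuple[str, float]]:
    """Rank subreddits by the fraction of their posts that hit a keyword.

    A hit is a whole lowercase token of the concatenated title+body matching
    any keyword. Subreddits with fewer than ``min_posts`` posts are dropped;
    the rest are ordered by descending score, then descending post count,
    then name.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    kw = {k.lower() for k in keywords}
    hits: Counter[str] = Counter()
    totals: Counter[str] = Counter()
    for post in posts:
        totals[post.subreddit] += 1
        if kw.intersection(tokenize_post(post)):
            hits[post.subreddit] += 1
    scored = [
        (sub, hits[sub] / n, n) for sub, n in totals.items() if n >= min_posts
    ]
    scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return [(sub, score) for sub, score, _ in scored]


def label_corpus(posts: list[Post], theme_map: ThemeMap) -> LabeledCorpus:
    """Attach theme labels from the subreddit mapping; others stay unlabeled.

    Unlabeled posts are the candidate pool for control construction.
    """
    labels = [theme_map.theme_of(p.subreddit) for p in posts]
    return LabeledCorpus(list(posts), labels)


def build_control(
    posts: list[Post],
    labeled: LabeledCorpus,
    window_days: int = 180,
) -> list[Post]:
    """Select control posts by the index-date rule.

    For each author with mental-health posts (a theme label in ``labeled``),
    keep their posts in non-mental subreddits whose timestamp is at least
    ``window_days`` days older than the author's index date (boundary
    inclusive: exactly ``window_days`` qualifies). Authors with no
    mental-health posts contribute nothing: controls come from the same
    author pool.
    """
    if window_days < 0:
        raise ValueError("window_days must be non-negative")
    index = AuthorIndex.from_labeled(labeled)
    cutoff = {a: d - window_days * SECONDS_PER_DAY for a, d in index.index_dates.items()}
    mental_subs = {
        p.subreddit
        for p, lab in zip(labeled.posts, labeled.labels)
        if lab is not None and lab != CONTROL_LABEL
    }
    control: list[Post] = []
    for post in posts:
        if post.subreddit in mental_subs:
            continue
        limit = cutoff.get(post.author)
        if limit is not None and post.created <= limit:
            control.append(post)
    return control


def attach_control_labels(labeled: LabeledCorpus, control: list[Post]) -> LabeledCorpus:
    """Return a copy of ``labeled`` with control posts labeled ``control``."""
    control_ids = {p.post_id for p in control}
    labels = [
        CONTROL_LABEL if (lab is None and p.post_id in control_ids) else lab
        for p, lab in zip(labeled.posts, labeled.labels)
    ]
    return LabeledCorpus(labeled.posts, labels)
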