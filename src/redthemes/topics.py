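"""Theme cohesion checks via per-theme topic models.

Each theme's posts (all member subreddits pooled) are lowercased,
tokenized, stripped of a frozen English stopword list, and fit with a
10-topic Latent Dirichlet Allocation model. If the subreddit grouping is
cohesive, the per-topic keyword lists should read as aspects of the theme
(symptoms, medications, consequences); on synthetic corpora with planted
word sets the topics recover the plants.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer

from .corpus_io import Post, load_stopwords
from .preprocess import tokenize_post

DEFAULT_N_TOPICS = 10


@dataclass
class TopicModelResult:
    """A fitted per-theme topic model: ranked (word, weight) lists per topic.

    Weights are each topic's word distribution (they sum to 1); within a
    topic words are ordered by descending weight, ties broken
    lexicographically. ``metadata`` records the estimator settings actually
    used so a result is reproducible from the record alone.
    """

    theme: str
    topics: list[list[tuple[str, float]]]
    n_topics: int
    seed: int
    metadata: dict = field(default_factory=dict)


def _documents(theme_posts: Sequence[Post], stopwords: frozenset[str]) -> list[list[str]]:
    docs = []
    for post in theme_posts:
        toks = [t for t in tokenize_post(post) if t not in stopwords]
        if toks:
            docs.append(toks)
    return docs


def fit_theme_topics(
    theme_posts: Sequence[Post] | Sequence[Sequence[str]],
    n_topics: int = DEFAULT_N_TOPICS,
    seed: int = 0,
    theme: str = "",
) -> TopicModelResult:
    """Fit an ``n_topics``-topic LDA model on one theme's pooled posts.

    Accepts either Post objects (tokenized and stopword-filtered here) or
    pre-tokenized documents (filtered against the same stopword list).
    Deterministic given the seed. Raises if fewer usable documents than
    topics remain — lower ``n_topics`` in that case.
    """
    stopwords = load_stopwords()
    if theme_posts and isinstance(theme_posts[0], Post):
        docs = _documents(theme_posts, stopwords)  # type: ignore[arg-type]
    else:
        docs = [
            [t for t in doc if t not in stopwords] for doc in theme_posts
        ]
        docs = [d for d in docs if d]
    if len(docs) < n_topics:
        raise ValueError(
            f"{len(docs)} usable documents < {n_topics} topics; lower n_topics"
        )
    vectorizer = CountVectorizer(analyzer=lambda d: d)
    counts = vectorizer.fit_transform(docs)
    words = vectorizer.get_feature_names_out()
    lda = LatentDirichletAllocation(n_components=n_topics, random_state=seed)
    lda.fit(counts)
    dists = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    topics = []
    for row in dists:
        order = np.lexsort((words, -row))
        topics.append([(str(words[i]), float(row[i])) for i in order])
    return TopicModelResult(
        theme=theme,
        topics=topics,
        n_topics=n_topics,
        seed=seed,
        metadata={
            "implementation": "sklearn.LatentDirichletAllocation",
            "max_iter": lda.max_iter,
            "learning_method": lda.learning_method,
            "doc_topic_prior": lda.doc_topic_prior,
            "topic_word_prior": lda.topic_word_prior,
            "n_documents": len(docs),
            "vocabulary_size": len(words),
        },
    )


def top_keywords(result: TopicModelResult, k: int = 10) -> list[list[str]]:
    """The ``k`` highest-weight words of each topic."""
    if any(len(t) < k for t in result.topics):
        raise ValueError(f"k={k} exceeds the model vocabulary")
    return [[w for w, _ in topic[:k]] for topic in result.topics]


def save_topics_tsv(result: TopicModelResult, path: str | Path, k: int = 10) -> None:
    """Persist as TSV (theme, topic_index, rank, word, weight)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["#theme", "topic", "rank", "word", "weight"])
        for ti, topic in enumerate(result.topics):
            for rank, (word, weight) in enumerate(topic[:k], start=1):
                w.writerow([result.theme, ti, rank, word, f"{weight:.6g}"])
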