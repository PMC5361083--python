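"""Shared fixtures: small hand-built corpora and one full-scale synthetic run."""

from __future__ import annotations

import numpy as np
import pytest

import redthemes as rt
from redthemes import pipeline

DAY = 86400
T0 = 1_400_000_000  # an arbitrary mid-2014 anchor timestamp


def make_post(post_id="p1", author="alice", created=T0, subreddit="depression",
              title="", body="") -> rt.Post:
    return rt.Post(post_id=post_id, author=author, created=created,
                   subreddit=subreddit, title=title, body=body)


@pytest.fixture(scope="session")
def theme_map() -> rt.ThemeMap:
    return rt.load_theme_map()


@pytest.fixture(scope="session")
def study_corpus() -> rt.LabeledCorpus:
    """The standard study conditions: 11 themes x 1,000 posts + controls."""
    return rt.generate_corpus(rt.default_config(seed=0))


@pytest.fixture(scope="session")
def study_datasets(study_corpus, theme_map):
    """(labeled, binary, multiclass) datasets derived from the study corpus."""
    return pipeline.build_datasets(study_corpus.posts, theme_map, window_days=180)


@pytest.fixture(scope="session")
def small_corpus() -> rt.LabeledCorpus:
    """A light corpus (3 themes) for fast unit tests."""
    cfg = rt.GeneratorConfig(
        themes=(
            rt.ThemeSpec("depression", n_posts=120, vocab_size=80, mean_length=40),
            rt.ThemeSpec("Anxiety", n_posts=120, vocab_size=80, mean_length=40),
            rt.ThemeSpec("bipolar", n_posts=120, vocab_size=80, mean_length=40),
        ),
        background_vocab_size=150,
        background_mix=0.2,
        n_control_posts=200,
        seed=7,
    )
    return rt.generate_corpus(cfg)
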