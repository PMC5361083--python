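"""Generator contracts: determinism, vocabulary overlap, authors, timestamps."""

import json

import numpy as np
import pytest

import redthemes as rt
from redthemes.preprocess import tokenize_post
from redthemes.synthetic import SECONDS_PER_DAY, sample_planted_docs


def two_theme_config(overlap=0.0, mix=0.0, n_posts=100, vocab=200, seed=3,
                     n_control=0, **kw):
    ov = np.array([[1.0, overlap], [overlap, 1.0]])
    return rt.GeneratorConfig(
        themes=(
            rt.ThemeSpec("alpha", n_posts=n_posts, vocab_size=vocab, mean_length=100),
            rt.ThemeSpec("beta", n_posts=n_posts, vocab_size=vocab, mean_length=100),
        ),
        overlap=ov,
        background_mix=mix,
        n_control_posts=n_control,
        seed=seed,
        **kw,
    )


def theme_token_types(corpus, theme):
    types = set()
    for post, label in zip(corpus.posts, corpus.labels):
        if label == theme:
            types.update(tokenize_post(post))
    return types


class TestConfigValidation:
    def test_asymmetric_overlap_rejected(self):
        ov = np.array([[1.0, 0.3], [0.1, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            rt.GeneratorConfig(themes=two_theme_config().themes, overlap=ov)

    def test_nonunit_diagonal_rejected(self):
        ov = np.array([[0.9, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="unit diagonal"):
            rt.GeneratorConfig(themes=two_theme_config().themes, overlap=ov)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError, match="background_mix"):
            rt.GeneratorConfig(themes=two_theme_config().themes, background_mix=1.5)

    def test_overlap_allocation_must_fit_vocab(self):
        themes = (
            rt.ThemeSpec("a", vocab_size=100),
            rt.ThemeSpec("b", vocab_size=100),
            rt.ThemeSpec("c", vocab_size=100),
        )
        ov = np.ones((3, 3)) * 0.6
        np.fill_diagonal(ov, 1.0)
        with pytest.raises(ValueError, match="exceed"):
            rt.GeneratorConfig(themes=themes, overlap=ov)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rt.ThemeSpec("a", n_posts=0)


class TestGenerateCorpus:
    def test_same_seed_gives_byte_identical_corpora(self):
        c1 = rt.generate_corpus(two_theme_config(seed=5, n_control=50))
        c2 = rt.generate_corpus(two_theme_config(seed=5, n_control=50))
        dump = lambda c: json.dumps([vars(p) for p in c.posts]) + json.dumps(c.labels)
        assert dump(c1) == dump(c2)
        c3 = rt.generate_corpus(two_theme_config(seed=6, n_control=50))
        assert dump(c1) != dump(c3)

    def test_zero_overlap_zero_mix_yields_disjoint_supports(self):
        c = rt.generate_corpus(two_theme_config(overlap=0.0, mix=0.0))
        assert not theme_token_types(c, "alpha") & theme_token_types(c, "beta")

    def test_half_overlap_realised_in_emitted_types(self):
        # brute-force shared-type count over the emitted corpus: with
        # overlap 0.5 and ~10,000 tokens per theme the realised shared
        # fraction should sit near one half
        c = rt.generate_corpus(two_theme_config(overlap=0.5, mix=0.0, seed=11))
        a = theme_token_types(c, "alpha")
        b = theme_token_types(c, "beta")
        frac = len(a & b) / np.mean([len(a), len(b)])
        assert abs(frac - 0.5) <= 0.05

    def test_overlap_monotonicity_in_jaccard(self):
        jac = []
        for o in (0.0, 0.3, 0.7):
            c = rt.generate_corpus(two_theme_config(overlap=o, mix=0.0, seed=2))
            a, b = theme_token_types(c, "alpha"), theme_token_types(c, "beta")
            jac.append(len(a & b) / len(a | b))
        assert jac[0] <= jac[1] <= jac[2]
        assert jac[0] == 0.0 and jac[2] > jac[1] > 0.0

    def test_every_post_has_exactly_one_label_and_unique_id(self, small_corpus):
        assert len(small_corpus.posts) == len(small_corpus.labels)
        assert all(l is not None for l in small_corpus.labels)
        ids = [p.post_id for p in small_corpus.posts]
        assert len(set(ids)) == len(ids)

    def test_minimum_document_length_and_title_split(self, small_corpus):
        for post in small_corpus.posts:
            toks = tokenize_post(post)
            assert len(toks) >= 5
            assert len(post.title.split()) == min(5, len(toks))

    def test_theme_posts_land_in_mapped_subreddits(self, study_corpus, theme_map):
        for post, label in zip(study_corpus.posts, study_corpus.labels):
            if label != rt.CONTROL_LABEL:
                assert theme_map.theme_of(post.subreddit) == label
            else:
                assert theme_map.theme_of(post.subreddit) is None

    def test_control_posts_are_pure_background(self, small_corpus):
        for post, label in zip(small_corpus.posts, small_corpus.labels):
            if label == rt.CONTROL_LABEL:
                assert all(t.startswith("bgw") for t in tokenize_post(post))

    def test_overlapping_control_author_timestamps_follow_offset_rule(self):
        cfg = two_theme_config(n_control=80, seed=9, control_time_offset_days=200,
                               author_overlap_fraction=1.0)
        c = rt.generate_corpus(cfg)
        earliest = {}
        for p, l in zip(c.posts, c.labels):
            if l != rt.CONTROL_LABEL:
                earliest[p.author] = min(earliest.get(p.author, np.inf), p.created)
        for p, l in zip(c.posts, c.labels):
            if l == rt.CONTROL_LABEL:
                assert p.author in earliest
                assert p.created == earliest[p.author] - 200 * SECONDS_PER_DAY


class TestCorpusSummary:
    def test_disjoint_author_sets_have_zero_intersection(self):
        posts = [
            rt.Post("p1", "a1", 0, "depression", "t", "b"),
            rt.Post("p2", "a2", 0, "funny", "t", "b"),
        ]
        s = rt.corpus_summary(rt.LabeledCorpus(posts, ["depression", "control"]))
        assert s.n_shared_authors == 0

    def test_single_author_on_both_sides(self):
        posts = [
            rt.Post("p1", "a", 0, "depression", "t", "b"),
            rt.Post("p2", "a", 0, "funny", "t", "b"),
        ]
        s = rt.corpus_summary(rt.LabeledCorpus(posts, ["depression", "control"]))
        assert s.n_shared_authors == 1
        assert s.shared_control_author_fraction == 1.0
        assert s.mental_posts_by_shared_fraction == 1.0

    def test_author_overlap_fraction_recovered(self):
        cfg = two_theme_config(n_posts=800, n_control=800, seed=21,
                               author_overlap_fraction=0.1)
        s = rt.corpus_summary(rt.generate_corpus(cfg))
        assert abs(s.shared_control_author_fraction - 0.1) < 0.03

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            rt.corpus_summary(rt.LabeledCorpus([], []))


def test_planted_docs_cover_each_set():
    sets = [[f"a{i}" for i in range(10)], [f"b{i}" for i in range(10)]]
    docs = sample_planted_docs(sets, n_docs=10, doc_length=20, seed=1)
    assert len(docs) == 10
    for doc in docs:
        prefixes = {t[0] for t in doc}
        assert len(prefixes) == 1  # each doc drawn from exactly one set
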