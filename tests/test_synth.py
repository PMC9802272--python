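"""The synthetic-corpus generator: determinism, planted-label semantics,
prevalence recovery, mixing distribution, and gold evaluation."""

import numpy as np
import pytest
from scipy import stats

from ibdtopics import (
    GeneratorConfig,
    classify_corpus,
    distress_filter,
    generate,
    gold_evaluation,
    implied_prevalence,
    write_corpus,
)
from ibdtopics.corpus import TWEET_MAX_CHARS
from ibdtopics.lexicons import (
    CANONICAL_TOPICS,
    default_distress,
    default_false_positives,
    default_topics,
)
from ibdtopics.synth import GeneratorError
from ibdtopics.topics import TopicAssignment


def originals(corpus):
    return [p for p in corpus if p.extra.get("synthetic_role") == "original"]


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = dict(seed=42, n_posts={"reddit": 150, "twitter": 150})
        p1 = write_corpus(generate(GeneratorConfig(**cfg)), tmp_path / "a.jsonl")
        p2 = write_corpus(generate(GeneratorConfig(**cfg)), tmp_path / "b.jsonl")
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        a = generate(GeneratorConfig(seed=1, n_posts={"reddit": 50}))
        b = generate(GeneratorConfig(seed=2, n_posts={"reddit": 50}))
        assert [p.text for p in a] != [p.text for p in b]


class TestPlantedStructure:
    def test_distress_rate_zero_plants_no_markers(self, tmp_path):
        corpus = generate(GeneratorConfig(
            seed=3, n_posts={"reddit": 200, "twitter": 200}, distress_rate=0.0,
        ))
        out, _ = distress_filter(corpus, default_distress())
        assert out.N == 0

    def test_tweets_respect_length_cap(self):
        corpus = generate(GeneratorConfig(seed=9, n_posts={"twitter": 300}))
        assert all(
            len(p.text) <= TWEET_MAX_CHARS for p in corpus if p.platform == "twitter"
        )

    def test_signal_terms_appear_iff_gold_topic(self):
        corpus = generate(GeneratorConfig(
            seed=11, n_posts={"reddit": 200}, fp_trap_rate=0.0,
        ))
        assignments = classify_corpus(
            corpus, default_topics(), default_false_positives()
        )
        for post, a in zip(corpus, assignments):
            if post.extra["synthetic_role"] == "original":
                assert a.topics == set(post.gold_labels.topics)

    def test_infeasible_tweet_content_raises(self):
        cfg = GeneratorConfig(seed=0, n_posts={"twitter": 5})
        cfg.distress_markers = ["afraid " * 60]  # ~420 chars, cannot fit
        cfg.distress_rate = 1.0
        with pytest.raises(GeneratorError, match="280"):
            generate(cfg)

    def test_strict_mode_rejects_overlapping_vocabularies(self):
        with pytest.raises(GeneratorError, match="disjoint"):
            GeneratorConfig(signal_terms={
                "symptoms": ["flare"], "medication": ["flare"],
            })

    def test_probabilities_validated(self):
        with pytest.raises(GeneratorError):
            GeneratorConfig(distress_rate=1.5)


class TestPrevalenceRecovery:
    def test_independent_mode_within_binomial_99ci(self):
        prevalence = GeneratorConfig().topic_prevalence
        cfg = GeneratorConfig(
            seed=2024, n_posts={"reddit": 1000, "twitter": 1000},
            label_mode="independent", irrelevant_rate=0.0,
            duplicate_rate=0.0, retweet_rate=0.0,
        )
        corpus = generate(cfg)
        assignments = classify_corpus(
            corpus, default_topics(), default_false_positives()
        )
        n = len(assignments)
        for topic, p in prevalence.items():
            k = sum(topic in a.topics for a in assignments)
            lo, hi = stats.binom.interval(0.99, n, p)
            assert lo <= k <= hi, f"{topic}: {k} outside [{lo}, {hi}]"

    def test_mixture_mode_matches_implied_prevalence(self):
        cfg = GeneratorConfig(
            seed=77, n_posts={"reddit": 1500}, irrelevant_rate=0.0,
            duplicate_rate=0.0, retweet_rate=0.0,
        )
        corpus = generate(cfg)
        implied = implied_prevalence(cfg)
        n = corpus.N
        for topic, p in implied.items():
            k = sum(topic in p_.gold_labels.topics for p_ in corpus)
            lo, hi = stats.binom.interval(0.999, n, p)
            assert lo <= k <= hi, f"{topic}: {k} outside [{lo}, {hi}] for p={p:.3f}"

    def test_implied_prevalence_sums_to_expected_topic_count(self):
        cfg = GeneratorConfig()
        implied = implied_prevalence(cfg)
        expected_k = sum(k * p for k, p in cfg.multi_topic_mixing.items())
        assert sum(implied.values()) == pytest.approx(expected_k, abs=1e-9)

    def test_mixing_distribution_chi_square(self):
        cfg = GeneratorConfig(
            seed=5, n_posts={"reddit": 1000, "twitter": 1000},
            irrelevant_rate=0.0, duplicate_rate=0.0, retweet_rate=0.0,
        )
        corpus = generate(cfg)
        counts = np.zeros(5)
        for p in originals(corpus):
            counts[min(len(p.gold_labels.topics), 4)] += 1
        expected = np.array([cfg.multi_topic_mixing[k] for k in range(5)]) * counts.sum()
        _, pval = stats.chisquare(counts, expected)
        assert pval > 0.01


@pytest.fixture(scope="module")
def trap_corpus():
    return generate(GeneratorConfig(
        seed=31, n_posts={"reddit": 1000}, fp_trap_rate=0.1,
        irrelevant_rate=0.0, duplicate_rate=0.0, retweet_rate=0.0,
    ))


class TestFalsePositiveTraps:

    def test_disabled_elimination_shows_false_positives(self, trap_corpus):
        assignments = classify_corpus(
            trap_corpus, default_topics(), default_false_positives(), fp_mode="off"
        )
        ev = gold_evaluation(assignments, trap_corpus)
        pooled_fp = sum(s.fp for s in ev.per_topic.values())
        assert pooled_fp > 0
        assert ev.micro_precision < 1.0

    def test_enabled_elimination_restores_exact_recovery(self, trap_corpus):
        assignments = classify_corpus(
            trap_corpus, default_topics(), default_false_positives(), fp_mode="overlap"
        )
        ev = gold_evaluation(assignments, trap_corpus)
        assert all(s.fp == 0 for s in ev.per_topic.values())
        assert ev.micro_precision == 1.0 and ev.micro_recall == 1.0

    def test_confusable_mode_exercises_precision_below_one(self):
        corpus = generate(GeneratorConfig(
            seed=13, n_posts={"reddit": 600}, vocabulary_mode="confusable",
            irrelevant_rate=0.0, duplicate_rate=0.0, retweet_rate=0.0,
        ))
        assignments = classify_corpus(
            corpus, default_topics(), default_false_positives()
        )
        ev = gold_evaluation(assignments, corpus)
        assert ev.micro_recall == 1.0
        assert ev.micro_precision < 1.0


class TestGoldEvaluation:
    def test_perfect_assignments_score_one(self, make_corpus, make_post):
        corpus = make_corpus(
            make_post("a", gold_topics={"symptoms"}),
            make_post("b", gold_topics={"stigma", "ostomy"}),
        )
        assignments = [
            TopicAssignment(post_id=p.post_id, topics=set(p.gold_labels.topics))
            for p in corpus
        ]
        ev = gold_evaluation(assignments, corpus)
        for t in ("symptoms", "stigma", "ostomy"):
            assert ev.per_topic[t].precision == 1.0
            assert ev.per_topic[t].recall == 1.0

    def test_empty_assignments_undefined_precision(self, make_corpus, make_post):
        corpus = make_corpus(make_post("a", gold_topics={"symptoms"}))
        ev = gold_evaluation([], corpus)
        assert ev.per_topic["symptoms"].recall == 0.0
        assert ev.per_topic["symptoms"].precision is None
        assert ev.micro_precision is None

    def test_corpus_without_gold_labels_rejected(self, make_corpus):
        corpus = make_corpus("no labels here")
        with pytest.raises(GeneratorError, match="gold"):
            gold_evaluation([], corpus)
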