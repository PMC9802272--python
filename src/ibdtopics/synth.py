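"""Seeded synthetic Reddit/Twitter-like corpora with gold labels.

The pipeline under test is purely lexical, so the generator emulates only
the lexical and structural features the pipeline reacts to: platform
length regimes (tweets <= 280 characters, long-form reddit posts),
hashtags, hyperlinks, same-user duplicates, retweets, off-topic noise,
planted distress markers, and planted topic labels whose signal terms are
exactly what the shipped topic dictionary matches.  Text realism beyond
that (grammar, discourse) is deliberately absent.

Two gold-label models are available:

``independent``
    each topic is an independent Bernoulli draw at its configured
    prevalence — the model under which classifier-recovered prevalence
    has an exact binomial reference distribution;
``mixture`` (default)
    a per-post topic *count* is drawn from the configured mixing
    distribution (truncated geometric on {0..4} by default) and that many
    distinct topics are then drawn successively without replacement with
    probability proportional to the prevalence weights.  The implied
    marginal prevalence of each topic is computable exactly with
    :func:`implied_prevalence`.

In ``strict`` vocabulary mode the per-topic signal vocabularies are
pairwise disjoint and disjoint from background filler, so the shipped
dictionary recovers gold labels exactly; ``confusable`` mode plants a
shared ambiguous term to exercise precision < 1 paths.  False-positive
traps (e.g. "tired of explaining") are inserted independently of gold
labels and are only neutralized by the false-positive dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Iterable, Optional, Sequence

import numpy as np

from .corpus import Corpus, GoldLabels, Post, TWEET_MAX_CHARS
from .lexicons import CANONICAL_TOPICS
from .topics import TopicAssignment


class GeneratorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

#: Per-topic signal terms: pairwise disjoint, disjoint from filler and from
#: every distress marker, each present in the shipped topic dictionary.
DEFAULT_SIGNAL_TERMS: dict[str, list[str]] = {
    "symptoms": ["flare", "diarrhea", "cramps", "bleeding", "nausea", "fatigue"],
    "medication": ["stelara", "prednisone", "humira", "remicade", "meds"],
    "nutrition": ["fodmap", "fiber", "gluten", "dairy"],
    "procedures": ["colonoscopy", "surgery", "endoscopy", "resection"],
    "marijuana": ["weed", "cannabis", "marijuana", "cbd"],
    "stigma": ["stigma", "taboo", "embarrassing"],
    "ostomy": ["ostomy", "stoma", "ileostomy", "colostomy"],
    "intimacy": ["intimacy", "dating", "relationship", "partner"],
}

#: False-positive trap phrases: each embeds an ambiguous term of its topic
#: dictionary in a non-topical sense, and each appears verbatim in the
#: shipped false-positive dictionary.
DEFAULT_TRAP_PHRASES: dict[str, str] = {
    "symptoms": "tired of explaining",
    "medication": "war on drugs",
    "nutrition": "diet coke",
    "procedures": "plastic surgery",
    "marijuana": "pot of coffee",
    "stigma": "what a shame",
    "ostomy": "shopping bag",
    "intimacy": "expiration date",
}

DEFAULT_DISTRESS_MARKERS: list[str] = [
    "afraid", "scared", "worried", "overwhelmed", "feel alone", "hard to manage",
]

DEFAULT_FILLER: list[str] = [
    "today", "really", "people", "think", "going", "know", "about", "still",
    "maybe", "because", "trying", "thread", "forum", "question", "advice",
    "experience", "anyone", "else", "wondering", "honestly", "started",
    "reading", "community", "everyone", "thanks", "support", "group",
    "sharing", "weekend", "doctor", "appointment", "morning", "update",
]

DEFAULT_KEYWORD_PHRASES: list[str] = [
    "living with crohns", "my ibd", "my ulcerative colitis",
    "dealing with inflammatory bowel disease", "this crohns thing",
]

DEFAULT_HASHTAGS: list[str] = [
    "ibd", "crohns", "colitis", "ibdawareness", "guthealth", "spoonie",
    "chronicillness",
]

DEFAULT_SUBREDDITS: list[tuple[str, float]] = [
    ("CrohnsDisease", 0.30), ("AskReddit", 0.15), ("UlcerativeColitis", 0.10),
    ("IBD", 0.08), ("ibs", 0.07), ("AskDocs", 0.06), ("ostomy", 0.05),
    ("relationships", 0.05), ("offmychest", 0.07), ("Advice", 0.07),
]

#: In ``confusable`` mode this term is planted in posts of *any* topic but
#: belongs to the symptoms dictionary, producing symptoms false positives.
CONFUSABLE_TERM = ("gut", "symptoms")


def _default_mixing() -> dict[int, float]:
    """Truncated geometric on {0..4} with ratio 1/2."""
    raw = {k: 0.5 ** k for k in range(5)}
    z = sum(raw.values())
    return {k: v / z for k, v in raw.items()}


def _default_prevalence() -> dict[str, float]:
    """Study-scale topic prevalences (long-form platform profile)."""
    return {
        "symptoms": 0.57, "medication": 0.30, "nutrition": 0.27,
        "procedures": 0.17, "marijuana": 0.08, "stigma": 0.04,
        "ostomy": 0.03, "intimacy": 0.02,
    }


@dataclass
class GeneratorConfig:
    """Knobs for one synthetic corpus.  All randomness flows from ``seed``."""

    seed: int = 0
    n_posts: dict[str, int] = field(
        default_factory=lambda: {"reddit": 2000, "twitter": 2000}
    )
    topic_prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    multi_topic_mixing: dict[int, float] = field(default_factory=_default_mixing)
    label_mode: str = "mixture"  # or "independent"
    vocabulary_mode: str = "strict"  # or "confusable"
    distress_rate: float = 0.40
    fp_trap_rate: float = 0.10
    duplicate_rate: float = 0.05
    retweet_rate: float = 0.10
    hashtag_rate: float = 0.31
    hyperlink_rate: dict[str, float] = field(
        default_factory=lambda: {"reddit": 0.04, "twitter": 0.25}
    )
    irrelevant_rate: float = 0.05
    confusable_rate: float = 0.20
    filler_words: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"reddit": (10, 40), "twitter": (2, 8)}
    )
    signal_terms: dict[str, list[str]] = field(
        default_factory=lambda: {t: list(v) for t, v in DEFAULT_SIGNAL_TERMS.items()}
    )
    trap_phrases: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TRAP_PHRASES)
    )
    distress_markers: list[str] = field(
        default_factory=lambda: list(DEFAULT_DISTRESS_MARKERS)
    )

    def __post_init__(self) -> None:
        rates = [
            self.distress_rate, self.fp_trap_rate, self.duplicate_rate,
            self.retweet_rate, self.hashtag_rate, self.irrelevant_rate,
            self.confusable_rate, *self.topic_prevalence.values(),
            *self.multi_topic_mixing.values(), *self.hyperlink_rate.values(),
        ]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise GeneratorError("all probabilities must lie in [0, 1]")
        if self.label_mode not in ("mixture", "independent"):
            raise GeneratorError(f"unknown label_mode {self.label_mode!r}")
        if self.vocabulary_mode not in ("strict", "confusable"):
            raise GeneratorError(f"unknown vocabulary_mode {self.vocabulary_mode!r}")
        if abs(sum(self.multi_topic_mixing.values()) - 1.0) > 1e-9:
            raise GeneratorError("multi_topic_mixing must sum to 1")
        if self.vocabulary_mode == "strict":
            self._check_disjoint()

    def _check_disjoint(self) -> None:
        seen: dict[str, str] = {}
        for topic, terms in self.signal_terms.items():
            for term in terms:
                if term in seen:
                    raise GeneratorError(
                        f"strict mode requires disjoint signal vocabularies: "
                        f"{term!r} in both {seen[term]!r} and {topic!r}"
                    )
                seen[term] = topic
        filler_overlap = set(seen) & set(DEFAULT_FILLER)
        if filler_overlap:
            raise GeneratorError(f"signal terms collide with filler: {filler_overlap}")

    @property
    def topics(self) -> list[str]:
        return [t for t in CANONICAL_TOPICS if t in self.topic_prevalence] + sorted(
            t for t in self.topic_prevalence if t not in CANONICAL_TOPICS
        )


# ---------------------------------------------------------------------------
# Gold-label models
# ---------------------------------------------------------------------------

def _draw_topics(config: GeneratorConfig, rng: np.random.Generator) -> frozenset[str]:
    topics = config.topics
    weights = np.array([config.topic_prevalence[t] for t in topics], dtype=float)
    if config.label_mode == "independent":
        mask = rng.random(len(topics)) < weights
        return frozenset(t for t, m in zip(topics, mask) if m)
    counts = sorted(config.multi_topic_mixing)
    probs = np.array([config.multi_topic_mixing[k] for k in counts], dtype=float)
    k = int(rng.choice(counts, p=probs))
    k = min(k, int((weights > 0).sum()))
    chosen: list[int] = []
    w = weights.copy()
    for _ in range(k):
        p = w / w.sum()
        idx = int(rng.choice(len(topics), p=p))
        chosen.append(idx)
        w[idx] = 0.0
    return frozenset(topics[i] for i in chosen)


def implied_prevalence(config: GeneratorConfig) -> dict[str, float]:
    """Exact marginal topic-inclusion probabilities under the label model.

    In ``independent`` mode this is the configured prevalence itself; in
    ``mixture`` mode it is obtained by exhaustive enumeration of the
    successive weighted draws without replacement.
    """
    topics = config.topics
    if config.label_mode == "independent":
        return {t: config.topic_prevalence[t] for t in topics}
    weights = np.array([config.topic_prevalence[t] for t in topics], dtype=float)
    max_k = min(max(config.multi_topic_mixing), int((weights > 0).sum()))
    # depth_probs[d][i]: probability topic i is selected at draw d
    depth_probs = np.zeros((max_k, len(topics)))

    def recurse(avail: list[int], depth: int, p: float) -> None:
        if depth == max_k or p == 0.0:
            return
        total = weights[avail].sum()
        for i in avail:
            pi = p * weights[i] / total
            depth_probs[depth, i] += pi
            recurse([j for j in avail if j != i], depth + 1, pi)

    recurse([i for i in range(len(topics)) if weights[i] > 0], 0, 1.0)
    implied = np.zeros(len(topics))
    for k, pk in config.multi_topic_mixing.items():
        implied += pk * depth_probs[: min(k, max_k)].sum(axis=0)
    return {t: float(implied[i]) for i, t in enumerate(topics)}


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

_START = datetime(2017, 9, 1, tzinfo=timezone.utc)


def generate(config: GeneratorConfig) -> Corpus:
    """Generate a labeled two-platform corpus; deterministic given the seed.

    ``n_posts`` counts authored originals per platform; same-user
    duplicates and retweets are injected on top at their configured rates.
    Every post carries a ``synthetic_role`` extra field (original /
    irrelevant / duplicate / retweet) so tests can isolate subsets.
    """
    rng = np.random.default_rng(config.seed)
    posts: list[Post] = []
    for platform in sorted(config.n_posts):
        posts.extend(_generate_platform(platform, config, rng))
    corpus = Corpus(
        posts,
        provenance=(
            f"synthetic corpus (seed={config.seed}, "
            f"label_mode={config.label_mode}, vocab={config.vocabulary_mode})"
        ),
    )
    corpus.validate()
    return corpus


def _generate_platform(
    platform: str, config: GeneratorConfig, rng: np.random.Generator
) -> list[Post]:
    n = config.n_posts[platform]
    n_users = max(1, n // 2)
    sub_names = [s for s, _ in DEFAULT_SUBREDDITS]
    sub_w = np.array([w for _, w in DEFAULT_SUBREDDITS])
    sub_w = sub_w / sub_w.sum()

    originals: list[Post] = []
    for i in range(n):
        post_id = f"{platform[0]}{i:06d}"
        author = f"{platform[0]}_user{int(rng.integers(0, n_users))}"
        ts = _START + timedelta(minutes=7 * len(originals) + (0 if platform == "reddit" else 3))
        role = "original"
        if rng.random() < config.irrelevant_rate:
            role = "irrelevant"
            gold = GoldLabels()
            text = _irrelevant_text(config, rng, platform)
        else:
            gold = GoldLabels(
                topics=_draw_topics(config, rng),
                distress=bool(rng.random() < config.distress_rate),
            )
            text = _assemble_text(platform, gold, config, rng)
        kwargs: dict = {"extra": {"synthetic_role": role}}
        if platform == "reddit":
            kwargs["subreddit"] = sub_names[int(rng.choice(len(sub_names), p=sub_w))]
            kwargs["post_type"] = "submission" if rng.random() < 0.05 else "comment"
        else:
            kwargs["post_type"] = "tweet"
            kwargs["is_retweet"] = False
        originals.append(Post(
            post_id=post_id, platform=platform, text=text, author=author,
            timestamp=ts, gold_labels=gold, **kwargs,
        ))

    extras: list[Post] = []
    candidates = [p for p in originals if p.extra["synthetic_role"] == "original"]
    n_dup = int(round(config.duplicate_rate * n))
    if candidates and n_dup:
        for j, idx in enumerate(rng.choice(len(candidates), size=min(n_dup, len(candidates)), replace=False)):
            src = candidates[int(idx)]
            extras.append(replace(
                src,
                post_id=f"{src.post_id}_dup",
                timestamp=src.timestamp + timedelta(days=1),
                extra={"synthetic_role": "duplicate", "duplicate_of": src.post_id},
            ))
    if platform == "twitter":
        n_rt = int(round(config.retweet_rate * n))
        if candidates and n_rt:
            for j, idx in enumerate(rng.choice(len(candidates), size=min(n_rt, len(candidates)), replace=False)):
                src = candidates[int(idx)]
                text = f"RT @{src.author}: {src.text}"[:TWEET_MAX_CHARS]
                extras.append(replace(
                    src,
                    post_id=f"{src.post_id}_rt{j}",
                    author=f"t_user{int(rng.integers(0, n_users))}",
                    text=text,
                    timestamp=src.timestamp + timedelta(hours=2),
                    is_retweet=True,
                    extra={"synthetic_role": "retweet", "retweet_of": src.post_id},
                ))
    return originals + extras


def _irrelevant_text(config, rng, platform) -> str:
    if rng.random() < 0.5:
        # carries an IBD keyword but in an excluded context
        base = "my dog has ibd the vet said"
    else:
        base = "quarterly earnings report looking strong"
    return base + " " + " ".join(_pick(DEFAULT_FILLER, rng, 4))


def _pick(pool: Sequence[str], rng: np.random.Generator, k: int) -> list[str]:
    if k <= 0 or not pool:
        return []
    return [pool[int(i)] for i in rng.integers(0, len(pool), size=k)]


def _assemble_text(
    platform: str,
    gold: GoldLabels,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> str:
    required: list[str] = [DEFAULT_KEYWORD_PHRASES[int(rng.integers(0, len(DEFAULT_KEYWORD_PHRASES)))]]
    topic_order = sorted(gold.topics)
    rng.shuffle(topic_order)
    for topic in topic_order:
        terms = config.signal_terms[topic]
        required.append(terms[int(rng.integers(0, len(terms)))])
    if gold.distress:
        required.append(config.distress_markers[int(rng.integers(0, len(config.distress_markers)))])
    if rng.random() < config.fp_trap_rate:
        trap_topic = config.topics[int(rng.integers(0, len(config.topics)))]
        required.append(config.trap_phrases[trap_topic])
    if config.vocabulary_mode == "confusable" and rng.random() < config.confusable_rate:
        required.append(CONFUSABLE_TERM[0])

    tail: list[str] = []
    if platform == "twitter" and rng.random() < config.hashtag_rate:
        n_tags = 1 + int(rng.geometric(0.6)) - 1
        tail.extend("#" + t for t in _pick(DEFAULT_HASHTAGS, rng, max(1, n_tags)))
    if rng.random() < config.hyperlink_rate.get(platform, 0.0):
        tail.append(f"https://example.org/{int(rng.integers(0, 10**6))}")

    lo, hi = config.filler_words[platform]
    filler = _pick(DEFAULT_FILLER, rng, int(rng.integers(lo, hi + 1)))

    base_len = len(" ".join(required + tail))
    if platform == "twitter":
        if base_len > TWEET_MAX_CHARS:
            raise GeneratorError(
                f"required tweet content exceeds {TWEET_MAX_CHARS} characters "
                f"({base_len}); reduce planted content"
            )
        budget = TWEET_MAX_CHARS - base_len - 1
        trimmed: list[str] = []
        for w in filler:
            if budget - len(w) - 1 < 0:
                break
            trimmed.append(w)
            budget -= len(w) + 1
        filler = trimmed

    cut = len(filler) // 2
    return " ".join(filler[:cut] + required + filler[cut:] + tail)


# ---------------------------------------------------------------------------
# Gold-label evaluation
# ---------------------------------------------------------------------------

@dataclass
class TopicScores:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def false_positive_rate(self) -> Optional[float]:
        d = self.fp + self.tn
        return self.fp / d if d else None


@dataclass
class EvaluationResult:
    per_topic: dict[str, TopicScores]

    def _micro(self, num_attr: str, den_attrs: tuple[str, str]) -> Optional[float]:
        num = sum(getattr(s, num_attr) for s in self.per_topic.values())
        den = sum(
            getattr(s, den_attrs[0]) + getattr(s, den_attrs[1])
            for s in self.per_topic.values()
        )
        return num / den if den else None

    @property
    def micro_precision(self) -> Optional[float]:
        return self._micro("tp", ("tp", "fp"))

    @property
    def micro_recall(self) -> Optional[float]:
        return self._micro("tp", ("tp", "fn"))

    def to_json(self) -> dict:
        return {
            "per_topic": {
                t: {
                    "tp": s.tp, "fp": s.fp, "fn": s.fn, "tn": s.tn,
                    "precision": s.precision, "recall": s.recall,
                }
                for t, s in self.per_topic.items()
            },
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
        }


def gold_evaluation(
    assignments: Iterable[TopicAssignment],
    corpus: Corpus,
    topics: Sequence[str] = CANONICAL_TOPICS,
) -> EvaluationResult:
    """Per-topic precision/recall of assignments against the corpus gold labels."""
    by_id = {a.post_id: a for a in assignments}
    scores = {t: TopicScores() for t in topics}
    for post in corpus:
        if post.gold_labels is None:
            raise GeneratorError(f"post {post.post_id!r} carries no gold labels")
        predicted = by_id[post.post_id].topics if post.post_id in by_id else set()
        for t in topics:
            in_gold = t in post.gold_labels.topics
            in_pred = t in predicted
            s = scores[t]
            if in_gold and in_pred:
                s.tp += 1
            elif in_pred:
                s.fp += 1
            elif in_gold:
                s.fn += 1
            else:
                s.tn += 1
    return EvaluationResult(per_topic=scores)
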