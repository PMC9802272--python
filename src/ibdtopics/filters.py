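"""Corpus cleaning: relevance filtering, retweet removal, same-user
deduplication, and the distress-lexicon filter.

Every filter takes a :class:`~ibdtopics.corpus.Corpus` and returns the
retained corpus plus a :class:`FilterReport` whose removal counts are
conservative: retained + sum(removed) == input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .corpus import Corpus, Post
from .lexicons import DistressLexicon, RelevanceConfig
from .textnorm import contains_substring, find_phrase, joined, normalize_text

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Accounting for one filter pass."""

    rule: str
    input_count: int
    retained_count: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    #: optional per-post detail, e.g. which distress entries fired
    matches: dict[str, list[str]] = field(default_factory=dict)

    def check(self) -> None:
        if self.retained_count + sum(self.removed_by_rule.values()) != self.input_count:
            raise AssertionError(f"filter report for {self.rule!r} does not conserve counts")

    def to_json(self) -> dict:
        return {
            "rule": self.rule,
            "input_count": self.input_count,
            "retained_count": self.retained_count,
            "removed_by_rule": dict(self.removed_by_rule),
        }


def _finish(rule: str, corpus: Corpus, kept: list[Post],
            removed: dict[str, int], matches: dict[str, list[str]] | None = None) -> tuple[Corpus, FilterReport]:
    report = FilterReport(rule, corpus.N, len(kept), removed, matches or {})
    report.check()
    logger.info(
        "%s: retained %d of %d (%s)", rule, report.retained_count,
        report.input_count, report.removed_by_rule,
    )
    return corpus.subset(kept, f" | {rule}"), report


def relevance_filter(corpus: Corpus, config: RelevanceConfig) -> tuple[Corpus, FilterReport]:
    """Keep posts mentioning >=1 relevance keyword and no exclusion context.

    Keywords match as substrings of the normalized text (so "crohn" hits
    "crohns" and "#crohnsdisease"); exclusion contexts are normalized
    phrase matches, also substring over the joined tokens.
    """
    kept: list[Post] = []
    removed = {"no_keyword": 0, "exclusion_context": 0}
    for post in corpus:
        tokens = normalize_text(post.text)
        if not any(contains_substring(tokens, k.tokens) for k in config.keywords):
            removed["no_keyword"] += 1
        elif any(contains_substring(tokens, e.tokens) for e in config.exclusion_contexts):
            removed["exclusion_context"] += 1
        else:
            kept.append(post)
    return _finish("relevance", corpus, kept, removed)


def remove_retweets(corpus: Corpus) -> tuple[Corpus, FilterReport]:
    """Drop twitter reposts so only original content remains.

    A tweet is a retweet when its metadata flag says so, or as a fallback
    when its text begins with the conventional "RT @" prefix.  Reddit
    posts are never touched by this rule.
    """
    kept: list[Post] = []
    removed = {"retweet": 0}
    for post in corpus:
        if post.platform == "twitter" and (
            bool(post.is_retweet) or post.text.lstrip().lower().startswith("rt @")
        ):
            removed["retweet"] += 1
        else:
            kept.append(post)
    return _finish("retweets", corpus, kept, removed)


def dedup_same_user(corpus: Corpus) -> tuple[Corpus, FilterReport]:
    """Among same-author posts with identical normalized text keep the earliest.

    The same text published by *different* authors is never deduplicated,
    and posts with an empty author (anonymized corpora) are left alone —
    there is no evidence they share an author.  Earliest means smallest
    timestamp, falling back to corpus order when timestamps tie or are
    missing.
    """
    best: dict[tuple[str, str], tuple] = {}
    for idx, post in enumerate(corpus):
        if not post.author:
            continue
        key = (post.author, joined(normalize_text(post.text)))
        ts = post.timestamp
        rank = (0, ts.timestamp(), idx) if ts is not None else (1, 0.0, idx)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, idx)
    keep_idx = {idx for _, idx in best.values()}
    kept, removed = [], {"same_user_duplicate": 0}
    for idx, post in enumerate(corpus):
        if not post.author or idx in keep_idx:
            kept.append(post)
        else:
            removed["same_user_duplicate"] += 1
    return _finish("dedup", corpus, kept, removed)


def distress_filter(corpus: Corpus, lexicon: DistressLexicon) -> tuple[Corpus, FilterReport]:
    """Keep posts containing >=1 distress unigram (exact token) or phrase
    (consecutive tokens); record which entries fired per post."""
    if lexicon.n_entries == 0:
        raise ValueError("distress lexicon is empty")
    unigrams = {e.tokens[0] for e in lexicon.unigrams}
    kept: list[Post] = []
    removed = {"no_distress_marker": 0}
    matches: dict[str, list[str]] = {}
    for post in corpus:
        tokens = normalize_text(post.text)
        fired = sorted({t.text for t in tokens} & unigrams)
        fired += [
            " ".join(p.tokens) for p in lexicon.phrases if find_phrase(tokens, p.tokens)
        ]
        if fired:
            matches[post.post_id] = fired
            kept.append(post)
        else:
            removed["no_distress_marker"] += 1
    return _finish("distress", corpus, kept, removed, matches)
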