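"""Descriptive reporting: corpus characteristics, subreddit/hashtag
rankings, topic prevalence, and the single/multi-topic breakdown.

Percentage convention: round half-up to a whole percent, with nonzero
proportions that round to zero rendered "<1%" — the convention that
reproduces every printed topic percentage in the published prevalence
tables from their integer numerators and denominators.  Means and SDs are
reported to two decimals (sample SD by default).
"""

from __future__ import annotations

import json
import re
import statistics
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .corpus import Corpus
from .lexicons import CANONICAL_TOPICS
from .textnorm import URL_RE
from .topics import TopicAssignment


# ---------------------------------------------------------------------------
# Rounding conventions
# ---------------------------------------------------------------------------

def round_half_up(x: float, digits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_int(n: int, total: int) -> int:
    """Whole-percent value of n/total, rounded half-up; 0 when total is 0."""
    if total == 0:
        return 0
    return int(round_half_up(100.0 * n / total))


def format_percent(n: int, total: int) -> str:
    """Rendered percentage with the "<1%" rule for nonzero sub-half shares."""
    p = percent_int(n, total)
    if p == 0 and n > 0:
        return "<1%"
    return f"{p}%"


def mean_sd(values: Sequence[float], sd_mode: str = "sample") -> tuple[float, float]:
    """(mean, SD) rounded to 2 decimals; SD is sample (n-1) by default."""
    if not values:
        return (0.0, 0.0)
    m = statistics.fmean(values)
    if len(values) < 2:
        s = 0.0
    elif sd_mode == "population":
        s = statistics.pstdev(values)
    else:
        s = statistics.stdev(values)
    return (round_half_up(m, 2), round_half_up(s, 2))


# ---------------------------------------------------------------------------
# Text feature extraction
# ---------------------------------------------------------------------------

_HASHTAG_RE = re.compile(r"#([^\s#]+)")
_NON_ALNUM_RE = re.compile(r"[^0-9a-z]+")


def extract_hashtags(text: str) -> list[str]:
    """Normalized hashtags in order of appearance, duplicates preserved.

    Normalization: strip '#', lower-case, drop non-alphanumerics; tags
    empty after normalization are discarded.
    """
    out = []
    for m in _HASHTAG_RE.finditer(text):
        tag = _NON_ALNUM_RE.sub("", m.group(1).lower())
        if tag:
            out.append(tag)
    return out


def count_hyperlinks(text: str) -> int:
    """Occurrences of http(s):// or www.-prefixed URL patterns."""
    return len(URL_RE.findall(text))


# ---------------------------------------------------------------------------
# Summary report
# ---------------------------------------------------------------------------

@dataclass
class CountPct:
    n: int
    total: int

    @property
    def pct(self) -> str:
        return format_percent(self.n, self.total)

    def to_json(self) -> dict:
        return {"n": self.n, "pct": self.pct}


@dataclass
class PlatformSummary:
    """Descriptive block for one platform."""

    platform: str
    N: int
    unique_users: int
    mean_sd_posts_per_user: tuple[float, float]
    posts_with_hyperlinks: CountPct
    total_hyperlinks: int
    post_type_counts: dict[str, int]
    topic_prevalence: dict[str, CountPct]
    at_least_one_topic: CountPct
    zero_topics: CountPct
    exactly_1: CountPct
    exactly_2: CountPct
    three_plus: CountPct
    # reddit only
    unique_subreddits: Optional[int] = None
    top_subreddits: Optional[list[tuple[str, int]]] = None
    # twitter only
    total_hashtags: Optional[int] = None
    unique_hashtags: Optional[int] = None
    tweets_with_hashtags: Optional[CountPct] = None
    mean_sd_hashtags_per_post: Optional[tuple[float, float]] = None

    def check(self) -> None:
        assert (
            self.exactly_1.n + self.exactly_2.n + self.three_plus.n
            == self.at_least_one_topic.n
        )
        assert self.at_least_one_topic.n + self.zero_topics.n == self.N
        assert all(c.n <= self.N for c in self.topic_prevalence.values())

    def to_json(self) -> dict:
        def cp(v):
            return v.to_json() if v is not None else None

        return {
            "platform": self.platform,
            "N": self.N,
            "unique_users": self.unique_users,
            "mean_sd_posts_per_user": list(self.mean_sd_posts_per_user),
            "posts_with_hyperlinks": cp(self.posts_with_hyperlinks),
            "total_hyperlinks": self.total_hyperlinks,
            "post_type_counts": self.post_type_counts,
            "unique_subreddits": self.unique_subreddits,
            "top_subreddits": self.top_subreddits,
            "total_hashtags": self.total_hashtags,
            "unique_hashtags": self.unique_hashtags,
            "tweets_with_hashtags": cp(self.tweets_with_hashtags),
            "mean_sd_hashtags_per_post": (
                list(self.mean_sd_hashtags_per_post)
                if self.mean_sd_hashtags_per_post is not None else None
            ),
            "topic_prevalence": {t: v.to_json() for t, v in self.topic_prevalence.items()},
            "at_least_one_topic": cp(self.at_least_one_topic),
            "zero_topics": cp(self.zero_topics),
            "single_multi_topic": {
                "1 topic": cp(self.exactly_1),
                "2 topics": cp(self.exactly_2),
                "3+ topics": cp(self.three_plus),
            },
        }


@dataclass
class SummaryReport:
    platforms: dict[str, PlatformSummary] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {p: s.to_json() for p, s in self.platforms.items()}

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json(), indent=2) + "\n", encoding="utf-8")
        return path

    def render_text(self) -> str:
        return "\n\n".join(_render_platform(s) for s in self.platforms.values())


def rank_table(
    items: Iterable[tuple[str, int]], k: int, N: int
) -> list[tuple[str, int, str]]:
    """Top-k items by count (ties lexicographic) with n and rendered %."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(items, key=lambda kv: (-kv[1], kv[0]))[:k]
    return [(name, n, format_percent(n, N)) for name, n in ranked]


def summarize(
    corpus: Corpus,
    assignments: Sequence[TopicAssignment],
    topics: Sequence[str] = CANONICAL_TOPICS,
    sd_mode: str = "sample",
    top_k: int = 10,
) -> SummaryReport:
    """Compute the full descriptive report, one block per platform present.

    ``assignments`` must be order-aligned with the corpus (same ids in the
    same order), as produced by ``classify_corpus``.
    """
    if len(assignments) != corpus.N or any(
        p.post_id != a.post_id for p, a in zip(corpus, assignments)
    ):
        raise ValueError("assignments are not aligned with the corpus")

    report = SummaryReport()
    for platform in ("reddit", "twitter"):
        pairs = [
            (p, a) for p, a in zip(corpus, assignments) if p.platform == platform
        ]
        if pairs:
            report.platforms[platform] = _summarize_platform(
                platform, pairs, topics, sd_mode, top_k
            )
    return report


def _summarize_platform(platform, pairs, topics, sd_mode, top_k) -> PlatformSummary:
    posts = [p for p, _ in pairs]
    assigns = [a for _, a in pairs]
    N = len(posts)

    user_counts: dict[str, int] = {}
    for p in posts:
        if p.author:
            user_counts[p.author] = user_counts.get(p.author, 0) + 1

    link_counts = [count_hyperlinks(p.text) for p in posts]
    type_counts: dict[str, int] = {}
    for p in posts:
        type_counts[p.post_type] = type_counts.get(p.post_type, 0) + 1

    topic_counts = {t: sum(t in a.topics for a in assigns) for t in topics}
    k_counts = [a.n_topics for a in assigns]
    n1 = sum(k == 1 for k in k_counts)
    n2 = sum(k == 2 for k in k_counts)
    n3 = sum(k >= 3 for k in k_counts)
    n_any = n1 + n2 + n3

    summary = PlatformSummary(
        platform=platform,
        N=N,
        unique_users=len(user_counts),
        mean_sd_posts_per_user=mean_sd(list(user_counts.values()), sd_mode),
        posts_with_hyperlinks=CountPct(sum(c > 0 for c in link_counts), N),
        total_hyperlinks=sum(link_counts),
        post_type_counts=type_counts,
        topic_prevalence={t: CountPct(topic_counts[t], N) for t in topics},
        at_least_one_topic=CountPct(n_any, N),
        zero_topics=CountPct(N - n_any, N),
        # single/multi-topic shares are conventionally reported among the
        # posts that mention at least one topic
        exactly_1=CountPct(n1, n_any),
        exactly_2=CountPct(n2, n_any),
        three_plus=CountPct(n3, n_any),
    )

    if platform == "reddit":
        sub_counts: dict[str, int] = {}
        for p in posts:
            if p.subreddit:
                sub_counts[p.subreddit] = sub_counts.get(p.subreddit, 0) + 1
        summary.unique_subreddits = len(sub_counts)
        summary.top_subreddits = [
            (name, n) for name, n, _ in rank_table(sub_counts.items(), top_k, N)
        ]
    else:
        per_post_tags = [extract_hashtags(p.text) for p in posts]
        all_tags = [t for tags in per_post_tags for t in tags]
        summary.total_hashtags = len(all_tags)
        summary.unique_hashtags = len(set(all_tags))
        summary.tweets_with_hashtags = CountPct(
            sum(bool(tags) for tags in per_post_tags), N
        )
        summary.mean_sd_hashtags_per_post = mean_sd(
            [len(tags) for tags in per_post_tags], sd_mode
        )

    summary.check()
    return summary


def _render_platform(s: PlatformSummary) -> str:
    def row(label, value):
        return f"  {label:<38}{value}"

    lines = [f"{s.platform.capitalize()} (N = {s.N})", "-" * 50]
    m, sd = s.mean_sd_posts_per_user
    lines += [
        row("Unique users", s.unique_users),
        row("Average posts per user", f"{m:.2f} ± {sd:.2f}"),
        row("Posts containing hyperlinks",
            f"{s.posts_with_hyperlinks.n} ({s.posts_with_hyperlinks.pct})"),
        row("Total number of hyperlinks", s.total_hyperlinks),
    ]
    for ptype, n in sorted(s.post_type_counts.items()):
        lines.append(row(f"Post type: {ptype}", f"{n} ({format_percent(n, s.N)})"))
    if s.unique_subreddits is not None:
        lines.append(row("Unique subreddits", s.unique_subreddits))
        for name, n in s.top_subreddits or ():
            lines.append(row(f"  r/{name}", f"{n} ({format_percent(n, s.N)})"))
    if s.total_hashtags is not None:
        m, sd = s.mean_sd_hashtags_per_post
        lines += [
            row("Total number of hashtags", s.total_hashtags),
            row("Unique hashtags", s.unique_hashtags),
            row("Tweets with 1 or more hashtag",
                f"{s.tweets_with_hashtags.n} ({s.tweets_with_hashtags.pct})"),
            row("Average hashtags per post", f"{m:.2f} ± {sd:.2f}"),
        ]
    lines.append(row("At least 1 topic present",
                     f"{s.at_least_one_topic.n} ({s.at_least_one_topic.pct})"))
    lines.append(row("No topic present", f"{s.zero_topics.n} ({s.zero_topics.pct})"))
    for t, c in s.topic_prevalence.items():
        lines.append(row(f"Topic: {t}", f"{c.n} ({c.pct})"))
    lines += [
        row("1 topic", f"{s.exactly_1.n} ({s.exactly_1.pct})"),
        row("2 topics", f"{s.exactly_2.n} ({s.exactly_2.pct})"),
        row("3+ topics", f"{s.three_plus.n} ({s.three_plus.pct})"),
    ]
    return "\n".join(lines)
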