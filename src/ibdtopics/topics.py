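"""Eight-topic dictionary classification with false-positive elimination.

A post is assigned a topic when at least one dictionary term for that
topic matches its normalized text.  A second, per-topic false-positive
dictionary then removes spurious hits: in the default ``overlap`` mode
only topic matches whose character span overlaps a false-positive phrase
occurrence are discarded (a genuine co-mention elsewhere in the post
survives); in ``veto`` mode any false-positive occurrence drops the whole
topic for that post; ``off`` disables elimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import Corpus, Post
from .lexicons import FalsePositiveLexicon, LexEntry, TopicLexicon
from .textnorm import (
    Token,
    char_span,
    find_phrase,
    find_token_substring,
    normalize_text,
    spans_overlap,
)

FP_MODES = ("overlap", "veto", "off")

#: (matched term display form, (char start, char end))
Span = tuple[str, tuple[int, int]]


@dataclass
class TopicAssignment:
    """Per-post classification outcome with supporting match spans."""

    post_id: str
    topics: set[str] = field(default_factory=set)
    match_spans: dict[str, list[Span]] = field(default_factory=dict)
    fp_suppressed: dict[str, list[Span]] = field(default_factory=dict)

    @property
    def n_topics(self) -> int:
        return len(self.topics)

    def to_json(self) -> dict:
        return {
            "post_id": self.post_id,
            "topics": sorted(self.topics),
            "match_spans": {t: [[term, list(span)] for term, span in v]
                            for t, v in self.match_spans.items()},
            "fp_suppressed": {t: [[term, list(span)] for term, span in v]
                              for t, v in self.fp_suppressed.items()},
        }

    @classmethod
    def from_json(cls, obj: dict) -> "TopicAssignment":
        def spans(block: dict) -> dict[str, list[Span]]:
            return {t: [(term, (s[0], s[1])) for term, s in v] for t, v in block.items()}
        return cls(
            post_id=obj["post_id"],
            topics=set(obj.get("topics", ())),
            match_spans=spans(obj.get("match_spans", {})),
            fp_suppressed=spans(obj.get("fp_suppressed", {})),
        )


def _entry_matches(tokens: Sequence[Token], entry: LexEntry) -> list[Span]:
    if entry.substring:
        hits = find_token_substring(tokens, entry.tokens[0])
    else:
        hits = find_phrase(tokens, entry.tokens)
    return [(entry.display(), char_span(tokens, i, j)) for i, j in hits]


def classify_topics(
    post: Post,
    lexicon: TopicLexicon,
    fp: FalsePositiveLexicon | None = None,
    fp_mode: str = "overlap",
) -> TopicAssignment:
    """Classify one post against the topic dictionary.

    Topics are not mutually exclusive: every topic with >=1 surviving
    match span is assigned.  See the module docstring for ``fp_mode``.
    """
    if fp_mode not in FP_MODES:
        raise ValueError(f"fp_mode must be one of {FP_MODES}, got {fp_mode!r}")
    fp = fp or FalsePositiveLexicon()
    tokens = normalize_text(post.text)
    assignment = TopicAssignment(post_id=post.post_id)

    for topic in lexicon.topic_names:
        raw: list[Span] = []
        for entry in lexicon.topics[topic]:
            raw.extend(_entry_matches(tokens, entry))
        if not raw:
            continue
        fp_spans: list[Span] = []
        if fp_mode != "off":
            for entry in fp.entries.get(topic, ()):
                fp_spans.extend(_entry_matches(tokens, entry))
        if fp_mode == "veto" and fp_spans:
            surviving: list[Span] = []
            suppressed = raw
        else:
            surviving, suppressed = [], []
            for span in raw:
                if any(spans_overlap(span[1], f[1]) for f in fp_spans):
                    suppressed.append(span)
                else:
                    surviving.append(span)
        if surviving:
            assignment.topics.add(topic)
            assignment.match_spans[topic] = surviving
        if suppressed:
            assignment.fp_suppressed[topic] = suppressed
    return assignment


def classify_corpus(
    corpus: Corpus | Iterable[Post],
    lexicon: TopicLexicon,
    fp: FalsePositiveLexicon | None = None,
    fp_mode: str = "overlap",
) -> list[TopicAssignment]:
    """One :class:`TopicAssignment` per post, order-aligned with the corpus."""
    return [classify_topics(p, lexicon, fp, fp_mode) for p in corpus]


def write_assignments(assignments: Iterable[TopicAssignment], path) -> None:
    import json
    with open(path, "w", encoding="utf-8") as fh:
        for a in assignments:
            fh.write(json.dumps(a.to_json(), ensure_ascii=False) + "\n")


def read_assignments(path) -> list[TopicAssignment]:
    import json
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(TopicAssignment.from_json(json.loads(line)))
    return out
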