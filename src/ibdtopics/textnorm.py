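"""Text normalization shared by every lexical stage.

All matching in the pipeline (relevance keywords, distress terms, topic
dictionaries, false-positive phrases) operates on the same normalized view
of a post: lower-cased tokens of maximal alphanumeric runs, with
within-word apostrophes stripped ("Crohn's" -> "crohns"), URLs collapsed
to a sentinel token, and the original character span retained per token so
that matches can be reported and compared as spans in the raw text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

#: Sentinel token substituted for hyperlinks.  Contains a character that can
#: never appear in a normalized token, so no lexicon entry can collide with it.
URL_TOKEN = "<url>"

URL_RE = re.compile(r"(?:https?://|www\.)[^\s]+", re.IGNORECASE)

# A word is a run of alphanumerics, optionally joined by apostrophes
# (straight or curly) which are dropped from the normalized form.
_WORD_RE = re.compile(r"[0-9A-Za-zÀ-ɏ]+(?:['’][0-9A-Za-zÀ-ɏ]+)*")
_APOSTROPHE_RE = re.compile(r"['’]")


@dataclass(frozen=True)
class Token:
    """A normalized token plus its span in the original text."""

    text: str
    start: int
    end: int


def normalize_text(text: str) -> list[Token]:
    """Tokenize ``text`` into lower-cased alphanumeric tokens with spans.

    URLs become a single :data:`URL_TOKEN` token covering the URL's span.
    Case and within-word apostrophes are erased, so ``"IBD"`` and ``"ibd"``
    normalize identically and ``"Crohn's"`` becomes ``"crohns"``.
    """
    tokens: list[Token] = []
    cursor = 0
    for url in URL_RE.finditer(text):
        tokens.extend(_tokenize_plain(text, cursor, url.start()))
        tokens.append(Token(URL_TOKEN, url.start(), url.end()))
        cursor = url.end()
    tokens.extend(_tokenize_plain(text, cursor, len(text)))
    return tokens


def _tokenize_plain(text: str, start: int, end: int) -> list[Token]:
    return [
        Token(_APOSTROPHE_RE.sub("", m.group(0)).lower(), m.start(), m.end())
        for m in _WORD_RE.finditer(text, start, end)
    ]


def normalize_term(term: str) -> tuple[str, ...]:
    """Normalize a lexicon entry to its token tuple (lower-cased, no spans)."""
    return tuple(t.text for t in normalize_text(term))


def joined(tokens: Sequence[Token]) -> str:
    """Space-joined normalized text, the haystack for substring matching."""
    return " ".join(t.text for t in tokens)


def contains_substring(tokens: Sequence[Token], phrase: str | tuple[str, ...]) -> bool:
    """Substring containment of a normalized phrase in the joined token text.

    This is the relevance-keyword match mode: "crohn" hits "crohns" and
    hashtag compounds such as "#crohnsdisease" (whose token is
    "crohnsdisease"), and multi-word phrases span token boundaries.
    """
    needle = " ".join(phrase) if isinstance(phrase, tuple) else " ".join(normalize_term(phrase))
    return bool(needle) and needle in joined(tokens)


def find_phrase(
    tokens: Sequence[Token], phrase: tuple[str, ...]
) -> list[tuple[int, int]]:
    """All occurrences of ``phrase`` as consecutive tokens.

    Returns token-index ranges ``(i, j)`` with ``tokens[i:j]`` matching.
    """
    if not phrase:
        return []
    n, k = len(tokens), len(phrase)
    hits = []
    for i in range(n - k + 1):
        if all(tokens[i + d].text == phrase[d] for d in range(k)):
            hits.append((i, i + k))
    return hits


def find_token_substring(tokens: Sequence[Token], needle: str) -> list[tuple[int, int]]:
    """Occurrences of ``needle`` as a substring of a single token."""
    return [(i, i + 1) for i, t in enumerate(tokens) if needle in t.text]


def char_span(tokens: Sequence[Token], i: int, j: int) -> tuple[int, int]:
    """Character span in the original text covered by tokens[i:j]."""
    return (tokens[i].start, tokens[j - 1].end)


def spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def lower_all(entries: Iterable[str]) -> set[str]:
    return {e.lower() for e in entries}
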