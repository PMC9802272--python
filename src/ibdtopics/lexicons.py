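"""Lexicon configuration: relevance keywords, distress terms, topic
dictionaries and per-topic false-positive phrase dictionaries.

Config files are YAML.  A single file may carry any subset of the
top-level keys ``relevance``, ``exclusions``, ``distress`` and ``topics``:

.. code-block:: yaml

    relevance: [crohn, ibd, colitis]
    exclusions: ["my dog has", "investors business daily"]
    distress:
      unigrams: [afraid, scared]
      phrases: ["feel alone", "hard to manage"]
    topics:
      symptoms:
        terms: [flare, pain, "stomach ache", "crohn*"]
        false_positives: ["tired of explaining"]

Entries are stored lower-cased.  A single-word topic term normally matches
as an exact token; a trailing ``*`` marks it as a substring entry (needed
for hashtag compounds such as ``#crohnsdisease``).  Multi-word entries
always match as consecutive normalized tokens.

The module ships illustrative default lexicons assembled from the
vocabulary of published IBD-distress content analyses (topic names,
"FODMAP", "weed", example-post wording).  They are a stand-in for a
full curated dictionary, which is a config drop-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .textnorm import normalize_term

#: The eight canonical, non-mutually-exclusive IBD topics, in the
#: conventional prevalence-report order.
CANONICAL_TOPICS = (
    "symptoms",
    "medication",
    "nutrition",
    "procedures",
    "marijuana",
    "stigma",
    "ostomy",
    "intimacy",
)


class LexiconError(ValueError):
    """Invalid lexicon configuration."""


@dataclass(frozen=True)
class LexEntry:
    """One dictionary entry: a normalized token tuple plus its match mode.

    ``substring=True`` is only meaningful for single-token entries.
    """

    tokens: tuple[str, ...]
    substring: bool = False

    @classmethod
    def parse(cls, raw: str) -> "LexEntry":
        raw = raw.strip()
        substring = raw.endswith("*")
        tokens = normalize_term(raw.rstrip("*"))
        if not tokens:
            raise LexiconError(f"empty lexicon entry {raw!r}")
        if substring and len(tokens) > 1:
            raise LexiconError(f"substring mode is single-word only: {raw!r}")
        return cls(tokens, substring)

    def display(self) -> str:
        return " ".join(self.tokens) + ("*" if self.substring else "")


@dataclass
class RelevanceConfig:
    """Disease-relevance keywords and off-topic exclusion contexts."""

    keywords: list[LexEntry] = field(default_factory=list)
    exclusion_contexts: list[LexEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.keywords:
            raise LexiconError("relevance keyword list must be non-empty")

    @classmethod
    def from_lists(
        cls, keywords: Iterable[str], exclusions: Iterable[str] = ()
    ) -> "RelevanceConfig":
        return cls(
            [LexEntry.parse(k) for k in keywords],
            [LexEntry.parse(e) for e in exclusions],
        )


@dataclass
class DistressLexicon:
    """Unigrams and short phrases whose presence flags distress."""

    unigrams: list[LexEntry] = field(default_factory=list)
    phrases: list[LexEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.unigrams:
            if len(e.tokens) != 1:
                raise LexiconError(f"distress unigram has {len(e.tokens)} tokens: {e.display()!r}")
        for e in self.phrases:
            if len(e.tokens) < 2:
                raise LexiconError(f"distress phrase must be multi-token: {e.display()!r}")

    @property
    def n_entries(self) -> int:
        return len(self.unigrams) + len(self.phrases)

    @classmethod
    def from_lists(
        cls, unigrams: Iterable[str], phrases: Iterable[str] = ()
    ) -> "DistressLexicon":
        return cls(
            [LexEntry.parse(u) for u in unigrams],
            [LexEntry.parse(p) for p in phrases],
        )


@dataclass
class TopicLexicon:
    """Per-topic term dictionaries for the 8-topic classification."""

    topics: dict[str, list[LexEntry]] = field(default_factory=dict)

    def validate_canonical(self) -> None:
        """The canonical profile requires exactly the 8 canonical topics."""
        if set(self.topics) != set(CANONICAL_TOPICS):
            raise LexiconError(
                "canonical topic lexicon must define exactly "
                f"{sorted(CANONICAL_TOPICS)}; got {sorted(self.topics)}"
            )

    @property
    def topic_names(self) -> list[str]:
        """Topics in canonical order where applicable, then alphabetical."""
        canon = [t for t in CANONICAL_TOPICS if t in self.topics]
        rest = sorted(t for t in self.topics if t not in CANONICAL_TOPICS)
        return canon + rest

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "TopicLexicon":
        return cls({t: [LexEntry.parse(e) for e in entries] for t, entries in mapping.items()})


@dataclass
class FalsePositiveLexicon:
    """Per-topic phrases whose matches suppress spurious topic hits."""

    entries: dict[str, list[LexEntry]] = field(default_factory=dict)

    def validate_against(self, lexicon: TopicLexicon) -> None:
        unknown = set(self.entries) - set(lexicon.topics)
        if unknown:
            raise LexiconError(
                f"false-positive lexicon names topics absent from the topic lexicon: {sorted(unknown)}"
            )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "FalsePositiveLexicon":
        return cls({t: [LexEntry.parse(e) for e in entries] for t, entries in mapping.items()})


# ---------------------------------------------------------------------------
# YAML I/O
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML lexicon config into typed lexicon objects.

    Returns a dict with any of the keys ``relevance`` (RelevanceConfig),
    ``distress`` (DistressLexicon), ``topics`` (TopicLexicon) and
    ``false_positives`` (FalsePositiveLexicon) that the file defines.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    if "relevance" in raw:
        out["relevance"] = RelevanceConfig.from_lists(
            raw["relevance"], raw.get("exclusions", ())
        )
    if "distress" in raw:
        block = raw["distress"]
        if isinstance(block, list):
            block = {"unigrams": block}
        out["distress"] = DistressLexicon.from_lists(
            block.get("unigrams", ()), block.get("phrases", ())
        )
    if "topics" in raw:
        terms: dict[str, list[str]] = {}
        fps: dict[str, list[str]] = {}
        for topic, block in raw["topics"].items():
            if isinstance(block, list):
                block = {"terms": block}
            terms[topic] = list(block.get("terms", ()))
            if block.get("false_positives"):
                fps[topic] = list(block["false_positives"])
        out["topics"] = TopicLexicon.from_mapping(terms)
        out["false_positives"] = FalsePositiveLexicon.from_mapping(fps)
        out["false_positives"].validate_against(out["topics"])
    return out


def dump_config(path: str | Path, **sections) -> Path:
    """Write lexicon objects back to a YAML config (inverse of load_config)."""
    raw: dict = {}
    if "relevance" in sections:
        rc: RelevanceConfig = sections["relevance"]
        raw["relevance"] = [e.display() for e in rc.keywords]
        raw["exclusions"] = [e.display() for e in rc.exclusion_contexts]
    if "distress" in sections:
        dl: DistressLexicon = sections["distress"]
        raw["distress"] = {
            "unigrams": [e.display() for e in dl.unigrams],
            "phrases": [e.display() for e in dl.phrases],
        }
    if "topics" in sections:
        tl: TopicLexicon = sections["topics"]
        fp: FalsePositiveLexicon = sections.get(
            "false_positives", FalsePositiveLexicon()
        )
        raw["topics"] = {
            t: {
                "terms": [e.display() for e in entries],
                "false_positives": [e.display() for e in fp.entries.get(t, ())],
            }
            for t, entries in tl.topics.items()
        }
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False, allow_unicode=True)
    return path


# ---------------------------------------------------------------------------
# Shipped illustrative defaults
# ---------------------------------------------------------------------------

def default_relevance() -> RelevanceConfig:
    """IBD relevance keywords (substring mode) and off-topic contexts.

    "ibd" is also the abbreviation of Investor's Business Daily, and IBD is
    a common veterinary diagnosis; the exclusion contexts drop those senses.
    """
    return RelevanceConfig.from_lists(
        ["crohn", "ibd", "colitis", "inflammatory bowel disease", "ileitis", "ileoceceal"],
        ["investors business daily", "my dog has", "my cat has"],
    )


def default_distress() -> DistressLexicon:
    """Illustrative distress lexicon (a stand-in for a ~300-entry curated list)."""
    return DistressLexicon.from_lists(
        unigrams=[
            "afraid", "scared", "anxiety", "anxious", "depressed", "depression",
            "distress", "worried", "stressed", "struggling", "fear", "crying",
            "overwhelmed", "hopeless", "miserable", "exhausted", "isolated",
            "suffering", "terrified", "lonely",
        ],
        phrases=[
            "feel alone", "hard to manage", "cant cope", "so hard to deal",
            "breaking down", "cant take it",
        ],
    )


#: Per-topic term dictionaries.  Terms without ``*`` match exact tokens;
#: multi-word terms match consecutive tokens.  Deliberately includes a few
#: ambiguous terms ("tired", "bag", "pot", ...) that motivate the
#: false-positive dictionary below.
_DEFAULT_TOPIC_TERMS: dict[str, list[str]] = {
    "symptoms": [
        "symptom", "symptoms", "flare", "flares", "flare up", "flare ups",
        "pain", "stomach", "diarrhea", "cramps", "bleeding", "fatigue",
        "nausea", "sick", "tired", "gut",
    ],
    "medication": [
        "medication", "medications", "meds", "stelara", "prednisone",
        "steroids", "humira", "remicade", "infusion", "drugs",
    ],
    "nutrition": [
        "nutrition", "fodmap", "diet", "fiber", "alcohol", "gluten",
        "dairy", "eating",
    ],
    "procedures": [
        "procedure", "procedures", "surgery", "colonoscopy", "endoscopy",
        "resection", "scope",
    ],
    "marijuana": ["marijuana", "weed", "cannabis", "cbd", "pot"],
    "stigma": ["stigma", "taboo", "awkward", "embarrassing", "uncomfortable", "shame"],
    "ostomy": ["ostomy", "stoma", "ileostomy", "colostomy", "bag"],
    "intimacy": ["intimacy", "dating", "date", "relationship", "relationships", "partner"],
}

#: Phrases that fire the ambiguous terms above in non-topical senses.
_DEFAULT_FP_PHRASES: dict[str, list[str]] = {
    "symptoms": ["tired of explaining", "sick of explaining"],
    "medication": ["war on drugs"],
    "nutrition": ["diet coke"],
    "procedures": ["plastic surgery"],
    "marijuana": ["pot of coffee"],
    "stigma": ["what a shame"],
    "ostomy": ["shopping bag", "sleeping bag"],
    "intimacy": ["expiration date", "up to date"],
}


def default_topics() -> TopicLexicon:
    """The shipped 8-topic dictionary (illustrative, canonical profile)."""
    lex = TopicLexicon.from_mapping(_DEFAULT_TOPIC_TERMS)
    lex.validate_canonical()
    return lex


def default_false_positives() -> FalsePositiveLexicon:
    return FalsePositiveLexicon.from_mapping(_DEFAULT_FP_PHRASES)
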