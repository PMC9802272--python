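"""Post/corpus data model and JSONL / CSV interchange.

The on-disk interchange format is JSON Lines: one post object per line,
UTF-8, ISO-8601 UTC timestamps.  CSV export flattens the gold-label set to
a semicolon-joined string and serializes unknown extra metadata as a JSON
column, so both formats round-trip field-for-field.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

PLATFORMS = ("reddit", "twitter")
POST_TYPES = ("submission", "comment", "tweet")
TWEET_MAX_CHARS = 280

_CORE_FIELDS = (
    "post_id",
    "platform",
    "author",
    "timestamp",
    "text",
    "post_type",
    "subreddit",
    "is_retweet",
    "gold_labels",
)


class CorpusError(Exception):
    """Base error for corpus ingest/serialization problems."""


class FormatError(CorpusError):
    """Raised when a file is structurally unreadable as a corpus."""


class IngestError(CorpusError):
    """Raised on invariant violations such as duplicate post ids."""


@dataclass(frozen=True)
class GoldLabels:
    """Ground-truth annotations carried by synthetic corpora only."""

    topics: frozenset[str] = frozenset()
    distress: bool = False

    def to_json(self) -> dict:
        return {"topics": sorted(self.topics), "distress": self.distress}

    @classmethod
    def from_json(cls, obj: dict) -> "GoldLabels":
        return cls(frozenset(obj.get("topics", ())), bool(obj.get("distress", False)))


@dataclass
class Post:
    """One social-media record.

    ``subreddit`` is meaningful only for reddit posts and ``is_retweet``
    only for twitter posts; the constructor nulls out the field belonging
    to the other platform.  Unknown metadata from platform dumps is kept
    opaquely in ``extra`` and survives round-trips.
    """

    post_id: str
    platform: str
    text: str
    author: str = ""
    timestamp: Optional[datetime] = None
    post_type: str = "comment"
    subreddit: Optional[str] = None
    is_retweet: Optional[bool] = None
    gold_labels: Optional[GoldLabels] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise IngestError(f"unknown platform {self.platform!r} for post {self.post_id!r}")
        if self.post_type not in POST_TYPES:
            raise IngestError(f"unknown post_type {self.post_type!r} for post {self.post_id!r}")
        if self.platform == "reddit":
            self.is_retweet = None
        else:
            self.subreddit = None
            if self.is_retweet is None:
                self.is_retweet = False
            if len(self.text) > TWEET_MAX_CHARS:
                logger.warning(
                    "tweet %s exceeds %d characters (len=%d)",
                    self.post_id, TWEET_MAX_CHARS, len(self.text),
                )
        if self.timestamp is not None and self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.replace(tzinfo=timezone.utc)

    def to_json(self) -> dict:
        obj = {
            "post_id": self.post_id,
            "platform": self.platform,
            "author": self.author,
            "timestamp": self.timestamp.isoformat() if self.timestamp else None,
            "text": self.text,
            "post_type": self.post_type,
        }
        if self.platform == "reddit":
            obj["subreddit"] = self.subreddit
        else:
            obj["is_retweet"] = self.is_retweet
        if self.gold_labels is not None:
            obj["gold_labels"] = self.gold_labels.to_json()
        for k, v in self.extra.items():
            if k not in obj:
                obj[k] = v
        return obj

    @classmethod
    def from_json(cls, obj: dict) -> "Post":
        missing = [k for k in ("post_id", "platform", "text") if k not in obj]
        if missing:
            raise FormatError(f"record missing required field(s) {missing}")
        ts = obj.get("timestamp")
        gold = obj.get("gold_labels")
        return cls(
            post_id=str(obj["post_id"]),
            platform=obj["platform"],
            text=obj["text"],
            author=obj.get("author", "") or "",
            timestamp=datetime.fromisoformat(ts) if ts else None,
            post_type=obj.get(
                "post_type", "tweet" if obj["platform"] == "twitter" else "comment"
            ),
            subreddit=obj.get("subreddit"),
            is_retweet=obj.get("is_retweet"),
            gold_labels=GoldLabels.from_json(gold) if gold else None,
            extra={k: v for k, v in obj.items() if k not in _CORE_FIELDS},
        )


@dataclass
class LoadReport:
    """Accounting for one ingest: well-formed + skipped = lines read."""

    lines_read: int = 0
    well_formed: int = 0
    skipped: int = 0

    def __post_init__(self) -> None:
        assert self.well_formed + self.skipped == self.lines_read


@dataclass
class Corpus:
    """An ordered collection of posts with unique ids."""

    posts: list[Post] = field(default_factory=list)
    provenance: str = ""
    load_report: Optional[LoadReport] = None

    @property
    def N(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts)

    def __len__(self) -> int:
        return len(self.posts)

    def validate(self) -> None:
        seen: set[str] = set()
        for p in self.posts:
            if p.post_id in seen:
                raise IngestError(f"duplicate post_id {p.post_id!r}")
            seen.add(p.post_id)

    def subset(self, posts: Iterable[Post], provenance_suffix: str = "") -> "Corpus":
        return Corpus(list(posts), provenance=self.provenance + provenance_suffix)


def read_corpus(path: str | Path, format: str = "jsonl") -> Corpus:
    """Load a corpus, skipping (and counting) malformed records.

    Raises :class:`FormatError` when no record is well-formed in a
    non-empty file, and :class:`IngestError` on duplicate post ids.
    """
    path = Path(path)
    if format == "jsonl":
        records = _iter_jsonl(path)
    elif format == "csv":
        records = _iter_csv(path)
    else:
        raise ValueError(f"unknown corpus format {format!r}")

    posts: list[Post] = []
    report = LoadReport()
    for raw in records:
        report.lines_read += 1
        try:
            posts.append(Post.from_json(raw))
            report.well_formed += 1
        except (CorpusError, KeyError, ValueError, TypeError) as exc:
            report.skipped += 1
            logger.info("skipping malformed record %d: %s", report.lines_read, exc)
    if report.lines_read > 0 and report.well_formed == 0:
        raise FormatError(f"{path}: no well-formed records among {report.lines_read}")
    corpus = Corpus(posts, provenance=str(path), load_report=report)
    corpus.validate()
    logger.info(
        "loaded %s: %d well-formed, %d skipped of %d lines",
        path, report.well_formed, report.skipped, report.lines_read,
    )
    return corpus


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> Path:
    """Serialize a corpus; ``read_corpus`` of the result reproduces it."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for post in corpus.posts:
                fh.write(json.dumps(post.to_json(), ensure_ascii=False) + "\n")
    elif format == "csv":
        _write_csv(corpus, path)
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    return path


def _iter_jsonl(path: Path) -> Iterator[dict]:
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError:
                yield {"__malformed__": line}
                continue
            yield obj if isinstance(obj, dict) else {"__malformed__": obj}


_CSV_COLUMNS = [
    "post_id", "platform", "author", "timestamp", "text", "post_type",
    "subreddit", "is_retweet", "gold_topics", "gold_distress", "extra",
]


def _write_csv(corpus: Corpus, path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
        writer.writeheader()
        for p in corpus.posts:
            writer.writerow({
                "post_id": p.post_id,
                "platform": p.platform,
                "author": p.author,
                "timestamp": p.timestamp.isoformat() if p.timestamp else "",
                "text": p.text,
                "post_type": p.post_type,
                "subreddit": p.subreddit or "",
                "is_retweet": "" if p.is_retweet is None else str(int(p.is_retweet)),
                "gold_topics": ";".join(sorted(p.gold_labels.topics)) if p.gold_labels else "",
                "gold_distress": (
                    str(int(p.gold_labels.distress)) if p.gold_labels else ""
                ),
                "extra": json.dumps(p.extra, ensure_ascii=False) if p.extra else "",
            })


def _iter_csv(path: Path) -> Iterator[dict]:
    with path.open("r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            obj: dict = {
                "post_id": row.get("post_id"),
                "platform": row.get("platform"),
                "text": row.get("text"),
                "author": row.get("author", ""),
                "post_type": row.get("post_type") or None,
            }
            obj = {k: v for k, v in obj.items() if v is not None}
            if row.get("timestamp"):
                obj["timestamp"] = row["timestamp"]
            if row.get("subreddit"):
                obj["subreddit"] = row["subreddit"]
            if row.get("is_retweet"):
                obj["is_retweet"] = bool(int(row["is_retweet"]))
            if row.get("gold_distress") or row.get("gold_topics"):
                topics = [t for t in (row.get("gold_topics") or "").split(";") if t]
                obj["gold_labels"] = {
                    "topics": topics,
                    "distress": bool(int(row.get("gold_distress") or 0)),
                }
            if row.get("extra"):
                obj.update(json.loads(row["extra"]))
            if "post_type" not in obj or not obj.get("post_type"):
                obj.pop("post_type", None)
            yield obj
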