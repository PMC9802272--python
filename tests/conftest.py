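from datetime import datetime, timedelta, timezone

import pytest

from ibdtopics import Corpus, GoldLabels, Post


@pytest.fixture
def make_post():
    """Factory for quick posts with sensible defaults."""
    counter = {"n": 0}

    def _make(text, platform="reddit", author="alice", post_id=None,
              timestamp=None, gold_topics=None, gold_distress=False, **kwargs):
        counter["n"] += 1
        if post_id is None:
            post_id = f"p{counter['n']:03d}"
        if timestamp is None:
            timestamp = datetime(2018, 1, 1, tzinfo=timezone.utc) + timedelta(
                minutes=counter["n"]
            )
        gold = None
        if gold_topics is not None or gold_distress:
            gold = GoldLabels(frozenset(gold_topics or ()), gold_distress)
        if platform == "twitter":
            kwargs.setdefault("post_type", "tweet")
        return Post(
            post_id=post_id, platform=platform, text=text, author=author,
            timestamp=timestamp, gold_labels=gold, **kwargs,
        )

    return _make


@pytest.fixture
def make_corpus(make_post):
    def _make(*texts_or_posts, **kwargs):
        posts = [
            p if isinstance(p, Post) else make_post(p, **kwargs)
            for p in texts_or_posts
        ]
        return Corpus(list(posts), provenance="test")

    return _make
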