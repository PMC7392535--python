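"""Co-occurrence query over a tweet stream.

Keeps tweets inside the study window that contain at least one grief keyword
and at least one territory identifier (directly or through a killer form),
and attributes each kept tweet to the territory/ies it references. Window
membership uses the tweet's local calendar date in the study timezone
(America/Chicago), inclusive on both ends.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Iterator
from zoneinfo import ZoneInfo

from .lexicon import GriefLexicon, LexiconMatcher, LexiconRegistry

logger = logging.getLogger(__name__)

LOCAL_TZ = ZoneInfo("America/Chicago")


@dataclass(frozen=True)
class Tweet:
    """One short-text record: author, timestamp, text, retweet flag, mentions."""

    tweet_id: str
    user_id: str
    created_at: datetime
    text: str
    is_retweet: bool = False
    mentions: tuple[str, ...] = ()

    def local_date(self) -> date:
        """Calendar date in the study timezone; daily binning uses this."""
        ts = self.created_at
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=LOCAL_TZ)
        return ts.astimezone(LOCAL_TZ).date()

    def to_json(self) -> str:
        return json.dumps(
            {
                "id": self.tweet_id,
                "user_id": self.user_id,
                "created_at": self.created_at.isoformat(),
                "text": self.text,
                "is_retweet": self.is_retweet,
                "mentions": list(self.mentions),
            },
            sort_keys=True,
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, line: str) -> "Tweet":
        obj = json.loads(line)
        return cls(
            tweet_id=str(obj["id"]),
            user_id=str(obj["user_id"]),
            created_at=datetime.fromisoformat(obj["created_at"]),
            text=obj["text"],
            is_retweet=bool(obj.get("is_retweet", False)),
            mentions=tuple(obj.get("mentions", ())),
        )


@dataclass(frozen=True)
class CandidateTweet:
    """A tweet passing the co-occurrence contract, with its lexicon hits."""

    tweet: Tweet
    grief_hits: frozenset[str]
    territory_ids: frozenset[str]
    via_killer_form: bool = False

    def __post_init__(self) -> None:
        if not self.grief_hits or not self.territory_ids:
            raise ValueError(
                "candidate requires >=1 grief hit and >=1 territory hit"
            )


def write_tweets_jsonl(path: str | Path, tweets: Iterable[Tweet]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tw in tweets:
            fh.write(tw.to_json() + "\n")


def read_tweets_jsonl(path: str | Path) -> Iterator[Tweet]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield Tweet.from_json(line)


def query_stream(
    stream: Iterable[Tweet],
    grief: GriefLexicon,
    registry: LexiconRegistry,
    window: tuple[date, date],
) -> list[CandidateTweet]:
    """Apply the co-occurrence query to a stream.

    Returns exactly the in-window tweets with >=1 grief hit and >=1 territory
    hit, in stable (created_at, tweet_id) order. Records with unparseable
    timestamps are skipped with a logged warning and counted.
    """
    start, end = window
    if start > end:
        raise ValueError(f"invalid window {start}..{end}")
    matcher = LexiconMatcher(grief, registry)
    kept: list[CandidateTweet] = []
    n_bad_ts = 0
    for tweet in stream:
        try:
            local = tweet.local_date()
        except (ValueError, OverflowError, AttributeError, TypeError):
            n_bad_ts += 1
            logger.warning("skipping tweet %s: unparseable timestamp", tweet.tweet_id)
            continue
        if not (start <= local <= end):
            continue
        grief_hits, terr_hits, via_killer = matcher.match(tweet.text)
        if grief_hits and terr_hits:
            kept.append(
                CandidateTweet(
                    tweet=tweet,
                    grief_hits=frozenset(grief_hits),
                    territory_ids=frozenset(terr_hits),
                    via_killer_form=via_killer,
                )
            )
    if n_bad_ts:
        logger.warning("query_stream skipped %d records with bad timestamps", n_bad_ts)
    kept.sort(key=lambda c: (c.tweet.created_at, c.tweet.tweet_id))
    return kept


def assign_territories(candidate: CandidateTweet) -> list[tuple[str, Tweet]]:
    """Fan a candidate out to one (territory_id, tweet) pair per territory hit.

    A tweet naming two territories contributes to both territory streams;
    community-level counting is preserved rather than discarding ambiguity.
    """
    return [(tid, candidate.tweet) for tid in sorted(candidate.territory_ids)]
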