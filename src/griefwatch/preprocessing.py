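"""Filtering and normalization chain for candidate tweets.

Rule order (fixed): retweet filter -> handle-keyword filter -> same-user/
same-day dedup -> lowercase + masking -> punctuation/length/character-collapse
-> lemmatization. Masking renders tweets non-territory-specific by replacing
identifiers, URLs, emails, phone numbers and @-mentions with sentinel tokens,
so classifier features generalize across territories. Identical texts by
*different* users on the same day are all retained — simultaneous identical
posts are exactly the collective signal the pipeline measures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

from .extraction import Tweet
from .lexicon import (
    GriefLexicon,
    LexiconRegistry,
    normalize_phrase,
    tokenize_matchable,
)

MASK_IDENTIFIER = "_IDENTIFIER_"
MASK_URL = "_URL_"
MASK_EMAIL = "_EMAIL_"
MASK_PHONE = "_PHONE_"
MASK_MENTION = "_MENTION_"

_SENTINEL_RE = re.compile(r"(_(?:IDENTIFIER|URL|EMAIL|PHONE|MENTION)_)")

_URL_RE = re.compile(r"\[url\]|https?://\S+|www\.\S+")
_EMAIL_RE = re.compile(r"\b[\w.+-]+@[\w-]+\.[\w.-]+\b")
_PHONE_RE = re.compile(r"\b(?:\+?1[\s.-]?)?(?:\(\d{3}\)|\d{3})[\s.-]?\d{3}[\s.-]?\d{4}\b")
_MENTION_RE = re.compile(r"@\w+")
_REPEAT_RE = re.compile(r"(.)\1{2,}")
_NONWORD_RE = re.compile(r"[^a-z0-9_]+")


@dataclass(frozen=True)
class NormalizedTweet:
    """A cleaned per-territory record ready for classification and counting."""

    tweet_id: str
    territory_id: str
    date: date
    masked_text: str
    tokens: tuple[str, ...]
    raw_text: str = ""  # unmasked text retained for reporting / name matching


# ---------------------------------------------------------------------------
# stream-level filters
# ---------------------------------------------------------------------------

def _handle_contains_grief(handle: str, variants_norm: set[str]) -> bool:
    squashed = re.sub(r"[^a-z0-9]+", "", handle.lower().lstrip("@"))
    return any(v.replace(" ", "") in squashed for v in variants_norm)


def filter_stream(
    candidates: Sequence[tuple[str, Tweet]],
    grief: GriefLexicon,
    counts: dict[str, int] | None = None,
) -> list[tuple[str, Tweet]]:
    """Apply retweet removal, handle-keyword exclusion, and dedup.

    Dedup keeps, per (user, territory, local date, exact text) group, the
    earliest tweet only. ``counts`` (optional dict) receives per-rule drop
    counts for logging.
    """
    variants_norm = {normalize_phrase(v) for v in grief.all_variants()}
    drop = {"retweet": 0, "handle_keyword": 0, "duplicate": 0}

    stage1: list[tuple[str, Tweet]] = []
    for tid, tw in candidates:
        if tw.is_retweet:
            drop["retweet"] += 1
            continue
        stage1.append((tid, tw))

    stage2: list[tuple[str, Tweet]] = []
    for tid, tw in stage1:
        handles = list(tw.mentions) or [t for t in tw.text.split() if t.startswith("@")]
        grief_handle = any(_handle_contains_grief(h, variants_norm) for h in handles)
        if grief_handle:
            # removed only when the handle is the sole source of a grief hit
            body_tokens = tokenize_matchable(tw.text, drop_mentions=True)
            body = " ".join(body_tokens)
            body_hit = any(f" {v} " in f" {body} " for v in variants_norm)
            if not body_hit:
                drop["handle_keyword"] += 1
                continue
        stage2.append((tid, tw))

    best: dict[tuple[str, str, date, str], tuple[str, Tweet]] = {}
    order: list[tuple[str, str, date, str]] = []
    for tid, tw in stage2:
        key = (tw.user_id, tid, tw.local_date(), tw.text)
        if key not in best:
            best[key] = (tid, tw)
            order.append(key)
        else:
            drop["duplicate"] += 1
            if tw.created_at < best[key][1].created_at:
                best[key] = (tid, tw)
    if counts is not None:
        counts.update(drop)
    return [best[k] for k in order]


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def _identifier_pattern(registry: LexiconRegistry) -> re.Pattern | None:
    phrases: set[str] = set()
    for terr in registry:
        for ident in terr.identifiers:
            phrases.add(normalize_phrase(ident))
        for kf in terr.killer_forms:
            phrases.add(normalize_phrase(kf))
    phrases.discard("")
    if not phrases:
        return None
    # longest first so killer forms ("cbek") win over their base identifier
    parts = sorted(phrases, key=len, reverse=True)
    alts = "|".join(re.escape(p).replace(r"\ ", r"\s+") for p in parts)
    return re.compile(rf"(?<![a-z0-9])(?:{alts})(?![a-z0-9])")


def mask_text(text: str, registry: LexiconRegistry) -> str:
    """Lowercase, then mask identifiers, URLs, emails, phones and @-mentions.

    Lowercasing happens first so identifier matching is exact; replacement is
    span-safe (longest identifier first, sentinels never rewritten).
    """
    out = text.lower()
    out = _URL_RE.sub(MASK_URL, out)
    out = _EMAIL_RE.sub(MASK_EMAIL, out)
    out = _PHONE_RE.sub(MASK_PHONE, out)
    out = _MENTION_RE.sub(MASK_MENTION, out)
    pattern = _identifier_pattern(registry)
    if pattern is not None:
        out = pattern.sub(MASK_IDENTIFIER, out)
    return out


class TextMasker:
    """Masker with the identifier pattern compiled once for a whole stream."""

    def __init__(self, registry: LexiconRegistry) -> None:
        self._pattern = _identifier_pattern(registry)

    def mask(self, text: str) -> str:
        out = text.lower()
        out = _URL_RE.sub(MASK_URL, out)
        out = _EMAIL_RE.sub(MASK_EMAIL, out)
        out = _PHONE_RE.sub(MASK_PHONE, out)
        out = _MENTION_RE.sub(MASK_MENTION, out)
        if self._pattern is not None:
            out = self._pattern.sub(MASK_IDENTIFIER, out)
        return out


# ---------------------------------------------------------------------------
# token normalization
# ---------------------------------------------------------------------------

_IRREGULAR_LEMMAS = {
    "children": "child",
    "men": "man",
    "women": "woman",
    "people": "person",
    "feet": "foot",
    "teeth": "tooth",
}

_VOWELS = set("aeiou")


def lemmatize(token: str) -> str:
    """Deterministic rule-based lemmatizer.

    Conservative suffix stripping: plural nouns to singular, ``-ing``/``-ed``
    verb forms to a stem ("running" -> "run"); never produces a stem shorter
    than three characters. Applied to a fixpoint so normalization is
    idempotent ("feelings" -> "feel" in one pass). A lightweight component by
    design — it only needs to collapse inflectional variants consistently,
    not be linguistically complete.
    """
    for _ in range(4):
        out = _lemmatize_once(token)
        if out == token:
            return out
        token = out
    return token


def _lemmatize_once(token: str) -> str:
    if token in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[token]
    if not token.isalpha():
        return token

    # plurals
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith(("sses", "xes", "ches", "shes", "zes")) and len(token) > 4:
        return token[:-2]
    if (
        token.endswith("s")
        and not token.endswith(("ss", "us", "is"))
        and len(token) >= 4
    ):
        return token[:-1]

    # -ing / -ed verb forms
    for suffix, min_len in (("ing", 6), ("ed", 5)):
        if token.endswith(suffix) and len(token) >= min_len:
            stem = token[: -len(suffix)]
            if len(stem) < 3:
                break
            if suffix == "ed" and stem.endswith("i"):
                return stem[:-1] + "y"  # cried -> cry
            if (
                len(stem) >= 4
                and stem[-1] == stem[-2]
                and stem[-1] not in _VOWELS
                and stem[-1] not in "ls"
            ):
                stem = stem[:-1]  # running -> run
            return stem
    return token


def collapse_repeats(token: str) -> str:
    """Collapse runs of three or more identical characters to one occurrence
    ("looool" -> "lol")."""
    return _REPEAT_RE.sub(r"\1", token)


def normalize_tokens(masked_text: str) -> list[str]:
    """Punctuation to spaces, collapse repeats, drop tokens of length <= 2,
    lemmatize. Mask sentinels pass through intact; order is preserved."""
    tokens: list[str] = []
    for part in _SENTINEL_RE.split(masked_text):
        if not part:
            continue
        if _SENTINEL_RE.fullmatch(part):
            tokens.append(part)
            continue
        for raw in _NONWORD_RE.sub(" ", part.replace("_", " ")).split():
            tok = collapse_repeats(raw)
            if len(tok) <= 2:
                continue
            tok = lemmatize(tok)
            if len(tok) > 2:
                tokens.append(tok)
    return tokens


def write_normalized_jsonl(path, records: Iterable[NormalizedTweet]) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for nt in records:
            fh.write(
                json.dumps(
                    {
                        "tweet_id": nt.tweet_id,
                        "territory_id": nt.territory_id,
                        "date": nt.date.isoformat(),
                        "masked_text": nt.masked_text,
                        "tokens": list(nt.tokens),
                        "raw_text": nt.raw_text,
                    },
                    sort_keys=True,
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_normalized_jsonl(path) -> list[NormalizedTweet]:
    import json

    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            out.append(
                NormalizedTweet(
                    tweet_id=obj["tweet_id"],
                    territory_id=obj["territory_id"],
                    date=date.fromisoformat(obj["date"]),
                    masked_text=obj["masked_text"],
                    tokens=tuple(obj["tokens"]),
                    raw_text=obj.get("raw_text", ""),
                )
            )
    return out


def normalize_stream(
    filtered: Iterable[tuple[str, Tweet]], registry: LexiconRegistry
) -> list[NormalizedTweet]:
    """Mask and tokenize a filtered (territory_id, tweet) stream."""
    masker = TextMasker(registry)
    out = []
    for tid, tw in filtered:
        masked = masker.mask(tw.text)
        out.append(
            NormalizedTweet(
                tweet_id=tw.tweet_id,
                territory_id=tid,
                date=tw.local_date(),
                masked_text=masked,
                tokens=tuple(normalize_tokens(masked)),
                raw_text=tw.text,
            )
        )
    return out
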