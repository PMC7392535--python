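"""Grief-keyword and territory-identifier lexicons.

The extraction query is a co-occurrence rule: a tweet is a candidate when it
contains at least one traumatic-grief keyword (canonical families ``RIP``,
``Rest Up``, ``Long Live``, each with surface variants such as ``r.i.p`` or
``rest in peace``) and at least one online territory identifier — a word,
acronym, or hashtag that uniquely signals one gang faction / neighborhood.
Identifiers appended with the suffix ``k`` ("killer" forms) name a rival
faction and also count as a reference to the identifier's owner.

Matching is case-insensitive and punctuation-tolerant: tokens are *squashed*
(non-alphanumeric characters removed) before lookup, so ``R.I.P`` and ``#rip``
both hit the ``rip`` variant, while ``trip`` does not (whole-token matching).
Grief and territory matches inside @-mention tokens are ignored; a handle like
``@rip_legend`` carries neither grief content nor spatial context.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CANONICAL_GRIEF_KEYWORDS = ("RIP", "Rest Up", "Long Live")

#: Default surface variants for each canonical grief keyword family.
DEFAULT_GRIEF_VARIANTS: dict[str, tuple[str, ...]] = {
    "RIP": ("rip", "r.i.p", "r i p", "rest in peace"),
    "Rest Up": ("rest up", "restup"),
    "Long Live": ("long live", "longlive"),
}

_SQUASH_RE = re.compile(r"[^a-z0-9]+")


def _squash(word: str) -> str:
    """Lowercase a word and strip every non-alphanumeric character."""
    return _SQUASH_RE.sub("", word.lower())


def normalize_phrase(phrase: str) -> str:
    """Canonical matchable form of a variant/identifier: per-word squash,
    single spaces. ``"R.I.P"`` -> ``"rip"``, ``"Benzie  Block"`` -> ``"benzie block"``.
    """
    words = [_squash(w) for w in phrase.split()]
    return " ".join(w for w in words if w)


def tokenize_matchable(text: str, *, drop_mentions: bool = True) -> list[str]:
    """Squashed tokens of ``text``; @-mention tokens are dropped by default."""
    out = []
    for tok in text.split():
        if drop_mentions and tok.startswith("@"):
            continue
        sq = _squash(tok)
        if sq:
            out.append(sq)
    return out


def is_primarily_numeric(identifier: str) -> bool:
    """True when digits make up more than half of the non-space characters.

    Identifiers like ``#700`` or ``059`` lack specificity and mostly return
    irrelevant content, so they are excluded from registries.
    """
    chars = [c for c in identifier if not c.isspace()]
    if not chars:
        return False
    digits = sum(c.isdigit() for c in chars)
    return digits > len(chars) / 2


@dataclass(frozen=True)
class GriefLexicon:
    """Canonical grief keyword -> set of lowercase surface variants."""

    entries: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("grief lexicon must have at least one keyword")
        seen: dict[str, str] = {}
        for canon, variants in self.entries.items():
            if not variants:
                raise ValueError(f"grief keyword {canon!r} has no variants")
            for v in variants:
                if v != v.lower():
                    raise ValueError(f"variant {v!r} is not lowercase")
                if v in seen:
                    raise ValueError(
                        f"variant {v!r} appears under both {seen[v]!r} and {canon!r}"
                    )
                seen[v] = canon

    @classmethod
    def default(cls) -> "GriefLexicon":
        return cls({k: frozenset(v) for k, v in DEFAULT_GRIEF_VARIANTS.items()})

    def all_variants(self) -> set[str]:
        return {v for vs in self.entries.values() for v in vs}


@dataclass(frozen=True)
class TerritoryLexicon:
    """Identifier set for one territory, plus derived killer ("k") forms."""

    territory_id: str
    identifiers: frozenset[str]
    killer_forms: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        expected = frozenset(i + "k" for i in self.identifiers)
        if not self.killer_forms:
            object.__setattr__(self, "killer_forms", expected)
        elif self.killer_forms != expected:
            raise ValueError(
                f"killer_forms for {self.territory_id!r} must be identifiers + 'k'"
            )
        for ident in self.identifiers:
            if is_primarily_numeric(ident):
                raise ValueError(
                    f"identifier {ident!r} in {self.territory_id!r} is primarily numeric"
                )


class DuplicateIdentifierError(ValueError):
    """An identifier was claimed by two territories; identifiers must be unique."""


@dataclass(frozen=True)
class LexiconRegistry:
    """All territory lexicons, with fast normalized-phrase lookup tables."""

    territories: tuple[TerritoryLexicon, ...]

    def __post_init__(self) -> None:
        owner: dict[str, str] = {}
        for terr in self.territories:
            for ident in terr.identifiers:
                key = normalize_phrase(ident)
                if key in owner and owner[key] != terr.territory_id:
                    raise DuplicateIdentifierError(
                        f"identifier {ident!r} claimed by both "
                        f"{owner[key]!r} and {terr.territory_id!r}"
                    )
                owner[key] = terr.territory_id

    def territory_ids(self) -> list[str]:
        return [t.territory_id for t in self.territories]

    def __iter__(self):
        return iter(self.territories)

    def __len__(self) -> int:
        return len(self.territories)


class _PhraseIndex:
    """n-gram lookup of normalized phrases over squashed token streams."""

    def __init__(self, phrases: Mapping[str, object]) -> None:
        self.by_len: dict[int, dict[tuple[str, ...], object]] = {}
        for phrase, payload in phrases.items():
            words = tuple(phrase.split())
            if not words:
                continue
            self.by_len.setdefault(len(words), {})[words] = payload

    def scan(self, tokens: Sequence[str]):
        """Yield payloads for every phrase occurrence in ``tokens``."""
        for n, table in self.by_len.items():
            if len(tokens) < n:
                continue
            for i in range(len(tokens) - n + 1):
                gram = tuple(tokens[i : i + n])
                if gram in table:
                    yield table[gram]


class LexiconMatcher:
    """Compiled matcher for one grief lexicon plus a territory registry.

    Build once, reuse across a stream; ``match`` is a pure function of the
    tweet text.
    """

    def __init__(self, grief: GriefLexicon, registry: LexiconRegistry) -> None:
        self.grief = grief
        self.registry = registry
        grief_phrases: dict[str, str] = {}
        for canon, variants in grief.entries.items():
            for v in variants:
                grief_phrases[normalize_phrase(v)] = canon
        self._grief_index = _PhraseIndex(grief_phrases)

        terr_phrases: dict[str, tuple[str, bool]] = {}
        for terr in registry:
            for ident in terr.identifiers:
                terr_phrases[normalize_phrase(ident)] = (terr.territory_id, False)
            for kf in terr.killer_forms:
                key = normalize_phrase(kf)
                # an identifier may legitimately equal another's killer form;
                # the direct identifier reading wins
                terr_phrases.setdefault(key, (terr.territory_id, True))
        self._terr_index = _PhraseIndex(terr_phrases)

    def match(self, text: str) -> tuple[set[str], set[str], bool]:
        """Return (grief keyword families hit, territory ids hit, via-killer flag).

        Empty text yields empty sets. Matches inside @-mention tokens never
        count.
        """
        if not text or not text.strip():
            return set(), set(), False
        tokens = tokenize_matchable(text, drop_mentions=True)
        grief_hits = set(self._grief_index.scan(tokens))
        terr_hits: set[str] = set()
        via_killer = False
        for tid, killer in self._terr_index.scan(tokens):
            terr_hits.add(tid)
            via_killer = via_killer or killer
        return grief_hits, terr_hits, via_killer


def match_text(
    text: str, grief: GriefLexicon, registry: LexiconRegistry
) -> tuple[set[str], set[str], bool]:
    """One-shot form of :meth:`LexiconMatcher.match` (compiles per call)."""
    return LexiconMatcher(grief, registry).match(text)


def compile_lexicons(
    grief_rows: Iterable[tuple[str, str]],
    territory_rows: Iterable[tuple[str, str]],
) -> tuple[GriefLexicon, LexiconRegistry]:
    """Build lexicons from (canonical, variant) and (territory_id, identifier) rows.

    Primarily numeric identifiers are dropped with a warning; an identifier
    claimed by two territories raises :class:`DuplicateIdentifierError`; an
    empty grief lexicon raises ``ValueError``.
    """
    grief_map: dict[str, set[str]] = {}
    for canon, variant in grief_rows:
        canon = canon.strip()
        variant = variant.strip().lower()
        if not canon or not variant:
            continue
        grief_map.setdefault(canon, set()).add(variant)
    if not grief_map:
        raise ValueError("grief lexicon is empty")
    grief = GriefLexicon({k: frozenset(v) for k, v in grief_map.items()})

    terr_map: dict[str, set[str]] = {}
    for tid, ident in territory_rows:
        tid = tid.strip()
        ident = ident.strip().lower()
        if not tid or not ident:
            continue
        if is_primarily_numeric(ident):
            logger.warning(
                "dropping primarily numeric identifier %r for territory %r",
                ident,
                tid,
            )
            continue
        terr_map.setdefault(tid, set()).add(ident)
    registry = LexiconRegistry(
        tuple(
            TerritoryLexicon(tid, frozenset(idents))
            for tid, idents in sorted(terr_map.items())
        )
    )
    return grief, registry


# ---------------------------------------------------------------------------
# file representation: CSV with columns (kind, canonical_or_territory_id,
# variant_or_identifier), UTF-8
# ---------------------------------------------------------------------------

def write_lexicon_csv(
    path: str | Path, grief: GriefLexicon, registry: LexiconRegistry
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["kind", "canonical_or_territory_id", "variant_or_identifier"])
        for canon in sorted(grief.entries):
            for v in sorted(grief.entries[canon]):
                writer.writerow(["grief", canon, v])
        for terr in sorted(registry, key=lambda t: t.territory_id):
            for ident in sorted(terr.identifiers):
                writer.writerow(["territory", terr.territory_id, ident])


def read_lexicon_csv(path: str | Path) -> tuple[GriefLexicon, LexiconRegistry]:
    grief_rows: list[tuple[str, str]] = []
    terr_rows: list[tuple[str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            if row["kind"] == "grief":
                grief_rows.append(
                    (row["canonical_or_territory_id"], row["variant_or_identifier"])
                )
            elif row["kind"] == "territory":
                terr_rows.append(
                    (row["canonical_or_territory_id"], row["variant_or_identifier"])
                )
            else:
                raise ValueError(f"unknown lexicon row kind {row['kind']!r}")
    return compile_lexicons(grief_rows, terr_rows)


# ---------------------------------------------------------------------------
# keyword validation by topic modeling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KeywordRanking:
    """Tokens of the most grief-loaded topic, ranked by within-topic weight."""

    ranked: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        weights = [w for _, w in self.ranked]
        if any(b > a for a, b in zip(weights, weights[1:])):
            raise ValueError("weights must be non-increasing")

    def tokens(self) -> list[str]:
        return [t for t, _ in self.ranked]


def validate_keywords(
    corpus: Sequence[Sequence[str]],
    n_topics: int,
    seed: int,
    grief: GriefLexicon | None = None,
) -> KeywordRanking:
    """Rank tokens of the topic most associated with the grief lexicon.

    Fits LDA topic modeling (scikit-learn) on token counts, picks the topic
    with the highest aggregate weight on grief-lexicon word forms, and returns
    that topic's tokens ordered by within-topic weight. Deterministic for a
    fixed ``seed``.
    """
    from sklearn.decomposition import LatentDirichletAllocation
    from sklearn.feature_extraction.text import CountVectorizer

    if not corpus:
        raise ValueError("corpus is empty")
    if n_topics < 1:
        raise ValueError("n_topics must be >= 1")
    if len(corpus) < n_topics:
        raise ValueError(
            f"corpus has {len(corpus)} documents, fewer than n_topics={n_topics}"
        )
    grief = grief or GriefLexicon.default()
    grief_words = {w for v in grief.all_variants() for w in normalize_phrase(v).split()}

    vectorizer = CountVectorizer(
        analyzer=lambda doc: [t.lower() for t in doc], lowercase=False
    )
    counts = vectorizer.fit_transform(corpus)
    vocab = np.asarray(vectorizer.get_feature_names_out())

    lda = LatentDirichletAllocation(
        n_components=n_topics, random_state=seed, learning_method="batch"
    )
    lda.fit(counts)
    grief_cols = np.array([i for i, t in enumerate(vocab) if t in grief_words])
    if grief_cols.size:
        topic = int(np.argmax(lda.components_[:, grief_cols].sum(axis=1)))
    else:
        topic = int(np.argmax(lda.components_.sum(axis=1)))
    weights = lda.components_[topic]
    order = np.argsort(-weights, kind="stable")
    return KeywordRanking(tuple((str(vocab[i]), float(weights[i])) for i in order))
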