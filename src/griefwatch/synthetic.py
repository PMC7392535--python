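"""Synthetic multi-territory tweet stream with known ground truth.

Emulates the statistical structure the analysis assumes: per territory, a
Poisson baseline of everyday memorial chatter; injected loss events that
trigger geometrically decaying bursts of acute-grief tweets ("hours and days
immediately following loss"); single-day anniversary recurrences on yearly
death/birth dates; and irrelevant noise — celebrity-death tweets, out-of-city
tweets, tweets whose only grief keyword sits inside a mentioned handle,
numeric-confusable tags, retweets and same-user duplicates.

Every tweet carries a ground-truth relevance label and the context flags the
annotation rule needs, and the bundle records which territory-days were
engineered to be spikes, so the whole downstream pipeline is testable without
any external data. Output is byte-identical for a fixed seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .classifier import IRRELEVANT, RELEVANT
from .extraction import LOCAL_TZ, Tweet, write_tweets_jsonl
from .lexicon import GriefLexicon, LexiconRegistry, TerritoryLexicon
from .matching import ACUTE, ANNIVERSARY, LossEvent, write_ledger_csv

MAX_TWEET_LEN = 280


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerritoryConfig:
    territory_id: str
    baseline_rate: float  # expected relevant grief tweets/day
    identifiers: tuple[str, ...]
    user_pool_size: int = 60

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.user_pool_size < 1:
            raise ValueError("user_pool_size must be >= 1")


@dataclass(frozen=True)
class EventSeed:
    person_id: str
    aliases: tuple[str, ...]
    death_date: date
    territory_id: str
    birth_date: date | None = None
    burst_magnitude: float = 12.5  # expected extra tweets on day 0
    decay_halflife_days: float = 1.0
    anniversary_magnitude: float = 12.5

    def to_loss_event(self) -> LossEvent:
        return LossEvent(
            person_id=self.person_id,
            aliases=frozenset(a.lower() for a in self.aliases),
            death_date=self.death_date,
            birth_date=self.birth_date,
            territory_id=self.territory_id,
        )


@dataclass(frozen=True)
class NoiseConfig:
    celebrity_rate: float = 0.20  # irrelevant tweets/territory-day, per class
    out_of_city_rate: float = 0.10
    handle_keyword_rate: float = 0.10
    numeric_confusable_rate: float = 0.05
    retweet_probability: float = 0.20
    duplicate_probability: float = 0.05

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class StreamConfig:
    start: date
    end: date
    territories: tuple[TerritoryConfig, ...]
    events: tuple[EventSeed, ...]
    noise: NoiseConfig = NoiseConfig()
    seed: int = 0
    injected_day_min_ratio: float = 20.0  # expectation/baseline ratio for an
    # engineered day to count as ground truth

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("window is empty")
        tids = {t.territory_id for t in self.territories}
        for ev in self.events:
            if ev.territory_id not in tids:
                raise ValueError(f"event {ev.person_id!r}: unknown territory")
            if not (self.start <= ev.death_date <= self.end):
                raise ValueError(
                    f"event {ev.person_id!r}: death_date {ev.death_date} "
                    f"outside window {self.start}..{self.end}"
                )

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass
class TruthBundle:
    tweets: list[Tweet]
    labels: dict[str, str]  # tweet_id -> relevant|irrelevant
    flags: dict[str, dict[str, bool]]
    ledger: list[LossEvent]
    injected_spike_days: dict[str, set[date]]
    injected_day_types: dict[tuple[str, date], str]  # acute | anniversary
    grief: GriefLexicon
    registry: LexiconRegistry
    config: StreamConfig

    def __post_init__(self) -> None:
        ids = [t.tweet_id for t in self.tweets]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate tweet ids")
        if set(ids) != set(self.labels):
            raise ValueError("labels must cover every tweet exactly once")


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------
# Each template is (format, class); relevant classes by construction contain
# >= 1 grief variant and >= 1 identifier outside @-tokens, irrelevant classes
# each violate one relevance rule.

TEMPLATES: dict[str, tuple[str, str]] = {
    "acute1": ("RIP {name} {ident} gone too soon", "acute"),
    "acute2": ("cant believe it rest up {name} {ident}", "acute"),
    "acute3": ("my boy {name} gone long live {name} {ident}", "acute"),
    "acute4": ("R.I.P {name} #{identsq} we love you", "acute"),
    "acute5": ("just got the news {ident} rip {name}", "acute"),
    "anniv1": ("its {name} day rip {name} {ident}", "anniversary"),
    "anniv2": ("another year gone rest up {name} {ident}", "anniversary"),
    "anniv3": ("we out here for {name} day #{identsq} rip", "anniversary"),
    "anniv4": ("happy bday {name} long live {name} {ident}", "anniversary"),
    "base1": ("rip {name} we miss you {ident}", "baseline"),
    "base2": ("long live {name} {ident} forever", "baseline"),
    "base3": ("rest up {name} thinking bout you {ident}", "baseline"),
    "celeb1": ("rip {celeb} the world lost a legend", "celebrity"),
    "celeb2": ("cant believe {celeb} died rip", "celebrity"),
    "city1": ("rip {name} out in {city} praying for {ident} folks", "out_of_city"),
    "city2": ("{ident} fam in {city} rest up {name}", "out_of_city"),
    "handle1": ("@rip_{namesq} thinking bout you {ident}", "handle_keyword"),
    "handle2": ("@longlive{namesq} you already know {ident}", "handle_keyword"),
    "num1": ("rip {name} #{num} forever", "numeric_confusable"),
    "num2": ("rest up {name} #{num}", "numeric_confusable"),
}

_CLASS_TEMPLATES: dict[str, list[str]] = {}
for _tid, (_fmt, _cls) in TEMPLATES.items():
    _CLASS_TEMPLATES.setdefault(_cls, []).append(_tid)

RELEVANT_CLASSES = frozenset({"acute", "anniversary", "baseline"})

#: generic decedent names used in baseline chatter — deliberately absent from
#: any ledger, so baseline-driven spike days stay unmatched.
CHATTER_NAMES = (
    "smokey", "bando", "reese", "juju", "blaze",
    "scooby", "pudge", "tiny", "fresco", "dimes",
)
CELEBRITY_NAMES = ("prince maliko", "sir duke", "queen raina")
CITY_NAMES = ("atlanta", "memphis", "houston", "detroit", "milwaukee")
NUMERIC_TAGS = ("059", "700", "311", "600", "099")


def render_tweet(template_id: str, slots: Mapping[str, str]) -> str:
    """Render one template; raises on unknown slots or overlong output."""
    fmt, _cls = TEMPLATES[template_id]
    try:
        text = fmt.format(**slots)
    except KeyError as exc:
        raise ValueError(f"template {template_id!r} missing slot {exc}") from exc
    if len(text) > MAX_TWEET_LEN:
        raise ValueError(f"rendered tweet exceeds {MAX_TWEET_LEN} characters")
    return text


def _flags_for(cls: str) -> dict[str, bool]:
    return {
        "celebrity_subject": cls == "celebrity",
        "out_of_city": cls == "out_of_city",
        "keyword_only_in_handle": cls == "handle_keyword",
    }


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _burst_profile(magnitude: float, halflife: float, max_days: int) -> list[float]:
    """Expected extra tweets on day 0, 1, ... (geometric decay, truncated)."""
    out = []
    for d in range(max_days):
        lam = magnitude * 2.0 ** (-d / halflife)
        if lam < 0.05:
            break
        out.append(lam)
    return out


def _anniversary_days(ev: EventSeed, start: date, end: date) -> list[date]:
    """In-window yearly recurrences of the death date (later years) and, when
    known, post-death birthday recurrences; Feb-29 maps to Feb-28."""
    days = []
    bases = [(ev.death_date, True)]
    if ev.birth_date is not None:
        bases.append((ev.birth_date, False))
    for base, is_death in bases:
        first_year = base.year + 1 if is_death else ev.death_date.year
        for year in range(first_year, end.year + 1):
            try:
                anniv = base.replace(year=year)
            except ValueError:
                anniv = date(year, 2, 28)
            if not is_death and anniv <= ev.death_date:
                continue
            if start <= anniv <= end:
                days.append(anniv)
    return sorted(set(days))


def simulate_stream(config: StreamConfig) -> TruthBundle:
    """Generate the full stream plus ground truth for one seed.

    Per territory-day the relevant-tweet count is Poisson(baseline + sum of
    event contributions); an event contributes burst_magnitude *
    2^(-days_since_death / halflife) from its death day onward and
    anniversary_magnitude on each yearly recurrence. Noise classes are
    independent Poisson streams; retweets and duplicates are sampled per
    original tweet.
    """
    rng = np.random.default_rng(config.seed)
    n_days = config.n_days
    grief = GriefLexicon.default()
    registry = LexiconRegistry(
        tuple(
            TerritoryLexicon(t.territory_id, frozenset(i.lower() for i in t.identifiers))
            for t in config.territories
        )
    )

    injected: dict[str, set[date]] = {t.territory_id: set() for t in config.territories}
    injected_types: dict[tuple[str, date], str] = {}

    # draft records: (timestamp, user, text, is_retweet, mentions, cls)
    drafts: list[tuple[datetime, str, str, bool, tuple[str, ...], str]] = []

    events_by_tid: dict[str, list[EventSeed]] = {}
    for ev in config.events:
        events_by_tid.setdefault(ev.territory_id, []).append(ev)

    def day_at(i: int) -> date:
        return config.start + timedelta(days=i)

    def stamp(day: date) -> datetime:
        secs = int(rng.integers(0, 86400))
        return datetime(
            day.year, day.month, day.day,
            secs // 3600, (secs % 3600) // 60, secs % 60,
            tzinfo=LOCAL_TZ,
        )

    def pick(seq: Sequence[str]) -> str:
        return seq[int(rng.integers(0, len(seq)))]

    for terr in config.territories:
        tid = terr.territory_id
        users = [f"u_{tid}_{i:03d}" for i in range(terr.user_pool_size)]
        idents = [i.lower() for i in terr.identifiers]

        # expected extra tweets per day, split by (event, kind)
        contribs: list[tuple[EventSeed, str, np.ndarray]] = []
        for ev in events_by_tid.get(tid, []):
            lam = np.zeros(n_days)
            start_off = (ev.death_date - config.start).days
            profile = _burst_profile(
                ev.burst_magnitude, ev.decay_halflife_days, n_days - start_off
            )
            for d, v in enumerate(profile):
                lam[start_off + d] = v
            contribs.append((ev, ACUTE, lam))
            if ev.burst_magnitude >= config.injected_day_min_ratio * terr.baseline_rate - 1e-9:
                injected[tid].add(ev.death_date)
                injected_types[(tid, ev.death_date)] = ACUTE

            ann = np.zeros(n_days)
            for ad in _anniversary_days(ev, config.start, config.end):
                ann[(ad - config.start).days] += ev.anniversary_magnitude
                if ev.anniversary_magnitude >= config.injected_day_min_ratio * terr.baseline_rate - 1e-9:
                    injected[tid].add(ad)
                    injected_types.setdefault((tid, ad), ANNIVERSARY)
            contribs.append((ev, ANNIVERSARY, ann))

        base_counts = rng.poisson(terr.baseline_rate, n_days)
        event_counts = [rng.poisson(lam) for _, _, lam in contribs]
        noise = config.noise
        noise_counts = {
            "celebrity": rng.poisson(noise.celebrity_rate, n_days),
            "out_of_city": rng.poisson(noise.out_of_city_rate, n_days),
            "handle_keyword": rng.poisson(noise.handle_keyword_rate, n_days),
            "numeric_confusable": rng.poisson(noise.numeric_confusable_rate, n_days),
        }

        for i in range(n_days):
            day = day_at(i)
            originals: list[tuple[datetime, str, str, tuple[str, ...], str]] = []

            def render(cls: str, name: str) -> tuple[str, tuple[str, ...]]:
                template_id = pick(_CLASS_TEMPLATES[cls])
                ident = pick(idents)
                slots = {
                    "name": name,
                    "namesq": name.replace(" ", ""),
                    "ident": ident,
                    "identsq": ident.replace(" ", ""),
                    "celeb": pick(CELEBRITY_NAMES),
                    "city": pick(CITY_NAMES),
                    "num": pick(NUMERIC_TAGS),
                }
                text = render_tweet(template_id, slots)
                mentions = tuple(t for t in text.split() if t.startswith("@"))
                return text, mentions

            for _ in range(int(base_counts[i])):
                text, mentions = render("baseline", pick(CHATTER_NAMES))
                originals.append((stamp(day), pick(users), text, mentions, "baseline"))
            for (ev, kind, _lam), counts in zip(contribs, event_counts):
                for _ in range(int(counts[i])):
                    cls = "acute" if kind == ACUTE else "anniversary"
                    text, mentions = render(cls, pick(list(sorted(ev.aliases))))
                    originals.append((stamp(day), pick(users), text, mentions, cls))
            for cls, counts in noise_counts.items():
                for _ in range(int(counts[i])):
                    text, mentions = render(cls, pick(CHATTER_NAMES))
                    originals.append((stamp(day), pick(users), text, mentions, cls))

            for ts, user, text, mentions, cls in originals:
                drafts.append((ts, user, text, False, mentions, cls))
                if rng.random() < noise.duplicate_probability:
                    drafts.append((stamp(day), user, text, False, mentions, cls))
                if rng.random() < noise.retweet_probability:
                    rt_user = pick(users)
                    rt_text = f"rt @{user} {text}"
                    drafts.append(
                        (stamp(day), rt_user, rt_text, True, (f"@{user}",) + mentions, cls)
                    )

    # stable chronological ids
    drafts.sort(key=lambda d: (d[0], d[1], d[2]))
    tweets: list[Tweet] = []
    labels: dict[str, str] = {}
    flags: dict[str, dict[str, bool]] = {}
    for n, (ts, user, text, is_rt, mentions, cls) in enumerate(drafts):
        tweet_id = f"t{n:08d}"
        tweets.append(
            Tweet(
                tweet_id=tweet_id,
                user_id=user,
                created_at=ts,
                text=text,
                is_retweet=is_rt,
                mentions=mentions,
            )
        )
        labels[tweet_id] = RELEVANT if cls in RELEVANT_CLASSES else IRRELEVANT
        flags[tweet_id] = _flags_for(cls)

    return TruthBundle(
        tweets=tweets,
        labels=labels,
        flags=flags,
        ledger=[ev.to_loss_event() for ev in config.events],
        injected_spike_days=injected,
        injected_day_types=injected_types,
        grief=grief,
        registry=registry,
        config=config,
    )


# ---------------------------------------------------------------------------
# the default study conditions
# ---------------------------------------------------------------------------

# (name, baseline tweets/day, death dates) — baselines follow the reference
# deployment's per-territory daily averages (floored at 0.10 so every
# territory clears the 100-tweet stable-presence bar with Poisson margin);
# high-activity territories carry more loss events, mirroring the observed
# pattern that busy territories produced the most spikes. Deaths in earlier
# years yield in-window yearly anniversaries.
_DEFAULT_TERRITORIES: tuple[tuple[str, float, tuple[str, ...]], ...] = (
    ("ashgrove", 0.53, ("2015-04-12",)),
    ("briarfield", 0.10, ("2016-03-21",)),
    ("calloway", 0.63, ("2014-06-18",)),
    ("dunmore", 1.48, ("2013-03-15", "2015-10-05")),
    ("eastbrook", 0.24, ("2016-08-14",)),
    ("fernwood", 0.55, ("2015-07-22",)),
    ("glenrose", 0.44, ("2015-09-03",)),
    ("harlow", 0.18, ("2016-05-10",)),
    ("ivydale", 0.59, ("2015-02-11",)),
    ("juniper", 0.20, ("2016-10-02",)),
    ("kenmore", 0.10, ("2016-04-18",)),
    ("larkspur", 0.10, ("2016-07-09",)),
    ("maplecrest", 0.56, ("2015-11-19",)),
    ("northgate", 0.10, ("2016-02-24",)),
    ("oakmont", 0.13, ("2016-09-12",)),
    ("pinehurst", 0.10, ("2016-06-27",)),
    ("quarry", 0.18, ("2016-11-08",)),
    ("redfern", 0.13, ("2016-01-29",)),
)

_DECEDENT_NAMES = (
    "vonte", "tayshawn", "marcell", "deshawn", "keyon", "tremaine", "rashad",
    "dontae", "jamari", "quentin", "darnell", "teo", "malik", "savon",
    "cortez", "devante", "romell", "zaire", "amir",
)


def default_config(seed: int = 0) -> StreamConfig:
    """The default study conditions: the five-year window 2012-01-01..
    2016-12-31 (1,827 days), 18 territories with baselines averaging 0.35
    relevant tweets/day, and bursts of max(12.5, 20x baseline) expected
    tweets (12.5 being the typical observed spike size), so every injected
    burst is at least 20x its territory's baseline."""
    territories = []
    events = []
    name_iter = iter(_DECEDENT_NAMES)
    for name, rate, death_dates in _DEFAULT_TERRITORIES:
        abbrev = name[:3]
        territories.append(
            TerritoryConfig(
                territory_id=name,
                baseline_rate=rate,
                identifiers=(name, f"{name}block", f"{name}gang", abbrev),
            )
        )
        magnitude = max(12.5, 20.0 * rate)
        for dd in death_dates:
            person = next(name_iter)
            events.append(
                EventSeed(
                    person_id=person,
                    aliases=(person, f"lil {person}"),
                    death_date=date.fromisoformat(dd),
                    territory_id=name,
                    burst_magnitude=magnitude,
                    decay_halflife_days=1.0,
                    anniversary_magnitude=magnitude,
                )
            )
    return StreamConfig(
        start=date(2012, 1, 1),
        end=date(2016, 12, 31),
        territories=tuple(territories),
        events=tuple(events),
        noise=NoiseConfig(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_bundle(bundle: TruthBundle, outdir: str | Path) -> None:
    """tweets.jsonl + labels.csv + ledger.csv + lexicons.csv + config.yaml."""
    from .lexicon import write_lexicon_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tweets_jsonl(outdir / "tweets.jsonl", bundle.tweets)
    with open(outdir / "labels.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tweet_id", "label"])
        for tw in bundle.tweets:
            writer.writerow([tw.tweet_id, bundle.labels[tw.tweet_id]])
    write_ledger_csv(outdir / "ledger.csv", bundle.ledger)
    write_lexicon_csv(outdir / "lexicons.csv", bundle.grief, bundle.registry)
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(bundle.config), fh, sort_keys=True)


def config_to_dict(config: StreamConfig) -> dict:
    d = asdict(config)
    d["start"] = config.start.isoformat()
    d["end"] = config.end.isoformat()
    for ev in d["events"]:
        ev["death_date"] = ev["death_date"].isoformat()
        ev["birth_date"] = ev["birth_date"].isoformat() if ev["birth_date"] else None
        ev["aliases"] = list(ev["aliases"])
    for t in d["territories"]:
        t["identifiers"] = list(t["identifiers"])
    d["territories"] = list(d["territories"])
    d["events"] = list(d["events"])
    return d


def config_from_dict(d: Mapping) -> StreamConfig:
    return StreamConfig(
        start=date.fromisoformat(d["start"]),
        end=date.fromisoformat(d["end"]),
        territories=tuple(
            TerritoryConfig(
                territory_id=t["territory_id"],
                baseline_rate=float(t["baseline_rate"]),
                identifiers=tuple(t["identifiers"]),
                user_pool_size=int(t.get("user_pool_size", 60)),
            )
            for t in d["territories"]
        ),
        events=tuple(
            EventSeed(
                person_id=e["person_id"],
                aliases=tuple(e["aliases"]),
                death_date=date.fromisoformat(e["death_date"]),
                territory_id=e["territory_id"],
                birth_date=(
                    date.fromisoformat(e["birth_date"]) if e.get("birth_date") else None
                ),
                burst_magnitude=float(e.get("burst_magnitude", 12.5)),
                decay_halflife_days=float(e.get("decay_halflife_days", 1.0)),
                anniversary_magnitude=float(e.get("anniversary_magnitude", 12.5)),
            )
            for e in d["events"]
        ),
        noise=NoiseConfig(**d.get("noise", {})),
        seed=int(d.get("seed", 0)),
        injected_day_min_ratio=float(d.get("injected_day_min_ratio", 20.0)),
    )
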