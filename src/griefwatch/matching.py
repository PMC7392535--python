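"""Spike-to-event matching and territory-level reporting.

A detected spike is a *positive match* when a decedent in the loss-event
ledger is named (case-insensitively, punctuation-tolerantly) in at least one
of the spike's member tweets and belongs to the spike's territory. Matched
spikes are typed: *acute* when the spike falls within the first days after
the death, *anniversary* when it falls within a small tolerance of a yearly
death or birth anniversary, and *general* otherwise (name-matched memorials
with no date relation — e.g. tweets mourning several friends at once).

Reports mirror the per-territory summary layout: tweets, daily average,
spikes, matches, match rate, plus unweighted mean/median aggregates across
territories.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .lexicon import normalize_phrase, tokenize_matchable
from .spikes import DailySeries, Spike, daily_average

ACUTE = "acute"
ANNIVERSARY = "anniversary"
GENERAL = "general"
UNMATCHED = "unmatched"

#: Spike-type counts over the 91 positive matches of the original five-year
#: deployment the method was developed on (acute / anniversary / general).
REFERENCE_TYPE_COUNTS: dict[str, int] = {ACUTE: 30, ANNIVERSARY: 35, GENERAL: 26}


@dataclass(frozen=True)
class LossEvent:
    person_id: str
    aliases: frozenset[str]
    death_date: date
    territory_id: str
    birth_date: date | None = None

    def __post_init__(self) -> None:
        if not self.aliases:
            raise ValueError(f"event {self.person_id!r} has no aliases")


@dataclass(frozen=True)
class MatchWindows:
    """Date windows for typing matched spikes.

    ``acute_days`` is a half-open day-offset interval after death, starting
    at 0 (default [0, 7) — "hours and days immediately following");
    ``anniversary_tolerance`` is +/- days around yearly death/birth
    anniversaries (default 2).
    """

    acute_days: tuple[int, int] = (0, 7)
    anniversary_tolerance: int = 2

    def __post_init__(self) -> None:
        if self.acute_days[0] != 0 or self.acute_days[1] <= 0:
            raise ValueError("acute interval must start at 0 and be non-empty")
        if self.anniversary_tolerance < 0:
            raise ValueError("anniversary_tolerance must be >= 0")


@dataclass(frozen=True)
class MatchResult:
    spike: Spike
    matched_events: tuple[LossEvent, ...]
    type: str

    def __post_init__(self) -> None:
        if self.type not in (ACUTE, ANNIVERSARY, GENERAL, UNMATCHED):
            raise ValueError(f"bad match type {self.type!r}")
        if (self.type == UNMATCHED) != (not self.matched_events):
            raise ValueError("type is unmatched iff no events matched")


def _anniversary_date(base: date, year: int) -> date:
    """Yearly recurrence of ``base`` in ``year``; Feb-29 maps to Feb-28 in
    non-leap years."""
    try:
        return base.replace(year=year)
    except ValueError:
        return date(year, 2, 28)


def classify_spike_type(
    spike_date: date, event: LossEvent, windows: MatchWindows | None = None
) -> str:
    """Type one name-matched (spike, event) pair: acute, anniversary, general.

    Acute requires 0 <= spike - death < acute upper bound. Anniversary checks
    yearly recurrences (later year, same month/day, +/- tolerance) of the
    death date and, when known, the birth date. Anything else — including a
    pre-death name hit, since mourning can only follow death — is general.
    """
    windows = windows or MatchWindows()
    offset = (spike_date - event.death_date).days
    if windows.acute_days[0] <= offset < windows.acute_days[1]:
        return ACUTE
    bases = [event.death_date]
    if event.birth_date is not None:
        bases.append(event.birth_date)
    tol = windows.anniversary_tolerance
    for base in bases:
        for year in (spike_date.year - 1, spike_date.year, spike_date.year + 1):
            if year <= base.year:
                continue
            anniv = _anniversary_date(base, year)
            if abs((spike_date - anniv).days) <= tol:
                return ANNIVERSARY
    return GENERAL


def _alias_in_texts(alias: str, norm_texts: Sequence[str], token_sets: Sequence[set]) -> bool:
    norm = normalize_phrase(alias)
    if not norm:
        return False
    squashed = norm.replace(" ", "")
    needle = f" {norm} "
    for nt, toks in zip(norm_texts, token_sets):
        if needle in nt or squashed in toks:
            return True
    return False


def match_spike(
    spike: Spike,
    member_texts: Sequence[str],
    ledger: Sequence[LossEvent],
    windows: MatchWindows | None = None,
) -> MatchResult:
    """Match one spike against the ledger and type it.

    An event matches when any alias appears in any member tweet text
    (punctuation-tolerant, ``#LILJOSH`` hits alias "lil josh") and the event
    belongs to the spike's territory. Type precedence over matched events:
    acute > anniversary > general.
    """
    if not member_texts:
        raise ValueError("spike has no member tweets")
    windows = windows or MatchWindows()
    token_lists = [tokenize_matchable(t, drop_mentions=False) for t in member_texts]
    norm_texts = [f" {' '.join(toks)} " for toks in token_lists]
    token_sets = [set(toks) for toks in token_lists]
    matched = []
    for event in ledger:
        if event.territory_id != spike.territory_id:
            continue
        if any(
            _alias_in_texts(alias, norm_texts, token_sets) for alias in event.aliases
        ):
            matched.append(event)
    if not matched:
        return MatchResult(spike, (), UNMATCHED)
    types = {classify_spike_type(spike.date, ev, windows) for ev in matched}
    for t in (ACUTE, ANNIVERSARY, GENERAL):
        if t in types:
            return MatchResult(spike, tuple(matched), t)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TerritoryReport:
    territory_id: str
    n_tweets: int
    daily_average: float
    n_spikes: int
    n_matches: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_matches <= max(self.n_spikes, 0)):
            raise ValueError("need 0 <= n_matches <= n_spikes")

    @property
    def match_rate_pct(self) -> float | None:
        """100 * matches / spikes, one decimal; undefined for 0 spikes."""
        if self.n_spikes == 0:
            return None
        return round(100.0 * self.n_matches / self.n_spikes, 1)


def aggregate_reports(reports: Sequence[TerritoryReport]) -> dict[str, float]:
    """Aggregate statistics across territory reports.

    The mean/median of per-territory match rates are unweighted (a territory
    with 2 spikes counts as much as one with 14); the pooled rate
    ``overall_match_rate_pct`` = 100 * total matches / total spikes is a
    different quantity and reported under its own name. Territories with zero
    spikes are excluded from the rate mean/median. Percentages and means
    round to one decimal, daily averages to two.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    n = len(reports)
    rates = [r.match_rate_pct for r in reports if r.match_rate_pct is not None]
    total_spikes = sum(r.n_spikes for r in reports)
    total_matches = sum(r.n_matches for r in reports)
    out = {
        "n_territories": n,
        "total_tweets": int(sum(r.n_tweets for r in reports)),
        "total_spikes": int(total_spikes),
        "total_matches": int(total_matches),
        "mean_tweets_per_territory": round(sum(r.n_tweets for r in reports) / n, 1),
        "mean_daily_average": round(sum(r.daily_average for r in reports) / n, 2),
        "mean_spikes_per_territory": round(total_spikes / n, 1),
        "mean_matches_per_territory": round(total_matches / n, 1),
    }
    if rates:
        out["mean_match_rate_pct"] = round(float(np.mean(rates)), 1)
        out["median_match_rate_pct"] = round(float(np.median(rates)), 1)
    if total_spikes:
        out["overall_match_rate_pct"] = round(100.0 * total_matches / total_spikes, 1)
    return out


def type_breakdown(type_counts: Mapping[str, int]) -> dict[str, float]:
    """Percentage of matched spikes per type (one decimal)."""
    total = sum(type_counts.get(t, 0) for t in (ACUTE, ANNIVERSARY, GENERAL))
    if total == 0:
        return {t: 0.0 for t in (ACUTE, ANNIVERSARY, GENERAL)}
    return {
        t: round(100.0 * type_counts.get(t, 0) / total, 1)
        for t in (ACUTE, ANNIVERSARY, GENERAL)
    }


def summarize(
    matches_by_territory: Mapping[str, Sequence[MatchResult]],
    series_set: Sequence[DailySeries],
) -> tuple[list[TerritoryReport], dict[str, float]]:
    """Territory reports plus aggregates (including the type breakdown)."""
    series_by_id = {s.territory_id: s for s in series_set}
    reports = []
    type_counts = {ACUTE: 0, ANNIVERSARY: 0, GENERAL: 0}
    for tid in sorted(series_by_id):
        series = series_by_id[tid]
        results = matches_by_territory.get(tid, [])
        n_matches = sum(1 for r in results if r.type != UNMATCHED)
        for r in results:
            if r.type != UNMATCHED:
                type_counts[r.type] += 1
        reports.append(
            TerritoryReport(
                territory_id=tid,
                n_tweets=series.total,
                daily_average=round(daily_average(series), 2),
                n_spikes=len(results),
                n_matches=n_matches,
            )
        )
    aggregates = aggregate_reports(reports)
    for t, pct in type_breakdown(type_counts).items():
        aggregates[f"{t}_spike_pct"] = pct
    for t, c in type_counts.items():
        aggregates[f"{t}_spike_count"] = c
    return reports, aggregates


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_ledger_csv(path: str | Path) -> list[LossEvent]:
    """Ledger CSV: person_id, aliases (pipe-separated), death_date,
    birth_date (optional), territory_id; ISO dates."""
    events = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            birth = row.get("birth_date") or ""
            events.append(
                LossEvent(
                    person_id=row["person_id"],
                    aliases=frozenset(
                        a.strip().lower() for a in row["aliases"].split("|") if a.strip()
                    ),
                    death_date=date.fromisoformat(row["death_date"]),
                    birth_date=date.fromisoformat(birth) if birth else None,
                    territory_id=row["territory_id"],
                )
            )
    return events


def write_ledger_csv(path: str | Path, events: Iterable[LossEvent]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["person_id", "aliases", "death_date", "birth_date", "territory_id"]
        )
        for ev in events:
            writer.writerow(
                [
                    ev.person_id,
                    "|".join(sorted(ev.aliases)),
                    ev.death_date.isoformat(),
                    ev.birth_date.isoformat() if ev.birth_date else "",
                    ev.territory_id,
                ]
            )


def write_report_csv(
    path: str | Path,
    reports: Sequence[TerritoryReport],
    aggregates: Mapping[str, float],
) -> None:
    """Per-territory rows plus an aggregates footer."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["territory_id", "n_tweets", "daily_average", "n_spikes", "n_matches",
             "match_rate_pct"]
        )
        for r in reports:
            rate = "" if r.match_rate_pct is None else r.match_rate_pct
            writer.writerow(
                [r.territory_id, r.n_tweets, f"{r.daily_average:.2f}", r.n_spikes,
                 r.n_matches, rate]
            )
        writer.writerow([])
        for key in sorted(aggregates):
            writer.writerow([key, aggregates[key]])


def load_reference_reports() -> list[TerritoryReport]:
    """The bundled 18-territory reference summary (five-year deployment):
    per-territory tweets, daily average, spikes and matches, as published."""
    ref = resources.files("griefwatch.data").joinpath("territory_reference.csv")
    reports = []
    with ref.open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            reports.append(
                TerritoryReport(
                    territory_id=row["territory_id"],
                    n_tweets=int(row["n_tweets"]),
                    daily_average=float(row["daily_average"]),
                    n_spikes=int(row["n_spikes"]),
                    n_matches=int(row["n_matches"]),
                )
            )
    return reports
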