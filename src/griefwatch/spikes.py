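"""Per-territory daily series and single-day spike detection.

A territory's relevant tweets are binned by local calendar day over the study
window. Territories with fewer than ``stable_presence_min`` (default 100)
relevant tweets lack a stable online presence and are excluded. Within a
retained territory, *candidate days* are days whose count reaches
``min_count`` (a collective spike needs at least two tweets); the top
``top_fraction`` (default 1%) of candidate days by count are called spikes,
each scored relative to the territory's own baseline so spikes are comparable
across territories of very different activity levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np

from .preprocessing import NormalizedTweet


@dataclass(frozen=True)
class DailySeries:
    """Non-negative counts for every calendar day of the window (inclusive)."""

    territory_id: str
    window: tuple[date, date]
    counts: tuple[int, ...]
    members: tuple[tuple[str, ...], ...] = ()  # tweet ids per day, optional

    def __post_init__(self) -> None:
        start, end = self.window
        n_days = (end - start).days + 1
        if n_days < 1:
            raise ValueError(f"empty window {start}..{end}")
        if len(self.counts) != n_days:
            raise ValueError(
                f"counts length {len(self.counts)} != window length {n_days}"
            )
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.members and len(self.members) != n_days:
            raise ValueError("members length must equal window length")

    @property
    def n_days(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def day(self, i: int) -> date:
        return self.window[0] + timedelta(days=i)


@dataclass(frozen=True)
class SpikeConfig:
    top_fraction: float = 0.01
    min_count: int = 2
    stable_presence_min: int = 100
    baseline_stat: str = "mean_all_days"  # or "mean_nonzero_days"
    score: str = "zscore"  # or "fold"

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.min_count < 1 or self.stable_presence_min < 1:
            raise ValueError("min_count and stable_presence_min must be >= 1")
        if self.baseline_stat not in ("mean_all_days", "mean_nonzero_days"):
            raise ValueError(f"unknown baseline_stat {self.baseline_stat!r}")
        if self.score not in ("zscore", "fold"):
            raise ValueError(f"unknown score {self.score!r}")


@dataclass(frozen=True)
class Spike:
    """One territory-day flagged as elevated collective grief."""

    territory_id: str
    date: date
    count: int
    baseline: float
    score: float
    tweet_ids: tuple[str, ...] = ()


def build_daily_series(
    relevant: Iterable[NormalizedTweet],
    territory_id: str,
    window: tuple[date, date],
) -> DailySeries:
    """Bin relevant tweets for one territory into explicit daily counts.

    Days without tweets are explicit zeros; a tweet outside the window is an
    error (extraction should have filtered it).
    """
    start, end = window
    n_days = (end - start).days + 1
    counts = [0] * n_days
    members: list[list[str]] = [[] for _ in range(n_days)]
    for tw in relevant:
        if tw.territory_id != territory_id:
            continue
        offset = (tw.date - start).days
        if not (0 <= offset < n_days):
            raise ValueError(
                f"tweet {tw.tweet_id} dated {tw.date} outside window {start}..{end}"
            )
        counts[offset] += 1
        members[offset].append(tw.tweet_id)
    return DailySeries(
        territory_id=territory_id,
        window=window,
        counts=tuple(counts),
        members=tuple(tuple(m) for m in members),
    )


def daily_average(series: DailySeries) -> float:
    """Mean relevant tweets per day over the window (reports round to 2 dp)."""
    return series.total / series.n_days


def stable_presence_filter(
    series_set: Sequence[DailySeries], config: SpikeConfig | None = None
) -> list[DailySeries]:
    """Retain exactly the series with total count >= stable_presence_min."""
    config = config or SpikeConfig()
    return [s for s in series_set if s.total >= config.stable_presence_min]


def _baseline(series: DailySeries, config: SpikeConfig) -> float:
    arr = np.asarray(series.counts, dtype=float)
    if config.baseline_stat == "mean_all_days":
        return float(arr.mean())
    nz = arr[arr > 0]
    return float(nz.mean()) if nz.size else 0.0


def _score_day(count: int, baseline: float, sd: float, config: SpikeConfig) -> float:
    if config.score == "zscore":
        return (count - baseline) / sd if sd > 0 else 0.0
    return count / baseline if baseline > 0 else math.inf if count else 0.0


def detect_spikes(series: DailySeries, config: SpikeConfig | None = None) -> list[Spike]:
    """Call the top-``top_fraction`` single-day spikes of one territory.

    Candidate days have count >= min_count; k = ceil(top_fraction * number of
    candidate days); the k candidates with the largest counts are returned
    (ties broken by larger score, then earlier date), each carrying a
    baseline-relative score. No candidate days -> empty list.
    """
    config = config or SpikeConfig()
    arr = np.asarray(series.counts, dtype=float)
    baseline = _baseline(series, config)
    sd = float(arr.std(ddof=0))
    candidates = [
        i for i, c in enumerate(series.counts) if c >= config.min_count
    ]
    if not candidates:
        return []
    k = math.ceil(config.top_fraction * len(candidates))
    scored = [
        (
            series.counts[i],
            _score_day(series.counts[i], baseline, sd, config),
            series.day(i),
            i,
        )
        for i in candidates
    ]
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    spikes = []
    for count, score, day, i in scored[:k]:
        ids = series.members[i] if series.members else ()
        spikes.append(
            Spike(
                territory_id=series.territory_id,
                date=day,
                count=int(count),
                baseline=baseline,
                score=score,
                tweet_ids=tuple(ids),
            )
        )
    return spikes
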