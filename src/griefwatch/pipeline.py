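"""End-to-end orchestration: stream -> spikes -> matches -> report.

Chains the co-occurrence query, the preprocessing filters, a relevance step
(annotation rule or trained classifier), per-territory daily series with the
stable-presence filter, top-fraction spike detection, and ledger matching.
Also provides the ground-truth evaluation used on synthetic streams: what
fraction of engineered spike days the pipeline recovers, and whether the
recovered ones match the right event with the right type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classifier import (
    RELEVANT,
    RelevanceLabel,
    predict_relevance,
    rule_label,
    train_classifier,
)
from .extraction import assign_territories, query_stream
from .matching import (
    UNMATCHED,
    MatchResult,
    MatchWindows,
    TerritoryReport,
    match_spike,
    summarize,
)
from .preprocessing import NormalizedTweet, filter_stream, normalize_stream
from .spikes import DailySeries, Spike, SpikeConfig, build_daily_series, detect_spikes, stable_presence_filter
from .synthetic import TruthBundle


@dataclass
class PipelineResult:
    relevant: list[NormalizedTweet]
    series: list[DailySeries]
    retained_series: list[DailySeries]
    spikes_by_territory: dict[str, list[Spike]]
    matches_by_territory: dict[str, list[MatchResult]]
    reports: list[TerritoryReport]
    aggregates: dict[str, float]
    drop_counts: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    bundle: TruthBundle,
    spike_config: SpikeConfig | None = None,
    windows: MatchWindows | None = None,
    relevance: str = "rule",
    train_sample_size: int = 2219,
    train_seed: int = 7,
) -> PipelineResult:
    """Run the full analysis over a truth bundle.

    ``relevance`` selects the relevance step: ``"rule"`` applies the
    annotation rule (context flags come from the bundle), ``"model"`` trains
    the classifier on a random labeled sample of ``train_sample_size`` tweets
    (the hand-coding budget of the reference deployment) and predicts the
    rest.
    """
    spike_config = spike_config or SpikeConfig()
    windows = windows or MatchWindows()
    cfg = bundle.config
    window = (cfg.start, cfg.end)

    candidates = query_stream(bundle.tweets, bundle.grief, bundle.registry, window)
    hits = {
        c.tweet.tweet_id: (c.grief_hits, c.territory_ids) for c in candidates
    }
    pairs = [pair for c in candidates for pair in assign_territories(c)]
    drop_counts: dict[str, int] = {}
    filtered = filter_stream(pairs, bundle.grief, counts=drop_counts)

    needs_tokens = relevance == "model"
    if needs_tokens:
        normalized = normalize_stream(filtered, bundle.registry)
    else:
        normalized = [
            NormalizedTweet(
                tweet_id=tw.tweet_id,
                territory_id=tid,
                date=tw.local_date(),
                masked_text="",
                tokens=(),
                raw_text=tw.text,
            )
            for tid, tw in filtered
        ]

    if relevance == "rule":
        labels: dict[str, RelevanceLabel] = {}
        for nt in normalized:
            grief_hits, terr_hits = hits[nt.tweet_id]
            labels[nt.tweet_id] = rule_label(
                nt.tweet_id, grief_hits, terr_hits, bundle.flags[nt.tweet_id]
            )
    elif relevance == "model":
        import numpy as np

        rng = np.random.default_rng(train_seed)
        all_ids = [tw.tweet_id for tw in bundle.tweets]
        sample_ids = set(
            rng.choice(
                all_ids, size=min(train_sample_size, len(all_ids)), replace=False
            )
        )
        by_id = {tw.tweet_id: tw for tw in bundle.tweets}
        train_norm = normalize_stream(
            [("_train_", by_id[i]) for i in sorted(sample_ids)], bundle.registry
        )
        labeled = [
            (nt, RelevanceLabel(nt.tweet_id, bundle.labels[nt.tweet_id], "human"))
            for nt in train_norm
        ]
        model = train_classifier(labeled, seed=train_seed)
        preds = predict_relevance(model, normalized)
        labels = {p.tweet_id: p for p in preds}
    else:
        raise ValueError(f"unknown relevance mode {relevance!r}")

    relevant = [nt for nt in normalized if labels[nt.tweet_id].label == RELEVANT]

    territory_ids = [t.territory_id for t in cfg.territories]
    series = [
        build_daily_series(relevant, tid, window) for tid in sorted(territory_ids)
    ]
    retained = stable_presence_filter(series, spike_config)

    text_by_id = {nt.tweet_id: nt.raw_text for nt in normalized}
    spikes_by_territory: dict[str, list[Spike]] = {}
    matches_by_territory: dict[str, list[MatchResult]] = {}
    for s in retained:
        spikes = detect_spikes(s, spike_config)
        spikes_by_territory[s.territory_id] = spikes
        matches_by_territory[s.territory_id] = [
            match_spike(
                sp, [text_by_id[i] for i in sp.tweet_ids], bundle.ledger, windows
            )
            for sp in spikes
        ]

    reports, aggregates = summarize(matches_by_territory, retained)
    return PipelineResult(
        relevant=relevant,
        series=series,
        retained_series=retained,
        spikes_by_territory=spikes_by_territory,
        matches_by_territory=matches_by_territory,
        reports=reports,
        aggregates=aggregates,
        drop_counts=drop_counts,
    )


def evaluate_recovery(bundle: TruthBundle, result: PipelineResult) -> dict[str, float]:
    """Ground-truth scoring of a pipeline run on a synthetic stream.

    ``recovery`` — fraction of engineered (injected) spike days that appear
    among the detected spikes; ``correct_match_rate`` — among detected
    engineered days, the fraction positively matched to a ledger event with
    the engineered type (acute vs anniversary).
    """
    n_injected = 0
    n_detected = 0
    n_correct = 0
    for tid, days in bundle.injected_spike_days.items():
        detected_days = {sp.date for sp in result.spikes_by_territory.get(tid, [])}
        match_by_day = {
            m.spike.date: m for m in result.matches_by_territory.get(tid, [])
        }
        for day in days:
            n_injected += 1
            if day not in detected_days:
                continue
            n_detected += 1
            m = match_by_day.get(day)
            if (
                m is not None
                and m.type != UNMATCHED
                and m.type == bundle.injected_day_types[(tid, day)]
            ):
                n_correct += 1
    return {
        "n_injected_days": n_injected,
        "n_detected": n_detected,
        "n_correct_type_matches": n_correct,
        "recovery": n_detected / n_injected if n_injected else float("nan"),
        "correct_match_rate": n_correct / n_detected if n_detected else float("nan"),
    }
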