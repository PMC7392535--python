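from datetime import date

import pytest

from griefwatch.matching import (
    ACUTE,
    ANNIVERSARY,
    GENERAL,
    UNMATCHED,
    LossEvent,
    TerritoryReport,
    aggregate_reports,
    classify_spike_type,
    load_reference_reports,
    match_spike,
    read_ledger_csv,
    summarize,
    type_breakdown,
    write_ledger_csv,
    write_report_csv,
)
from griefwatch.spikes import DailySeries, Spike


def _event(person="josh", aliases=("lil josh",), death=date(2012, 3, 8),
           tid="g6", birth=None):
    return LossEvent(person, frozenset(aliases), death, tid, birth)


def _spike(tid="g6", day=date(2012, 3, 9), ids=("a", "b")):
    return Spike(tid, day, len(ids), 0.1, 5.0, tuple(ids))


class TestClassifySpikeType:
    def test_zero_offset_is_acute(self):
        assert classify_spike_type(date(2012, 3, 8), _event()) == ACUTE

    def test_day_after_death_is_acute(self):
        assert classify_spike_type(date(2012, 3, 9), _event()) == ACUTE
        assert (
            classify_spike_type(
                date(2014, 7, 26), _event(death=date(2014, 7, 25))
            )
            == ACUTE
        )

    def test_acute_window_upper_bound_exclusive(self):
        assert classify_spike_type(date(2012, 3, 14), _event()) == ACUTE
        assert classify_spike_type(date(2012, 3, 15), _event()) == GENERAL

    def test_yearly_anniversary_within_tolerance(self):
        ev = _event(death=date(2011, 7, 8))
        assert classify_spike_type(date(2013, 7, 7), ev) == ANNIVERSARY
        assert classify_spike_type(date(2013, 7, 10), ev) == ANNIVERSARY
        assert classify_spike_type(date(2013, 7, 11), ev) == GENERAL

    def test_365_days_later_non_leap(self):
        ev = _event(death=date(2013, 3, 1))
        assert (
            classify_spike_type(date(2013, 3, 1) + (date(2014, 3, 1) - date(2013, 3, 1)), ev)
            == ANNIVERSARY
        )

    def test_feb29_maps_to_feb28_in_non_leap_years(self):
        ev = _event(death=date(2012, 2, 29))
        assert classify_spike_type(date(2013, 2, 28), ev) == ANNIVERSARY

    def test_birthday_anniversary(self):
        ev = _event(death=date(2012, 3, 8), birth=date(1995, 9, 14))
        assert classify_spike_type(date(2013, 9, 14), ev) == ANNIVERSARY

    def test_pre_death_name_hit_falls_through_to_general(self):
        assert classify_spike_type(date(2012, 1, 1), _event()) == GENERAL


class TestMatchSpike:
    def test_name_and_territory_match_acute(self):
        texts = ["REST UP gang6 LIL JOSH", "rip lil josh gone"]
        result = match_spike(_spike(), texts, [_event()])
        assert result.type == ACUTE
        assert result.matched_events == (_event(),)

    def test_hashtag_alias_matches(self):
        result = match_spike(_spike(), ["YOU WILL ALWAYS BE LOVED #LILJOSH"], [_event()])
        assert result.type == ACUTE

    def test_wrong_territory_unmatched(self):
        result = match_spike(_spike(tid="g5"), ["rip lil josh"],
                             [_event(tid="g6")])
        assert result.type == UNMATCHED
        assert result.matched_events == ()

    def test_nobody_in_ledger_unmatched(self):
        result = match_spike(_spike(), ["rip somebody else"], [_event()])
        assert result.type == UNMATCHED

    def test_several_decedents_outside_date_windows_is_general(self):
        events = [
            _event("a", ("tutu",), date(2010, 1, 15)),
            _event("b", ("crack",), date(2010, 6, 20)),
        ]
        result = match_spike(
            _spike(day=date(2012, 11, 3)), ["rip tutu crack and all dem"], events
        )
        assert result.type == GENERAL
        assert len(result.matched_events) == 2

    def test_acute_takes_precedence_over_anniversary(self):
        events = [
            _event("new", ("marco",), date(2013, 5, 2)),
            _event("old", ("dre",), date(2012, 5, 2)),
        ]
        result = match_spike(
            _spike(day=date(2013, 5, 2)), ["rip marco rip dre"], events
        )
        assert result.type == ACUTE

    def test_empty_member_set_raises(self):
        with pytest.raises(ValueError, match="member"):
            match_spike(_spike(), [], [_event()])


class TestReports:
    def test_single_territory_two_spikes_one_match(self):
        report = TerritoryReport("t", 100, 0.5, 2, 1)
        assert report.match_rate_pct == 50.0

    def test_zero_spike_territory_excluded_from_rate_stats(self):
        reports = [
            TerritoryReport("a", 100, 0.1, 2, 2),
            TerritoryReport("b", 100, 0.1, 0, 0),
        ]
        agg = aggregate_reports(reports)
        assert agg["mean_match_rate_pct"] == 100.0
        assert reports[1].match_rate_pct is None

    def test_match_counts_cannot_exceed_spikes(self):
        with pytest.raises(ValueError):
            TerritoryReport("a", 10, 0.1, 1, 2)

    def test_type_breakdown_reference_counts(self):
        assert type_breakdown({ACUTE: 30, ANNIVERSARY: 35, GENERAL: 26}) == {
            ACUTE: 33.0,
            ANNIVERSARY: 38.5,
            GENERAL: 28.6,
        }

    def test_summarize_partitions_matched_types(self):
        window = (date(2012, 1, 1), date(2012, 1, 10))
        series = [DailySeries("t1", window, tuple([3] * 10))]
        ev = _event("m", ("marco",), date(2012, 1, 2), "t1")
        results = [
            match_spike(_spike("t1", date(2012, 1, 2)), ["rip marco"], [ev]),
            match_spike(_spike("t1", date(2012, 1, 8)), ["rip nobody"], [ev]),
        ]
        reports, agg = summarize({"t1": results}, series)
        assert reports[0].n_spikes == 2 and reports[0].n_matches == 1
        type_total = (
            agg["acute_spike_count"]
            + agg["anniversary_spike_count"]
            + agg["general_spike_count"]
        )
        assert type_total == agg["total_matches"] == 1


def test_reference_reports_match_rates_recompute_to_printed_values():
    rates = {r.territory_id: r.match_rate_pct for r in load_reference_reports()}
    assert rates["7"] == 91.7
    assert rates["24"] == 90.9
    assert rates["54"] == 25.0


def test_ledger_csv_roundtrip(tmp_path):
    events = [
        _event("josh", ("lil josh", "josh"), date(2012, 3, 8), "g6",
               birth=date(1995, 9, 14)),
        _event("tay", ("tay",), date(2011, 7, 8), "g43"),
    ]
    path = tmp_path / "ledger.csv"
    write_ledger_csv(path, events)
    assert read_ledger_csv(path) == events


def test_report_csv_includes_rows_and_footer(tmp_path):
    reports = [TerritoryReport("a", 100, 0.35, 2, 1)]
    path = tmp_path / "report.csv"
    write_report_csv(path, reports, aggregate_reports(reports))
    text = path.read_text()
    assert "a,100,0.35,2,1,50.0" in text
    assert "total_matches,1" in text
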