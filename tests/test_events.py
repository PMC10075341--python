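"""Event model: I/O round trips, independence filtering, and tabulations."""

from datetime import timedelta

import pytest
from hypothesis import given, strategies as st

from ursamark.errors import EmptyDataError, RowParseError, SchemaError
from ursamark.ethogram import default_ethogram
from ursamark.events import (
    apply_merge,
    filter_independent_events,
    parse_event_log,
    summarize_durations,
    tabulate_behavior_frequencies,
    tabulate_class_behavior,
    tabulate_mark_heights,
    write_event_log,
)
from ursamark.fixtures import make_fixture_results_1

from conftest import detection, ts, visit


# ---------------------------------------------------------------------------
# parsing and round trip


def test_native_roundtrip(tmp_path, synthetic_dataset):
    """Writing and re-parsing the native CSV preserves every field."""
    path = tmp_path / "events.csv"
    originals = synthetic_dataset.detections
    write_event_log(originals, path)
    parsed = parse_event_log(path)
    assert len(parsed) == len(originals)
    for a, b in zip(originals, parsed):
        assert (a.site_id, a.timestamp, a.bear_class, a.source, a.mark_height) == (
            b.site_id,
            b.timestamp,
            b.bear_class,
            b.source,
            b.mark_height,
        )
        assert a.bouts == b.bouts


def test_parse_single_detection(tmp_path):
    path = tmp_path / "e.csv"
    write_event_log([detection(codes=["dorsal"])], path)
    dets = parse_event_log(path)
    assert len(dets) == 1 and len(dets[0].bouts) == 1
    assert dets[0].bouts[0].behavior == "dorsal"


def test_parse_empty_file(tmp_path):
    path = tmp_path / "e.csv"
    path.write_text(
        "site_id,timestamp_iso8601_utc,class,behavior,start_offset_s,duration_s,source,mark_height\n"
    )
    assert parse_event_log(path) == []


def test_parse_rejects_unknown_behavior(tmp_path):
    path = tmp_path / "e.csv"
    path.write_text(
        "site_id,timestamp_iso8601_utc,class,behavior,start_offset_s,duration_s,source,mark_height\n"
        "S01,2021-06-01T12:00:00+00:00,adult_male,jumping,0,5,systematic,\n"
    )
    with pytest.raises(RowParseError, match="dorsal"):  # error lists allowed codes
        parse_event_log(path)


def test_parse_missing_column_names_it(tmp_path):
    path = tmp_path / "e.csv"
    path.write_text("site_id,timestamp_iso8601_utc,class\nS01,2021-06-01T12:00:00,x\n")
    with pytest.raises(SchemaError, match="behavior"):
        parse_event_log(path)


def test_parse_bad_timestamp_reports_line(tmp_path):
    path = tmp_path / "e.csv"
    path.write_text(
        "site_id,timestamp_iso8601_utc,class,behavior,start_offset_s,duration_s,source,mark_height\n"
        "S01,not-a-time,adult_male,dorsal,0,5,systematic,\n"
    )
    with pytest.raises(RowParseError, match="line 2"):
        parse_event_log(path)


def test_parse_boris_dialect(tmp_path):
    events = tmp_path / "boris.csv"
    events.write_text(
        "Observation id,Subject,Behavior,Start (s),Stop (s)\n"
        "obs1,bear,dorsal,0,12.5\n"
        "obs1,bear,investigation,13,20\n"
    )
    sidecar = tmp_path / "side.csv"
    sidecar.write_text(
        "observation_id,site_id,timestamp_iso8601_utc,class\n"
        "obs1,S01,2021-06-01T12:00:00+00:00,adult_male\n"
    )
    dets = parse_event_log(events, dialect="boris_aggregated", sidecar=sidecar)
    assert len(dets) == 1
    assert [b.behavior for b in dets[0].bouts] == ["dorsal", "investigation"]
    assert dets[0].bouts[0].duration_s == 12.5


# ---------------------------------------------------------------------------
# independence filtering


@pytest.mark.parametrize(
    "gaps_min, sites, window, expected",
    [
        ([0, 10], ["S01", "S01"], 30, 1),  # within window -> merged
        ([0, 40], ["S01", "S01"], 30, 2),  # beyond window -> separate
        ([0, 5], ["S01", "S02"], 30, 2),  # independence is per-site
        ([0, 25, 50], ["S01"] * 3, 30, 1),  # gap rule chains
    ],
)
def test_filter_window_rules(gaps_min, sites, window, expected):
    dets = [
        detection(site=s, when=ts(10, 0) + timedelta(minutes=g), codes=["dorsal"])
        for g, s in zip(gaps_min, sites)
    ]
    assert len(filter_independent_events(dets, window)) == expected


def test_filter_concatenates_bouts_in_time_order():
    d1 = detection(when=ts(10, 0), codes=["dorsal"])
    d2 = detection(when=ts(10, 10), codes=["facial"])
    (event,) = filter_independent_events([d1, d2], 30)
    assert [b.behavior for b in event.bouts] == ["dorsal", "facial"]
    # second detection's bout offset is shifted by the 10-min gap
    assert event.bouts[1].start_offset_s == 600.0
    assert event.behavior_flags == {"dorsal": True, "facial": True}


def test_filter_rejects_bad_window():
    with pytest.raises(ValueError):
        filter_independent_events([], 0)


@given(
    st.lists(
        st.tuples(st.sampled_from(["S01", "S02"]), st.integers(0, 5000)),
        min_size=1,
        max_size=30,
    )
)
def test_filter_idempotent(spec):
    """Filtering an already-filtered event set changes nothing."""
    dets = [
        detection(site=s, when=ts(0, 0) + timedelta(minutes=m), codes=["dorsal"])
        for s, m in spec
    ]
    events = filter_independent_events(dets, 30)
    again = filter_independent_events(events, 30)
    assert [(e.site_id, e.start) for e in again] == [
        (e.site_id, e.start) for e in events
    ]


# ---------------------------------------------------------------------------
# merge views


def test_apply_merge_chemical():
    ev = visit(codes=["dorsal", "facial"])
    (merged,) = apply_merge([ev], default_ethogram(), "chemical_view")
    assert [b.behavior for b in merged.bouts] == ["rubbing", "rubbing"]


def test_apply_merge_visual():
    ev = visit(codes=["clawing", "biting"])
    (merged,) = apply_merge([ev], default_ethogram(), "visual_view")
    assert [b.behavior for b in merged.bouts] == ["debarking", "debarking"]


def test_apply_merge_empty_and_unknown_view():
    ev = visit(codes=[])
    (merged,) = apply_merge([ev], default_ethogram(), "chemical_view")
    assert merged.bouts == ()
    with pytest.raises(KeyError, match="chemical_view"):  # lists available views
        apply_merge([ev], default_ethogram(), "nope")


# ---------------------------------------------------------------------------
# tabulations


def test_behavior_frequencies_fixture_percentages():
    """The reconstructed 285-event set reproduces all five published percents."""
    events = apply_merge(make_fixture_results_1(), default_ethogram(), "visual_view")
    freq = tabulate_behavior_frequencies(events)
    assert freq.loc["dorsal", "percent"] == 77.9
    assert freq.loc["investigation", "percent"] == 71.6
    assert freq.loc["pedal", "percent"] == 23.5
    assert freq.loc["facial", "percent"] == 21.8
    assert freq.loc["debarking", "percent"] == 8.8
    assert dict(freq.n_events) == {
        "dorsal": 222,
        "investigation": 204,
        "pedal": 67,
        "facial": 62,
        "debarking": 25,
    }


def test_behavior_frequencies_simple_cases():
    all_codes = ["dorsal", "facial", "pedal", "investigation"]
    one = [visit(codes=all_codes)]
    freq = tabulate_behavior_frequencies(one)
    assert (freq.percent == 100.0).all()

    four = [visit(f"E{i}", codes=["pedal"] if i == 0 else ["dorsal"]) for i in range(4)]
    assert tabulate_behavior_frequencies(four).loc["pedal", "percent"] == 25.0

    with pytest.raises(EmptyDataError):
        tabulate_behavior_frequencies([])


def test_class_behavior_columns():
    # only adult males debark -> visual column 100 / 0
    events = [
        visit("E1", codes=["dorsal", "clawing"], cls="adult_male"),
        visit("E2", codes=["dorsal"], cls="adult_female"),
        visit("E3", codes=["investigation"], cls="subadult_male"),
    ]
    tab = tabulate_class_behavior(events)
    assert tab.loc["adult_male", "visual_marking"] == 100.0
    assert tab.loc["adult_female", "visual_marking"] == 0.0

    single = [visit(codes=["investigation"], cls="adult_female")]
    assert tabulate_class_behavior(single).loc["adult_female", "investigation"] == 100.0

    uniform = [
        visit(f"E{i}", codes=["investigation"], cls=c)
        for i, c in enumerate(["adult_male", "adult_female", "subadult_male", "cub"])
    ]
    col = tabulate_class_behavior(uniform)["investigation"]
    assert col[["adult_male", "adult_female", "subadult", "cub"]].tolist() == [25.0] * 4


def test_class_behavior_columns_sum_to_100(synthetic_dataset):
    events = filter_independent_events(synthetic_dataset.detections, 30)
    tab = tabulate_class_behavior(events)
    # each rounded cell can deviate by at most 0.05, so a 5-row column sums
    # to 100 within 0.25
    for cat in tab.columns:
        if tab[cat].sum() > 0:
            assert tab[cat].sum() == pytest.approx(100.0, abs=0.05 * len(tab))


def test_durations_zero_fill():
    one = [visit(codes=["dorsal"])]  # builder gives the bout 5.0 s
    d = summarize_durations(one, behaviors=["dorsal"])
    assert d.loc["dorsal"].tolist() == [5.0, 0.0, 5.0, 5.0, 1]

    two = [visit("E1", codes=["dorsal"]), visit("E2", codes=["facial"])]
    d = summarize_durations(two, behaviors=["dorsal", "pedal"])
    assert d.loc["dorsal", "mean_s"] == 2.5  # 5 s + zero-filled absence
    assert d.loc["dorsal", "min_s"] == 0.0
    assert (d.loc["pedal"][["mean_s", "sd_s", "min_s", "max_s"]] == 0).all()

    with pytest.raises(EmptyDataError):
        summarize_durations([])


@pytest.mark.parametrize(
    "above, below, pct_above",
    [(15, 9, 62.5), (1, 0, 100.0), (2, 2, 50.0)],
)
def test_mark_heights(above, below, pct_above):
    events = [
        visit(f"A{i}", codes=["clawing"], mark_height="above_shoulder")
        for i in range(above)
    ] + [
        visit(f"B{i}", codes=["biting"], mark_height="below_shoulder")
        for i in range(below)
    ]
    res = tabulate_mark_heights(events)
    assert res["n_marks"] == above + below
    assert res["percent_above"] == pct_above
    assert res["percent_above"] + res["percent_below"] == 100.0


def test_mark_heights_requires_annotations():
    with pytest.raises(EmptyDataError):
        tabulate_mark_heights([visit(codes=["dorsal"])])
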