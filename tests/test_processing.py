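"""Export parsing, ROI assignment, dwell aggregation, non-analyzability."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from gazesharp.events import (
    ROI,
    FixationEvent,
    FixationParseError,
    FixationStream,
    ROILayout,
    read_fixation_export,
    write_fixation_export,
)
from gazesharp.processing import assign_fixations, summarize_durations


def ev(t, x, y, d):
    return FixationEvent(t_start=t, x=x, y=y, duration_ms=d)


@pytest.fixture
def layout():
    # three well-separated ROIs
    return ROILayout(
        rois=[ROI("a", 100, 100, 20), ROI("b", 300, 100, 20), ROI("c", 500, 100, 20)]
    )


@pytest.fixture
def overlapping_layout():
    # centres 30 px apart, radius 20: midpoint (115, 100) is inside both
    return ROILayout(rois=[ROI("a", 100, 100, 20), ROI("b", 130, 100, 20)])


class TestExportIO:
    def test_header_only_file_is_empty_stream(self, tmp_path):
        p = tmp_path / "f.tsv"
        write_fixation_export(FixationStream(), p)
        assert p.read_text() == "t_start_ms\tx\ty\tduration_ms\n"
        assert len(read_fixation_export(p)) == 0

    def test_single_event_round_trip(self, tmp_path):
        p = tmp_path / "f.tsv"
        s = FixationStream([ev(0, 10.5, 20, 800)])
        write_fixation_export(s, p)
        assert read_fixation_export(p) == s

    def test_negative_duration_names_row(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("t_start_ms\tx\ty\tduration_ms\n0\t1\t1\t500\n600\t2\t2\t-5\n")
        with pytest.raises(FixationParseError, match="row 3"):
            read_fixation_export(p)

    def test_non_numeric_field_names_row(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("t_start_ms\tx\ty\tduration_ms\n0\tlots\t1\t500\n")
        with pytest.raises(FixationParseError, match="row 2"):
            read_fixation_export(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("t_start_ms\tx\ty\tduration_ms\n0\t1\t500\n")
        with pytest.raises(FixationParseError, match="row 2"):
            read_fixation_export(p)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 10**7),
                st.floats(0, 2000, allow_nan=False),
                st.floats(0, 2000, allow_nan=False),
                st.integers(1, 10**6),
            ),
            max_size=60,
            unique_by=lambda t: t[0],
        )
    )
    def test_round_trip_property(self, tmp_path_factory, rows):
        p = tmp_path_factory.mktemp("rt") / "f.tsv"
        stream = FixationStream([ev(*r) for r in sorted(rows)])
        write_fixation_export(stream, p)
        assert read_fixation_export(p) == stream


class TestAssignment:
    def test_fixation_at_centre_counts(self, layout):
        out = assign_fixations(FixationStream([ev(0, 100, 100, 700)]), layout)
        by = {s.site_id: s for s in out}
        assert by["a"].total_fixation_ms == 700 and by["a"].n_fixations == 1
        assert by["a"].analyzable
        assert by["b"].total_fixation_ms == 0 and by["c"].total_fixation_ms == 0

    def test_boundary_point_is_inside(self, layout):
        out = assign_fixations(FixationStream([ev(0, 120, 100, 500)]), layout)
        assert {s.site_id: s.total_fixation_ms for s in out}["a"] == 500

    def test_background_fixation_discarded(self, layout):
        out = assign_fixations(FixationStream([ev(0, 200, 400, 900)]), layout)
        assert all(s.total_fixation_ms == 0 for s in out)

    def test_overlap_flags_both_sites(self, overlapping_layout):
        out = assign_fixations(FixationStream([ev(0, 115, 100, 600)]), overlapping_layout)
        assert all(not s.analyzable for s in out)

    def test_flag_is_sticky_for_the_reading(self, overlapping_layout):
        stream = FixationStream([ev(0, 115, 100, 600), ev(700, 100, 100, 400)])
        out = assign_fixations(stream, overlapping_layout)
        by = {s.site_id: s for s in out}
        assert not by["a"].analyzable  # later clean fixation does not unflag

    def test_every_layout_site_reported_once(self, layout):
        out = assign_fixations(FixationStream(), layout)
        assert [s.site_id for s in out] == ["a", "b", "c"]

    def test_empty_layout_rejected(self):
        with pytest.raises(ValueError):
            assign_fixations(FixationStream(), ROILayout())


class TestAggregation:
    def test_durations_add(self, layout):
        stream = FixationStream([ev(0, 100, 100, 800), ev(900, 101, 99, 1200)])
        df = summarize_durations(assign_fixations(stream, layout))
        assert df.set_index("site_id").loc["a", "total_fixation_ms"] == 2000

    def test_non_analyzable_row_retained(self, overlapping_layout):
        df = summarize_durations(
            assign_fixations(FixationStream([ev(0, 115, 100, 600)]), overlapping_layout)
        )
        assert set(df["site_id"]) == {"a", "b"}
        assert not df["analyzable"].any()

    def test_conservation_for_disjoint_layout(self, layout):
        stream = FixationStream(
            [ev(i * 1000, x, y, 250) for i, (x, y) in enumerate(
                [(100, 100), (300, 100), (500, 100), (10, 10), (290, 110), (700, 700)]
            )]
        )
        df = summarize_durations(assign_fixations(stream, layout))
        assigned = df["total_fixation_ms"].sum()
        background = 2 * 250  # (10,10) and (700,700)
        assert assigned + background == stream.total_duration_ms()

    def test_order_independence(self, layout):
        events = [ev(i * 100, 100 + (i % 3) * 200, 100, 50 + i) for i in range(30)]
        base = summarize_durations(assign_fixations(FixationStream(events), layout))
        shuffled = events[:]
        random.Random(0).shuffle(shuffled)
        other = summarize_durations(assign_fixations(FixationStream(shuffled), layout))
        assert base.equals(other)

    def test_monotonicity(self, layout):
        events = [ev(0, 100, 100, 500)]
        before = {s.site_id: s.total_fixation_ms for s in
                  assign_fixations(FixationStream(events), layout)}
        events.append(ev(600, 300, 100, 900))
        after = {s.site_id: s.total_fixation_ms for s in
                 assign_fixations(FixationStream(events), layout)}
        assert after["b"] == before["b"] + 900
        assert after["a"] == before["a"] and after["c"] == before["c"]
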