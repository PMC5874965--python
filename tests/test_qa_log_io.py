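"""CSV dialect round-trips, validation, and series extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tomospc import (
    AXES,
    EmptySelectionError,
    OffsetTrial,
    QAParseError,
    QARecord,
    SeriesSpec,
    generate_series,
    read_experiment,
    read_qa_log,
    series_to_records,
    to_series,
    write_experiment,
    write_qa_log,
)

HEADER = "timestamp,unit_id,axis,offset_mm,energy_pct,output_pct,gantry_phase_deg\n"


def _write(tmp_path, body, name="log.csv"):
    p = tmp_path / name
    p.write_text(HEADER + body)
    return p


class TestReadQALog:
    def test_well_formed_rows_returned_in_order(self, tmp_path):
        p = _write(
            tmp_path,
            "2020-01-01T09:00:00,T1,IECX,0.1,,,\n"
            "2020-01-02T09:00:00,T1,IECY,-0.2,0.5,,\n"
            "2020-01-03T09:00:00,T2,IECZ,1.5,,,0.1\n",
        )
        recs = read_qa_log(p)
        assert [r.axis for r in recs] == ["IECX", "IECY", "IECZ"]
        assert recs[1].energy_pct == 0.5
        assert recs[0].energy_pct is None

    def test_invalid_axis_reports_line_number(self, tmp_path):
        p = _write(
            tmp_path,
            "2020-01-01T09:00:00,T1,IECX,0.1,,,\n"
            "2020-01-02T09:00:00,T1,IECY,0.2,,,\n"
            "2020-01-03T09:00:00,T1,IECQ,0.3,,,\n",
        )
        with pytest.raises(QAParseError, match="line 4"):
            read_qa_log(p)

    def test_unparseable_numeric_reports_line_number(self, tmp_path):
        p = _write(tmp_path, "2020-01-01T09:00:00,T1,IECX,abc,,,\n")
        with pytest.raises(QAParseError, match="line 2"):
            read_qa_log(p)

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("timestamp,unit_id,axis,offset\n")
        with pytest.raises(QAParseError, match="offset_mm"):
            read_qa_log(p)

    def test_offset_sanity_bound_rejected(self, tmp_path):
        p = _write(tmp_path, "2020-01-01T09:00:00,T1,IECX,99.0,,,\n")
        with pytest.raises(QAParseError, match="line 2"):
            read_qa_log(p)

    def test_drop_invalid_collects_errors_without_raising(self, tmp_path):
        p = _write(
            tmp_path,
            "2020-01-01T09:00:00,T1,IECX,0.1,,,\n"
            "2020-01-02T09:00:00,T1,IECQ,0.2,,,\n",
        )
        recs, errors = read_qa_log(p, drop_invalid=True)
        assert len(recs) == 1
        assert errors[0][0] == 3

    def test_filters(self, tmp_path):
        p = _write(
            tmp_path,
            "2020-01-01T09:00:00,T1,IECX,0.1,,,\n"
            "2020-01-02T09:00:00,T2,IECX,0.2,,,\n"
            "2020-01-03T09:00:00,T1,IECY,0.3,,,\n",
        )
        assert len(read_qa_log(p, unit_filter="T1")) == 2
        assert len(read_qa_log(p, axis_filter="IECX")) == 2
        assert len(read_qa_log(p, unit_filter="T1", axis_filter="IECY")) == 1


class TestRoundTrip:
    record_strategy = st.builds(
        QARecord,
        timestamp=st.datetimes(
            min_value=__import__("datetime").datetime(2013, 1, 1),
            max_value=__import__("datetime").datetime(2017, 1, 1),
        ).map(lambda d: d.isoformat()),
        unit_id=st.sampled_from(["T1", "T2"]),
        axis=st.sampled_from(AXES),
        offset_mm=st.floats(-49.9, 49.9, allow_nan=False, width=64),
        energy_pct=st.one_of(st.none(), st.floats(-5, 5, allow_nan=False)),
        output_pct=st.one_of(st.none(), st.floats(-5, 5, allow_nan=False)),
        gantry_phase_deg=st.one_of(st.none(), st.floats(-1, 1, allow_nan=False)),
    )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(records=st.lists(record_strategy, max_size=40))
    def test_write_read_identity(self, records, tmp_path_factory):
        path = tmp_path_factory.mktemp("rt") / "log.csv"
        write_qa_log(records, path)
        assert read_qa_log(path) == records

    def test_empty_list_gives_header_only_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        write_qa_log([], p)
        assert p.read_text() == HEADER
        assert read_qa_log(p) == []

    def test_single_record_gives_two_line_file(self, tmp_path):
        p = tmp_path / "one.csv"
        write_qa_log([QARecord("2020-01-01T09:00:00", "T1", "IECX", 0.1234)], p)
        assert len(p.read_text().strip().splitlines()) == 2

    def test_experiment_round_trip(self, tmp_path):
        trials = [
            OffsetTrial("IECZ", 5.0, (0.01, 1.17, 6.19), replicate=r,
                        gantry_phase_deg=0.02)
            for r in (1, 2, 3)
        ]
        p = tmp_path / "exp.csv"
        write_experiment(trials, p)
        assert read_experiment(p) == trials


class TestToSeries:
    def test_selects_only_requested_unit_axis(self, tmp_path):
        recs = [
            QARecord("2020-01-01T09:00:00", "T1", "IECX", 0.1),
            QARecord("2020-01-02T09:00:00", "T2", "IECX", 9.9),
            QARecord("2020-01-03T09:00:00", "T1", "IECX", 0.2),
        ]
        s = to_series(recs, "T1", "IECX")
        assert s.n == 2 and list(s.values) == [0.1, 0.2]

    def test_shuffled_timestamps_sorted_ascending(self):
        recs = [
            QARecord("2020-01-03T09:00:00", "T1", "IECX", 3.0),
            QARecord("2020-01-01T09:00:00", "T1", "IECX", 1.0),
            QARecord("2020-01-02T09:00:00", "T1", "IECX", 2.0),
        ]
        s = to_series(recs, "T1", "IECX")
        assert list(s.values) == [1.0, 2.0, 3.0]

    def test_tied_timestamps_keep_input_order(self):
        recs = [
            QARecord("2020-01-01T09:00:00", "T1", "IECX", 1.0),
            QARecord("2020-01-01T09:00:00", "T1", "IECX", 2.0),
        ]
        assert list(to_series(recs, "T1", "IECX").values) == [1.0, 2.0]

    def test_empty_selection_raises(self):
        recs = [QARecord("2020-01-01T09:00:00", "T1", "IECX", 0.1)]
        with pytest.raises(EmptySelectionError):
            to_series(recs, "T2", "IECZ")

    def test_four_year_count_plumbed_through(self, tmp_path):
        """A 1530-observation synthetic archive survives export/import intact."""
        series, _ = generate_series(SeriesSpec(unit_id="T1", n=1530, seed=3))
        path = tmp_path / "t1.csv"
        write_qa_log(series_to_records(series), path)
        back = to_series(read_qa_log(path), "T1", "IECX")
        assert back.n == 1530
        np.testing.assert_allclose(back.values, series.values)
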