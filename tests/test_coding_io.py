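import numpy as np
import pandas as pd
import pytest

from patterngrid import coding_io
from patterngrid.coding_io import (
    CODING_COLUMNS,
    VARIABLE_KEYS,
    SessionCoding,
    average_coders,
    export_trajectories,
    read_codings,
    read_trajectory,
    validate_dataset,
    write_codings,
)
from patterngrid.errors import (
    CodingFormatError,
    CodingParseError,
    ContractError,
    IntegrityError,
)


def _row(pid="p1", session=1, coder="a", value=0, **overrides):
    row = {"patient_id": pid, "session_number": session, "coder_id": coder}
    row.update({k: value for k in VARIABLE_KEYS})
    row.update(overrides)
    return row


def _frame(rows):
    return pd.DataFrame(rows, columns=list(CODING_COLUMNS))


class TestReadCodings:
    def test_identity_parse_of_zero_ratings(self, tmp_path):
        path = tmp_path / "c.csv"
        _frame([_row(), _row(coder="b")]).to_csv(path, index=False)
        df = read_codings(path)
        assert len(df) == 2
        assert (df[list(VARIABLE_KEYS)].to_numpy() == 0).all()

    def test_missing_column_is_a_format_error(self, tmp_path):
        path = tmp_path / "c.csv"
        _frame([_row()]).drop(columns=["neg_somatic"]).to_csv(path, index=False)
        with pytest.raises(CodingFormatError, match="neg_somatic"):
            read_codings(path)

    def test_non_ordinal_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "c.csv"
        _frame([_row(), _row(coder="b", pos_hope="high")]).to_csv(path, index=False)
        with pytest.raises(CodingParseError, match="pos_hope"):
            read_codings(path)

    def test_out_of_scale_rating_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        _frame([_row(neg_emotion=4)]).to_csv(path, index=False)
        with pytest.raises(CodingParseError):
            read_codings(path)

    def test_conflicting_duplicate_rows_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        _frame([_row(pos_hope=1), _row(pos_hope=2)]).to_csv(path, index=False)
        with pytest.raises(IntegrityError):
            read_codings(path)

    def test_missing_cells_become_nan(self, tmp_path):
        path = tmp_path / "c.csv"
        frame = _frame([_row()]).astype(object)
        frame.loc[0, "processing"] = ""
        frame.to_csv(path, index=False)
        df = read_codings(path)
        assert np.isnan(df.loc[0, "processing"])


def test_write_then_read_is_identity(cohort, tmp_path):
    codings, _, _ = cohort
    path = tmp_path / "roundtrip.csv"
    write_codings(codings, path)
    back = read_codings(path)
    pd.testing.assert_frame_equal(back, codings.reset_index(drop=True))
    assert back["patient_id"].nunique() == 27
    assert (back.groupby(["patient_id", "session_number"])["coder_id"]
            .nunique() == 2).all()


class TestAverageCoders:
    def test_arithmetic_mean_of_two_coders(self):
        df = _frame([_row(value=0, neg_emotion=3), _row(coder="b", value=0, neg_emotion=2)])
        avg = average_coders(df)
        assert avg.loc[0, "neg_emotion"] == 2.5
        assert avg.loc[0, "n_coders"] == 2

    def test_identical_coders_give_identity(self):
        df = _frame([_row(value=2), _row(coder="b", value=2)])
        avg = average_coders(df)
        assert (avg[list(VARIABLE_KEYS)].to_numpy() == 2).all()

    def test_opposite_extremes_average_to_midpoint(self):
        df = _frame([_row(value=0), _row(coder="b", value=3)])
        avg = average_coders(df)
        assert (avg[list(VARIABLE_KEYS)].to_numpy() == 1.5).all()

    def test_single_coder_passes_through(self):
        df = _frame([_row(value=1)])
        avg = average_coders(df)
        assert avg.loc[0, "n_coders"] == 1
        assert (avg[list(VARIABLE_KEYS)].to_numpy() == 1).all()

    def test_permutation_invariant_in_coder_order(self):
        a, b = _row(value=1, pos_hope=3), _row(coder="b", value=2)
        first = average_coders(_frame([a, b]))
        second = average_coders(_frame([b, a]))
        pd.testing.assert_frame_equal(first, second)

    def test_partial_missing_uses_available_coder(self):
        a = _row(value=1, pos_hope=np.nan)
        b = _row(coder="b", value=1)
        avg = average_coders(_frame([a, b]))
        assert avg.loc[0, "pos_hope"] == 1.0

    def test_conflicting_duplicates_raise(self):
        df = _frame([_row(pos_hope=1), _row(pos_hope=2)])
        with pytest.raises(IntegrityError):
            average_coders(df)


class TestValidateDataset:
    def test_complete_synthetic_cohort_has_no_violations(self, cohort):
        codings, outcomes, _ = cohort
        report = validate_dataset(codings, outcomes)
        assert report.ok, report.to_frame()
        assert (report.coverage["has_baseline"]).all()

    def test_out_of_range_rating_is_flagged(self, cohort):
        codings, outcomes, _ = cohort
        bad = codings.copy()
        bad.loc[0, "pos_hope"] = 4
        report = validate_dataset(bad, outcomes)
        assert any(v["kind"] == "out_of_range" for v in report.violations)
        # validation never mutates its inputs
        assert bad.loc[0, "pos_hope"] == 4

    def test_missing_phase2_coverage_is_flagged(self, cohort):
        codings, outcomes, _ = cohort
        pid = codings["patient_id"].iloc[0]
        trimmed = codings[
            ~((codings["patient_id"] == pid) & (codings["session_number"] >= 11))
        ]
        report = validate_dataset(trimmed, outcomes)
        assert any(
            v["kind"] == "insufficient_phase_coverage" and v["patient_id"] == pid
            for v in report.violations
        )


class TestTrajectories:
    def test_serialization_order(self, tmp_path):
        paths = export_trajectories(
            {("p1", "phase2"): [(11, 0, 4), (15, 1, 3), (19, 2, 2)]}, tmp_path
        )
        lines = paths[0].read_text().splitlines()
        assert lines[0].split("\t") == ["Onset", "pos_activation", "neg_activation"]
        assert lines[1:] == ["11\t0\t4", "15\t1\t3", "19\t2\t2"]

    def test_empty_trajectory_writes_header_only(self, tmp_path):
        paths = export_trajectories({("p1", "phase1"): []}, tmp_path)
        assert paths[0].read_text() == "Onset\tpos_activation\tneg_activation\n"

    def test_round_trip(self, tmp_path):
        pts = [(11, 0, 4), (15, 4, 0)]
        paths = export_trajectories({("p9", "phase2"): pts}, tmp_path)
        assert read_trajectory(paths[0]) == pts

    def test_out_of_range_coordinate_rejected(self, tmp_path):
        with pytest.raises(ContractError):
            export_trajectories({("p1", "phase1"): [(1, 5, 0)]}, tmp_path)


def test_session_coding_record_enforces_invariants():
    ratings = {k: 0 for k in VARIABLE_KEYS}
    SessionCoding("p", 1, "a", ratings)  # valid
    with pytest.raises(ContractError):
        SessionCoding("p", 1, "a", {**ratings, "processing": 5})
    with pytest.raises(ContractError):
        SessionCoding("p", 1, "a", {k: 0 for k in list(VARIABLE_KEYS)[:-1]})
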