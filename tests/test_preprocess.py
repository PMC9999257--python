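"""Criterion derivation, day padding, criterion shift, and time features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biscuit_ema import (
    TruthConfig,
    build_predictor_matrix,
    cyclical_features,
    derive_binge_outcome,
    generate_participant,
    insert_day_padding,
    shift_criterion,
    time_of_day_dummies,
)
from biscuit_ema.preprocess import (
    CRITERION,
    CYCLE_PREDICTORS,
    DUMMY_PREDICTORS,
    PREDICTOR_NAMES,
    read_matrix,
    write_matrix,
)
from conftest import make_prompts


def events_frame(rows):
    return pd.DataFrame(rows, columns=["timestamp", "excessive_amount", "loss_of_control"])


class TestBingeOutcome:
    def test_signal_reported_binge(self):
        assert derive_binge_outcome("binge", True, None) == 1

    def test_qualifying_event(self):
        ev = events_frame([{"timestamp": pd.Timestamp("2025-03-02 09:00"),
                            "excessive_amount": True, "loss_of_control": True}])
        assert derive_binge_outcome("snack", True, ev) == 1

    def test_event_without_loss_of_control_does_not_qualify(self):
        ev = events_frame([{"timestamp": pd.Timestamp("2025-03-02 09:00"),
                            "excessive_amount": True, "loss_of_control": False}])
        assert derive_binge_outcome("snack", True, ev) == 0

    def test_unanswered_without_event_is_missing(self):
        assert np.isnan(derive_binge_outcome(None, False, None))

    def test_unanswered_with_qualifying_event_is_positive(self):
        ev = events_frame([{"timestamp": pd.Timestamp("2025-03-02 09:00"),
                            "excessive_amount": "yes", "loss_of_control": "yes"}])
        assert derive_binge_outcome(None, False, ev) == 1

    def test_malformed_event_rejected_with_warning(self):
        ev = events_frame([{"timestamp": pd.Timestamp("2025-03-02 09:00"),
                            "excessive_amount": "yes", "loss_of_control": None}])
        with pytest.warns(UserWarning, match="rejected"):
            assert derive_binge_outcome("snack", True, ev) == 0


class TestDayPadding:
    def test_one_padding_row_per_day(self):
        prompts = make_prompts([[0] * 6, [0] * 6])
        out = insert_day_padding(prompts)
        assert len(out) == 14
        assert int(out["is_padding"].sum()) == 2
        # padding sits immediately after the last prompt of each day
        assert out["is_padding"].tolist() == [False] * 6 + [True] + [False] * 6 + [True]

    def test_single_day(self):
        out = insert_day_padding(make_prompts([[0]]))
        assert len(out) == 2 and out["is_padding"].tolist() == [False, True]

    def test_empty_input(self):
        out = insert_day_padding(make_prompts([]))
        assert len(out) == 0

    def test_original_rows_unchanged(self):
        prompts = make_prompts([[0, 1, 0], [1, 0, 0]])
        out = insert_day_padding(prompts)
        kept = out[~out["is_padding"]].reset_index(drop=True)
        # values preserved; integer columns may upcast to float via the NaN pad
        pd.testing.assert_frame_equal(kept[prompts.columns], prompts, check_dtype=False)

    def test_unsorted_input_rejected(self):
        prompts = make_prompts([[0, 0, 0]]).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            insert_day_padding(prompts)


class TestShiftCriterion:
    def test_within_day_shift(self):
        padded = insert_day_padding(make_prompts([[0, 0, 1, 0, 0, 0]]))
        y = shift_criterion(padded["binge"], padded["is_padding"])
        observed = y[~padded["is_padding"]]
        assert observed.tolist()[:5] == [0, 1, 0, 0, 0]
        assert np.isnan(observed.tolist()[5])

    def test_single_prompt_day(self):
        padded = insert_day_padding(make_prompts([[1]]))
        y = shift_criterion(padded["binge"], padded["is_padding"])
        assert y.isna().all()

    def test_no_pair_spans_a_day_boundary(self):
        padded = insert_day_padding(make_prompts([[0, 1], [1, 0]]))
        y = shift_criterion(padded["binge"], padded["is_padding"])
        observed = y[~padded["is_padding"]].tolist()
        assert observed[0] == 1 and np.isnan(observed[1])
        assert observed[2] == 0 and np.isnan(observed[3])

    @given(st.lists(st.lists(st.integers(0, 1), min_size=1, max_size=6), min_size=1, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_shift_is_inverse_of_within_day_forward_shift(self, days):
        padded = insert_day_padding(make_prompts(days))
        y = shift_criterion(padded["binge"], padded["is_padding"])
        binge = padded["binge"].to_numpy()
        pad = padded["is_padding"].to_numpy()
        for i in range(len(padded)):
            if not np.isnan(y.iloc[i]):
                assert not pad[i] and not pad[i + 1]
                assert y.iloc[i] == binge[i + 1]
            elif not pad[i]:
                assert i + 1 >= len(padded) or pad[i + 1]


class TestTimeFeatures:
    @pytest.mark.parametrize(
        "hours,period,expected",
        [
            (0.0, 24.0, (0.0, 1.0)),
            (6.0, 12.0, (0.0, -1.0)),
            (2.5, 24.0, (0.608761, 0.793353)),
        ],
    )
    def test_cyclical_values(self, hours, period, expected):
        sin_v, cos_v = cyclical_features(hours, period)
        assert sin_v == pytest.approx(expected[0], abs=1e-6)
        assert cos_v == pytest.approx(expected[1], abs=1e-6)

    def test_invalid_period(self):
        with pytest.raises(ValueError):
            cyclical_features(1.0, 0.0)

    @given(st.floats(min_value=0, max_value=1000), st.sampled_from([8.0, 12.0, 24.0]))
    @settings(max_examples=100, deadline=None)
    def test_unit_circle_identity(self, hours, period):
        s, c = cyclical_features(hours, period)
        assert abs(s**2 + c**2 - 1.0) < 1e-12

    @pytest.mark.parametrize("slot,label_idx", [(1, 0), (6, 5)])
    def test_dummy_one_hot(self, slot, label_idx):
        d = time_of_day_dummies(slot)
        assert d[label_idx] == 1 and d.sum() == 1

    def test_dummy_out_of_range(self):
        with pytest.raises(ValueError):
            time_of_day_dummies(7)


class TestPredictorMatrix:
    def test_shape_and_columns(self, driver_matrix):
        assert len(driver_matrix) == 84 + 14
        assert int(driver_matrix["is_padding"].sum()) == 14
        assert [c for c in driver_matrix.columns if c in PREDICTOR_NAMES] == PREDICTOR_NAMES
        assert CRITERION in driver_matrix.columns

    def test_padding_rows_all_missing(self, driver_matrix):
        pads = driver_matrix[driver_matrix["is_padding"]]
        assert pads[PREDICTOR_NAMES].isna().all().all()
        assert pads[CRITERION].isna().all()

    def test_y_missing_at_day_end(self, driver_matrix):
        rows = driver_matrix[~driver_matrix["is_padding"]]
        last_of_day = rows.groupby("day").tail(1)
        assert last_of_day[CRITERION].isna().all()
        defined = rows[CRITERION].dropna()
        assert set(defined.unique()) <= {0.0, 1.0}

    def test_dummies_exclusive_and_exhaustive(self, driver_matrix):
        rows = driver_matrix[~driver_matrix["is_padding"]]
        sums = rows[DUMMY_PREDICTORS].sum(axis=1)
        assert (sums == 1).all()

    def test_cyclical_identity_on_real_rows(self, driver_matrix):
        rows = driver_matrix[~driver_matrix["is_padding"]]
        for period in (8, 12, 24):
            s, c = rows[f"sin_{period}h"], rows[f"cos_{period}h"]
            assert np.allclose(s**2 + c**2, 1.0, atol=1e-12)

    def test_cum_hours_follow_schedule(self, driver_matrix):
        rows = driver_matrix[~driver_matrix["is_padding"]]
        day1 = rows[rows["day"] == 1]
        assert np.allclose(day1["cum_hours"], [0, 2.5, 5, 7.5, 10, 12.5])

    def test_no_binges_gives_zero_criterion(self):
        cfg = TruthConfig(beta0=-20.0, missing_rate=0.0, nonqualifying_event_rate=0.0, seed=0)
        dataset, _ = generate_participant(cfg)
        M = build_predictor_matrix(dataset)
        rows = M[~M["is_padding"]]
        assert (rows["binge_now"] == 0).all()
        assert set(rows[CRITERION].dropna()) <= {0.0}

    def test_matrix_csv_round_trip(self, driver_matrix, tmp_path):
        path = tmp_path / "matrix.csv"
        write_matrix(driver_matrix, path)
        back = read_matrix(path)
        pd.testing.assert_frame_equal(
            back, driver_matrix.reset_index(drop=True), check_dtype=False, atol=1e-9
        )

    def test_event_only_binge_recovered(self):
        """A binge at an unanswered prompt is recoverable via its event report."""
        cfg = TruthConfig(
            beta0=2.0, missing_rate=1.0, event_report_rate=1.0, seed=13
        )
        dataset, truth = generate_participant(cfg)
        M = build_predictor_matrix(dataset)
        rows = M[~M["is_padding"]]
        assert rows["binge_now"].sum() == truth.realized_binge_count > 0
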