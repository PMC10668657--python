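"""Data preparation: pooling, deterministic ageing, covariates, m-array."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agecjs import (
    EncounterRecord,
    assign_age_trajectory,
    build_age_covariate,
    build_m_array,
    build_trap_covariate,
    make_grid,
    pool_to_occasions,
)
from agecjs.encounter_data import (
    ADULT,
    IMMATURE,
    JUVENILE,
    UNDEFINED,
    read_capture_history,
    write_capture_history,
)


def rec(ind, iso_date, code):
    return EncounterRecord(ind, dt.date.fromisoformat(iso_date), code)


class TestPooling:
    def test_within_semester_captures_collapse_to_one_detection(self, grid5):
        records = [rec("X", "2013-02-01", "2cy"), rec("X", "2013-05-20", "2cy")]
        history, summary = pool_to_occasions(records, grid5)
        assert history.n == 1
        occ = grid5.index_of(2013, 1)
        assert history.y[0].tolist() == [1 if t == occ else 0 for t in range(5)]
        assert summary.n_within_occasion_collapsed == 1

    def test_unknown_age_individuals_are_dropped_and_counted(self, grid5):
        records = [
            rec("A", "2012-03-01", "unknown"),
            rec("A", "2013-03-01", "unknown"),
            rec("B", "2012-03-01", "3cy"),
        ]
        history, summary = pool_to_occasions(records, grid5)
        assert history.n == 1
        assert history.ids[0] == "B"
        assert summary.n_unknown_age_dropped == 1
        assert summary.n_retained + summary.n_unknown_age_dropped == summary.n_individuals_input

    def test_partially_unknown_individual_is_kept_with_propagated_age(self, grid5):
        # unknown at first capture (2012S1), aged 3cy at 2013S1: one S2
        # boundary in between, so age at first capture is 2 years
        records = [rec("C", "2012-02-01", "unknown"), rec("C", "2013-04-01", "3cy")]
        history, _ = pool_to_occasions(records, grid5)
        assert history.n == 1
        assert history.age_at_first[0] == 2

    def test_duplicate_id_date_pairs_collapse_silently_but_counted(self, grid5):
        records = [rec("D", "2012-03-01", "5cy+")] * 3
        history, summary = pool_to_occasions(records, grid5)
        assert history.n == 1
        assert summary.n_duplicate_records == 2

    def test_date_outside_grid_is_rejected_naming_the_record(self, grid5):
        records = [rec("E", "2030-01-01", "2cy")]
        with pytest.raises(ValueError, match="2030-01-01"):
            pool_to_occasions(records, grid5)

    def test_roundtrip_through_matrix_csv(self, grid5, tmp_path):
        records = [
            rec("A", "2012-03-01", "1cy"),
            rec("A", "2013-08-01", "3cy"),
            rec("B", "2012-09-01", "5cy+"),
            rec("B", "2013-02-01", "5cy+"),
        ]
        history, _ = pool_to_occasions(records, grid5)
        path = tmp_path / "history.csv"
        write_capture_history(history, path)
        back = read_capture_history(path, grid5)
        np.testing.assert_array_equal(back.y, history.y)
        np.testing.assert_array_equal(back.f, history.f)
        np.testing.assert_array_equal(back.age_at_first, history.age_at_first)
        assert list(back.ids) == list(history.ids)


class TestAgeTrajectory:
    def test_juvenile_becomes_immature_second_semester_of_following_year(self):
        grid = make_grid(2013, 1, 6)  # 2013S1..2015S2
        f = grid.index_of(2013, 2)
        traj = assign_age_trajectory(1, f, grid)
        assert traj[grid.index_of(2013, 2)] == JUVENILE
        assert traj[grid.index_of(2014, 1)] == JUVENILE
        assert traj[grid.index_of(2014, 2)] == IMMATURE
        assert traj[grid.index_of(2015, 1)] == IMMATURE

    def test_adult_class_is_absorbing(self, grid22):
        traj = assign_age_trajectory(5, 3, grid22)
        assert (traj[3:] == ADULT).all()

    def test_two_cy_from_2012s1_is_immature_for_three_s2_boundaries(self):
        # calendar ages 2 -> 3 -> 4 -> 5 at successive second semesters
        grid = make_grid(2012, 1, 8)
        traj = assign_age_trajectory(2, 0, grid)
        # ages: 2 (2012S1), 3 (2012S2..2013S1), 4 (2013S2..2014S1), 5 (2014S2-)
        expected = [IMMATURE] * 5 + [ADULT] * 3
        assert traj.tolist() == expected

    def test_undefined_before_first_capture(self, grid5):
        traj = assign_age_trajectory(3, 2, grid5)
        assert (traj[:2] == UNDEFINED).all()
        assert (traj[2:] != UNDEFINED).all()


class TestAgeCovariate:
    def test_newly_marked_adult_then_resident(self, grid22, history_builder):
        row = [0] * 22
        for t in (2, 3, 5):
            row[t] = 1
        history = history_builder([row], [5], grid22)
        A = build_age_covariate(history)
        assert (A[0, :2] == UNDEFINED).all()
        assert A[0, 2] == 4  # newly-marked adult on the first interval
        assert (A[0, 3:] == 5).all()  # resident adult thereafter

    def test_juvenile_is_category_one_until_s2_transition_then_resident(self):
        grid = make_grid(2015, 1, 6)  # 2015S1..2017S2
        f = grid.index_of(2015, 2)
        y = np.zeros((1, 6), dtype=np.uint8)
        y[0, f] = 1
        from tests.conftest import history_from_rows

        history = history_from_rows(y.tolist(), [1], grid)
        A = build_age_covariate(history)
        # category 1 on intervals starting 2015S2 and 2016S1, then resident immature
        assert A[0, grid.index_of(2015, 2)] == 1
        assert A[0, grid.index_of(2016, 1)] == 1
        assert A[0, grid.index_of(2016, 2)] == 3

    def test_final_year_immature_newly_marked_then_resident_adult(self):
        # a 4cy bird: newly-marked immature at f, resident adult after its
        # S2 transition
        grid = make_grid(2012, 1, 4)
        y = [[1, 0, 0, 0]]
        from tests.conftest import history_from_rows

        history = history_from_rows(y, [4], grid)
        A = build_age_covariate(history)
        assert A[0].tolist() == [2, 5, 5]


class TestTrapCovariate:
    def test_hand_traced_adult_row(self, history_builder):
        grid = make_grid(2012, 1, 4)
        history = history_builder([[1, 1, 0, 1]], [5], grid)
        T = build_trap_covariate(history)
        # captured at occasions 1,2 as adult; not captured at 3
        assert T[0].tolist() == [3, 3, 4]

    def test_never_recaptured_individual(self, history_builder):
        grid = make_grid(2012, 1, 5)
        history = history_builder([[0, 1, 0, 0, 0]], [5], grid)
        T = build_trap_covariate(history)
        assert T[0].tolist() == [UNDEFINED, 3, 4, 4]

    def test_category_reflects_age_at_previous_occasion(self, history_builder):
        # immature transitioning to adult: the trap category at the
        # transition interval uses the class at the PREVIOUS occasion
        grid = make_grid(2012, 1, 4)  # ages 4 -> 5 at 2012S2
        history = history_builder([[1, 1, 1, 1]], [4], grid)
        T = build_trap_covariate(history)
        # occasion 1: immature (4cy); occasions 2..3: adult
        assert T[0].tolist() == [2, 3, 3]


class TestMArray:
    def test_single_history_with_gap(self, history_builder):
        grid = make_grid(2012, 1, 3)
        history = history_builder([[1, 0, 1]], [5], grid)
        m = build_m_array(history)
        assert m.loc[1, "next_3"] == 1
        assert m.loc[1, "never"] == 0
        assert m.loc[1, "released"] == 1

    def test_always_recaptured_gives_superdiagonal(self, history_builder):
        grid = make_grid(2012, 1, 4)
        history = history_builder([[1, 1, 1, 1]] * 3, [5, 5, 5], grid)
        m = build_m_array(history)
        for t in range(1, 4):
            assert m.loc[t, f"next_{t + 1}"] == 3
            assert m.loc[t, "released"] == 3
        assert (m["never"] == 0).all()

    def test_row_sums_equal_release_counts_on_simulated_data(self):
        from agecjs import make_fixture, simulate

        cfg = make_fixture("tiny", seed=5)
        records, _ = simulate(cfg)
        history, _ = pool_to_occasions(records, cfg.grid)
        m = build_m_array(history)
        next_cols = [c for c in m.columns if c.startswith("next_")]
        assert (m[next_cols].sum(axis=1) + m["never"] == m["released"]).all()
        # direct count oracle: releases at occasion t = captures at t (t < k)
        for t in range(1, history.k):
            assert m.loc[t, "released"] == int(history.y[:, t - 1].sum())


@st.composite
def random_histories(draw):
    k = draw(st.integers(4, 8))
    n = draw(st.integers(1, 12))
    rows, ages = [], []
    for _ in range(n):
        f = draw(st.integers(0, k - 1))
        row = [0] * k
        row[f] = 1
        for t in range(f + 1, k):
            row[t] = draw(st.integers(0, 1))
        rows.append(row)
        ages.append(draw(st.integers(1, 5)))
    return rows, ages, k


class TestInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(random_histories())
    def test_age_covariate_structure(self, data):
        from tests.conftest import history_from_rows

        rows, ages, k = data
        grid = make_grid(2012, 1, k)
        history = history_from_rows(rows, ages, grid)
        A = build_age_covariate(history)
        for i in range(history.n):
            defined = A[i][A[i] != UNDEFINED]
            resident = defined[np.isin(defined, (1, 3, 5))]
            assert (np.diff(resident) >= 0).all(), "resident categories must not revert"
            for cat in (2, 4):
                where = np.flatnonzero(A[i] == cat)
                assert len(where) <= 1
                if len(where):
                    assert where[0] == history.f[i]
            # defined exactly from f onwards
            assert (A[i, : history.f[i]] == UNDEFINED).all()
            assert (A[i, history.f[i]:] != UNDEFINED).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(random_histories())
    def test_pooling_conservation(self, data):
        rows, ages, k = data
        grid = make_grid(2012, 1, k)
        codes = [f"{a}cy" if a < 5 else "5cy+" for a in ages]
        records = []
        for i, row in enumerate(rows):
            for t, v in enumerate(row):
                if v:
                    year, sem = grid.occasions[t]
                    records.append(
                        EncounterRecord(f"i{i}", dt.date(year, 3 if sem == 1 else 9, 15),
                                        codes[i] if t == np.argmax(row) else "unknown")
                    )
        history, summary = pool_to_occasions(records, grid)
        assert history.y.sum() <= len(records)
        assert summary.n_retained + summary.n_unknown_age_dropped == summary.n_individuals_input
        assert history.n == len(rows)  # every row has a known code at f
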