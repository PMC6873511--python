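"""Transition matrix, certainty direction, and the rate-table summary."""

from collections import Counter
from datetime import date

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import varreclass as v
from varreclass.terms import TERM_INDEX, TERM_ORDER
from varreclass.terms import ClassificationTerm as T

# Independent statement of the certainty-direction memberships: the six
# moves away from VUS, and the eight swaps across the pathogenic/benign
# divide; everything else moves toward less certainty.
MORE_CERTAIN = {(T.VUS, T.LP), (T.VUS, T.P), (T.VUS, T.LB), (T.VUS, T.B),
                (T.LP, T.P), (T.LB, T.B)}
OPPOSING = {(T.P, T.LB), (T.P, T.B), (T.LP, T.LB), (T.LP, T.B),
            (T.LB, T.P), (T.LB, T.LP), (T.B, T.P), (T.B, T.LP)}


def matrix_from_grid(grid, start_totals=None):
    counts = np.asarray(grid, dtype=np.int64)
    if start_totals is None:
        start_totals = {t: int(counts[TERM_INDEX[t]].sum()) for t in TERM_ORDER}
    return v.TransitionMatrix(counts=counts, start_totals=start_totals)


nonneg_grid = arrays(np.int64, (5, 5), elements=st.integers(0, 50)).map(
    lambda g: g - np.diag(np.diagonal(g))
)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "pair, expected",
        [((T.LP, T.P), "more_certain"),
         ((T.LP, T.LB), "opposing"),
         ((T.P, T.VUS), "less_certain"),
         ((T.LB, T.P), "opposing"),
         ((T.B, T.LB), "less_certain")],
    )
    def test_examples(self, pair, expected):
        assert v.classify_direction(*pair) == expected

    def test_no_change_is_an_error(self):
        with pytest.raises(ValueError):
            v.classify_direction(T.LP, T.LP)

    def test_all_twenty_pairs_against_enumerated_memberships(self):
        tally = Counter()
        for f in T:
            for t in T:
                if f is t:
                    continue
                got = v.classify_direction(f, t)
                tally[got] += 1
                if (f, t) in MORE_CERTAIN:
                    assert got == "more_certain", (f, t)
                elif (f, t) in OPPOSING:
                    assert got == "opposing", (f, t)
                else:
                    assert got == "less_certain", (f, t)
        assert tally == {"more_certain": 6, "less_certain": 6, "opposing": 8}

    def test_antisymmetric_about_vus(self):
        for x in T:
            if x is T.VUS:
                continue
            assert v.classify_direction(T.VUS, x) == "more_certain"
            assert v.classify_direction(x, T.VUS) == "less_certain"


class TestTransitionMatrix:
    def test_build_from_hand_events(self):
        events = [
            v.ReclassificationEvent("a", "l", T.VUS, T.P, date(2016, 1, 2), date(2017, 1, 1)),
            v.ReclassificationEvent("b", "l", T.VUS, T.P, date(2016, 1, 2), date(2017, 1, 1)),
            v.ReclassificationEvent("c", "l", T.LB, T.B, date(2016, 1, 2), date(2017, 1, 1)),
        ]
        m = v.build_transition_matrix(events, Counter({T.VUS: 10, T.LB: 5}))
        assert m.count(T.VUS, T.P) == 2
        assert m.count(T.LB, T.B) == 1
        assert m.total_events == 3

    def test_empty_events_all_zero(self):
        m = v.build_transition_matrix([], Counter())
        assert m.total_events == 0
        assert v.summarize_directions(m) == v.DirectionSummary(0, 0, 0)

    def test_diagonal_must_be_zero(self):
        grid = np.zeros((5, 5), dtype=int)
        grid[0, 0] = 1
        with pytest.raises(ValueError, match="diagonal"):
            v.TransitionMatrix(counts=grid, start_totals={t: 10 for t in TERM_ORDER})

    def test_row_cannot_exceed_start_total(self):
        grid = np.zeros((5, 5), dtype=int)
        grid[TERM_INDEX[T.LP], TERM_INDEX[T.P]] = 5
        with pytest.raises(ValueError, match="more events"):
            v.TransitionMatrix(counts=grid, start_totals={t: 1 for t in TERM_ORDER})


@given(nonneg_grid)
def test_direction_partition_is_exact(grid):
    """more + less + opposing equals total events for arbitrary matrices."""
    m = matrix_from_grid(grid)
    ds = v.summarize_directions(m)
    assert ds.total == m.total_events


@given(nonneg_grid)
def test_direction_totals_match_event_walk(grid):
    """Cell-wise accumulation equals re-walking an expanded event list."""
    m = matrix_from_grid(grid)
    walk = Counter()
    for f in TERM_ORDER:
        for t in TERM_ORDER:
            if f is not t:
                walk[v.classify_direction(f, t)] += m.count(f, t)
    ds = v.summarize_directions(m)
    assert (ds.more_certain, ds.less_certain, ds.opposing) == (
        walk["more_certain"], walk["less_certain"], walk["opposing"])


class TestRateTable:
    def test_single_event_row(self):
        grid = np.zeros((5, 5), dtype=int)
        grid[TERM_INDEX[T.LP], TERM_INDEX[T.P]] = 1
        m = v.TransitionMatrix(counts=grid, start_totals={t: 4 for t in TERM_ORDER})
        table = v.summarize_rates(m)
        row = table.row(T.LP)
        assert row.frac_reclassified == pytest.approx(0.25)
        (cell,) = [c for c in row.cells if c.count]
        assert cell.frac_of_group == 1.0

    def test_zero_start_total_with_events_is_inconsistent(self):
        grid = np.zeros((5, 5), dtype=int)
        grid[TERM_INDEX[T.LP], TERM_INDEX[T.P]] = 1
        m = v.TransitionMatrix.__new__(v.TransitionMatrix)  # bypass guard
        m.counts = grid
        m.start_totals = {t: 0 for t in TERM_ORDER}
        with pytest.raises(ValueError, match="start total"):
            v.summarize_rates(m)

    @given(nonneg_grid)
    def test_percentage_columns_sum_to_one(self, grid):
        table = v.summarize_rates(matrix_from_grid(grid))
        for row in table.rows:
            if row.n_reclassified:
                assert sum(c.frac_of_group for c in row.cells) == pytest.approx(1.0)
        if table.total_events:
            all_cells = [c for row in table.rows for c in row.cells]
            assert sum(c.frac_of_all for c in all_cells) == pytest.approx(1.0)


class TestReferenceReproduction:
    """The deterministic reference dataset reproduces the published summary."""

    def test_start_totals(self, reference_matrix):
        expected = {T.P: 63_658, T.LP: 36_808, T.VUS: 272_581, T.LB: 140_779, T.B: 58_024}
        assert reference_matrix.start_totals == expected
        assert reference_matrix.total_classifications == 571_850

    def test_lp_row_cells(self, reference_matrix):
        assert reference_matrix.row(T.LP) == {T.P: 625, T.VUS: 165, T.LB: 4, T.B: 2}

    def test_spot_cells(self, reference_matrix):
        assert reference_matrix.count(T.VUS, T.LB) == 1586
        assert reference_matrix.count(T.B, T.P) == 1
        assert reference_matrix.total_events == 4501

    def test_direction_partition(self, reference_matrix):
        ds = v.summarize_directions(reference_matrix)
        assert (ds.more_certain, ds.less_certain, ds.opposing) == (4135, 347, 19)

    def test_lp_row_rates(self, reference_matrix):
        table = v.summarize_rates(reference_matrix)
        row = table.row(T.LP)
        assert row.n_reclassified == 796
        assert 100 * row.frac_reclassified == pytest.approx(2.16, abs=0.005)
        to_p = next(c for c in row.cells if c.to_term is T.P)
        assert 100 * to_p.frac_of_group == pytest.approx(78.5, abs=0.05)
        assert 100 * to_p.frac_of_all == pytest.approx(13.9, abs=0.05)

    def test_benign_row_rate(self, reference_matrix):
        row = v.summarize_rates(reference_matrix).row(T.B)
        assert row.n_reclassified == 15
        assert f"{100 * row.frac_reclassified:.2f}%" == "0.03%"
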