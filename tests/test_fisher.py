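"""Core FI statistic: state binning, the discrete index, and the moving window."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lakefi as lf
from lakefi.fisher import (
    DataError,
    NormalizationError,
    SizingError,
    _greedy_assign,
    bin_states,
    compute_fi,
    estimate_sost,
    windowed_fi,
)


def naive_fi(p):
    """Independent straight-line evaluation: zero-padded amplitude differences."""
    q = [0.0] + [np.sqrt(v) for v in p] + [0.0]
    return 4.0 * sum((q[i] - q[i + 1]) ** 2 for i in range(len(q) - 1))


def oracle_bin(points, sost):
    """Exhaustive restatement of the greedy membership rule (pure python)."""
    refs, labels, counts = [], [], []
    for x in points:
        for s, ref in enumerate(refs):
            if all(abs(a - b) <= t for a, b, t in zip(x, ref, sost)):
                labels.append(s + 1)
                counts[s] += 1
                break
        else:
            refs.append(x)
            counts.append(1)
            labels.append(len(refs))
    return labels, counts


class TestComputeFi:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([1.0], 8.0),
            ([0.5, 0.5], 4.0),
            ([0.1] * 10, 0.8),
        ],
    )
    def test_reference_values(self, p, expected):
        assert compute_fi(p) == pytest.approx(expected, abs=1e-12)

    def test_matches_naive_oracle_on_random_distributions(self, rng):
        for _ in range(300):
            m = rng.integers(1, 13)
            p = rng.dirichlet(np.ones(m))
            fi = compute_fi(p)
            assert fi == pytest.approx(naive_fi(p), abs=1e-12)
            assert 0.0 <= fi <= 8.0
            assert (fi == pytest.approx(8.0)) == (m == 1)

    def test_rejects_unnormalized_probabilities(self):
        with pytest.raises(NormalizationError):
            compute_fi([0.5, 0.4])

    def test_accepts_state_assignment(self):
        sa = bin_states(np.zeros((4, 2)), [1.0, 1.0])
        assert compute_fi(sa) == pytest.approx(8.0)


class TestBinStates:
    def test_identical_rows_form_one_state(self):
        sa = bin_states(np.ones((10, 3)) * 2.5, [0.0, 0.0, 0.0])
        assert sa.n_states == 1
        assert sa.p.tolist() == [1.0]

    def test_separated_points_each_found_a_state(self):
        sa = bin_states(np.array([[0.0], [10.0], [20.0]]), [1.0])
        assert sa.n_states == 3
        np.testing.assert_allclose(sa.p, [1 / 3, 1 / 3, 1 / 3])

    def test_membership_is_against_the_founding_reference(self):
        # third row is within 1 of the second, but not of state 1's reference
        sa = bin_states(np.array([[0.0], [0.5], [1.2]]), [1.0])
        assert sa.labels.tolist() == [1, 1, 2]
        np.testing.assert_allclose(sa.p, [2 / 3, 1 / 3])

    def test_matches_exhaustive_oracle_on_random_windows(self):
        for seed in range(200):
            r = np.random.default_rng(seed)
            n, v = int(r.integers(1, 7)), int(r.integers(1, 4))
            pts = r.normal(size=(n, v))
            sost = r.uniform(0.0, 2.0, v)
            sa = bin_states(pts, sost)
            labels, counts = oracle_bin(pts.tolist(), sost.tolist())
            assert sa.labels.tolist() == labels
            assert sa.counts.tolist() == counts
            assert compute_fi(sa) == pytest.approx(naive_fi(sa.p), abs=1e-12)

    @pytest.mark.parametrize("c", [0.5, 2.0, 3.0, 10.0])
    def test_affine_invariance_of_assignments(self, rng, c):
        """Rescaling a variable and its tolerance together changes nothing."""
        pts = rng.normal(size=(12, 3))
        sost = rng.uniform(0.1, 1.5, 3)
        base = bin_states(pts, sost)
        scaled_pts = pts * np.array([c, 1.0, 1.0])
        scaled_sost = sost * np.array([c, 1.0, 1.0])
        scaled = bin_states(scaled_pts, scaled_sost)
        assert base.labels.tolist() == scaled.labels.tolist()
        assert compute_fi(base) == compute_fi(scaled)

    def test_empty_window_and_missing_values_rejected(self):
        with pytest.raises(SizingError):
            bin_states(np.empty((0, 2)), [1.0, 1.0])
        with pytest.raises(DataError):
            bin_states(np.array([[1.0], [np.nan]]), [1.0])


class TestEstimateSost:
    def test_zero_variance_window_is_selected(self):
        data = np.vstack([np.tile([1.0, 2.0], (4, 1)), np.random.default_rng(0).normal(size=(4, 2))])
        sv = estimate_sost(data, window_size=4, multiplier=2.0)
        np.testing.assert_allclose(sv.tolerances, [0.0, 0.0])
        assert sv.source == "estimated"

    def test_single_variable_constant_first_window(self):
        data = np.array([1, 1, 1, 1, 5, 9, 1, 7], dtype=float)
        sv = estimate_sost(data, window_size=4, multiplier=2.0)
        assert sv.tolerances.tolist() == [0.0]

    def test_matches_brute_force_scan(self, rng):
        """Oracle enumerates every disjoint window, rescales sds, takes the min."""
        data = rng.normal(size=(30, 3)) * np.array([1.0, 10.0, 0.1])
        w = 5
        overall = data.std(axis=0, ddof=1)
        best, best_score = None, np.inf
        for k in range(len(data) // w):
            sds = data[k * w : (k + 1) * w].std(axis=0, ddof=1)
            score = np.mean(sds / overall)
            if score < best_score:
                best, best_score = sds, score
        sv = estimate_sost(data, window_size=w, multiplier=2.0)
        np.testing.assert_allclose(sv.tolerances, 2.0 * best)

    def test_constant_variable_warns_and_gets_zero_tolerance(self, rng):
        data = np.column_stack([np.full(12, 3.0), rng.normal(size=12)])
        with pytest.warns(UserWarning, match="constant"):
            sv = estimate_sost(data, window_size=4)
        assert sv.tolerances[0] == 0.0

    def test_too_few_rows_raises(self):
        with pytest.raises(SizingError):
            estimate_sost(np.zeros((3, 2)), window_size=4)


class TestWindowedFi:
    def test_window_count_85_stations_window_10_step_1(self, rng):
        data = rng.normal(size=(85, 4))
        wins = windowed_fi(data, [1.0] * 4, window_size=10, step=1)
        assert len(wins) == 76
        assert [w.index for w in wins] == list(range(1, 77))

    def test_identical_rows_give_fi_max_everywhere(self):
        wins = windowed_fi(np.ones((20, 2)), [0.5, 0.5], window_size=5)
        assert all(w.fi == pytest.approx(8.0) for w in wins)
        assert all(w.n_states == 1 for w in wins)

    def test_planted_break_depresses_straddling_windows(self):
        """Two tight clusters far apart: only windows crossing the break drop."""
        lo = np.full((6, 2), 0.0)
        hi = np.full((6, 2), 100.0)
        data = np.vstack([lo, hi]) + np.random.default_rng(1).normal(scale=0.01, size=(12, 2))
        wins = windowed_fi(data, [1.0, 1.0], window_size=4, step=1)
        for w in wins:
            start = w.index - 1
            straddles = start < 6 < start + 4
            if straddles:
                assert w.fi < 8.0
                # by hand: the window splits into exactly the two clusters
                k = 6 - start
                expected = naive_fi([k / 4, (4 - k) / 4])
                assert w.fi == pytest.approx(expected, abs=1e-12)
            else:
                assert w.fi == pytest.approx(8.0)

    def test_anchor_and_members_bookkeeping(self):
        idx = [f"S{i:02d}" for i in range(6)]
        df = pd.DataFrame(np.zeros((6, 2)), index=idx, columns=["a", "b"])
        coords = pd.DataFrame(
            {"lat": np.linspace(55, 60, 6), "lon": 15.0}, index=idx
        )
        wins = windowed_fi(df, [1.0, 1.0], window_size=3, coords=coords)
        assert wins[0].anchor == "S00"
        assert wins[0].members == ("S00", "S01", "S02")
        assert wins[-1].anchor == "S03"
        assert wins[0].lat == pytest.approx(55.0)

    def test_oversized_window_rejected(self):
        with pytest.raises(SizingError):
            windowed_fi(np.zeros((5, 1)), [1.0], window_size=6)

    @given(st.integers(0, 500))
    def test_fi_range_and_normalization_invariants(self, seed):
        r = np.random.default_rng(seed)
        data = r.normal(size=(12, 2)) * r.uniform(0.1, 5)
        sost = r.uniform(0.0, 2.0, 2)
        for w in windowed_fi(data, sost, window_size=4, step=2):
            assert 0.0 <= w.fi <= 8.0
            assert (w.fi == pytest.approx(8.0)) == (w.n_states == 1)

    def test_permuting_cobinned_or_distinct_rows_preserves_fi(self, rng):
        # all rows mutually co-binned: any permutation keeps one state
        tight = rng.normal(scale=0.01, size=(8, 2))
        perm = rng.permutation(8)
        f1 = windowed_fi(tight, [1.0, 1.0], 8)[0].fi
        f2 = windowed_fi(tight[perm], [1.0, 1.0], 8)[0].fi
        assert f1 == f2 == pytest.approx(8.0)
        # all rows mutually distinct: permutation keeps all-singletons
        spread = np.arange(8, dtype=float)[:, None] * 100
        f3 = windowed_fi(spread, [1.0], 8)[0].fi
        f4 = windowed_fi(spread[rng.permutation(8)], [1.0], 8)[0].fi
        assert f3 == f4


def test_greedy_assign_tie_goes_to_earliest_state():
    # point 2 matches both refs 0 and 1; must join state 1 (founded first)
    cobin = np.array(
        [
            [True, False, True],
            [False, True, True],
            [True, True, True],
        ]
    )
    labels, counts = _greedy_assign(cobin)
    assert labels.tolist() == [1, 2, 1]
    assert counts.tolist() == [2, 1]
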