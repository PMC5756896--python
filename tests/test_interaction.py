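import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from songspace import (BinarySeries, BirdSpec, InteractionSpec, SongTimeline,
                       TEParams, active_overlap_duration,
                       asymmetric_overlap_test, binarize, bootstrap_effect,
                       decompose, shuffle_gaps, simulate_timelines, solo_test,
                       te_test, transfer_entropy)

from conftest import random_timeline


def tl(individual, intervals, window):
    return SongTimeline(individual, tuple(intervals), window)


# ---------------------------------------------------------------------------
# decompose
# ---------------------------------------------------------------------------

class TestDecompose:
    def test_hand_countable(self):
        d = decompose(tl("X", [(0, 4)], (0, 10)), tl("Y", [(3, 6)], (0, 10)))
        assert d.vacant == pytest.approx(4.0)
        assert d.overlapped == pytest.approx(1.0)
        assert d.solo == pytest.approx(5.0)

    def test_conservation_identity_420s(self):
        # construct a pair with neither-sings 81.8 s and both-sing 67.1 s
        occupied = 420.0 - 81.8
        dx = (occupied + 67.1) / 2.0
        x = tl("X", [(0.0, dx)], (0.0, 420.0))
        y = tl("Y", [(dx - 67.1, occupied)], (0.0, 420.0))
        d = decompose(x, y)
        assert d.vacant == pytest.approx(81.8, abs=1e-9)
        assert d.overlapped == pytest.approx(67.1, abs=1e-9)
        assert d.solo == pytest.approx(271.1, abs=1e-9)

    def test_matches_millisecond_grid_oracle(self, rng):
        for _ in range(10):
            x = random_timeline(rng, "X", window=(0.0, 20.0))
            y = random_timeline(rng, "Y", window=(0.0, 20.0))
            d = decompose(x, y)
            ts = np.arange(0.0005, 20.0, 0.001)
            in_x = np.zeros(len(ts), bool)
            for b, e in x.intervals:
                in_x |= (ts >= b) & (ts < e)
            in_y = np.zeros(len(ts), bool)
            for b, e in y.intervals:
                in_y |= (ts >= b) & (ts < e)
            assert d.overlapped == pytest.approx((in_x & in_y).sum() * 0.001, abs=0.002)
            assert d.vacant == pytest.approx((~in_x & ~in_y).sum() * 0.001, abs=0.002)
            assert d.solo == pytest.approx((in_x ^ in_y).sum() * 0.001, abs=0.002)

    def test_conservation_property(self, rng):
        for _ in range(2000):
            x = random_timeline(rng, "X", window=(0.0, 30.0), max_songs=5)
            y = random_timeline(rng, "Y", window=(0.0, 30.0), max_songs=5)
            d = decompose(x, y)
            assert abs(d.vacant + d.overlapped + d.solo - d.duration) < 1e-9


# ---------------------------------------------------------------------------
# gap shuffling
# ---------------------------------------------------------------------------

class TestShuffleGaps:
    def test_single_song_two_gaps(self, rng):
        x = tl("X", [(2.0, 5.0)], (0.0, 10.0))  # gaps 2 and 5
        seen = set()
        for _ in range(50):
            s = shuffle_gaps(x, rng)
            assert s.intervals[0][1] - s.intervals[0][0] == pytest.approx(3.0)
            seen.add(round(s.intervals[0][0], 6))
        assert seen == {2.0, 5.0}

    def test_zero_gap_identity(self, rng):
        x = tl("X", [(0.0, 10.0)], (0.0, 10.0))
        assert shuffle_gaps(x, rng).intervals == x.intervals

    def test_preserves_durations_order_window(self, rng):
        for _ in range(100):
            x = random_timeline(rng, "X", window=(0.0, 50.0))
            s = shuffle_gaps(x, rng)
            assert s.window == x.window
            assert len(s.intervals) == len(x.intervals)
            got = [e - b for b, e in s.intervals]
            want = [e - b for b, e in x.intervals]
            assert got == pytest.approx(want, abs=1e-9)
            assert s.total_singing == pytest.approx(x.total_singing, abs=1e-9)

    def test_uniform_over_orderings(self, rng):
        # 3 distinct gaps -> 6 orderings, each ~1/6 over 10,000 shuffles
        x = tl("X", [(1.0, 2.0), (4.0, 5.0)], (0.0, 10.0))  # gaps 1, 2, 5
        counts = {}
        for _ in range(10_000):
            s = shuffle_gaps(x, rng)
            key = tuple(round(v, 6) for v in np.concatenate([s.begins, s.ends]))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        chi2, p = sps.chisquare(list(counts.values()))
        assert p > 0.01


# ---------------------------------------------------------------------------
# exact-null enumeration oracles
# ---------------------------------------------------------------------------

def _timeline_from_gaps(gaps, durs, window, individual="X"):
    begins, t = [], window[0]
    for g, d in zip(gaps, list(durs) + [None]):
        t += g
        if d is None:
            break
        begins.append(t)
        t += d
    return tl(individual, [(b, b + d) for b, d in zip(begins, durs)], window)


def _gaps_durs(x):
    durs = (x.ends - x.begins).tolist()
    b, e = x.begins, x.ends
    gaps = [b[0] - x.window[0]] + (b[1:] - e[:-1]).tolist() + [x.window[1] - e[-1]]
    return gaps, durs


def exact_solo_p(x, y):
    """Enumerate all gap permutations of both timelines; p = P(solo > obs)."""
    obs = decompose(x, y).solo
    gx, dx = _gaps_durs(x)
    gy, dy = _gaps_durs(y)
    larger = total = 0
    for px in itertools.permutations(gx):
        xs = _timeline_from_gaps(px, dx, x.window)
        for py in itertools.permutations(gy):
            ys = _timeline_from_gaps(py, dy, y.window, "Y")
            total += 1
            if decompose(xs, ys).solo > obs:
                larger += 1
    return larger / total


def exact_asym_p(x, y):
    """Enumerate target gap permutations; p = P(active overlap < obs)."""
    obs = active_overlap_duration(x, y)
    gx, dx = _gaps_durs(x)
    smaller = total = 0
    for px in itertools.permutations(gx):
        xs = _timeline_from_gaps(px, dx, x.window)
        total += 1
        if active_overlap_duration(xs, y) < obs:
            smaller += 1
    return smaller / total


@pytest.fixture
def small_pair():
    x = tl("X", [(1.0, 3.0), (6.0, 9.0), (12.0, 13.0)], (0.0, 20.0))  # 4 gaps
    y = tl("Y", [(2.0, 4.0), (8.0, 11.0)], (0.0, 20.0))  # 3 gaps
    return x, y


class TestExactNullOracles:
    def test_solo_test_matches_enumeration(self, small_pair):
        x, y = small_pair
        p_exact = exact_solo_p(x, y)
        n_rand = 10_000
        res = solo_test(x, y, n_rand=n_rand, seed=17)
        tol = 3 * math.sqrt(max(p_exact * (1 - p_exact), 1e-4) / n_rand)
        assert abs(res.p_value - p_exact) <= tol

    def test_asym_test_matches_enumeration(self, small_pair):
        x, y = small_pair
        p_exact = exact_asym_p(x, y)
        n_rand = 10_000
        res = asymmetric_overlap_test(x, y, n_rand=n_rand, seed=23)
        tol = 3 * math.sqrt(max(p_exact * (1 - p_exact), 1e-4) / n_rand)
        assert abs(res.p_value - p_exact) <= tol


# ---------------------------------------------------------------------------
# solo test
# ---------------------------------------------------------------------------

class TestSoloTest:
    def test_identical_timelines_flag_active_overlap(self):
        # 5 distinct gaps: the null rarely reproduces the exact arrangement,
        # so almost every draw has solo > 0
        x = tl("X", [(1.0, 3.0), (4.5, 7.5), (9.5, 10.5), (13.0, 14.0)], (0.0, 17.0))
        y = tl("Y", x.intervals, (0.0, 17.0))
        res = solo_test(x, y, n_rand=2000, seed=1)
        assert res.observed == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.975

    def test_hard_avoider_detected(self):
        hits = 0
        for r in range(100):
            birds = [BirdSpec("D", (0, 0), song_log_mu=0.7, song_log_sigma=0.5,
                              gap_mean=2.5),
                     BirdSpec("V", (50, 0), song_log_mu=0.7, song_log_sigma=0.5,
                              gap_mean=2.5)]
            sc = simulate_timelines(birds, InteractionSpec("avoider", 0.0, (("V", "D"),)),
                                    (0.0, 600.0), seed=4000 + r)
            p = solo_test(sc.timelines["D"], sc.timelines["V"], n_rand=500,
                          seed=5000 + r).p_value
            hits += p < 0.025
        assert hits >= 95

    def test_deterministic_under_seed(self, small_pair):
        x, y = small_pair
        a = solo_test(x, y, n_rand=500, seed=9)
        b = solo_test(x, y, n_rand=500, seed=9)
        assert a == b


# ---------------------------------------------------------------------------
# active overlap
# ---------------------------------------------------------------------------

class TestActiveOverlap:
    def test_hand_countable(self):
        x = tl("X", [(2.0, 5.0)], (0.0, 10.0))
        y = tl("Y", [(1.0, 3.0)], (0.0, 10.0))
        assert active_overlap_duration(x, y) == pytest.approx(1.0)
        assert active_overlap_duration(y, x) == 0.0

    def test_disjoint_zero(self):
        x = tl("X", [(0.0, 2.0)], (0.0, 10.0))
        y = tl("Y", [(5.0, 7.0)], (0.0, 10.0))
        assert active_overlap_duration(x, y) == 0.0

    def test_matches_per_song_oracle(self, rng):
        for _ in range(200):
            x = random_timeline(rng, "X", window=(0.0, 30.0))
            y = random_timeline(rng, "Y", window=(0.0, 30.0))
            expect = 0.0
            for b, e in x.intervals:
                if any(yb < b < ye for yb, ye in y.intervals):
                    expect += sum(max(0.0, min(e, ye) - max(b, yb))
                                  for yb, ye in y.intervals)
            assert active_overlap_duration(x, y) == pytest.approx(expect, abs=1e-9)

    def test_sum_bounded_by_overlap_on_constructed_case(self):
        # every overlapped second lies inside some later-starting song
        x = tl("X", [(0.0, 4.0), (10.0, 14.0)], (0.0, 20.0))
        y = tl("Y", [(2.0, 6.0), (9.0, 12.0)], (0.0, 20.0))
        total = decompose(x, y).overlapped
        s = active_overlap_duration(x, y) + active_overlap_duration(y, x)
        assert s == pytest.approx(total, abs=1e-9)

    def test_onset_song_attribution(self):
        # x starts inside y1; co-singing with later y2 only counts under union
        x = tl("X", [(2.0, 10.0)], (0.0, 20.0))
        y = tl("Y", [(1.0, 3.0), (5.0, 8.0)], (0.0, 20.0))
        assert active_overlap_duration(x, y, "union") == pytest.approx(4.0)
        assert active_overlap_duration(x, y, "onset_song") == pytest.approx(1.0)


class TestAsymmetricOverlapTest:
    def test_zero_observed_is_minimum(self):
        x = tl("X", [(6.0, 8.0)], (0.0, 20.0))
        y = tl("Y", [(0.0, 2.0)], (0.0, 20.0))
        res = asymmetric_overlap_test(x, y, n_rand=1000, seed=2)
        assert res.observed == 0.0
        assert res.p_value == 0.0  # nothing can be strictly smaller than 0

    def test_deterministic_under_seed(self, small_pair):
        x, y = small_pair
        assert (asymmetric_overlap_test(x, y, 500, seed=3)
                == asymmetric_overlap_test(x, y, 500, seed=3))


# ---------------------------------------------------------------------------
# transfer entropy
# ---------------------------------------------------------------------------

def te_oracle(x, y, k, l):
    """Exhaustive plug-in TE over all 2^(k+l+1) outcome patterns."""
    x = np.asarray(x, int)
    y = np.asarray(y, int)
    n = len(x)
    m = max(k, l)
    joint = {}
    for t in range(m - 1, n - 1):
        key = (x[t + 1], tuple(x[t - k + 1:t + 1]), tuple(y[t - l + 1:t + 1]))
        joint[key] = joint.get(key, 0) + 1
    N = sum(joint.values())
    te = 0.0
    for (x1, xk, yl), c in joint.items():
        c_xkyl = sum(v for (a, b, g), v in joint.items() if b == xk and g == yl)
        c_x1xk = sum(v for (a, b, g), v in joint.items() if a == x1 and b == xk)
        c_xk = sum(v for (a, b, g), v in joint.items() if b == xk)
        te += (c / N) * math.log2((c / c_xkyl) / (c_x1xk / c_xk))
    return te


class TestTransferEntropy:
    def test_constant_series_zero(self):
        x = BinarySeries(np.ones(100))
        y = BinarySeries(np.random.default_rng(0).integers(0, 2, 100))
        assert transfer_entropy(x, y) == 0.0

    def test_perfect_coupling_one_bit(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 10_000)
        x = np.concatenate([[0], y[:-1]])  # x_{t+1} = y_t
        te = transfer_entropy(BinarySeries(x), BinarySeries(y))
        assert abs(te - 1.0) < 0.02

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 21))
            k = int(rng.integers(1, 3))
            l = int(rng.integers(1, 3))
            if n <= max(k, l) + 1:
                continue
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            got = transfer_entropy(BinarySeries(x), BinarySeries(y), TEParams(k, l))
            assert got == pytest.approx(te_oracle(x, y, k, l), abs=1e-12)
            assert got >= 0.0

    def test_relabel_invariance(self, rng):
        for _ in range(20):
            x = rng.integers(0, 2, 200)
            y = rng.integers(0, 2, 200)
            a = transfer_entropy(BinarySeries(x), BinarySeries(y), TEParams(2, 1))
            b = transfer_entropy(BinarySeries(1 - x), BinarySeries(1 - y), TEParams(2, 1))
            assert a == pytest.approx(b, abs=1e-12)

    def test_too_short_error(self):
        with pytest.raises(ValueError):
            transfer_entropy(BinarySeries([1, 0]), BinarySeries([0, 1]), TEParams(2, 2))


class TestTETest:
    def test_deterministic_under_seed(self):
        birds = [BirdSpec("A", (0, 0), song_log_mu=0.2, song_log_sigma=0.8,
                          gap_mean=2.0),
                 BirdSpec("B", (50, 0), song_log_mu=0.2, song_log_sigma=0.8,
                          gap_mean=2.0)]
        sc = simulate_timelines(birds, InteractionSpec(), (0.0, 300.0), seed=2)
        a = te_test(sc.timelines["A"], sc.timelines["B"], n_rand=300, seed=5)
        b = te_test(sc.timelines["A"], sc.timelines["B"], n_rand=300, seed=5)
        assert a == b

    def test_null_mean_close_to_observed_for_independent(self):
        birds = [BirdSpec("A", (0, 0), song_log_mu=0.2, song_log_sigma=0.8,
                          gap_mean=2.0),
                 BirdSpec("B", (50, 0), song_log_mu=0.2, song_log_sigma=0.8,
                          gap_mean=2.0)]
        sc = simulate_timelines(birds, InteractionSpec(), (0.0, 600.0), seed=3)
        res = te_test(sc.timelines["A"], sc.timelines["B"], n_rand=500, seed=6)
        assert res.expected < 0.05  # small-sample bias scale, not signal


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_degenerate_constant_effect(self):
        vals = [(1.0, 4.0)] * 5  # expected - observed = 3 in every session
        r = bootstrap_effect(vals, "expected_minus_observed", n_boot=1000, seed=1)
        assert r.mean == pytest.approx(3.0)
        assert r.ci95 == (pytest.approx(3.0), pytest.approx(3.0))
        assert r.p_value == 0.0

    def test_requires_two_sessions(self):
        with pytest.raises(ValueError):
            bootstrap_effect([(1.0, 2.0)], "expected_minus_observed")

    def test_symmetric_null_rarely_significant(self):
        rng = np.random.default_rng(11)
        insignificant = 0
        for r in range(100):
            effects = rng.normal(0.0, 1.0, 7)
            vals = [(0.0, float(e)) for e in effects]  # expected-observed = e
            res = bootstrap_effect(vals, "expected_minus_observed",
                                   n_boot=500, seed=100 + r)
            insignificant += res.p_value > 0.05
        assert insignificant >= 80  # ~alpha-level rejections only

    def test_matches_enumeration_on_three_sessions(self):
        effects = np.array([-1.0, 1.0, 2.0])
        vals = [(0.0, float(e)) for e in effects]
        # exhaustive with-replacement enumeration: 27 equally likely resamples
        stats = np.array([np.mean([effects[i], effects[j], effects[k]])
                          for i in range(3) for j in range(3) for k in range(3)])
        p_le0 = np.mean(stats <= 0.0)   # 7/27
        p_ge0 = np.mean(stats >= 0.0)   # 23/27
        p_exact = 2 * min(p_le0, p_ge0)
        n_boot = 20_000
        r = bootstrap_effect(vals, "expected_minus_observed", n_boot=n_boot, seed=5)
        tol = 3 * 2 * math.sqrt(p_le0 * (1 - p_le0) / n_boot)
        assert abs(r.p_value - p_exact) <= tol
        assert r.mean == pytest.approx(effects.mean())
        assert stats.min() <= r.ci95[0] <= r.ci95[1] <= stats.max()

    def test_ratio_diff_effect(self):
        vals = [((2.0, 4.0), (1.0, 4.0)), ((3.0, 6.0), (1.0, 2.0))]
        r = bootstrap_effect(vals, "obs_exp_ratio_diff", n_boot=200, seed=2)
        assert r.mean == pytest.approx(np.mean([0.5 - 0.25, 0.5 - 0.5]))
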