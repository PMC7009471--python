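"""Burst detection, overlap removal, non-burst complement, state windows."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burstdecode import bursts as bst
from burstdecode import preprocess as pp
from tests.conftest import make_trialset

DT = 0.01


def rect_envelope(total_s, excursions, base=1.0, high=10.0):
    """Baseline-level envelope with rectangular supra excursions."""
    env = np.full(int(round(total_s / DT)), base)
    for s, e in excursions:
        env[int(round(s / DT)):int(round(e / DT))] = high
    return env


class TestDetect:
    def test_single_150ms_excursion(self):
        iv = bst.detect_bursts(rect_envelope(10.0, [(2.0, 2.15)]), DT)
        assert iv.shape == (1, 2)
        assert iv[0] == pytest.approx([2.0, 2.15], abs=DT)

    def test_80ms_excursion_rejected(self):
        iv = bst.detect_bursts(rect_envelope(10.0, [(2.0, 2.08)]), DT)
        assert len(iv) == 0

    def test_constant_envelope_no_bursts(self):
        assert len(bst.detect_bursts(np.ones(1000), DT)) == 0

    def test_supra_threshold_time_matches_brute_force(self):
        """Before the duration filter, total supra time equals the mask; the
        filter can only remove time."""
        rng = np.random.default_rng(0)
        for p in (60.0, 75.0, 90.0):
            env = rng.standard_normal(2000).cumsum()  # correlated walk
            thr = np.percentile(env, p)
            mask_time = (env > thr).sum() * DT
            unfiltered = bst.detect_bursts(env, DT, percentile=p,
                                           min_duration=0.0)
            assert sum(e - s for s, e in unfiltered) == pytest.approx(
                mask_time, abs=1e-9)
            filtered = bst.detect_bursts(env, DT, percentile=p)
            assert sum(e - s for s, e in filtered) <= mask_time + 1e-9

    def test_idempotent(self):
        env = np.random.default_rng(1).standard_normal(3000).cumsum()
        a = bst.detect_bursts(env, DT)
        b = bst.detect_bursts(env, DT)
        assert np.array_equal(a, b)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            env = rng.standard_normal(2000).cumsum()
            prev_count, prev_occ = np.inf, np.inf
            for p in (60.0, 75.0, 90.0):
                iv = bst.detect_bursts(env, DT, percentile=p)
                occ = sum(e - s for s, e in iv)
                assert len(iv) <= prev_count or occ <= prev_occ + 1e-12
                assert occ <= prev_occ + 1e-12
                prev_count, prev_occ = len(iv), occ

    def test_short_envelope_rejected(self):
        with pytest.raises(ValueError):
            bst.detect_bursts(np.ones(50), DT)

    def test_bad_percentile_rejected(self):
        with pytest.raises(ValueError):
            bst.detect_bursts(np.ones(1000), DT, percentile=0.0)


def brute_force_overlap_filter(a, b):
    keep_a = [ai for ai in a
              if not any(ai[0] < bj[1] and bj[0] < ai[1] for bj in b)]
    keep_b = [bj for bj in b
              if not any(bj[0] < ai[1] and ai[0] < bj[1] for ai in a)]
    return (np.array(keep_a).reshape(-1, 2), np.array(keep_b).reshape(-1, 2))


class TestResolveOverlaps:
    def test_overlapping_pair_both_removed(self):
        a, b = bst.resolve_overlaps(np.array([[1.0, 1.2]]),
                                    np.array([[1.1, 1.3]]))
        assert len(a) == 0 and len(b) == 0

    def test_touching_half_open_kept(self):
        a, b = bst.resolve_overlaps(np.array([[1.0, 1.2]]),
                                    np.array([[1.2, 1.4]]))
        assert len(a) == 1 and len(b) == 1

    def test_random_sets_match_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            def rand_ivs():
                s = np.sort(rng.uniform(0, 10, rng.integers(0, 8)))
                return np.column_stack([s, s + rng.uniform(0.05, 1.0, len(s))])
            a, b = rand_ivs(), rand_ivs()
            got_a, got_b = bst.resolve_overlaps(a, b)
            exp_a, exp_b = brute_force_overlap_filter(a, b)
            assert np.allclose(got_a, exp_a) and np.allclose(got_b, exp_b)

    def test_survivors_disjoint_occupancy_zero(self):
        """After removal, alpha and beta survivors share no sample."""
        rng = np.random.default_rng(4)
        grid = np.arange(0, 10, 0.001)
        for _ in range(20):
            s = np.sort(rng.uniform(0, 10, 6))
            a = np.column_stack([s, s + rng.uniform(0.1, 0.8, 6)])
            s = np.sort(rng.uniform(0, 10, 6))
            b = np.column_stack([s, s + rng.uniform(0.1, 0.8, 6)])
            ra, rb = bst.resolve_overlaps(a, b)
            mask_a = np.zeros(len(grid), bool)
            mask_b = np.zeros(len(grid), bool)
            for x, y in ra:
                mask_a |= (grid >= x) & (grid < y)
            for x, y in rb:
                mask_b |= (grid >= x) & (grid < y)
            assert not (mask_a & mask_b).any()


class TestNonBurst:
    def test_no_bursts_full_span(self):
        out = bst.nonburst_periods([np.empty((0, 2))], (0.0, 4.0))
        assert np.allclose(out, [[0.0, 4.0]])

    def test_fully_tiled_span_empty(self):
        out = bst.nonburst_periods([np.array([[0.0, 2.0], [2.0, 4.0]])],
                                   (0.0, 4.0))
        assert len(out) == 0

    def test_matches_mask_complement(self):
        rng = np.random.default_rng(5)
        grid = np.arange(0, 8, 0.0005)
        for _ in range(100):
            lists = []
            for _ in range(3):
                s = np.sort(rng.uniform(0, 8, rng.integers(0, 6)))
                lists.append(np.column_stack(
                    [s, s + rng.uniform(0.05, 1.5, len(s))]))
            out = bst.nonburst_periods(lists, (0.0, 8.0), min_duration=0.0)
            mask = np.zeros(len(grid), bool)
            for ivs in lists:
                for s, e in ivs:
                    mask[(grid >= s) & (grid < e)] = True
            got = np.zeros(len(grid), bool)
            for s, e in out:
                got[(grid >= s) & (grid < e)] = True
            assert (got == ~mask).mean() > 0.999  # grid-edge tolerance


class TestStateWindows:
    def test_burst_midpoint(self):
        w = bst.make_state_windows(np.array([[2.0, 2.3]]), np.empty((0, 2)),
                                   np.empty((0, 2)), span=(0.0, 4.0))
        assert len(w) == 1
        assert (w[0].start, w[0].end) == pytest.approx((2.10, 2.20))
        assert w[0].state == "alpha_burst"

    def test_nonburst_midpoint(self):
        w = bst.make_state_windows(np.empty((0, 2)), np.empty((0, 2)),
                                   np.array([[0.0, 4.0]]), span=(0.0, 4.0))
        assert (w[0].start, w[0].end) == pytest.approx((1.95, 2.05))

    def test_minimal_burst_at_span_edge_kept(self):
        w = bst.make_state_windows(np.array([[0.0, 0.1]]), np.empty((0, 2)),
                                   np.empty((0, 2)), span=(0.0, 4.0))
        assert len(w) == 1
        assert (w[0].start, w[0].end) == pytest.approx((0.0, 0.1))

    def test_window_beyond_span_dropped(self):
        w = bst.make_state_windows(np.array([[-0.4, 0.08]]), np.empty((0, 2)),
                                   np.empty((0, 2)), span=(0.0, 4.0))
        assert len(w) == 0


class TestStatistics:
    def test_arithmetic(self):
        ivs = np.array([[i, i + 0.2] for i in range(5)], dtype=float)
        s = bst.burst_statistics(ivs, span_s=10.0)
        assert s["rate"] == pytest.approx(0.5)
        assert s["mean_duration"] == pytest.approx(0.2)
        assert s["occupancy"] == pytest.approx(0.1)

    def test_empty_set(self):
        s = bst.burst_statistics(np.empty((0, 2)), span_s=10.0,
                                 other=np.empty((0, 2)))
        assert s["rate"] == 0.0
        assert np.isnan(s["mean_duration"])
        assert np.isnan(s["overlap_proportion"])

    def test_overlap_proportion(self):
        a = np.array([[0.0, 0.5], [2.0, 2.5], [4.0, 4.5], [6.0, 6.5]])
        b = np.array([[0.4, 0.9], [4.4, 4.6]])
        s = bst.burst_statistics(a, span_s=10.0, other=b)
        assert s["overlap_proportion"] == pytest.approx(0.5)


class TestBandEnvelope:
    def tone_tf(self, freq):
        fs = 2048.0
        t = np.arange(int(3.0 * fs)) / fs
        x = np.sin(2 * np.pi * freq * t)
        trials = make_trialset(x[None, None])
        freqs = np.arange(8.0, 46.0)
        return pp.morlet_decompose(trials, freqs=freqs,
                                   n_cycles=freqs / 2.0, out_span=(-0.5, 0.5))

    def test_band_separation(self):
        tf = self.tone_tf(20.0)
        beta = bst.band_envelope(tf.power[0, 0], tf.freqs, "beta", DT)
        alpha = bst.band_envelope(tf.power[0, 0], tf.freqs, "alpha", DT)
        assert beta.mean() > 100 * alpha.mean()
        assert (beta > 0).all()

    def test_amplitude_modulation_tracked(self):
        fs = 2048.0
        t = np.arange(int(4.0 * fs)) / fs
        mod = 1.0 + 0.8 * np.sin(2 * np.pi * 1.0 * t)
        x = mod * np.sin(2 * np.pi * 20.0 * t)
        trials = make_trialset(x[None, None], pre_s=1.5, post_s=1.5)
        freqs = np.arange(13.0, 31.0)
        tf = pp.morlet_decompose(trials, freqs=freqs,
                                 n_cycles=freqs / 2.0, out_span=(-1.0, 1.0))
        env = bst.band_envelope(tf.power[0, 0], tf.freqs, "beta", DT,
                                smooth_s=0.05)
        target = (mod ** 2)[np.round((tf.times + 2.0) * fs).astype(int)]
        assert np.corrcoef(env, target)[0, 1] > 0.9

    def test_zero_signal_zero_envelope(self):
        power = np.zeros((10, 100))
        env = bst.band_envelope(power, np.arange(8.0, 18.0), "alpha", DT)
        assert np.all(env == 0)

    def test_unknown_band_range_rejected(self):
        with pytest.raises(ValueError):
            bst.band_envelope(np.ones((5, 50)), np.arange(8.0, 13.0),
                              (100.0, 120.0), DT)


def test_constructed_epoch_pipeline():
    """A 2 s epoch with one planted alpha and one planted beta excursion
    (non-overlapping) yields exactly one burst each, both >= 100 ms, and
    non-burst windows in the remaining span."""
    alpha_env = rect_envelope(2.0, [(0.4, 0.58)])
    beta_env = rect_envelope(2.0, [(1.3, 1.52)])
    gamma_env = rect_envelope(2.0, [])
    a = bst.detect_bursts(alpha_env, DT)
    b = bst.detect_bursts(beta_env, DT)
    g = bst.detect_bursts(gamma_env, DT)
    assert len(a) == 1 and len(b) == 1 and len(g) == 0
    assert (a[0, 1] - a[0, 0]) >= 0.1 and (b[0, 1] - b[0, 0]) >= 0.1
    ra, rb = bst.resolve_overlaps(a, b)
    assert len(ra) == 1 and len(rb) == 1
    nb = bst.nonburst_periods([a, b, g], (0.0, 2.0))
    wins = bst.make_state_windows(ra, rb, nb, (0.0, 2.0))
    states = sorted(w.state for w in wins)
    assert states.count("alpha_burst") == 1
    assert states.count("beta_burst") == 1
    assert states.count("non_burst") >= 1
    for w in wins:
        assert w.end - w.start == pytest.approx(0.1)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(0, 9), st.floats(0.05, 1.0)),
                min_size=0, max_size=6))
def test_nonburst_never_intersects_bursts(raw):
    ivs = np.array([[s, s + d] for s, d in raw]).reshape(-1, 2)
    out = bst.nonburst_periods([ivs], (0.0, 10.0), min_duration=0.0)
    for s, e in out:
        for bs, be in ivs:
            assert e <= bs + 1e-12 or s >= be - 1e-12
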