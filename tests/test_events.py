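"""Event-locked analysis: refractory filter, alignment, rates, deciles, phases."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fiberfeed as ff
from fiberfeed.events import decile_assignments, phase_means
from fiberfeed.io import ValidationError
from fiberfeed.preprocess import NormalizedTrace


def brute_refractory(times, r):
    """All-pairs scan: keep e iff no poke lies strictly inside (e - r, e)."""
    times = np.sort(np.asarray(times, dtype=float))
    return np.array(
        [e for e in times if not np.any((times > e - r) & (times < e))]
    )


class TestRefractoryFilter:
    def test_spec_example(self):
        kept = ff.refractory_filter(np.array([0.0, 30.0, 80.0, 120.0]), 45.0)
        np.testing.assert_allclose(kept, [0.0, 80.0])

    def test_single_and_empty(self):
        np.testing.assert_allclose(ff.refractory_filter(np.array([5.0]), 45.0), [5.0])
        assert len(ff.refractory_filter(np.array([]), 45.0)) == 0

    def test_filter_is_against_all_pokes(self):
        # 30 is removed by 0; 60 must still be removed by (removed) 30
        kept = ff.refractory_filter(np.array([0.0, 30.0, 60.0]), 45.0)
        np.testing.assert_allclose(kept, [0.0])

    @given(
        st.lists(st.floats(0, 1000), min_size=0, max_size=40),
        st.floats(1.0, 120.0),
    )
    def test_matches_all_pairs_oracle(self, times, r):
        got = ff.refractory_filter(np.array(times), r)
        np.testing.assert_allclose(got, brute_refractory(times, r))


def ripple_trace(n=4000, dt=0.1, step_at=None, step=0.0):
    t = np.arange(n) * dt
    y = 100.0 + 0.5 * np.sin(2 * np.pi * t / 7.3)
    if step_at is not None:
        y = y + step * (t >= step_at)
    return NormalizedTrace(t=t, y=y, kind="corrected")


class TestAlignToEvents:
    def test_step_shows_up_post_event(self):
        trace = ripple_trace(step_at=200.0, step=5.0)
        aligned = ff.align_to_events(trace, np.array([200.0]))
        assert len(aligned) == 1
        pre = aligned.mean()[aligned.rel_t < -1.0]
        post = aligned.mean()[aligned.rel_t > 5.0]
        assert np.mean(np.abs(pre)) < 1.0
        assert np.mean(post) > 3.0

    def test_incomplete_windows_excluded(self):
        trace = ripple_trace()
        events = np.array([10.0, 200.0, 399.9])  # first/last lack full windows
        aligned = ff.align_to_events(trace, events)
        assert len(aligned) + aligned.n_excluded == 3
        assert len(aligned) == 1

    def test_constant_trace_rows_excluded_and_summary_refuses(self):
        t = np.arange(2000) * 0.1
        trace = NormalizedTrace(t=t, y=np.full(2000, 7.0), kind="corrected")
        aligned = ff.align_to_events(trace, np.array([100.0]))
        assert len(aligned) == 0 and aligned.n_excluded == 1
        with pytest.raises(ValidationError, match="no events"):
            aligned.mean()

    def test_default_window_spans_minus45_plus100(self):
        trace = ripple_trace()
        aligned = ff.align_to_events(trace, np.array([200.0]))
        assert aligned.rel_t[0] == pytest.approx(-45.0)
        assert aligned.rel_t[-1] == pytest.approx(100.0)


class TestPoolAndAverage:
    def test_two_stage_mean(self):
        means, group, sem = ff.pool_and_average({"A": [1.0, 3.0], "B": [2.0]})
        assert means["A"] == pytest.approx(2.0)
        assert means["B"] == pytest.approx(2.0)
        assert group == pytest.approx(2.0)
        assert sem == pytest.approx(0.0)

    def test_single_mouse_has_no_sem(self):
        means, group, sem = ff.pool_and_average({"A": [4.2]})
        assert group == pytest.approx(4.2)
        assert sem is None

    def test_trial_order_invariant(self):
        a = ff.pool_and_average({"A": [1.0, 5.0, 3.0], "B": [2.0, 0.0]})
        b = ff.pool_and_average({"A": [3.0, 1.0, 5.0], "B": [0.0, 2.0]})
        assert a[1] == pytest.approx(b[1])

    def test_mouse_without_trials_dropped(self, caplog):
        with caplog.at_level("WARNING"):
            means, _, _ = ff.pool_and_average({"A": [1.0], "B": []})
        assert "B" not in means


class TestPokeRate:
    def test_regular_poking_interior_rate(self):
        pokes = np.arange(0.0, 7200.0, 60.0)
        grid, rate = ff.poke_rate(pokes, session_span=(0.0, 7200.0))
        interior = (grid > 1800) & (grid < 5400)
        np.testing.assert_allclose(rate[interior], 1.0, atol=0.05)

    def test_no_pokes_zero_rate(self):
        grid, rate = ff.poke_rate(np.array([]), session_span=(0.0, 3600.0))
        np.testing.assert_allclose(rate, 0.0)

    def test_doubling_pokes_doubles_rate(self):
        pokes = np.arange(0.0, 7200.0, 60.0)
        _, r1 = ff.poke_rate(pokes, session_span=(0.0, 7200.0))
        _, r2 = ff.poke_rate(np.repeat(pokes, 2), session_span=(0.0, 7200.0))
        np.testing.assert_allclose(r2, 2.0 * r1)

    def test_rate_integrates_to_total_count(self, rng):
        pokes = np.sort(rng.uniform(0, 7200.0, 80))
        grid, rate = ff.poke_rate(pokes, session_span=(0.0, 7200.0), grid_dt_s=10.0)
        total = np.trapezoid(rate, grid) / 60.0
        assert total == pytest.approx(80, rel=0.15)


class TestDecileSplit:
    def test_ten_pokes_one_per_decile(self):
        np.testing.assert_array_equal(decile_assignments(10), np.arange(1, 11))

    def test_n23_size_vector(self):
        sizes = np.bincount(decile_assignments(23), minlength=11)[1:]
        np.testing.assert_array_equal(sizes, [2, 2, 2, 3, 2, 2, 3, 2, 2, 3])

    @given(st.integers(1, 200))
    def test_matches_ceiling_oracle_and_partitions(self, n):
        got = decile_assignments(n)
        oracle = np.array(
            [min(10, max(1, int(np.ceil(100.0 * i / n / 10.0)))) for i in range(1, n + 1)]
        )
        np.testing.assert_array_equal(got, oracle)
        # contiguous in time order, sizes differ by <= 1 from balance
        assert np.all(np.diff(got) >= 0)
        sizes = np.bincount(got, minlength=11)[1:]
        assert sizes.sum() == n

    def test_presented_deciles(self):
        trace = ripple_trace(n=30000)
        events = np.linspace(100.0, 2800.0, 12)
        aligned = ff.align_to_events(trace, events)
        split = ff.decile_split(aligned)
        assert split.presented_deciles == (1, 4, 7, 10)
        assert len(split.decile_index) == len(aligned)


class TestPhaseMeans:
    def make_trace(self):
        t = np.arange(-40.0, 40.0, 0.1)
        y = np.where(t > 10.0, -1.0, 0.0)
        return NormalizedTrace(t=t, y=y, kind="dff")

    def test_constant_trace_equal_phases(self):
        t = np.arange(-40.0, 40.0, 0.1)
        trace = NormalizedTrace(t=t, y=np.full(len(t), 0.3), kind="dff")
        out = phase_means(trace, 0.0, 10.0, 20.0)
        assert all(v == pytest.approx(0.3) for v in out.values())

    def test_piecewise_construction(self):
        out = phase_means(self.make_trace(), 0.0, 10.0, 20.0)
        assert out["pre_drop"] == pytest.approx(0.0)
        assert out["pre_contact"] == pytest.approx(0.0)
        assert out["pre_bite"] == pytest.approx(-1.0)
        assert out["bite"] == pytest.approx(-1.0)

    def test_empty_window_is_absent_not_zero(self):
        out = phase_means(self.make_trace(), 0.0, 0.5, 20.0)
        assert out["pre_contact"] is None

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValidationError, match="ordered"):
            phase_means(self.make_trace(), 0.0, 20.0, 10.0)
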