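import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import finchloop as fl
from finchloop import behavior_metrics as bm
from finchloop.events import PerchEvent, perch_events_to_frame


SCHED = fl.DaySchedule(lights_on_s=0.0, lights_off_s=1000.0, n_days=3, day_length_s=2000.0)


def _events(rows):
    return perch_events_to_frame([PerchEvent(*r) for r in rows])


class TestLandingRate:
    def test_count_ratio(self):
        ev = _events([(0, 0, 1, 10.0 * i, 10.0 * i + 5) for i in range(8)]
                     + [(0, 0, 2, 200.0 + 10 * i, 205.0 + 10 * i) for i in range(2)])
        assert bm.landing_rate(ev, 0, 1, SCHED) == pytest.approx(0.8)

    def test_no_landings_missing(self):
        ev = _events([])
        assert np.isnan(bm.landing_rate(ev, 0, 1, SCHED))

    def test_lights_off_landings_excluded(self):
        # second landing occurs after lights-off and must not count
        ev = _events([(0, 0, 1, 10.0, 20.0), (0, 0, 2, 1500.0, 1600.0)])
        assert bm.landing_rate(ev, 0, 1, SCHED) == 1.0

    def test_row_order_invariance(self):
        rows = [(0, 0, 1, 10.0, 20.0), (0, 0, 2, 30.0, 35.0), (0, 0, 1, 50.0, 55.0)]
        a = bm.landing_rate(_events(rows), 0, 1, SCHED)
        b = bm.landing_rate(_events(rows[::-1]), 0, 1, SCHED)
        assert a == b


class TestOccupancy:
    def test_time_ratio(self):
        ev = _events([(0, 0, 1, 0.0, 30.0), (0, 0, 2, 40.0, 50.0)])
        assert bm.occupancy(ev, 0, 1, SCHED) == pytest.approx(0.75)

    def test_bout_clipped_at_lights_off(self):
        # 10 s before the boundary + 5 s into lights-off: only 10 s counts
        ev = _events([(0, 0, 1, 990.0, 1005.0), (0, 0, 2, 0.0, 10.0)])
        assert bm.occupancy(ev, 0, 1, SCHED) == pytest.approx(0.5)

    def test_zero_time_missing(self):
        assert np.isnan(bm.occupancy(_events([]), 0, 1, SCHED))

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([1, 2]),
                st.floats(min_value=0, max_value=900),
                st.floats(min_value=1.0, max_value=90.0),
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_complementarity(self, bouts):
        ev = _events([(0, 0, p, t, t + d) for p, t, d in bouts])
        o1 = bm.occupancy(ev, 0, 1, SCHED)
        o2 = bm.occupancy(ev, 0, 2, SCHED)
        assert o1 + o2 == pytest.approx(1.0)
        assert 0.0 <= o1 <= 1.0


class TestSingingSplit:
    def test_sings_only_on_perch1(self):
        # equal overall occupancy, but all singing time falls inside P1 bouts
        ev = _events([(0, 0, 1, 0.0, 100.0), (0, 0, 2, 100.0, 200.0)])
        track = bm.SingingStateTrack.from_song_epochs([(10.0, 50.0)], (0.0, 1000.0))
        sing, nonsing = bm.split_by_singing(ev, track, 0, 1, SCHED)
        assert sing == 1.0
        # P1 keeps its 58 s non-singing remainder against P2's full 100 s
        assert nonsing == pytest.approx(58.0 / 158.0)

    def test_no_singing_all_day(self):
        ev = _events([(0, 0, 1, 0.0, 30.0), (0, 0, 2, 40.0, 50.0)])
        track = bm.SingingStateTrack.from_song_epochs([], (0.0, 1000.0))
        sing, nonsing = bm.split_by_singing(ev, track, 0, 1, SCHED)
        assert np.isnan(sing)
        assert nonsing == pytest.approx(bm.occupancy(ev, 0, 1, SCHED))

    def test_track_must_tile(self):
        bad = bm.SingingStateTrack(intervals=((0.0, 500.0, "singing"),))
        ev = _events([(0, 0, 1, 0.0, 30.0)])
        with pytest.raises(ValueError):
            bm.split_by_singing(ev, bad, 0, 1, SCHED)

    def test_random_state_labels_give_equal_occupancy(self):
        """With state labels independent of location, singing and non-singing
        occupancy agree (permutation-style null)."""
        rng = np.random.default_rng(0)
        rows, t = [], 0.0
        while t < 900:
            perch = int(rng.integers(1, 3))
            d = rng.uniform(5, 20)
            rows.append((0, 0, perch, t, min(t + d, 1000.0)))
            t += d + rng.uniform(1, 5)
        ev = _events(rows)
        epochs = [(s, s + 10.0) for s in np.arange(5.0, 950.0, 40.0)]
        track = bm.SingingStateTrack.from_song_epochs(epochs, (0.0, 1000.0))
        sing, nonsing = bm.split_by_singing(ev, track, 0, 1, SCHED)
        assert abs(sing - nonsing) < 0.12

    def test_singing_gaps_under_2s_never_split(self):
        track = bm.SingingStateTrack.from_song_epochs(
            [(10.0, 12.0), (13.5, 15.0)], (0.0, 1000.0)
        )
        singing = [iv for iv in track.intervals if iv[2] == "singing"]
        assert len(singing) == 1
        assert singing[0][0] == pytest.approx(9.0)
        assert singing[0][1] == pytest.approx(16.0)


class TestDailyPitchChange:
    def _frame(self, day_means, n=30, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for day, mu in enumerate(day_means):
            for p in rng.normal(mu, sd, n) if sd else [mu] * n:
                rows.append({"bird_id": 0, "day": day, "pitch_hz": float(p)})
        return pd.DataFrame(rows)

    def test_linear_ramp(self):
        assert bm.daily_pitch_change(self._frame([600, 610, 620])) == pytest.approx(10.0)

    def test_constant(self):
        assert bm.daily_pitch_change(self._frame([600, 600, 600])) == 0.0

    def test_sparse_days_excluded(self):
        df = self._frame([600, 610, 620])
        df = pd.concat([df, pd.DataFrame([{"bird_id": 0, "day": 3, "pitch_hz": 900.0}])])
        # day 3 has a single rendition -> excluded, estimate unchanged
        assert bm.daily_pitch_change(df) == pytest.approx(10.0)

    def test_too_few_days_missing(self):
        assert np.isnan(bm.daily_pitch_change(self._frame([600])))
        assert np.isnan(bm.daily_pitch_change(pd.DataFrame(columns=["day", "pitch_hz"])))

    def test_drift_recovery_monte_carlo(self):
        """A configured +8 Hz/day drift is recovered to within 1.5 Hz/day."""
        estimates = []
        for seed in range(20):
            day_means = [600 + 8 * d for d in range(5)]
            df = self._frame(day_means, n=400, sd=25.0, seed=seed)
            estimates.append(bm.daily_pitch_change(df))
        assert np.mean(estimates) == pytest.approx(8.0, abs=1.5)


class TestOneSampleT:
    def test_all_at_null(self):
        res = bm.one_sample_t([0.5, 0.5, 0.5])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_matches_hand_formula(self):
        x = np.array([0.8, 0.9, 0.85, 0.95])
        expected_t = (x.mean() - 0.5) / (x.std(ddof=1) / np.sqrt(4))
        res = bm.one_sample_t(x)
        assert res.t == pytest.approx(expected_t)
        assert 0 < res.p < 0.01

    def test_degenerate_off_null(self):
        res = bm.one_sample_t([0.8, 0.8, 0.8])
        assert np.isinf(res.t) and res.p == 0.0 and res.degenerate

    def test_type_one_error_rate(self):
        """Under the null, p < 0.05 about 5% of the time (10,000 replicates)."""
        rng = np.random.default_rng(0)
        x = rng.normal(0.5, 0.1, size=(10_000, 10))
        from scipy import stats

        _, p = stats.ttest_1samp(x, popmean=0.5, axis=1)
        rate = np.mean(p < 0.05)
        assert abs(rate - 0.05) < 0.01


class TestTwoWayAnova:
    @staticmethod
    def _balanced_table(cell_means, n=5, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for (cond, state), mu in cell_means.items():
            for v in (rng.normal(mu, sd, n) if sd else [mu] * n):
                rows.append({"occupancy": float(v), "condition": cond,
                             "singing_state": state})
        return pd.DataFrame(rows)

    def test_identical_cells_give_zero_f(self):
        # same within-cell values in every cell: cell means identical,
        # within-cell variance nonzero -> every F exactly 0
        rows = [
            {"occupancy": v, "condition": c, "singing_state": s}
            for c in ("a", "b")
            for s in ("sing", "non")
            for v in (0.6, 0.7, 0.8)
        ]
        res = bm.two_way_anova(pd.DataFrame(rows))
        assert res.f_condition == pytest.approx(0.0, abs=1e-10)
        assert res.f_state == pytest.approx(0.0, abs=1e-10)
        assert res.f_interaction == pytest.approx(0.0, abs=1e-10)

    def test_matches_closed_form_sums_of_squares(self):
        """Balanced 2x2: F statistics agree with the textbook SS decomposition."""
        cells = {("a", "s"): 0.8, ("a", "n"): 0.75, ("b", "s"): 0.35, ("b", "n"): 0.42}
        n = 6
        table = self._balanced_table(cells, n=n, sd=0.05, seed=2)
        res = bm.two_way_anova(table)

        y = table["occupancy"].to_numpy()
        grand = y.mean()
        mean_a = table.groupby("condition")["occupancy"].mean()
        mean_b = table.groupby("singing_state")["occupancy"].mean()
        mean_ab = table.groupby(["condition", "singing_state"])["occupancy"].mean()
        ss_a = 2 * n * ((mean_a - grand) ** 2).sum()
        ss_b = 2 * n * ((mean_b - grand) ** 2).sum()
        ss_cells = n * ((mean_ab - grand) ** 2).sum()
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum(
            ((table[(table.condition == c) & (table.singing_state == s)]["occupancy"]
              - mean_ab[(c, s)]) ** 2).sum()
            for c, s in cells
        )
        df_err = 4 * n - 4
        assert res.f_condition == pytest.approx(ss_a / 1 / (ss_err / df_err), rel=1e-6)
        assert res.f_state == pytest.approx(ss_b / 1 / (ss_err / df_err), rel=1e-6)
        assert res.f_interaction == pytest.approx(ss_ab / 1 / (ss_err / df_err), rel=1e-6)
        assert res.df_num == 1 and res.df_den == df_err

    def test_label_shuffle_preserves_total_ss(self):
        table = self._balanced_table(
            {("a", "s"): 0.8, ("a", "n"): 0.7, ("b", "s"): 0.4, ("b", "n"): 0.5},
            n=6, sd=0.05, seed=3,
        )
        rng = np.random.default_rng(4)
        shuffled = table.copy()
        shuffled["condition"] = rng.permutation(shuffled["condition"].to_numpy())
        total = ((table["occupancy"] - table["occupancy"].mean()) ** 2).sum()
        total_shuffled = ((shuffled["occupancy"] - shuffled["occupancy"].mean()) ** 2).sum()
        assert total == pytest.approx(total_shuffled)
        bm.two_way_anova(shuffled)  # still well-posed

    def test_empty_cell_named_in_error(self):
        table = self._balanced_table(
            {("a", "s"): 0.8, ("a", "n"): 0.7, ("b", "s"): 0.4, ("b", "n"): 0.5}, n=3
        )
        table = table[~((table.condition == "b") & (table.singing_state == "n"))]
        with pytest.raises(ValueError, match="condition='b'"):
            bm.two_way_anova(table)


class TestMetricsTable:
    def test_probability_bounds_and_missing_propagation(self):
        ev = _events(
            [(0, 0, 1, 10.0, 40.0), (0, 0, 2, 50.0, 60.0), (0, 1, 1, 10.0, 20.0)]
        )
        metrics = bm.compute_metrics(ev, SCHED)
        for col in ("perch1_landing_rate", "perch1_occupancy"):
            valid = metrics[col].dropna()
            assert ((valid >= 0) & (valid <= 1)).all()
        # no renditions supplied -> pitch columns missing, not zero
        assert metrics["mean_pitch_hz"].isna().all()
        assert metrics["delta_pitch_hz_per_day"].isna().all()
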