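"""Death calling, rates, histograms and the ancillary population statistics."""

import numpy as np
import pandas as pd
import pytest

from necroptodyn import kinetics as kn


def _trace(n_frames=200, spikes=(), level=1000.0, base=0.0):
    tr = np.full(n_frames, base)
    for a, b in spikes:
        tr[a:b] = level
    return tr


class TestCallDeaths:
    def test_six_frame_run_calls_first_frame(self):
        """A run of exactly six above-threshold frames is a death at its first frame."""
        tr = _trace(spikes=[(100, 106), (110, 200)])
        matrix, table = kn.call_deaths(tr, threshold=500.0)
        assert table.data["death_frame"].iloc[0] == 100
        assert matrix.values[0, 99] == 0 and matrix.values[0, 100] == 1
        assert matrix.values[0, 150] == 1  # latched

    def test_five_frame_run_censored(self):
        tr = _trace(spikes=[(100, 105)])
        _, table = kn.call_deaths(tr, threshold=500.0)
        assert bool(table.data["censored"].iloc[0])

    def test_constant_zero_censored(self):
        matrix, table = kn.call_deaths(_trace(), threshold=500.0)
        assert bool(table.data["censored"].iloc[0])
        assert not matrix.values.any()

    def test_latched_despite_later_dips(self):
        """Once called, later sub-threshold values do not resurrect the cell."""
        tr = _trace(spikes=[(50, 60)])  # above for 10, then back to base
        matrix, table = kn.call_deaths(tr, threshold=500.0)
        assert table.data["death_frame"].iloc[0] == 50
        assert matrix.values[0, -1] == 1

    def test_strictly_greater_than_threshold(self):
        tr = np.full(50, 500.0)
        _, table = kn.call_deaths(tr, threshold=500.0)
        assert bool(table.data["censored"].iloc[0])

    def test_nan_trace_raises_with_cell_name(self):
        traces = np.zeros((2, 50))
        traces[1, 10] = np.nan
        with pytest.raises(ValueError, match="1"):
            kn.call_deaths(traces, threshold=1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            kn.call_deaths(np.empty((0, 0)), threshold=1.0)

    def test_long_format_input(self):
        df = pd.DataFrame(
            {
                "cell_id": np.repeat([7, 9], 50),
                "frame": np.tile(np.arange(50), 2),
                "value": np.concatenate([_trace(50, [(10, 50)]), _trace(50)]),
            }
        )
        _, table = kn.call_deaths(df, threshold=500.0)
        row7 = table.data.set_index("cell_id").loc[7]
        assert row7["death_frame"] == 10
        assert bool(table.data.set_index("cell_id").loc[9, "censored"])


class TestDeathRate:
    def test_hand_computed_window(self):
        """50 alive, 10 deaths in the 5-h window: 0.20/window = 0.04/h."""
        n_frames = 2 * 200 + 1  # 10 h at 1.5 min... use explicit construction
        frames_per_hour = 40
        n_frames = 10 * frames_per_hour + 1
        m = np.zeros((50, n_frames), dtype=np.int8)
        # 10 cells die spread through (0, 5 h]
        for i in range(10):
            m[i, (i + 1) * 18 :] = 1
        mat = kn.AliveDeadMatrix(m, frame_interval_min=1.5)
        rs = kn.death_rate(mat, window_hours=5.0)
        assert rs.rate_per_hour[0] == pytest.approx(10 / 50 / 5.0)

    def test_no_deaths_zero_series(self):
        mat = kn.AliveDeadMatrix(np.zeros((20, 400), np.int8), frame_interval_min=1.5)
        rs = kn.death_rate(mat, window_hours=5.0)
        assert np.all(rs.rate_per_hour == 0.0)

    def test_stop_rule_toy_matrix(self):
        """All 10 cells die in the first window: the series stops at the
        frame where the alive population drops below 1/3 of start."""
        m = np.zeros((10, 400), np.int8)
        for i in range(10):
            m[i, 10 + i :] = 1  # deaths at frames 10..19
        mat = kn.AliveDeadMatrix(m, frame_interval_min=1.5)
        rs = kn.death_rate(mat, window_hours=5.0)
        # alive counts: 10 until f=9, then 9,8,...; below 10/3 at frame 17
        alive = 10 - m.sum(axis=0)
        expected_stop = int(np.flatnonzero(alive < 10 / 3)[0])
        assert rs.stop_index == expected_stop
        assert rs.times_hours.size == expected_stop

    def test_rates_bounded(self):
        rng = np.random.default_rng(0)
        deaths = rng.integers(0, 400, size=30)
        m = np.zeros((30, 400), np.int8)
        for i, d in enumerate(deaths):
            m[i, d:] = 1
        mat = kn.AliveDeadMatrix(m, frame_interval_min=1.5)
        rs = kn.death_rate(mat, window_hours=5.0)
        assert np.all(rs.rate_per_hour >= 0)
        assert np.all(rs.window_fraction() <= 1.0 + 1e-12)

    def test_row_monotonicity_enforced(self):
        bad = np.array([[0, 1, 0, 1]], dtype=np.int8)
        with pytest.raises(ValueError):
            kn.AliveDeadMatrix(bad)


class TestHistogram:
    def test_two_deaths_first_bin(self):
        table = kn.DeathTimeTable.from_arrays([1.0, 2.0])
        h = kn.death_time_histogram(table)
        assert h.density[0] == pytest.approx(0.5)
        assert np.all(h.density[1:] == 0)

    def test_uniform_one_per_bin(self):
        times = np.arange(1.5, 24.5, 2.0)  # one death per 2-h bin
        h = kn.death_time_histogram(kn.DeathTimeTable.from_arrays(times))
        assert h.counts.sum() == 12
        assert np.allclose(h.density, 1.0 / 24.0)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(1)
        times = rng.uniform(0.5, 24.5, 137)
        h = kn.death_time_histogram(kn.DeathTimeTable.from_arrays(times))
        assert np.sum(h.density * np.diff(h.bin_edges)) == pytest.approx(1.0)

    def test_zero_deaths_flagged(self):
        table = kn.DeathTimeTable.from_arrays([np.nan, np.nan])
        with pytest.warns(UserWarning):
            h = kn.death_time_histogram(table)
        assert h.empty

    def test_out_of_range_counted(self):
        table = kn.DeathTimeTable.from_arrays([0.1, 25.0, 5.0])
        h = kn.death_time_histogram(table)
        assert h.n_out_of_range == 2
        assert h.n_deaths == 1


class TestCompareUnimodality:
    def test_identical_groups_t_zero(self):
        t, _ = kn.compare_unimodality([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert t == pytest.approx(0.0)

    def test_separated_groups_closed_form(self):
        a, b = [0.9, 0.8, 0.85], [0.01, 0.02, 0.03]
        t, p = kn.compare_unimodality(a, b)
        # closed-form pooled-variance two-sample t
        na, nb = 3, 3
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_exp = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_exp)
        assert p < 0.01

    def test_antisymmetry(self):
        t1, p1 = kn.compare_unimodality([0.9, 0.8], [0.1, 0.2])
        t2, p2 = kn.compare_unimodality([0.1, 0.2], [0.9, 0.8])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            kn.compare_unimodality([0.5], [0.4, 0.3])


class TestAncillary:
    def test_proliferative_index_arithmetic(self):
        m = np.zeros((40, 400), np.int8)
        mat = kn.AliveDeadMatrix(m, frame_interval_min=1.5)
        df = kn.proliferative_index([1.0, 2.0], mat, window_hours=4.0)
        assert df["index"].iloc[0] == pytest.approx(2 / 40)
        assert np.all(df["index"].iloc[1:] == 0)

    def test_proliferative_index_zero_alive_flagged(self):
        m = np.ones((5, 400), np.int8)
        m[:, 0] = 0
        mat = kn.AliveDeadMatrix(m, frame_interval_min=1.5)
        df = kn.proliferative_index([5.0], mat, window_hours=4.0)
        assert np.isnan(df["index"].iloc[1])

    def test_fractional_survival(self):
        m = np.zeros((10, 100), np.int8)
        m[:5, 50:] = 1
        mat = kn.AliveDeadMatrix(m, frame_interval_min=1.5)
        assert kn.fractional_survival_from_matrix(mat, 0.0) == 1.0
        assert kn.fractional_survival_from_matrix(mat, 2.0) == 0.5
        # non-increasing in t
        ts = np.linspace(0, 99 * 1.5 / 60, 20)
        surv = [kn.fractional_survival_from_matrix(mat, t) for t in ts]
        assert np.all(np.diff(surv) <= 0)

    def test_phase_rate_ratio_arithmetic(self):
        rs = kn.RateSeries(
            times_hours=np.array([6.0, 10.0, 14.0, 18.0]),
            rate_per_hour=np.array([0.02, 0.02, 0.04, 0.04]),
            window_hours=5.0,
        )
        pr = kn.phase_rate_ratio(rs, split_hours=12.0)
        assert pr.early_mean == pytest.approx(0.02)
        assert pr.late_mean == pytest.approx(0.04)
        assert pr.ratio == pytest.approx(2.0)

    def test_constant_rate_ratio_one(self):
        rs = kn.RateSeries(np.linspace(1, 20, 50), np.full(50, 0.03), 5.0)
        assert kn.phase_rate_ratio(rs).ratio == pytest.approx(1.0)

    def test_phase_requires_both_sides(self):
        rs = kn.RateSeries(np.array([1.0, 2.0]), np.array([0.1, 0.1]), 5.0)
        with pytest.raises(ValueError):
            kn.phase_rate_ratio(rs)
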