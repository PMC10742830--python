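import numpy as np
import pandas as pd
import pytest

import criticality as ca
from criticality.features import (grouping_report, median_frequency,
                                  represent, totals, window_features)
from criticality.ode_engine import ClampSchedule, Trajectory


def _traj(n_osc, series):
    """Trajectory with identical per-oscillator m/f series for testing."""
    n = len(series)
    states = np.zeros((n, n_osc * 4))
    labels = []
    for i in range(n_osc):
        states[:, 4 * i] = series      # m
        states[:, 4 * i + 1] = series  # f
        labels += [f"osc{i}:{v}" for v in ("m", "f", "p", "g")]
    return Trajectory(times=np.arange(n, dtype=float), states=states,
                      sample_boundaries=[(0, n)], channel_labels=labels)


class TestTotals:
    def test_single_oscillator_identity(self):
        series = np.sin(np.linspace(0, 10, 100))
        traj = _traj(1, series)
        assert np.array_equal(totals(traj, "m"), series)

    def test_two_identical_oscillators_double(self):
        series = np.linspace(0, 1, 50)
        traj = _traj(2, series)
        assert np.allclose(totals(traj, "m"), 2 * series)

    def test_subset_selection(self):
        series = np.ones(10)
        traj = _traj(8, series)
        assert np.all(totals(traj, "f", oscillators=range(6)) == 6.0)

    def test_unknown_variable(self):
        with pytest.raises(KeyError):
            totals(_traj(1, np.ones(4)), "q")


class TestWindowFeatures:
    def test_sine_maximum(self):
        sched = ClampSchedule(steps_per_sample=10_000, step_size=0.1,
                              transient_fraction=0.0)
        t = np.arange(1000) * 1.0
        sig = 2.0 + np.sin(0.37 * t)
        pt = window_features(sig, sig, sched, dt=1.0)
        assert pt.max_M == pytest.approx(3.0, abs=1e-2)
        assert not pt.converged

    def test_constant_series_converged(self):
        sched = ClampSchedule(steps_per_sample=1000, step_size=0.1)
        pt = window_features(np.full(100, 4.2), np.full(100, 4.2), sched, dt=1.0)
        assert pt.max_M == 4.2
        assert pt.converged
        assert np.isnan(pt.median_freq_F)

    def test_transient_excluded_from_maximum(self):
        # a huge ramp confined to the first half must not leak into the max
        sched = ClampSchedule(steps_per_sample=1000, step_size=0.1,
                              transient_fraction=0.5)
        ramp = np.concatenate([np.linspace(50, 0, 500),
                               2 + np.sin(0.2 * np.arange(500))])
        pt = window_features(ramp, ramp, sched, dt=1.0)
        assert pt.max_M == pytest.approx(3.0, abs=0.05)

    def test_too_short_window_rejected(self):
        sched = ClampSchedule(steps_per_sample=1000, transient_fraction=0.5)
        with pytest.raises(ValueError):
            window_features(np.ones(2), np.ones(2), sched, dt=1.0)


class TestMedianFrequency:
    def test_pure_sine_within_one_bin(self):
        dt, f0, n = 0.5, 0.11, 4096
        sig = np.sin(2 * np.pi * f0 * dt * np.arange(n))
        got = median_frequency(sig, dt)
        assert abs(got - f0) <= 1.0 / (n * dt)

    def test_two_tone_bracketed(self):
        dt, n = 1.0, 8192
        t = np.arange(n) * dt
        sig = np.sin(2 * np.pi * 0.05 * t) + np.sin(2 * np.pi * 0.21 * t)
        got = median_frequency(sig, dt)
        assert 0.05 <= got <= 0.21

    def test_matches_brute_force_cumulative_spectrum(self):
        """Cross-check against a from-scratch FFT periodogram."""
        rng = np.random.default_rng(5)
        sig = rng.standard_normal(2048)
        dt = 0.25
        got = median_frequency(sig, dt)

        x = sig - sig.mean()
        spec = np.abs(np.fft.rfft(x)) ** 2
        spec[1:-1] *= 2.0  # one-sided doubling (N even: Nyquist not doubled)
        freqs = np.fft.rfftfreq(len(x), d=dt)
        csum = np.cumsum(spec)
        expected = freqs[np.searchsorted(csum, 0.5 * csum[-1])]
        assert got == pytest.approx(expected, abs=1e-9)

    def test_constant_signal_flagged_not_raised(self):
        assert np.isnan(median_frequency(np.full(256, 3.3), 0.1))

    def test_peak_interval_estimator(self):
        dt, f0 = 0.1, 0.5
        t = np.arange(2000) * dt
        sig = np.sin(2 * np.pi * f0 * t)
        got = median_frequency(sig, dt, method="peak_intervals")
        assert got == pytest.approx(f0, rel=0.05)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            median_frequency(np.ones(100), 0.1, method="wavelet")


class TestRepresent:
    def test_empty_dataset(self, spec4, short_schedule):
        ds = ca.Dataset(values=np.empty((0, 4)), labels=None)
        res = represent(ds, spec4, short_schedule, [0.01] * 4)
        assert len(res.table) == 0
        assert res.metadata["model"] == "berry"

    def test_rerun_is_bit_identical(self, blob_dataset, spec4, short_schedule):
        kw = dict(shuffle_seed=3)
        a = represent(blob_dataset, spec4, short_schedule, [0.0075] * 4, **kw)
        b = represent(blob_dataset, spec4, short_schedule, [0.0075] * 4, **kw)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_duplicated_rows_identical_under_reset(self, short_schedule):
        """With per-sample reset the representation is a pure function of
        the row, so duplicated rows land on identical points."""
        X = np.tile([5.0, 4.0, 6.0, 5.5], (4, 1))
        ds = ca.Dataset(values=X, labels=np.arange(4))
        spec = ca.NetworkSpec(model="berry", n_oscillators=4, weights=0.0005,
                              input_map=(0, 1, 2, 3), reset_per_sample=True)
        res = represent(ds, spec, short_schedule, [0.0075] * 4)
        t = res.table
        assert t.max_F.nunique() == 1 and t.max_M.nunique() == 1

    def test_table_row_per_sample_with_ids_and_labels(self, blob_dataset,
                                                      spec4, short_schedule):
        res = represent(blob_dataset, spec4, short_schedule, [0.0075] * 4,
                        shuffle_seed=9)
        t = res.table
        assert len(t) == blob_dataset.n_samples
        assert sorted(t.sample_id) == list(range(blob_dataset.n_samples))
        assert list(t.sample_id) == res.metadata["presentation_order"]
        merged = t.set_index("sample_id").label
        assert np.array_equal(merged.sort_index().to_numpy(),
                              blob_dataset.labels)

    def test_wu_table_has_steady_state_columns(self, short_schedule):
        ds = ca.Dataset(values=np.array([[1.0, 2.0]]), labels=None)
        spec = ca.NetworkSpec(model="wu", n_oscillators=2, weights=0.0001,
                              input_map=(0, 1))
        sched = ca.ClampSchedule(steps_per_sample=1000, step_size=0.001)
        res = represent(ds, spec, sched, [0.001] * 2)
        for col in ("max_Y", "max_Z", "max_W", "converged"):
            assert col in res.table.columns


class TestGroupingReport:
    def test_identical_groups_at_chance(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((40, 2))
        df = pd.DataFrame(np.vstack([pts, pts]), columns=["max_F", "max_M"])
        labels = np.repeat([0, 1], 40)
        rep = grouping_report(df, labels, ["max_F", "max_M"], seed=0)
        assert rep["separability_ratio"] < 0.2
        assert rep["knn_accuracy"] < 0.75

    def test_displaced_groups_separate(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((30, 2))
        b = rng.standard_normal((30, 2)) + 12.0
        df = pd.DataFrame(np.vstack([a, b]), columns=["max_F", "max_M"])
        rep = grouping_report(df, np.repeat([0, 1], 30), ["max_F", "max_M"],
                              seed=0)
        assert rep["knn_accuracy"] >= 0.95
        assert rep["separability_ratio"] > 2.0

    def test_invariant_under_common_rescaling(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.standard_normal((25, 2)),
                       rng.standard_normal((25, 2)) + 4.0])
        y = np.repeat([0, 1], 25)
        df1 = pd.DataFrame(X, columns=["max_F", "max_M"])
        df2 = pd.DataFrame(X * 1e4, columns=["max_F", "max_M"])
        r1 = grouping_report(df1, y, ["max_F", "max_M"], seed=0)
        r2 = grouping_report(df2, y, ["max_F", "max_M"], seed=0)
        assert r1["knn_accuracy"] == r2["knn_accuracy"]
        assert r1["separability_ratio"] == pytest.approx(
            r2["separability_ratio"], rel=1e-9)

    def test_degenerate_groups_rejected(self):
        df = pd.DataFrame({"max_F": [1.0, 2.0], "max_M": [1.0, 2.0]})
        with pytest.raises(ValueError):
            grouping_report(df, [0, 1], ["max_F", "max_M"])
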