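"""Epoch extraction, baseline z-scoring, binning and the random null."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from fiberphot import (
    EventSeries,
    RandomSamplingSpec,
    bin_epoch_means,
    extract_epochs,
    heatmap_matrix,
    per_animal_average,
    random_timestamps,
    zscore_epochs,
)
from fiberphot.alignment import EpochMatrix
from fiberphot.preprocess import IsosbesticFit, ProcessedTrace


def _proc(dff, rate=240.0):
    n = len(dff)
    return ProcessedTrace(
        time_s=np.arange(n) / rate, dff=np.asarray(dff, float),
        fit=IsosbesticFit(1.0, 0.0, np.zeros(n), 0.0),
        filter_cutoff_hz=3.0, rate_hz=rate,
    )


def _events(onsets, label="social_novel"):
    onsets = np.asarray(onsets, float)
    return EventSeries(onsets, np.full(onsets.shape, label, dtype=object))


def _epoch_matrix(rows, rate=4.0, pre_s=1.0):
    rows = np.atleast_2d(np.asarray(rows, float))
    n = rows.shape[1]
    time_rel = (np.arange(n) - int(pre_s * rate)) / rate
    return EpochMatrix(
        values=rows, time_rel_s=time_rel,
        onsets=np.arange(rows.shape[0], dtype=float) * 10 + 30,
        labels=np.full(rows.shape[0], "social_novel", dtype=object),
    )


class TestExtractEpochs:
    def test_epoch_length_is_window_times_rate(self):
        proc = _proc(np.zeros(240 * 20))
        ep = extract_epochs(proc, _events([10.0]))
        assert ep.values.shape == (1, 960)
        assert ep.time_rel_s[0] == pytest.approx(-1.0)
        assert ep.time_rel_s[-1] == pytest.approx(3.0 - 1 / 240)

    def test_boundary_event_dropped_and_logged(self):
        proc = _proc(np.zeros(240 * 20))
        ep = extract_epochs(proc, _events([0.5, 10.0]))
        assert ep.n_events == 1
        assert len(ep.dropped) == 1
        assert ep.dropped[0][0] == 0.5

    def test_all_events_dropped_is_error(self):
        proc = _proc(np.zeros(240 * 5))
        with pytest.raises(ValueError, match="no events retained"):
            extract_epochs(proc, _events([0.1]))

    def test_constant_trace_gives_constant_rows(self):
        proc = _proc(np.full(240 * 20, 3.25))
        ep = extract_epochs(proc, _events([5.0, 10.0]))
        np.testing.assert_array_equal(ep.values, 3.25)


class TestZScore:
    def test_baseline_mean_zero_sd_one(self, processed_session):
        proc, events, _ = processed_session
        ep = extract_epochs(proc, events)
        z = zscore_epochs(ep, session_dff=proc.dff)
        mask = (z.time_rel_s >= -1) & (z.time_rel_s < 0)
        base = z.values[:, mask]
        assert np.abs(base.mean(axis=1)).max() < 1e-9
        assert np.abs(base.std(axis=1, ddof=1) - 1).max() < 1e-9

    def test_hand_computed_z_with_sample_sd(self):
        # baseline [-1, 1, -1, 1]: mean 0, sample SD sqrt(4/3);
        # a post-onset value of 2*sqrt(4/3) must map to z = 2
        sd = np.sqrt(4 / 3)
        row = [-1.0, 1.0, -1.0, 1.0] + [2 * sd] * 12
        z = zscore_epochs(_epoch_matrix(row))
        assert z.values[0, 4] == pytest.approx(2.0, abs=1e-12)
        assert z.baseline_sd[0] == pytest.approx(sd, abs=1e-12)

    def test_shift_invariance(self):
        row = np.sin(np.arange(16))
        z1 = zscore_epochs(_epoch_matrix(row))
        z2 = zscore_epochs(_epoch_matrix(row + 17.3))
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-9)

    def test_flat_baseline_falls_back_and_flags(self):
        row = np.concatenate([np.ones(4), np.arange(12.0)])
        session = np.sin(np.arange(1000) / 7)
        z = zscore_epochs(_epoch_matrix(row), session_dff=session)
        assert list(z.fallback_rows) == [0]
        assert z.baseline_sd[0] == pytest.approx(np.std(session, ddof=1))

    def test_flat_everything_is_error(self):
        row = np.ones(16)
        with pytest.raises(ValueError, match="degenerate"):
            zscore_epochs(_epoch_matrix(row), session_dff=np.ones(100))


class TestBinMeans:
    def test_constant_z_gives_constant_bins(self):
        z = zscore_epochs(_epoch_matrix(
            [-1, 1, -1, 1] + [1.0] * 12))
        # overwrite values directly to test the binning in isolation
        z = replace(z, values=np.ones_like(z.values))
        tab = bin_epoch_means(z)
        bins = [c for c in tab.columns if c.startswith("[")]
        np.testing.assert_allclose(tab[bins].to_numpy(), 1.0)

    def test_ramp_bin_means_match_integrals(self):
        # z(t) = t sampled densely: bin means -> midpoints {-.5,.5,1.5,2.5}
        rate = 240.0
        t = (np.arange(960) - 240) / rate
        em = _epoch_matrix(t[None, :], rate=rate)
        z = zscore_epochs(em, session_dff=np.sin(np.arange(1000.0)))
        z = replace(z, values=t[None, :].copy())
        tab = bin_epoch_means(z)
        bins = [c for c in tab.columns if c.startswith("[")]
        got = tab[bins].to_numpy()[0]
        # half-open bins at finite sampling: mean of t over [a, b) is
        # (a + b)/2 - 1/(2*rate)
        expected = np.array([-0.5, 0.5, 1.5, 2.5]) - 1 / (2 * rate)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_single_event_table_shape(self):
        z = zscore_epochs(_epoch_matrix(np.sin(np.arange(16))))
        tab = bin_epoch_means(z)
        assert len(tab) == 1
        assert sum(c.startswith("[") for c in tab.columns) == 4

    def test_empty_bin_rejected(self):
        z = zscore_epochs(_epoch_matrix(np.sin(np.arange(16))))
        with pytest.raises(ValueError, match="empty bin"):
            bin_epoch_means(z, edges=(-0.9, -0.85, 0.0, 1.0))


class TestPerAnimalAverage:
    def _table(self, animal, values):
        return pd.DataFrame({
            "animal_id": animal,
            "onset_s": np.arange(len(values), dtype=float),
            "label": "social_novel",
            "[0,1)": values,
        })

    def test_unweighted_mean_of_events(self):
        out = per_animal_average([self._table("a", [1.0, 3.0])])
        assert out.loc[0, "[0,1)"] == pytest.approx(2.0)
        assert out.loc[0, "n_events"] == 2

    def test_identical_animals_identical_rows(self):
        out = per_animal_average([self._table("a", [1.0, 2.0]),
                                  self._table("b", [1.0, 2.0])])
        assert out.loc[0, "[0,1)"] == out.loc[1, "[0,1)"]

    def test_event_order_invariance(self):
        a = per_animal_average([self._table("a", [1.0, 5.0, 3.0])])
        b = per_animal_average([self._table("a", [3.0, 1.0, 5.0])])
        pd.testing.assert_frame_equal(a, b)


class TestRandomTimestamps:
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_counts_and_windows(self, seed):
        ev = random_timestamps(300.0, seed=seed)
        assert len(ev) == 20
        in1 = (ev.onsets >= 5.0) & (ev.onsets <= 149.99)
        in2 = (ev.onsets >= 150.0) & (ev.onsets <= 294.99)
        assert in1.sum() == 10
        assert in2.sum() == 10
        assert set(ev.labels) == {"random"}

    def test_deterministic(self):
        a = random_timestamps(300.0, seed=3)
        b = random_timestamps(300.0, seed=3)
        np.testing.assert_array_equal(a.onsets, b.onsets)

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            random_timestamps(200.0, seed=0)


class TestHeatmap:
    def test_event_order_unchanged(self):
        z = zscore_epochs(_epoch_matrix(np.random.default_rng(0).normal(
            size=(5, 16))))
        mat, t, idx = heatmap_matrix(z, order="event_order")
        np.testing.assert_array_equal(mat, z.values)
        np.testing.assert_array_equal(idx, np.arange(5))

    def test_peak_order_sorts_by_peak_time(self):
        rows = np.zeros((3, 16))
        rows[0, 10] = 5.0  # late peak
        rows[1, 5] = 5.0   # early
        rows[2, 8] = 5.0   # middle
        rows[:, :4] = np.random.default_rng(1).normal(0, 0.1, (3, 4))
        z = zscore_epochs(_epoch_matrix(rows))
        _, _, idx = heatmap_matrix(z, order="peak")
        assert list(idx) == [1, 2, 0]

    def test_values_bit_identical(self):
        z = zscore_epochs(_epoch_matrix(np.random.default_rng(2).normal(
            size=(4, 16))))
        mat, _, idx = heatmap_matrix(z, order="peak")
        np.testing.assert_array_equal(mat, z.values[idx])
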