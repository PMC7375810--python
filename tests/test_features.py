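"""Spike detection, background statistics and the DC-shift test."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynamotype.features import (
    Recording,
    background_stats,
    detect_dc_shift,
    detect_spikes,
    extract_boundary_windows,
)
from dynamotype.surrogate import SurrogateSeizureSpec, gen_spike_train, render_waveform


def _surrogate_recording(seed=0, **spec_kw):
    sp = SurrogateSeizureSpec(seed=seed, **spec_kw)
    tr = gen_spike_train(sp)
    w = render_waveform(tr, seed=seed + 1)
    return tr, w, Recording(w.dc, w.fs, w.onset, w.offset, coupling="DC")


class TestRecording:
    def test_mark_validation(self):
        with pytest.raises(ValueError):
            Recording(np.zeros(100), fs=10.0, onset=8.0, offset=4.0)
        with pytest.raises(ValueError):
            Recording(np.zeros(100), fs=10.0, onset=2.0, offset=60.0)
        with pytest.raises(ValueError):
            Recording(np.zeros(100), fs=10.0, onset=1.0, offset=5.0, coupling="XY")


class TestBackgroundStats:
    def test_gaussian_sd_recovered(self, rng):
        x = rng.standard_normal(30 * 256)
        rec = Recording(x, 256.0, onset=20.0, offset=28.0)
        st_ = background_stats(rec, window=10.0)
        assert abs(st_.sd - 1.0) < 0.05
        assert abs(st_.mean) < 0.05

    def test_constant_signal_has_zero_sd(self):
        rec = Recording(np.full(20 * 100, 3.0), 100.0, onset=15.0, offset=19.0)
        st_ = background_stats(rec)
        assert st_.sd == 0.0 and st_.mean == 3.0

    def test_insufficient_preictal_data_is_an_error(self):
        rec = Recording(np.zeros(2000), 100.0, onset=3.0, offset=15.0)
        with pytest.raises(ValueError):
            background_stats(rec)


class TestDetectSpikes:
    def test_surrogate_round_trip(self):
        tr, w, rec = _surrogate_recording(seed=4, onset="SN", offset="FLC")
        st_ = background_stats(rec)
        ss = detect_spikes(rec, st_)
        assert len(ss) == len(tr.times)
        err = np.abs(ss.times - (tr.times + w.onset))
        assert err.max() < 0.025  # within the kernel half-width
        rel = np.abs(ss.amplitudes - tr.amplitudes) / tr.amplitudes
        assert np.median(rel) < 0.05

    def test_small_spikes_below_threshold_are_ignored(self):
        tr, w, rec = _surrogate_recording(seed=6, onset="SN", offset="FLC",
                                          amplitude=2.0)
        st_ = background_stats(rec)
        ss = detect_spikes(rec, st_, threshold_sd=3.0)
        assert len(ss) == 0

    def test_wide_transients_are_rejected(self, rng):
        fs = 256.0
        x = rng.standard_normal(int(40 * fs)) * 0.5
        t = np.arange(len(x)) / fs
        # a 400 ms wide bump well above threshold: not a spike
        x += 8.0 * np.exp(-((t - 25.0) ** 2) / (2 * 0.17**2))
        rec = Recording(x, fs, onset=20.0, offset=35.0)
        ss = detect_spikes(rec, background_stats(rec))
        assert not any(abs(tt - 25.0) < 0.5 for tt in ss.times)

    def test_scale_and_translation_equivariance(self):
        tr, w, rec = _surrogate_recording(seed=8, onset="SN", offset="FLC")
        ss = detect_spikes(rec, background_stats(rec))
        scaled = Recording(rec.samples * 5.0 + 11.0, rec.fs, rec.onset,
                           rec.offset, coupling="DC")
        ss2 = detect_spikes(scaled, background_stats(scaled))
        assert np.array_equal(ss.times, ss2.times)
        assert np.allclose(ss2.amplitudes, 5.0 * ss.amplitudes, rtol=1e-9)


class TestDetectDCShift:
    def _step_recording(self, magnitude, rise, persist, sd=1.0, seed=0):
        fs = 512.0
        rng = np.random.default_rng(seed)
        n = int(40 * fs)
        x = rng.standard_normal(n) * sd
        t = np.arange(n) / fs
        t0 = 20.0
        step = magnitude * sd / (1.0 + np.exp(-(t - t0) / (rise / 8.0)))
        fall = np.clip((t - (t0 + persist)) / 0.5, 0, 1)
        x += step * (1.0 - fall)
        return Recording(x, fs, onset=20.0, offset=30.0, coupling="DC")

    def test_printed_thresholds_exactly(self):
        # 6 SD, 0.3 s rise, 2 s persistence -> present
        rec = self._step_recording(6.0, 0.3, 2.0)
        r = detect_dc_shift(rec, "onset", background_stats(rec))
        assert r.present and r.polarity == 1
        assert r.rise < 0.5 and r.magnitude > 5.0 and r.persistence >= 1.0
        # 3 SD -> absent (magnitude rule)
        rec = self._step_recording(3.0, 0.3, 2.0)
        assert not detect_dc_shift(rec, "onset", background_stats(rec)).present
        # 6 SD lasting only 0.4 s -> absent (persistence rule)
        rec = self._step_recording(6.0, 0.3, 0.4)
        assert not detect_dc_shift(rec, "onset", background_stats(rec)).present

    def test_slow_drift_is_not_a_shift(self):
        # same magnitude but rising over 2 s: fails the sharpness rule
        rec = self._step_recording(6.0, 2.0, 3.0)
        assert not detect_dc_shift(rec, "onset", background_stats(rec)).present

    def test_ac_coupled_data_is_not_assessable(self):
        rec = self._step_recording(6.0, 0.3, 2.0)
        ac = Recording(rec.samples, rec.fs, rec.onset, rec.offset, coupling="AC")
        r = detect_dc_shift(ac, "onset", background_stats(ac))
        assert not r.assessable and not r.present

    def test_negative_polarity(self):
        rec = self._step_recording(-7.0, 0.3, 2.0)
        r = detect_dc_shift(rec, "onset", background_stats(rec))
        assert r.present and r.polarity == -1


class TestBoundaryWindows:
    def _series(self, n):
        tr, w, rec = _surrogate_recording(seed=3, onset="SN", offset="FLC")
        ss = detect_spikes(rec, background_stats(rec))
        return ss

    def test_disjoint_windows(self):
        ss = self._series(40)
        on, off = extract_boundary_windows(ss, n_spikes=10)
        assert len(on.times) == 10 and len(off.times) == 10
        assert on.times[-1] < off.times[0]
        assert not on.low_n and not on.overlapping

    def test_clamping_and_overlap_flag(self):
        ss = self._series(40)
        ss.times = ss.times[:6]
        ss.amplitudes = ss.amplitudes[:6]
        on, off = extract_boundary_windows(ss, n_spikes=10)
        assert len(on.times) == 6 and len(off.times) == 6
        assert on.overlapping

    def test_offset_window_respects_the_mark(self):
        ss = self._series(40)
        _, off = extract_boundary_windows(ss)
        assert np.all(np.diff(off.times) > 0)
        assert np.all(off.times <= ss.rec_offset)
        assert np.all(off.rel_times <= 0)

    def test_empty_series_is_an_error(self):
        from dynamotype.features import BackgroundStats, SpikeSeries

        empty = SpikeSeries(np.array([]), np.array([]),
                            BackgroundStats(0, 1, (0, 10)), 20.0, 30.0)
        with pytest.raises(ValueError):
            extract_boundary_windows(empty)
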