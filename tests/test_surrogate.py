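"""Surrogate spike trains: exact law recovery, rendering, AC filtering."""
import numpy as np
import pytest

from dynamotype.surrogate import (
    ONSET_LABELS,
    OFFSET_LABELS,
    ScalingLawSpec,
    SurrogateSeizureSpec,
    ac_filter,
    gen_spike_train,
    render_waveform,
)


@pytest.mark.parametrize("onset", ONSET_LABELS)
@pytest.mark.parametrize("offset", OFFSET_LABELS)
def test_zero_jitter_trains_follow_their_laws(onset, offset):
    sp = SurrogateSeizureSpec(onset=onset, offset=offset)
    tr = gen_spike_train(sp)
    t, a, isi = tr.times, tr.amplitudes, tr.isis
    k = sp.n_law
    assert np.all(np.diff(t) > 0) and np.all(a > 0)
    if onset == "SupH":
        slope = np.polyfit(np.log(t[:k]), np.log(a[:k]), 1)[0]
        assert abs(slope - 0.5) < 1e-3  # amplitude ~ sqrt(t - t_on), exactly
    if onset in ("SN", "SubH"):
        assert np.allclose(a[:k], a[:k][0])  # abrupt full-amplitude start
        assert np.ptp(isi[: k - 1]) < 1e-9
    if onset == "SNIC":
        med = np.median(isi[: k - 1])
        assert isi[0] > 3.0 * med  # long opening interval
    if offset == "SH":
        x = -np.log(sp.duration - t[-9:])
        y = isi[-9:]
        r = np.corrcoef(x, y)[0, 1]
        assert r * r > 0.999  # ISI linear in -ln(t_off - t)
        assert y[-1] > 2.0 * np.median(isi[-(k - 1):])
    if offset == "SupH":
        sel = t[-k:]
        slope = np.polyfit(np.log(sp.duration - sel), np.log(a[-k:]), 1)[0]
        assert abs(slope - 0.5) < 1e-3
    if offset == "FLC":
        assert np.allclose(a[-k:], a[-1])  # abrupt stop at full amplitude


def test_constant_constant_spec_is_flat():
    tr = gen_spike_train(SurrogateSeizureSpec(onset="SN", offset="FLC"))
    assert np.ptp(tr.isis) < 1e-9
    assert np.ptp(tr.amplitudes) < 1e-9


def test_seeded_reproducibility():
    sp = SurrogateSeizureSpec(onset="SN", offset="SH", isi_jitter=0.1,
                              amp_jitter=0.1, seed=42)
    a = gen_spike_train(sp)
    b = gen_spike_train(sp)
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.amplitudes, b.amplitudes)


def test_admissibility_of_dc_shifts():
    with pytest.raises(ValueError):
        SurrogateSeizureSpec(onset="SupH", dc_onset_polarity=1)
    with pytest.raises(ValueError):
        SurrogateSeizureSpec(offset="FLC", dc_offset_polarity=1)
    with pytest.raises(ValueError):
        SurrogateSeizureSpec(dc_rise=3.0, dc_persist=2.0)


def test_scaling_law_spec_validation():
    ScalingLawSpec("sqrt", "amplitude", t_bif=0.0)
    with pytest.raises(ValueError):
        ScalingLawSpec("cubic", "amplitude", t_bif=0.0)
    with pytest.raises(ValueError):
        ScalingLawSpec("sqrt", "phase", t_bif=0.0)


class TestRenderWaveform:
    def test_background_sd_matches_spec(self):
        sp = SurrogateSeizureSpec(onset="SN", offset="FLC", seed=3)
        tr = gen_spike_train(sp)
        w = render_waveform(tr, background_sd=2.0)
        pre = w.dc[: int(10 * w.fs)]
        assert abs(np.std(pre) - 2.0) / 2.0 < 0.05

    def test_single_spike_peak_to_peak(self):
        sp = SurrogateSeizureSpec(onset="SN", offset="FLC", amplitude=50.0)
        tr = gen_spike_train(sp)
        w = render_waveform(tr, background_sd=0.01)
        i = int((w.onset + tr.times[5]) * w.fs)
        half = int(0.1 * w.fs)
        seg = w.dc[i - half : i + half]
        ptp = seg.max() - seg.min()
        assert abs(ptp - 50.0 * 0.01) / (50.0 * 0.01) < 0.05

    def test_kernel_constraints(self):
        tr = gen_spike_train(SurrogateSeizureSpec())
        with pytest.raises(ValueError):
            render_waveform(tr, kernel_width=0.3)  # not a fast transient
        with pytest.raises(ValueError):
            render_waveform(tr, fs=40.0)  # cannot resolve the kernel

    def test_dc_step_present_only_on_dc_channel(self):
        sp = SurrogateSeizureSpec(onset="SN", offset="FLC", dc_onset_polarity=1,
                                  seed=5)
        w = render_waveform(gen_spike_train(sp))
        from dynamotype.features import Recording, background_stats, detect_dc_shift

        rec_dc = Recording(w.dc, w.fs, w.onset, w.offset, coupling="DC")
        st = background_stats(rec_dc)
        assert detect_dc_shift(rec_dc, "onset", st).present
        # the AC channel carries no sustained baseline step after settling
        i0 = int((w.onset + 1.0) * w.fs)
        i1 = int((w.onset + 2.0) * w.fs)
        pre = np.median(w.ac[: int(10 * w.fs)])
        assert abs(np.median(w.ac[i0:i1]) - pre) < 2.0  # within 2 SD


class TestAcFilter:
    def test_constant_input_goes_to_zero(self):
        out = ac_filter(np.full(4096, 7.0), fs=256.0, cutoff=0.5)
        assert np.max(np.abs(out)) < 1e-6 * 7.0

    def test_passband_sinusoid_preserved(self):
        t = np.arange(0, 30, 1 / 256)
        x = np.sin(2 * np.pi * 10 * t)
        out = ac_filter(x, fs=256.0, cutoff=0.5)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert abs(np.ptp(out[mid]) - np.ptp(x[mid])) / np.ptp(x[mid]) < 0.01

    def test_step_settles_back_to_zero(self):
        x = np.zeros(256 * 60)
        x[256 * 20 :] = 5.0
        out = ac_filter(x, fs=256.0, cutoff=0.5)
        settled = out[256 * 40 : 256 * 55]
        assert np.max(np.abs(settled)) < 0.05

    def test_cutoff_validation(self):
        with pytest.raises(ValueError):
            ac_filter(np.zeros(100), fs=100.0, cutoff=60.0)
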