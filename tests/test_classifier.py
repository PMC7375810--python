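"""Scaling-law fits and the onset/offset decision rules."""
import numpy as np
import pytest

from dynamotype.classifier import (
    OFFSET_CLASSES,
    ONSET_CLASSES,
    UNCLASSIFIED,
    classify_seizure,
    fit_scaling_models,
    tabulate_cohort,
)
from dynamotype.features import BoundaryWindow, Recording
from dynamotype.surrogate import SurrogateSeizureSpec, gen_spike_train, render_waveform


def _recordings(sp: SurrogateSeizureSpec, with_dc=True, seed=0):
    w = render_waveform(gen_spike_train(sp), seed=seed + 1000)
    recs = {"AC": Recording(w.ac, w.fs, w.onset, w.offset, coupling="AC")}
    if with_dc:
        recs["DC"] = Recording(w.dc, w.fs, w.onset, w.offset, coupling="DC")
    return recs


class TestScalingFits:
    def test_exact_sqrt_amplitude_recovers_bifurcation_time(self):
        t = 10.0 + 0.125 * np.arange(10)
        t_bif = 9.7
        a = 4.0 * np.sqrt(t - t_bif)
        win = BoundaryWindow("onset", t, t - 10.0, a, np.full(10, np.nan))
        fits = fit_scaling_models(win, "onset")
        best = min((f for f in fits if f.target == "amplitude"), key=lambda f: f.aicc)
        assert best.law == "sqrt"
        assert abs(best.t_bif - t_bif) < 0.1

    def test_jittered_constant_isi_selects_the_constant_law(self, rng):
        t = 10.0 + np.cumsum(0.125 * (1 + 0.05 * rng.standard_normal(10)))
        isi = np.concatenate([[np.nan], np.diff(t)])
        win = BoundaryWindow("offset", t, t - t[-1], np.full(10, 5.0), isi)
        fits = fit_scaling_models(win, "offset")
        best = min(
            (f for f in fits if f.target in ("isi", "frequency") and f.available),
            key=lambda f: f.aicc,
        )
        assert best.law == "constant"

    def test_too_few_spikes_is_an_error(self):
        win = BoundaryWindow("onset", np.arange(3.0), np.arange(3.0),
                             np.ones(3), np.full(3, np.nan))
        with pytest.raises(ValueError):
            fit_scaling_models(win, "onset")


# (onset, offset, dc flags) covering every grouped class in both columns
_GRID = [
    ("SupH", "SupH", 0, 0),
    ("SNIC", "SNIC", 0, 0),
    ("SN", "SH", 1, 1),
    ("SN", "SH", 0, 0),
    ("SubH", "FLC", 0, 0),
    ("SN", "FLC", 1, 0),
    ("SupH", "SH", 0, 1),
    ("SNIC", "SupH", 0, 0),
]


class TestDecisionRules:
    @pytest.mark.parametrize("onset,offset,dc_on,dc_off", _GRID)
    def test_clean_grouped_recovery(self, onset, offset, dc_on, dc_off):
        sp = SurrogateSeizureSpec(onset=onset, offset=offset,
                                  dc_onset_polarity=dc_on,
                                  dc_offset_polarity=dc_off, seed=11)
        lab = classify_seizure(_recordings(sp, seed=11))
        assert lab.onset == sp.grouped_onset
        assert lab.offset == sp.grouped_offset

    def test_grouping_monotonicity_without_dc_channel(self):
        sp = SurrogateSeizureSpec(onset="SN", offset="SH",
                                  dc_onset_polarity=1, dc_offset_polarity=1,
                                  seed=13)
        with_dc = classify_seizure(_recordings(sp, with_dc=True, seed=13))
        without = classify_seizure(_recordings(sp, with_dc=False, seed=13))
        assert with_dc.onset == "SN(+DC)" and with_dc.offset == "SH(+DC)"
        # dropping the DC channel moves labels to the grouped classes of the
        # same family, never to a different family
        assert without.onset == "SN(-DC)/SubH"
        assert without.offset == "SH(-DC)/SNIC"

    def test_outputs_stay_in_the_admissible_grid(self):
        for onset, offset, dc_on, dc_off in _GRID[:4]:
            sp = SurrogateSeizureSpec(onset=onset, offset=offset,
                                      dc_onset_polarity=dc_on,
                                      dc_offset_polarity=dc_off, seed=17)
            lab = classify_seizure(_recordings(sp, seed=17))
            assert lab.onset in ONSET_CLASSES
            assert lab.offset in OFFSET_CLASSES

    def test_empty_seizure_is_unclassified(self, rng):
        x = rng.standard_normal(40 * 256)
        rec = Recording(x, 256.0, onset=20.0, offset=35.0, coupling="DC")
        lab = classify_seizure(rec)
        assert lab.onset == UNCLASSIFIED and lab.offset == UNCLASSIFIED
        assert lab.slowing == "not assessed"

    def test_slowing_flag_reported(self):
        sp = SurrogateSeizureSpec(onset="SN", offset="SH", seed=19)
        lab = classify_seizure(_recordings(sp, seed=19))
        assert lab.slowing == "slowing"
        sp = SurrogateSeizureSpec(onset="SN", offset="FLC", seed=19)
        lab = classify_seizure(_recordings(sp, seed=19))
        assert lab.slowing == "constant"

    def test_confidence_in_unit_interval(self):
        sp = SurrogateSeizureSpec(onset="SN", offset="SH", seed=23)
        lab = classify_seizure(_recordings(sp, seed=23))
        assert 0.0 <= lab.confidence <= 1.0


class TestTabulateCohort:
    def _label(self, onset, offset, slowing):
        from dynamotype.classifier import DynamotypeLabel

        return DynamotypeLabel(onset, offset, slowing, 0.9)

    def test_single_seizure_table(self):
        t = tabulate_cohort([self._label("SN(+DC)", "SH(+DC)", "slowing")],
                            patients=["p1"], durations=[40.0])
        assert t["pair_table"].values.sum() == 1
        assert t["onset_counts"]["SN(+DC)"] == 1

    def test_offset_diversity_counts_distinct_slowing_flags(self):
        labs = [self._label("SN(+DC)", "SH(+DC)", "slowing"),
                self._label("SN(+DC)", "FLC", "constant")]
        t = tabulate_cohort(labs, patients=["p1", "p1"], durations=[40.0, 40.0])
        assert int(t["offset_diversity"]["p1"]) == 2

    def test_short_seizures_excluded_from_offset_tabulation(self):
        labs = [self._label("SN(+DC)", "SH(+DC)", "slowing"),
                self._label("SN(+DC)", "FLC", "constant")]
        t = tabulate_cohort(labs, patients=["p1", "p1"], durations=[40.0, 20.0])
        assert t["n_excluded_offset"] == 1
        assert "FLC" not in t["offset_counts"].index
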