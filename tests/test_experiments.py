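"""Experiment drivers, recording I/O and the CLI plumbing."""
import json

import numpy as np
import pytest

from dynamotype.canonical_model import NoiseSpec, SlowSpec, simulate_ensemble
from dynamotype.experiments import (
    DEFAULT_PATHS,
    default_path,
    extend_path,
    extract_seizure_recordings,
    measure_scaling_laws,
    read_recording,
    run_validation,
    simulate_forced_seizures,
    write_recording,
)
from dynamotype.features import Recording


class TestPaths:
    def test_default_paths_live_on_the_sphere(self):
        for name in DEFAULT_PATHS:
            p = default_path(name)
            for z in (0.0, 0.5, 1.0):
                assert abs(np.linalg.norm(p.point(z)) - 0.4) < 1e-9

    def test_extend_path_preserves_the_great_circle(self, snsh_path):
        ext = extend_path(snsh_path, before=0.2, beyond=0.4)
        n = np.cross(snsh_path.start.vector, snsh_path.end.vector)
        n /= np.linalg.norm(n)
        for z in (0.0, 0.5, 1.0):
            assert abs(ext.point(z) @ n) < 1e-9  # same plane through the origin


class TestRecordingIO:
    def test_csv_round_trip(self, tmp_path, rng):
        rec = Recording(rng.standard_normal(3000), fs=100.0, onset=12.0,
                        offset=25.0, coupling="DC", channel="chA")
        f = tmp_path / "rec.csv"
        write_recording(rec, f)
        back = read_recording(f)
        assert np.allclose(back.samples, rec.samples)
        assert back.fs == rec.fs and back.coupling == "DC"
        assert back.onset == 12.0 and back.offset == 25.0

    def test_invalid_marks_are_rejected(self, tmp_path, rng):
        rec = Recording(rng.standard_normal(3000), fs=100.0, onset=12.0, offset=25.0)
        f = tmp_path / "rec.csv"
        write_recording(rec, f)
        marks = json.loads(f.with_suffix(".marks.json").read_text())
        marks["onset_s"], marks["offset_s"] = 25.0, 12.0  # reversed
        with pytest.raises(ValueError):
            read_recording(f, marks=marks)

    def test_missing_sidecar_is_an_error(self, tmp_path):
        f = tmp_path / "naked.csv"
        f.write_text("time,value\n0,0\n0.1,1\n")
        with pytest.raises(ValueError):
            read_recording(f)


class TestSeizureExtraction:
    def test_extraction_produces_marked_pairs(self, snsh_path):
        ens = simulate_ensemble(
            snsh_path,
            SlowSpec(epsilon=1e-3),
            NoiseSpec(0.002, 0.0, seed=2),
            duration=3000.0,
            dt=0.02,
            n_sims=2,
            z0=0.4,
        )
        items = extract_seizure_recordings(ens, 0.02, merge_gap=100.0)
        assert items
        for it in items:
            dc, ac = it["recs"]["DC"], it["recs"]["AC"]
            assert dc.coupling == "DC" and ac.coupling == "AC"
            assert dc.onset < dc.offset
            assert len(dc.samples) == len(ac.samples)

    def test_forced_ramp_rejects_unknown_types(self):
        with pytest.raises(ValueError):
            simulate_forced_seizures("SN/SH")


class TestValidation:
    def test_clean_surrogate_matrix_is_diagonal(self):
        cm = run_validation(n_per_type=2, source="surrogate",
                            isi_jitter=0.0, amp_jitter=0.0, seed=3)
        assert cm.macro_recall == 1.0
        # diagonal: off-diagonal entries are all zero
        for df in (cm.onset, cm.offset):
            for truth in df.index:
                for pred in df.columns:
                    if pred != truth:
                        assert df.loc[truth, pred] == 0

    def test_validation_is_a_pure_function_of_config_and_seed(self):
        a = run_validation(n_per_type=1, source="surrogate", seed=5)
        b = run_validation(n_per_type=1, source="surrogate", seed=5)
        assert a.onset.equals(b.onset) and a.offset.equals(b.offset)

    def test_unknown_source_is_rejected(self):
        with pytest.raises(ValueError):
            run_validation(n_per_type=1, source="patients")


def test_scaling_law_report_has_all_quantities():
    laws = measure_scaling_laws()
    assert set(laws) >= {
        "suph_amplitude_exponent",
        "snic_frequency_exponent",
        "sh_isi_log_r2",
        "sn_first_amp_over_median",
    }
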