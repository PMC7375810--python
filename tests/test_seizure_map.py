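"""Analytic curves, the attractor oracle, paths and crossings."""
import math

import numpy as np
import pytest

from dynamotype.canonical_model import PathSpec, SphericalPoint, UnfoldingParams
from dynamotype.seizure_map import (
    BISTABLE_REST_SEIZURE,
    REST_ONLY,
    Crossing,
    DynamotypePair,
    classify_attractors,
    great_circle_path,
    hopf_curve,
    path_crossings,
    sn_curves,
)


def _params(v):
    return UnfoldingParams(mu1=-v[1], mu2=v[0], nu=v[2])


class TestAnalyticCurves:
    def test_sn_points_satisfy_double_root_condition(self):
        for branch in sn_curves(0.4):
            for v in branch.points[:: len(branch) // 10]:
                p = _params(v)
                # double root at s: both the cubic and its derivative vanish
                s = math.copysign(math.sqrt(max(p.mu2, 0) / 3.0), -p.mu1 or 1.0)
                assert abs(s**3 - p.mu2 * s - p.mu1) < 1e-10
                assert abs(3 * s * s - p.mu2) < 1e-10
                assert abs(np.linalg.norm(v) - 0.4) < 1e-10

    def test_cusp_is_a_triple_root(self):
        branch = sn_curves(0.4)[0]
        v = branch.points[0]  # the pole, where s -> 0
        p = _params(v)
        assert abs(p.mu1) < 1e-9 and abs(p.mu2) < 1e-9  # cubic is x^3

    def test_hopf_points_have_zero_trace_at_a_fixed_point(self):
        h = hopf_curve(0.4)
        for i in range(0, len(h), len(h) // 15):
            v = h.points[i]
            x = h.meta["x"][i]
            p = _params(v)
            assert abs(x**3 - p.mu2 * x - p.mu1) < 1e-9
            assert abs(p.nu + x + x * x) < 1e-9
            assert 3 * x * x - p.mu2 > 0  # complex pair, not a neutral saddle

    def test_criticality_flag_matches_simulation(self):
        from dynamotype.seizure_map import _DEFAULT_ICS, _point_attractors

        h = hopf_curve(0.4)
        sup = h.points[h.meta["supercritical"]]
        sub = h.points[~h.meta["supercritical"]]

        def small_cycle_beyond(v, x):
            # probe just on the unstable side by nudging nu toward -x-x^2
            # being exceeded: move along +/-nu and pick the side where the
            # focus destabilises
            for dn in (+0.004, -0.004):
                w = v + np.array([0.0, 0.0, dn])
                w = 0.4 * w / np.linalg.norm(w)
                p = _params(w)
                if -(p.nu + x + x * x) > 0:  # focus unstable here
                    ics = np.array([[0.02, 0.0]])  # spiral out from the focus
                    st = _point_attractors(
                        w[None, :], ics, t_transient=3000.0,
                        t_detect=800.0, amp_min=1e-3,
                    )
                    return bool(st["cycle"][0]), float(st["amp"][0])
            return False, math.nan

        i_sup = len(sup) // 5
        x_sup = h.meta["x"][h.meta["supercritical"]][i_sup]
        has_cycle, amp = small_cycle_beyond(sup[i_sup], x_sup)
        assert has_cycle and amp < 0.5  # a small stable cycle is born

    def test_curves_reject_bad_radius(self):
        with pytest.raises(ValueError):
            sn_curves(-1.0)
        with pytest.raises(ValueError):
            hopf_curve(0.0)


class TestAttractorOracle:
    def test_deep_rest_point(self):
        p = SphericalPoint.from_vector([0.2, -0.3, 0.15], R=0.4)
        assert classify_attractors(p) == REST_ONLY

    def test_bistable_point_on_the_square_wave_path(self, snsh_path):
        v = snsh_path.point(0.4)
        p = SphericalPoint.from_vector(v, R=0.4)
        assert classify_attractors(p) == BISTABLE_REST_SEIZURE

    def test_analytic_curves_agree_with_oracle_transversals(self):
        """Crossing an analytic SN or Hopf curve flips the oracle's label."""
        from dynamotype.seizure_map import _DEFAULT_ICS, _point_attractors

        checks = []
        sn = sn_curves(0.4)[0]
        h = hopf_curve(0.4)
        for curve, idxs in ((sn, [60, 110, 160]), (h, [80, 200, 320])):
            for i in idxs:
                v = curve.points[i]
                u = v / np.linalg.norm(v)
                j = i + 1 if i + 1 < len(curve) else i - 1
                tang = curve.points[j] / np.linalg.norm(curve.points[j]) - u
                nrm = np.cross(u, tang)
                nrm /= np.linalg.norm(nrm)
                step = 0.06
                a = 0.4 * (u * math.cos(step) + nrm * math.sin(step))
                b = 0.4 * (u * math.cos(step) - nrm * math.sin(step))
                sa = _point_attractors(a[None, :], _DEFAULT_ICS)
                sb = _point_attractors(b[None, :], _DEFAULT_ICS)
                la = (int(sa["n_stable"][0]), bool(sa["cycle"][0]), int(sa["n_roots"][0]))
                lb = (int(sb["n_stable"][0]), bool(sb["cycle"][0]), int(sb["n_roots"][0]))
                checks.append(la != lb)
        assert np.mean(checks) >= 0.8


class TestPathsAndCrossings:
    def test_zero_length_path_is_constant(self):
        a = SphericalPoint(1.0, 0.5, 0.4)
        path = great_circle_path(a, a)
        assert np.allclose(path.point(0.0), path.point(0.9))

    def test_midpoint_equidistant_and_arc_length(self):
        a = SphericalPoint.from_vector([0.4, 0, 0])
        b = SphericalPoint.from_vector([0, 0, 0.4])
        path = great_circle_path(a, b)
        assert abs(path.arc_length - 0.4 * math.pi / 2) < 1e-12
        mid = SphericalPoint.from_vector(path.point(0.5))
        assert abs(a.angle_to(mid) - mid.angle_to(b)) < 1e-12

    def test_antipodal_points_are_rejected(self):
        a = SphericalPoint.from_vector([0.4, 0, 0])
        b = SphericalPoint.from_vector([-0.4, 0, 0])
        with pytest.raises(ValueError):
            great_circle_path(a, b)

    def test_path_inside_one_region_has_no_crossings(self):
        curves = sn_curves(0.4) + [hopf_curve(0.4)]
        a = SphericalPoint.from_vector([0.1, -0.35, 0.15], R=0.4)
        b = SphericalPoint.from_vector([0.15, -0.3, 0.2], R=0.4)
        crs = [c for c in path_crossings(great_circle_path(a, b), curves)
               if not c.tangential]
        assert crs == []

    def test_square_wave_path_crosses_sn_then_sh(self, snsh_path):
        from dynamotype.experiments import extend_path

        curves = sn_curves(0.4) + [hopf_curve(0.4)]
        path = extend_path(snsh_path, before=0.0, beyond=0.0)
        crs = [c for c in path_crossings(path, curves) if not c.tangential]
        labels = [c.label for c in sorted(crs, key=lambda c: c.z)]
        assert "SN" in labels  # the onset fold is crossed

    def test_reversing_the_path_reverses_crossings(self, snsh_path):
        curves = sn_curves(0.4) + [hopf_curve(0.4)]
        fwd = [c for c in path_crossings(snsh_path, curves) if not c.tangential]
        rev = [c for c in path_crossings(snsh_path.reversed(), curves)
               if not c.tangential]
        assert sorted(round(c.z, 4) for c in rev) == sorted(
            round(1 - c.z, 4) for c in fwd
        )


class TestDynamotypeAdmissibility:
    def test_onset_only_and_offset_only_types(self):
        DynamotypePair("SN", "SH")  # admissible
        with pytest.raises(ValueError):
            DynamotypePair("FLC", "SH")  # FLC never starts a seizure
        with pytest.raises(ValueError):
            DynamotypePair("SN", "SN")  # SN never stops one
        with pytest.raises(ValueError):
            DynamotypePair("SH", "SH")  # SH never starts one
        with pytest.raises(ValueError):
            DynamotypePair("SupH", "SubH")  # SubH never stops one

    def test_crossing_capability_properties(self):
        assert Crossing(0.5, "SN").onset_capable
        assert not Crossing(0.5, "SN").offset_capable
        assert Crossing(0.5, "SH").offset_capable
        assert Crossing(0.5, "SNIC").onset_capable
        assert Crossing(0.5, "SNIC").offset_capable
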