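"""Prosthesis/implant metrics and cohort aggregation arithmetic."""

import numpy as np
import pytest

from tavi4d import (
    CSAProfile,
    PatientResult,
    PlaneSet,
    ProsthesisState,
    cohort_summary,
    csa_profile,
    displacement_series,
    locate_planes,
    prosthesis_state,
)


def _state(t, c, V=100.0):
    return ProsthesisState(t=t, V=V, c=np.asarray(c, float),
                           alpha=np.array([90.0, 90.0, 0.0]))


class TestProsthesisState:
    def test_cylinder_volume_and_alignment(self, cyl_result):
        res, truth, _ = cyl_result
        st = res.states[0]
        assert st.V == pytest.approx(float(truth.inner_volume_mm3[0]), rel=0.05)
        np.testing.assert_allclose(st.alpha, [90.0, 90.0, 0.0], atol=0.5)
        # direction cosines are consistent
        cosines = np.cos(np.deg2rad(st.alpha))
        assert np.sum(cosines**2) == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_frame_centroid_at_center(self, cyl_result):
        res, truth, _ = cyl_result
        center = res.frame_masks[0].physical_center()
        np.testing.assert_allclose(res.states[0].c, center,
                                   atol=0.5 * max(res.frame_masks[0].spacing))


class TestDisplacement:
    def test_static_series_is_zero(self, static_result):
        res, _ = static_result
        np.testing.assert_array_equal(res.displacements, np.zeros(3))

    def test_three_four_five(self):
        states = [_state(0, (0, 0, 0)), _state(1, (3, 4, 0))]
        np.testing.assert_allclose(displacement_series(states), [5.0])

    def test_translated_phantom_within_half_voxel_diagonal(self, moving_result):
        half_diag = 0.5 * np.sqrt(3) * 0.6
        assert np.all(np.abs(moving_result.displacements - 2.0) <= half_diag)

    def test_single_phase_is_an_error(self):
        with pytest.raises(ValueError, match="two phases"):
            displacement_series([_state(0, (0, 0, 0))])


class TestCSAProfile:
    def test_cylinder_midsection(self, cyl_result):
        res, _, _ = cyl_result
        p = res.profiles[0]
        sel = (p.h_grid >= 10) & (p.h_grid <= 90)
        np.testing.assert_allclose(p.csa_p[sel], np.pi * 100.0, rtol=0.05)

    def test_dcsa_identity_and_annulus(self, cyl_result):
        res, _, _ = cyl_result
        p = res.profiles[0]
        np.testing.assert_allclose(p.dcsa, p.csa_a - p.csa_p)
        sel = (p.h_grid >= 10) & (p.h_grid <= 90)
        np.testing.assert_allclose(p.dcsa[sel], np.pi * (14**2 - 10**2), rtol=0.07)
        assert (p.dcsa >= -1e-9).all()

    def test_root_optional(self, cyl_result):
        res, _, _ = cyl_result
        from tavi4d import reformat

        fr = reformat(res.filling_masks[0], res.axes[0])
        p = csa_profile(fr, None, res.axes[0])
        assert p.csa_a is None and p.dcsa is None
        np.testing.assert_allclose(p.csa_p, res.profiles[0].csa_p, rtol=0.01)

    def test_volume_consistency(self, cyl_result):
        res, _, _ = cyl_result
        p = res.profiles[0]
        assert p.integral_mm3() == pytest.approx(res.states[0].V, rel=0.02)


def _flat_profile(t, values):
    h = np.arange(0.0, 101.0, 1.0)
    return CSAProfile(t=t, h_grid=h, csa_p=np.asarray(values, float),
                      axial_length_mm=30.0, slice_thickness_mm=0.6)


class TestLocatePlanes:
    def test_distinct_peak(self):
        h = np.arange(0.0, 101.0, 1.0)
        csa = np.pi * (10 + 2 * np.exp(-(((h - 45) / 18) ** 2))) ** 2
        ps = locate_planes([_flat_profile(0, csa)])
        assert abs(ps.h2 - 45.0) <= 1.0

    def test_monotone_from_outflow(self):
        h = np.arange(0.0, 101.0, 1.0)
        csa = np.pi * (12 - 3 * h / 100.0) ** 2
        ps = locate_planes([_flat_profile(0, csa)])
        assert ps.h2 == 0.0 == ps.h1

    def test_constant_profile_ties_to_outflow(self):
        ps = locate_planes([_flat_profile(0, np.full(101, 314.16))])
        assert ps.h2 == 0.0

    def test_phantom_barrel_peak(self, barrel_result):
        res, truth = barrel_result
        assert abs(res.planes.h2 - truth.h2_true_percent) <= 1.0

    def test_phantom_taper_outflow(self, taper_result):
        res, _ = taper_result
        assert res.planes.h2 == 0.0 == res.planes.h1

    def test_plane_ordering_enforced(self):
        with pytest.raises(ValueError):
            PlaneSet(h1=0.0, h2=120.0, h3=100.0)


class TestCohort:
    def _patient(self, pid, model, V, d, csa_by_plane, h2=50.0):
        profiles = []
        for t in range(len(V)):
            h = np.arange(0.0, 101.0, 1.0)
            csa = np.interp(h, [0, 50, 100], csa_by_plane[t])
            profiles.append(CSAProfile(t=t, h_grid=h, csa_p=csa,
                                       axial_length_mm=30.0, slice_thickness_mm=0.6))
        states = [_state(t, (0, 0, 0), V=V[t]) for t in range(len(V))]
        return PatientResult(patient_id=pid, model=model, states=states,
                             displacements=list(d), profiles=profiles,
                             planes=PlaneSet(h1=0.0, h2=h2, h3=100.0))

    def test_hand_computed_scalars(self):
        pat = self._patient("p0", "A", V=[10.0, 12.0, 11.0], d=[1.0, 3.0],
                            csa_by_plane=[(300, 320, 310)] * 3)
        s = cohort_summary([pat])
        tidy = s.tidy.set_index("metric")
        assert tidy.loc["Vm", "mean"] == pytest.approx(11.0)
        assert tidy.loc["Vrange", "mean"] == pytest.approx(2.0)
        assert tidy.loc["dm", "mean"] == pytest.approx(2.0)
        assert tidy.loc["drange", "mean"] == pytest.approx(2.0)
        assert tidy.loc["CSA(h1)m", "mean"] == pytest.approx(300.0)
        assert tidy.loc["CSA(h2)m", "mean"] == pytest.approx(320.0)

    def test_group_mean_and_sample_sd(self):
        pats = [
            self._patient("p0", "A", V=[10.0] * 3, d=[1.0, 1.0], csa_by_plane=[(300, 320, 310)] * 3),
            self._patient("p1", "A", V=[14.0] * 3, d=[2.0, 2.0], csa_by_plane=[(300, 320, 310)] * 3),
        ]
        s = cohort_summary(pats)
        row = s.tidy[(s.tidy.metric == "Vm")].iloc[0]
        assert row["mean"] == pytest.approx(12.0)
        assert row["sd"] == pytest.approx(np.sqrt(8.0))  # sample sd = 2.828
        assert row["n"] == 2

    def test_h2_rows_omitted_when_coincident_with_h1(self):
        pat = self._patient("p0", "CV", V=[10.0] * 3, d=[1.0, 1.0],
                            csa_by_plane=[(320, 310, 300)] * 3, h2=0.0)
        s = cohort_summary([pat])
        assert not any("(h2)" in m for m in s.tidy.metric)
        assert any("(h1)" in m for m in s.tidy.metric)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            cohort_summary([])
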