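"""Stress summaries, principal systems, profiles, comparisons."""

import numpy as np
import pytest

from compax.fem import StressField
from compax.stress import (
    StressSummary,
    amplify_normalize,
    compare_to_reference,
    normal_stress_profile,
    pressure,
    principal,
    summarize,
    volumetric_mean,
)


def make_field(sigmas, volumes):
    sigmas = np.asarray(sigmas, float)
    volumes = np.asarray(volumes, float)
    return StressField(
        sigma=sigmas,
        volumes=volumes,
        J=np.ones(volumes.size),
        element_ids=np.arange(volumes.size),
    )


class TestPressure:
    def test_hydrostatic(self):
        assert pressure(-1000.0 * np.eye(3)) == pytest.approx(1000.0)

    def test_pure_shear_is_traceless(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 120.0
        assert pressure(s) == pytest.approx(0.0)

    def test_triaxial(self):
        assert pressure(np.diag([-600.0, -800.0, -1000.0])) == pytest.approx(800.0)

    def test_asymmetric_rejected(self):
        s = np.zeros((3, 3))
        s[0, 1] = 50.0
        with pytest.raises(ValueError):
            pressure(s)


class TestVolumetricMean:
    def test_uniform_field_unchanged(self):
        s = np.diag([-1.0, -2.0, -3.0])
        fld = make_field([s, s, s], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(volumetric_mean(fld), s)

    def test_equal_volume_average(self):
        fld = make_field(
            [np.diag([-1000.0, 0, 0]), np.diag([0, -1000.0, 0])], [1.0, 1.0]
        )
        np.testing.assert_allclose(volumetric_mean(fld), np.diag([-500.0, -500.0, 0.0]))

    def test_volume_weighted_pressures(self):
        # pressures 400 and 800 Pa with volumes 1 and 3 -> mean 700 Pa
        fld = make_field([-400.0 * np.eye(3), -800.0 * np.eye(3)], [1.0, 3.0])
        assert pressure(volumetric_mean(fld)) == pytest.approx(700.0)

    def test_pressure_linearity(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 3, 3))
        sig = 0.5 * (a + np.swapaxes(a, 1, 2))
        v = rng.uniform(0.5, 2.0, 5)
        fld = make_field(sig, v)
        per_point = -np.einsum("pii->p", sig) / 3.0
        expected = float((per_point * v).sum() / v.sum())
        assert pressure(volumetric_mean(fld)) == pytest.approx(expected, rel=1e-9)


class TestPrincipal:
    def test_hydrostatic_degenerate(self):
        vals, vecs = principal(-5.0 * np.eye(3))
        np.testing.assert_allclose(vals, [-5.0, -5.0, -5.0])
        np.testing.assert_allclose(vecs @ vecs.T, np.eye(3), atol=1e-12)

    def test_diagonal_permutation(self):
        vals, vecs = principal(np.diag([3.0, 1.0, 2.0]))
        np.testing.assert_allclose(vals, [3.0, 2.0, 1.0])
        np.testing.assert_allclose(np.abs(vecs), np.eye(3)[:, [0, 2, 1]], atol=1e-12)

    def test_similarity_invariance_under_rotation(self):
        th = 0.3
        Rz = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        )
        s = np.diag([3.0, 2.0, 1.0])
        vals, vecs = principal(Rz @ s @ Rz.T)
        np.testing.assert_allclose(vals, [3.0, 2.0, 1.0], atol=1e-12)
        for i in range(3):
            expect = Rz @ np.eye(3)[:, i]
            assert abs(abs(expect @ vecs[:, i]) - 1.0) < 1e-9

    def test_directions_orthonormal(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(3, 3))
        _, vecs = principal(a + a.T)
        np.testing.assert_allclose(vecs.T @ vecs, np.eye(3), atol=1e-12)


class TestNormalStressProfile:
    def test_isotropic_is_constant(self):
        prof = normal_stress_profile(-700.0 * np.eye(3), 90)
        np.testing.assert_allclose(prof.values, -700.0)

    def test_uniaxial_cos_squared(self):
        s = np.zeros((3, 3))
        s[0, 0] = 42.0
        prof = normal_stress_profile(s, 180)
        np.testing.assert_allclose(prof.values, 42.0 * np.cos(prof.angles) ** 2,
                                   atol=1e-12)

    def test_period_is_pi(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(3, 3))
        prof = normal_stress_profile(a + a.T, 360)
        np.testing.assert_allclose(prof.values, np.roll(prof.values, 180), atol=1e-12)

    def test_extrema_at_in_plane_principal_directions(self):
        th = 0.7
        Rz = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        )
        s = Rz @ np.diag([100.0, -30.0, 10.0]) @ Rz.T
        prof = normal_stress_profile(s, 3600)
        phi_max = prof.angles[np.argmax(prof.values)]
        assert min(abs(phi_max - th), abs(phi_max - th - np.pi)) < 2 * np.pi / 3600

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            normal_stress_profile(np.eye(3), 3)


class TestAmplifyNormalize:
    def make_profiles(self, arrays):
        from compax.stress import NormalStressProfile

        n = len(arrays[0])
        phi = 2 * np.pi * np.arange(n) / n
        return [NormalStressProfile(angles=phi, values=np.asarray(a, float))
                for a in arrays]

    def test_constant_profile_maps_to_sign(self):
        out = amplify_normalize(self.make_profiles([[-3.0] * 8]), factor=5.0)
        np.testing.assert_allclose(out[0].values, -1.0)

    def test_amplification_formula(self):
        # mean 100, value 120 at one angle, factor 5 -> amplified to 200
        vals = np.array([80.0, 100.0, 120.0, 100.0])
        amped = vals.mean() + 5.0 * (vals - vals.mean())
        assert amped[2] == pytest.approx(200.0)
        out = amplify_normalize(self.make_profiles([vals]), factor=5.0)
        np.testing.assert_allclose(out[0].values, amped / np.abs(amped).max())

    def test_global_max_is_exactly_one(self):
        rng = np.random.default_rng(3)
        profs = self.make_profiles(rng.normal(100.0, 20.0, size=(4, 16)))
        out = amplify_normalize(profs)
        assert max(np.abs(p.values).max() for p in out) == 1.0

    def test_per_time_point_means_preserved_up_to_global_constant(self):
        rng = np.random.default_rng(4)
        profs = self.make_profiles(rng.normal(50.0, 10.0, size=(3, 24)))
        out = amplify_normalize(profs, factor=5.0)
        ratios = [p.values.mean() / q.values.mean() for p, q in zip(out, profs)]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError):
            amplify_normalize(self.make_profiles([[0.0] * 8]))


class TestCompare:
    def make_summary(self, tensor, V_c=100.0, V_r=100.0):
        vals, vecs = principal(tensor)
        return StressSummary(
            mean_tensor=tensor,
            principal_values=vals,
            principal_directions=vecs,
            mean_pressure=pressure(tensor),
            V_c=V_c,
            V_r=V_r,
        )

    def test_identical_summaries_give_zeros(self):
        s = self.make_summary(np.diag([-100.0, -300.0, -900.0]))
        rec = compare_to_reference(s, s)
        np.testing.assert_allclose(rec.delta_principal, 0.0, atol=1e-12)
        assert rec.rel_delta_pressure == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rec.principal_angles_deg, 0.0, atol=1e-9)

    def test_relative_pressure_difference(self):
        ref = self.make_summary(-1000.0 * np.eye(3))
        cmx = self.make_summary(-950.0 * np.eye(3))
        rec = compare_to_reference(cmx, ref)
        assert rec.rel_delta_pressure == pytest.approx(-0.05, rel=1e-12)

    def test_five_degree_rotation_detected(self):
        th = np.radians(5.0)
        Rz = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        )
        s = np.diag([-100.0, -500.0, -900.0])
        ref = self.make_summary(s)
        cmx = self.make_summary(Rz @ s @ Rz.T)
        rec = compare_to_reference(cmx, ref)
        assert rec.principal_angles_deg[0] == pytest.approx(5.0, abs=1e-6)
        assert rec.principal_angles_deg[1] == pytest.approx(5.0, abs=1e-6)
        assert rec.principal_angles_deg[2] == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_pair_compared_subspace_wise(self):
        # axisymmetric tensors: the transverse eigenvector pair is arbitrary,
        # so any rotation within the pair's plane must count as aligned
        th = 1.1
        Rz = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        )
        s = np.diag([-700.0, -700.0, -900.0])
        ref = self.make_summary(s)
        cmx = self.make_summary(Rz @ s @ Rz.T)
        rec = compare_to_reference(cmx, ref)
        np.testing.assert_allclose(rec.principal_angles_deg, 0.0, atol=1e-6)

    def test_zero_reference_pressure_reported_absolute_only(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 10.0
        ref = self.make_summary(s)
        cmx = self.make_summary(1.5 * s)
        rec = compare_to_reference(cmx, ref)
        assert rec.rel_delta_pressure is None
        assert rec.delta_pressure == pytest.approx(0.0, abs=1e-12)


class TestSummarize:
    def test_summary_internal_consistency(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(6, 3, 3))
        fld = make_field(0.5 * (a + np.swapaxes(a, 1, 2)), rng.uniform(0.5, 1.5, 6))
        s = summarize(fld, V_r=123.0)
        assert s.mean_pressure == pytest.approx(
            -np.trace(s.mean_tensor) / 3.0, rel=1e-12
        )
        assert s.mean_pressure == pytest.approx(
            -s.principal_values.sum() / 3.0, rel=1e-9
        )
        assert s.V_c == pytest.approx(fld.volumes.sum())
        assert (np.diff(s.principal_values) <= 1e-12).all()
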