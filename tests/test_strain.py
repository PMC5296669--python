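"""Affine reorientation model and gelation-timing mixture."""

import numpy as np
import pytest

from anisoquant.strain import (DeformationGradient, GelationKinetics,
                               StrainProtocol, gelation_fraction, mixture_oi,
                               oi_vs_strain_duration, plane_angle,
                               pre_deformation_gradient,
                               predicted_oi_vs_strain, project_xy_angles,
                               release_deformation_gradient, reorient)
from anisoquant.synthetic import generate_ensemble_3d


class TestDeformationGradients:
    def test_identity_at_lambda_one(self):
        assert pre_deformation_gradient(1.0).diag == pytest.approx((1, 1, 1))
        assert release_deformation_gradient(1.0).diag == pytest.approx((1, 1, 1))

    @pytest.mark.parametrize("lam", [0.5, 0.7, 1.0, 1.4, 2.0])
    def test_volume_conserved(self, lam):
        for F in (pre_deformation_gradient(lam), release_deformation_gradient(lam)):
            assert np.prod(F.diag) == pytest.approx(1.0, abs=1e-9)

    def test_pre_stretch_structure(self):
        F = pre_deformation_gradient(1.4, "y")
        assert F.diag == pytest.approx((1.4 ** -0.5, 1.4, 1.4 ** -0.5))

    def test_release_structure(self):
        F = release_deformation_gradient(1.4, "y")
        assert F.diag == pytest.approx((1.4 ** 0.5, 1 / 1.4, 1.4 ** 0.5))

    def test_release_undoes_pre_deformation(self):
        pre = pre_deformation_gradient(1.4).as_array()
        rel = release_deformation_gradient(1.4).as_array()
        assert pre * rel == pytest.approx(np.ones(3))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pre_deformation_gradient(0.0)
        with pytest.raises(ValueError):
            release_deformation_gradient(-1.0)
        with pytest.raises(ValueError):
            DeformationGradient((2.0, 1.0, 1.0))  # det != 1


class TestReorient:
    def test_axis_aligned_vector_is_fixed_direction(self):
        ens = generate_ensemble_3d(1, "isotropic", seed=0)
        ens = type(ens)(np.array([[1.0, 0.0, 0.0]]))
        moved = reorient(ens, release_deformation_gradient(1.4))
        assert moved.directions[0] == pytest.approx([1.0, 0.0, 0.0])

    def test_prestretch_release_pulls_toward_x(self):
        v = np.array([[np.cos(np.pi / 4), np.sin(np.pi / 4), 0.0]])
        ens = type(generate_ensemble_3d(1, seed=0))(v)
        moved = reorient(ens, release_deformation_gradient(1.4))
        theta_rs = plane_angle(moved.directions[0], "xy").angle
        assert theta_rs == pytest.approx(np.degrees(np.arctan(1.4 ** -1.5)), abs=1e-9)
        assert theta_rs < 45.0

    def test_precompression_release_pulls_toward_y(self):
        v = np.array([[np.cos(np.pi / 4), np.sin(np.pi / 4), 0.0]])
        ens = type(generate_ensemble_3d(1, seed=0))(v)
        moved = reorient(ens, release_deformation_gradient(0.7))
        theta_rs = plane_angle(moved.directions[0], "xy").angle
        assert theta_rs == pytest.approx(np.degrees(np.arctan(0.7 ** -1.5)), abs=1e-9)
        assert theta_rs > 45.0

    @pytest.mark.parametrize("lam", [0.5, 0.7, 1.3, 1.5])
    def test_closed_form_tan_relations(self, lam):
        """tan theta_rs = lam^-3/2 tan theta_0 (xy); tan phi_rs,yz =
        lam^3/2 tan phi_0,yz; xz angle exactly invariant."""
        ens = generate_ensemble_3d(1000, "isotropic", seed=42)
        moved = reorient(ens, release_deformation_gradient(lam, "y"))
        v0, v1 = ens.directions, moved.directions
        tan_xy0 = v0[:, 1] / v0[:, 0]
        tan_xy1 = v1[:, 1] / v1[:, 0]
        np.testing.assert_allclose(tan_xy1, lam ** -1.5 * tan_xy0, rtol=1e-9)
        tan_yz0 = v0[:, 2] / v0[:, 1]
        tan_yz1 = v1[:, 2] / v1[:, 1]
        np.testing.assert_allclose(tan_yz1, lam ** 1.5 * tan_yz0, rtol=1e-9)
        xz0 = np.arctan2(v0[:, 2], v0[:, 0])
        xz1 = np.arctan2(v1[:, 2], v1[:, 0])
        np.testing.assert_allclose(xz1, xz0, atol=1e-9)

    def test_direction_of_change_matches_sign_of_strain(self):
        rng = np.random.default_rng(3)
        theta0 = rng.uniform(1.0, 89.0, 200)
        v = np.stack([np.cos(np.radians(theta0)), np.sin(np.radians(theta0)),
                      np.zeros_like(theta0)], axis=1)
        ens = type(generate_ensemble_3d(1, seed=0))(v)
        stretched = project_xy_angles(reorient(ens, release_deformation_gradient(1.5)))
        compressed = project_xy_angles(reorient(ens, release_deformation_gradient(0.7)))
        assert np.all(stretched < theta0)
        assert np.all(compressed > theta0)

    def test_antipodal_equivalence_preserved(self):
        ens = generate_ensemble_3d(100, "isotropic", seed=5)
        flipped = type(ens)(-ens.directions)
        F = release_deformation_gradient(1.3)
        np.testing.assert_allclose(reorient(ens, F).directions,
                                   -reorient(flipped, F).directions, atol=1e-12)


class TestPlaneAngle:
    def test_x_axis_examples(self):
        assert plane_angle([1, 0, 0], "xy").angle == pytest.approx(0.0)
        assert plane_angle(np.array([1, 0, 1]) / np.sqrt(2), "xz").angle \
            == pytest.approx(45.0)

    def test_degenerate_projection_raises(self):
        with pytest.raises(ValueError):
            plane_angle([0, 0, 1], "xy")


class TestPredictedOiVsStrain:
    def test_zero_strain_gives_zero_oi(self):
        df = predicted_oi_vs_strain([0.0], n=100_000, seed=1)
        assert abs(df["oi"].iloc[0]) < 0.02

    def test_strictly_increasing_under_prestretch(self):
        df = predicted_oi_vs_strain([0.1, 0.2, 0.3, 0.4, 0.5], n=100_000, seed=1)
        assert np.all(np.diff(df["oi"]) > 0)

    def test_precompression_aligns_along_y(self):
        df = predicted_oi_vs_strain([-0.3], n=100_000, seed=1)
        assert df["oi"].iloc[0] < 0

    def test_reflection_symmetry_of_initial_ensemble(self):
        ens = generate_ensemble_3d(50_000, "isotropic", seed=7)
        mirrored = type(ens)(ens.directions * np.array([1.0, -1.0, 1.0]))
        F = release_deformation_gradient(1.4)
        from anisoquant.stats import oi_from_angles
        a = oi_from_angles(project_xy_angles(reorient(ens, F))).oi
        b = oi_from_angles(project_xy_angles(reorient(mirrored, F))).oi
        assert a == pytest.approx(b, abs=1e-12)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            predicted_oi_vs_strain([-1.0], n=100)


class TestGelation:
    def test_midpoint_is_half(self):
        k = GelationKinetics()
        assert gelation_fraction(k.t_half, k) == pytest.approx(0.5)

    def test_lag_phase_stays_low(self):
        k = GelationKinetics()
        assert gelation_fraction(0.0, k) <= 0.05
        assert gelation_fraction(k.t_lag, k) <= 0.05

    def test_monotone_non_decreasing(self):
        k = GelationKinetics()
        t = np.linspace(0, 60, 200)
        f = [gelation_fraction(ti, k) for ti in t]
        assert np.all(np.diff(f) >= 0)

    def test_lag_constraint_enforced_at_construction(self):
        with pytest.raises(ValueError):
            GelationKinetics(t_lag=3.0, t_half=4.0, rate=0.5)  # f(t_lag) > 0.05


class TestMixtureOi:
    def test_no_fibrils_before_release_means_no_alignment(self):
        # steep kinetics: f(0) ~ 1e-7, so no reoriented population and no template
        k = GelationKinetics(t_lag=3.0, t_half=7.0, rate=2.5)
        proto = StrainProtocol(delta_ratio=0.5, t_D=0.0, kinetics=k)
        assert abs(mixture_oi(proto, n=100_000, seed=0).oi) < 0.02

    def test_strain_duration_window(self):
        """Alignment peaks at intermediate t_D: OI(5) > OI(3) and OI(5) > OI(30)."""
        ois = {t: mixture_oi(StrainProtocol(0.5, t_D=t), n=100_000, seed=2).oi
               for t in (3.0, 5.0, 30.0)}
        assert ois[5.0] > ois[3.0]
        assert ois[5.0] > ois[30.0]

    def test_full_templating_approaches_pure_affine_limit(self):
        k = GelationKinetics(template_efficiency=1.0)
        # t_D with f just below f_jam = 0.6
        t_d = k.t_half + np.log(0.58 / 0.42) / k.rate
        assert gelation_fraction(t_d, k) < k.f_jam
        res = mixture_oi(StrainProtocol(0.5, t_D=t_d, kinetics=k), n=100_000, seed=3)
        pure = predicted_oi_vs_strain([0.5], n=100_000, seed=3)["oi"].iloc[0]
        assert res.oi == pytest.approx(pure, abs=0.02)

    def test_deterministic_under_seed_and_bounded_by_affine(self):
        proto = StrainProtocol(0.5, t_D=5.0)
        a = mixture_oi(proto, n=20_000, seed=9).oi
        b = mixture_oi(proto, n=20_000, seed=9).oi
        assert a == b
        pure = predicted_oi_vs_strain([0.5], n=100_000, seed=9)["oi"].iloc[0]
        assert -0.02 <= a <= pure + 0.02

    def test_duration_sweep_table(self):
        df = oi_vs_strain_duration([0.0, 5.0, 30.0], n=5000, seed=1)
        assert list(df.columns) == ["t_D", "oi", "n"]
        assert len(df) == 3


def test_protocol_validation():
    with pytest.raises(ValueError):
        StrainProtocol(delta_ratio=-1.0)
    with pytest.raises(ValueError):
        StrainProtocol(delta_ratio=0.4, t_D=-1.0)
    with pytest.raises(ValueError):
        StrainProtocol(delta_ratio=0.4, strain_axis="z")
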