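"""Covariance, ellipsoid, Frenet-frame and tube geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import gaittube as gt
from gaittube.core import ellipsoid_series, project_covariance_to_plane
from tests.conftest import random_spd, random_strides


def strideset(values):
    values = np.asarray(values, dtype=float)
    return gt.StrideSet(values=values, stride_times=np.arange(values.shape[0] + 1, dtype=float))


class TestStrideCovariance:
    def test_identical_strides_zero_covariance(self, rng):
        one = rng.normal(size=(1, 50, 3))
        cov = gt.stride_covariance(strideset(np.repeat(one, 6, axis=0)))
        assert np.allclose(cov.Sigma, 0.0)

    def test_two_stride_formula(self):
        v = np.array([3.0, -1.0, 2.0])
        values = np.stack([np.tile(v, (10, 1)), np.tile(-v, (10, 1))])
        cov = gt.stride_covariance(strideset(values))
        assert np.allclose(cov.Sigma, 2.0 * np.outer(v, v))

    def test_isotropic_monte_carlo(self, rng):
        S, sd = 5000, 10.0
        ss = random_strides(rng, S=S, T=4, sd=(sd, sd, sd))
        cov = gt.stride_covariance(ss)
        se_var = sd**2 * np.sqrt(2.0 / (S - 1))  # SE of a variance estimate
        se_cov = sd**2 / np.sqrt(S - 1)
        for t in range(4):
            diag = np.diag(cov.Sigma[t])
            off = cov.Sigma[t][~np.eye(3, dtype=bool)]
            assert np.all(np.abs(diag - sd**2) < 3 * se_var)
            assert np.all(np.abs(off) < 3 * se_cov)

    def test_single_stride_rejected(self, rng):
        with pytest.raises(ValueError):
            gt.StrideSet(values=rng.normal(size=(1, 10, 3)), stride_times=np.arange(2.0))


class TestEllipsoid:
    def test_unit_sphere(self):
        e = gt.ellipsoid_from_covariance(np.eye(3), k=1.0)
        assert np.allclose(e.semi_axes, 1.0)
        assert e.volume == pytest.approx(4.0 * np.pi / 3.0, rel=1e-12)

    def test_diagonal_case(self):
        e = gt.ellipsoid_from_covariance(np.diag([4.0, 9.0, 16.0]), k=1.0)
        assert np.allclose(e.semi_axes, [4.0, 3.0, 2.0])
        assert e.volume == pytest.approx(32.0 * np.pi, rel=1e-12)

    def test_volume_against_determinant_oracle(self, rng):
        for _ in range(200):
            S = random_spd(rng)
            e = gt.ellipsoid_from_covariance(S, k=1.0)
            sign, logdet = np.linalg.slogdet(S)
            expected = (4.0 / 3.0) * np.pi * np.exp(0.5 * logdet)
            assert sign > 0
            assert e.volume == pytest.approx(expected, rel=1e-9)

    def test_k_scaling(self, rng):
        S = random_spd(rng)
        e1 = gt.ellipsoid_from_covariance(S, k=1.0)
        e2 = gt.ellipsoid_from_covariance(S, k=2.0)
        assert np.allclose(e2.semi_axes, 2.0 * e1.semi_axes)
        assert e2.volume == pytest.approx(8.0 * e1.volume, rel=1e-12)

    def test_orientation_proper_rotation(self, rng):
        e = gt.ellipsoid_from_covariance(random_spd(rng))
        assert np.allclose(e.orientation @ e.orientation.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(e.orientation) == pytest.approx(1.0, abs=1e-10)

    def test_asymmetric_rejected(self):
        M = np.array([[1.0, 0.5, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            gt.ellipsoid_from_covariance(M)

    def test_indefinite_rejected(self):
        with pytest.raises(ValueError, match="indefinite"):
            gt.ellipsoid_from_covariance(np.diag([1.0, 1.0, -0.5]))

    def test_series_matches_pointwise(self, rng):
        ss = random_strides(rng, S=30, T=7)
        cov = gt.stride_covariance(ss)
        series = ellipsoid_series(cov, k=1.5)
        for t in range(7):
            single = gt.ellipsoid_from_covariance(cov.Sigma[t], k=1.5)
            assert np.allclose(series.semi_axes[t], single.semi_axes)
            assert series.volume[t] == pytest.approx(single.volume, rel=1e-12)


class TestDirectionalVariability:
    def test_zero_noise(self, rng):
        one = rng.normal(size=(1, 20, 3))
        sd = gt.directional_variability(strideset(np.repeat(one, 5, axis=0)))
        assert np.allclose(sd, 0.0)

    def test_consistent_with_covariance_diagonal(self, rng):
        ss = random_strides(rng, S=50, T=11)
        sd = gt.directional_variability(ss)
        Sigma = gt.stride_covariance(ss).Sigma
        assert np.allclose(sd**2, np.diagonal(Sigma, axis1=1, axis2=2), rtol=1e-12)

    def test_axis_permutation_equivariance(self, rng):
        ss = random_strides(rng, S=40, T=9, sd=(5.0, 10.0, 20.0))
        perm = [2, 0, 1]
        sd = gt.directional_variability(ss)
        sd_perm = gt.directional_variability(strideset(ss.values[:, :, perm]))
        assert np.allclose(sd_perm, sd[:, perm], rtol=1e-12)


class TestSubjectSummary:
    def test_reported_group_sd_sum(self):
        # two strides at +/- d give a sample SD of exactly sqrt(2)*d per axis
        sds = np.array([75.07, 51.58, 93.60])
        d = sds / np.sqrt(2.0)
        values = np.stack([np.tile(d, (101, 1)), np.tile(-d, (101, 1))])
        summary = gt.subject_summary(strideset(values))
        assert summary.var_ap == pytest.approx(75.07, rel=1e-12)
        assert summary.var_ml == pytest.approx(51.58, rel=1e-12)
        assert summary.var_vt == pytest.approx(93.60, rel=1e-12)
        assert summary.total_variability == pytest.approx(220.25, rel=1e-12)

    def test_zero_noise_all_zero(self, rng):
        one = rng.normal(size=(1, 30, 3))
        summary = gt.subject_summary(strideset(np.repeat(one, 4, axis=0)))
        assert summary.mean_ellipsoid_volume == 0.0
        assert summary.total_variability == 0.0

    def test_doubling_noise_scales_volume_by_8(self, rng):
        ss = random_strides(rng, S=60, T=21)
        mean = ss.values.mean(axis=0, keepdims=True)
        doubled = strideset(mean + 2.0 * (ss.values - mean))
        s1, s2 = gt.subject_summary(ss), gt.subject_summary(doubled)
        assert s2.mean_ellipsoid_volume == pytest.approx(8.0 * s1.mean_ellipsoid_volume, rel=1e-9)
        assert s2.var_ap == pytest.approx(2.0 * s1.var_ap, rel=1e-9)
        assert s2.var_vt == pytest.approx(2.0 * s1.var_vt, rel=1e-9)

    def test_diagonal_consistency_on_preset(self, control_strides):
        # near-diagonal generator covariance: cycle-mean volume tracks
        # (4/3) pi k^3 times the product of the three cycle-mean SDs
        summary = gt.subject_summary(control_strides)
        approx = (4.0 / 3.0) * np.pi * summary.var_ap * summary.var_ml * summary.var_vt
        assert summary.mean_ellipsoid_volume == pytest.approx(approx, rel=0.25)


class TestRotationInvariance:
    def test_volume_waveform_invariant_orientation_equivariant(self, rng):
        ss = random_strides(rng, S=40, T=15, sd=(5.0, 12.0, 25.0))
        R = Rotation.random(random_state=7).as_matrix()
        rotated = strideset(ss.values @ R.T)
        s1 = gt.subject_summary(ss)
        s2 = gt.subject_summary(rotated)
        assert np.allclose(s2.volume_waveform, s1.volume_waveform, rtol=1e-9)
        Sig1 = gt.stride_covariance(ss).Sigma
        Sig2 = gt.stride_covariance(rotated).Sigma
        assert np.allclose(Sig2, np.einsum("ij,tjk,lk->til", R, Sig1, R), atol=1e-9)


class TestFrenetFrames:
    def test_helix_matches_closed_form(self):
        a, b = 1.0, 0.3
        s = np.linspace(0.0, 4.0 * np.pi, 200)
        traj = np.column_stack([a * np.cos(s), a * np.sin(s), b * s])
        fr = gt.frenet_frames(traj)
        c = np.sqrt(a**2 + b**2)
        tan = np.column_stack([-a * np.sin(s), a * np.cos(s), np.full_like(s, b)]) / c
        nor = np.column_stack([-np.cos(s), -np.sin(s), np.zeros_like(s)])
        bin_ = np.column_stack([b * np.sin(s), -b * np.cos(s), np.full_like(s, a)]) / c
        for got, exact in [(fr.tangent, tan), (fr.normal, nor), (fr.binormal, bin_)]:
            cosang = np.clip(np.sum(got * exact, axis=1), -1.0, 1.0)
            assert np.degrees(np.arccos(cosang)).max() < 1.0
        assert not fr.degenerate_flags.any()

    def test_straight_line_degenerate_fallback(self):
        traj = np.outer(np.linspace(0, 1, 50), [1.0, 2.0, 3.0])
        fr = gt.frenet_frames(traj)
        assert fr.degenerate_flags.all()
        assert np.ptp(fr.normal, axis=0).max() < 1e-12  # constant fallback frame

    @pytest.mark.parametrize("case", ["helix", "line", "loop", "noisy"])
    def test_orthonormality_contract(self, case, rng):
        s = np.linspace(0, 2 * np.pi, 120)
        traj = {
            "helix": np.column_stack([np.cos(s), np.sin(s), 0.2 * s]),
            "line": np.outer(s, [1.0, -1.0, 0.5]),
            "loop": np.column_stack([np.cos(s), np.sin(2 * s), np.sin(s)]),
            "noisy": np.cumsum(rng.normal(size=(120, 3)), axis=0) + np.outer(s, [5, 0, 0]),
        }[case]
        fr = gt.frenet_frames(traj)
        for v in (fr.tangent, fr.normal, fr.binormal):
            assert np.abs(np.linalg.norm(v, axis=1) - 1.0).max() < 1e-8
        assert np.abs(np.sum(fr.tangent * fr.normal, axis=1)).max() < 1e-8
        assert np.abs(np.sum(fr.tangent * fr.binormal, axis=1)).max() < 1e-8
        assert np.abs(np.sum(fr.normal * fr.binormal, axis=1)).max() < 1e-8

    def test_tangent_aligned_with_derivative(self):
        s = np.linspace(0, 2 * np.pi, 100)
        traj = np.column_stack([np.cos(s), np.sin(s), 0.1 * s])
        fr = gt.frenet_frames(traj)
        d1 = np.gradient(traj, axis=0, edge_order=2)
        dots = np.sum(fr.tangent * (d1 / np.linalg.norm(d1, axis=1, keepdims=True)), axis=1)
        assert dots.min() > 1.0 - 1e-10


class TestProjection:
    def test_identity_gives_unit_circle(self):
        frame = np.eye(3)
        e = project_covariance_to_plane(np.eye(3), frame)
        assert np.allclose(e.semi_axes, 1.0)

    def test_axis_aligned_plane(self):
        # plane spanned by axes 2 and 3 of diag(4, 9, 16): semi-axes (4, 3)
        frame = np.array([[1.0, 0, 0], [0, 0, 1.0], [0, 1.0, 0]])
        e = project_covariance_to_plane(np.diag([4.0, 9.0, 16.0]), frame)
        assert np.allclose(e.semi_axes, [4.0, 3.0])

    def test_sampling_oracle(self, rng):
        Sigma = random_spd(rng, scale=3.0)
        fr = gt.frenet_frames(
            np.column_stack(
                [np.cos(np.linspace(0, 6, 50)), np.sin(np.linspace(0, 6, 50)),
                 np.linspace(0, 2, 50)]
            )
        )
        frame = np.stack([fr.tangent[25], fr.normal[25], fr.binormal[25]])
        e = project_covariance_to_plane(Sigma, frame, k=1.0)
        n = 100_000
        samples = rng.multivariate_normal(np.zeros(3), Sigma, size=n) @ frame[1:].T
        emp = np.cov(samples.T)
        C = frame[1:] @ Sigma @ frame[1:].T
        se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / n)
        assert np.all(np.abs(emp - C) < 3 * se)
        assert e.semi_axes[0] == pytest.approx(np.sqrt(np.linalg.eigvalsh(C)[1]), rel=1e-12)

    def test_non_orthonormal_frame_rejected(self):
        frame = np.eye(3)
        frame[1, 0] = 0.3
        with pytest.raises(ValueError, match="orthonormal"):
            project_covariance_to_plane(np.eye(3), frame)


class TestSmoothWaveform:
    def test_constant_unchanged(self):
        x = np.full(101, 3.7)
        for w in (0, 5, 25, 100):
            assert np.allclose(gt.smooth_waveform(x, w), 3.7)

    def test_zero_window_identity(self, rng):
        x = rng.normal(size=101)
        assert np.array_equal(gt.smooth_waveform(x, 0), x)

    def test_impulse_spread_preserves_sum(self):
        x = np.zeros(101)
        x[50] = 1.0
        y = gt.smooth_waveform(x, 5)  # 5-point kernel at T=101
        assert np.allclose(y[48:53], 0.2)
        assert y.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.allclose(np.delete(y, range(48, 53)), 0.0)

    def test_circular_boundary(self):
        x = np.zeros(100)
        x[0] = 1.0
        y = gt.smooth_waveform(x, 5)
        assert y[-1] > 0  # wraps around the cycle
        assert y.sum() == pytest.approx(1.0, rel=1e-12)

    def test_window_above_100_rejected(self):
        with pytest.raises(ValueError):
            gt.smooth_waveform(np.zeros(101), 101)


class TestBuildGaitTube:
    def test_zero_noise_zero_area(self, rng):
        base = np.column_stack(
            [np.cos(np.linspace(0, 2 * np.pi, 101)),
             np.sin(np.linspace(0, 2 * np.pi, 101)),
             np.sin(2 * np.linspace(0, 2 * np.pi, 101))]
        ) * 100.0
        tube = gt.build_gait_tube(strideset(np.repeat(base[None], 5, axis=0)))
        assert np.allclose(tube.cross_section_areas, 0.0, atol=1e-12)
        assert np.allclose(tube.mean_trajectory, base)

    def test_isotropic_noise_circular_sections(self, rng):
        base = np.column_stack(
            [np.cos(np.linspace(0, 2 * np.pi, 101)),
             np.sin(np.linspace(0, 2 * np.pi, 101)),
             np.sin(2 * np.linspace(0, 2 * np.pi, 101))]
        ) * 500.0
        sigma = 10.0
        values = base[None] + rng.normal(size=(800, 101, 3)) * sigma
        tube = gt.build_gait_tube(strideset(values), k=1.0, window=5.0)
        radii = np.array([e.semi_axes for e in tube.cross_sections])
        assert np.abs(radii / sigma - 1.0).max() < 0.15  # near-circular, radius ~ k*sigma
        areas = tube.cross_section_areas
        assert np.all(np.abs(areas / (np.pi * sigma**2) - 1.0) < 0.25)

    def test_projected_area_bounded_by_largest_axes(self, rng):
        ss = random_strides(rng, S=60, T=31, sd=(5.0, 12.0, 25.0))
        tube = gt.build_gait_tube(ss, window=0.0)
        ell = ellipsoid_series(gt.stride_covariance(ss))
        bound = np.pi * ell.semi_axes[:, 0] * ell.semi_axes[:, 1]
        assert np.all(tube.cross_section_areas <= bound * (1 + 1e-9))

    def test_group_ordering_control_vs_pad(self):
        ctrl = gt.generate_trial(gt.control_profile(stride_time_cv=0.0), 200, seed=3)
        pad = gt.generate_trial(gt.pad_profile(stride_time_cv=0.0), 200, seed=4)
        tubes = {}
        for name, trial in (("control", ctrl), ("pad", pad)):
            ss = gt.strides_from_trial(trial.markers, trial.vgrf)
            tubes[name] = gt.build_gait_tube(ss)
        assert np.all(
            tubes["control"].cross_section_areas > tubes["pad"].cross_section_areas
        )


class TestGroupMeanWaveforms:
    def test_single_subject(self, rng):
        w = rng.normal(size=101)
        mean, sd = gt.group_mean_waveforms([w])
        assert np.array_equal(mean, w)
        assert np.allclose(sd, 0.0)

    def test_opposite_waveforms_cancel(self, rng):
        w = rng.normal(size=(101, 3))
        mean, _ = gt.group_mean_waveforms([w, -w])
        assert np.allclose(mean, 0.0)

    def test_band_sd_matches_noise_sd(self, rng):
        s = 4.0
        waves = rng.normal(size=(400, 101)) * s
        _, sd = gt.group_mean_waveforms(list(waves))
        se = s / np.sqrt(2 * (400 - 1))
        assert np.abs(sd.mean() - s) < 3 * se

    def test_mismatched_shapes_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatched"):
            gt.group_mean_waveforms([np.zeros(101), np.zeros(99)])
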