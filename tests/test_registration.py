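import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from shapecloud.cloud import RigidTransform, apply_transform, voxel_downsample
from shapecloud.errors import ContractError, DegenerateGeometryError
from shapecloud.features import compute_fpfh
from shapecloud.fixtures import symmetric_color_toy
from shapecloud.registration import (
    ColorICPParams,
    GlobalParams,
    color_gradient,
    colored_icp,
    global_registration,
    icp_cost,
    kabsch,
)
from shapecloud.surface import ColoredPointCloud


class TestKabsch:
    def test_identity_on_equal_sets(self, rng):
        P = rng.normal(size=(10, 3))
        T = kabsch(P, P)
        assert np.allclose(T.matrix, np.eye(4), atol=1e-10)

    def test_exact_recovery(self, rng):
        P = rng.normal(size=(8, 3))
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-5, 5, 3)
        T = kabsch(P, P @ R.T + t)
        assert np.allclose(T.rotation, R, atol=1e-9)
        assert np.allclose(T.translation, t, atol=1e-9)
        resid = T.apply(P) - (P @ R.T + t)
        assert np.sqrt(np.mean(resid**2)) < 1e-9

    def test_collinear_rejected(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            kabsch(P, P[::-1])

    def test_matches_rotation_grid_search_oracle(self, rng):
        # brute-force minimum over a coarse rotation grid on a noisy 4-point toy
        P = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.0, 0], [0.3, 0.4, 1.2]])
        Rtrue = Rotation.from_euler("zyx", [25, -40, 65], degrees=True).as_matrix()
        Q = P @ Rtrue.T + [1.0, -2.0, 0.5] + rng.normal(scale=0.05, size=P.shape)

        T = kabsch(P, Q)
        rmsd_kabsch = np.sqrt(np.mean(np.sum((T.apply(P) - Q) ** 2, axis=1)))

        step = 6
        full = np.arange(0, 360, step)
        half = np.arange(-90, 90 + step, step)  # Tait-Bryan middle angle
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        grid = np.deg2rad(
            np.stack([m.ravel() for m in np.meshgrid(full, half, full)], -1)
        )
        mats = Rotation.from_euler("zyx", grid).as_matrix()
        moved = np.einsum("bij,mj->bmi", mats, Pc)
        rmsds = np.sqrt(np.mean(np.sum((moved - Qc) ** 2, axis=2), axis=1))
        best = rmsds.min()
        assert rmsd_kabsch <= best + 1e-12
        # the grid optimum approaches the analytic optimum at grid resolution
        assert best - rmsd_kabsch < 0.2


def _fpfh_for(cloud, vs):
    return compute_fpfh(cloud, radius=5 * vs)


class TestGlobalRegistration:
    def test_recovers_large_rotation(self, sorbic_cloud, rng):
        vs = 0.5
        tgt = voxel_downsample(sorbic_cloud, vs)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        T = RigidTransform.from_rotation_translation(
            Rotation.from_rotvec(np.deg2rad(120) * axis).as_matrix(), [3.0, -1.0, 2.0]
        )
        src = apply_transform(tgt, T)
        res = global_registration(
            src, tgt, _fpfh_for(src, vs), _fpfh_for(tgt, vs), GlobalParams(vs=vs, seed=5)
        )
        assert res.success
        assert res.rmse < vs

    def test_proximity_threshold_is_vs_times_1_5(self):
        assert GlobalParams(vs=0.5).max_corr_dist == pytest.approx(0.75)

    def test_uniform_scaling_fails_edge_check(self, sorbic_cloud):
        # a 1.2x scaled copy violates the 10% edge-length tolerance everywhere
        vs = 0.5
        tgt = voxel_downsample(sorbic_cloud, vs)
        scaled = tgt.copy()
        scaled.positions = scaled.positions * 1.2
        res = global_registration(
            scaled, tgt, _fpfh_for(scaled, vs), _fpfh_for(tgt, vs),
            GlobalParams(vs=vs, seed=3, max_iterations=20000),
        )
        assert not res.success
        assert res.n_validations == 0

    def test_seeded_bit_reproducibility(self, sorbic_cloud):
        vs = 0.6
        tgt = voxel_downsample(sorbic_cloud, vs)
        src = apply_transform(
            tgt, RigidTransform.from_rotation_translation(
                Rotation.from_euler("y", 70, degrees=True).as_matrix(), [1, 2, 3]
            )
        )
        fs, ft = _fpfh_for(src, vs), _fpfh_for(tgt, vs)
        r1 = global_registration(src, tgt, fs, ft, GlobalParams(vs=vs, seed=42))
        r2 = global_registration(src, tgt, fs, ft, GlobalParams(vs=vs, seed=42))
        assert np.array_equal(r1.transform.matrix, r2.transform.matrix)
        assert r1.rmse == r2.rmse


class TestColorGradient:
    def _plane(self, colors=None):
        xs, ys = np.meshgrid(np.linspace(-1, 1, 9), np.linspace(-1, 1, 9))
        pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(81)])
        n = len(pts)
        if colors is None:
            colors = np.zeros(n)
        return ColoredPointCloud(
            pts, np.ones(n, int), np.asarray(colors, float),
            np.tile([0, 0, 1.0], (n, 1)), np.arange(n),
        )

    def test_uniform_color_zero_gradient(self):
        cloud = self._plane(np.full(81, 0.5))
        assert np.allclose(color_gradient(cloud, 0.6), 0.0)

    def test_linear_ramp_recovers_direction(self):
        cloud = self._plane()
        cloud.color = 0.5 + 0.3 * cloud.positions[:, 0]  # ramp along +x
        g = color_gradient(cloud, 0.6)
        interior = np.abs(cloud.positions[:, :2]).max(axis=1) < 0.7
        gi = g[interior]
        cos = gi[:, 0] / np.linalg.norm(gi, axis=1)
        assert np.all(cos > np.cos(np.deg2rad(5)))

    def test_gradients_orthogonal_to_normals(self, sorbic_cloud):
        reduced = voxel_downsample(sorbic_cloud, 0.5)
        g = color_gradient(reduced, 1.0)
        assert np.max(np.abs(np.einsum("ij,ij->i", g, reduced.normal))) < 1e-8


class TestColoredICP:
    def _params(self, vs=0.5):
        return ColorICPParams(max_corr_dist=1.5 * vs, gradient_radius=2 * vs)

    def test_fixed_point(self, sorbic_cloud):
        r = voxel_downsample(sorbic_cloud, 0.5)
        res = colored_icp(r, r, RigidTransform.identity(), self._params())
        assert res.n_iterations <= 2
        assert np.abs(res.transform.matrix - np.eye(4)).max() < 1e-6
        assert res.rmse < 1e-9

    def test_recovers_small_offset(self, sorbic_cloud):
        r = voxel_downsample(sorbic_cloud, 0.5)
        T0 = RigidTransform.from_rotation_translation(np.eye(3), [0.15, 0.0, 0.0])
        src = apply_transform(r, T0)
        res = colored_icp(src, r, RigidTransform.identity(), self._params())
        assert np.allclose(res.transform.translation, [-0.15, 0, 0], atol=1e-6)
        assert res.rmse < 0.15  # improved on the initial misfit

    def test_no_correspondence_returns_init(self, sorbic_cloud):
        r = voxel_downsample(sorbic_cloud, 0.5)
        far = apply_transform(
            r, RigidTransform.from_rotation_translation(np.eye(3), [100, 0, 0])
        )
        res = colored_icp(far, r, RigidTransform.identity(), self._params())
        assert not res.success
        assert np.array_equal(res.transform.matrix, np.eye(4))

    def test_never_worse_than_global_on_fixture(self, sorbic_cloud, rng):
        vs = 0.5
        tgt = voxel_downsample(sorbic_cloud, vs)
        src = apply_transform(tgt, RigidTransform.random(rng))
        fs, ft = _fpfh_for(src, vs), _fpfh_for(tgt, vs)
        g = global_registration(src, tgt, fs, ft, GlobalParams(vs=vs, seed=9))
        assert g.success
        c = colored_icp(src, tgt, g.transform, self._params(vs))
        assert c.rmse <= g.rmse + 1e-9

    def test_color_breaks_geometric_symmetry(self):
        toy = symmetric_color_toy(separation=0.25, seed=3)
        params = ColorICPParams(max_corr_dist=0.4, gradient_radius=0.6)
        e_true = icp_cost(toy.source, toy.target, toy.true_transform, params)
        e_flip = icp_cost(toy.source, toy.target, toy.flipped_transform, params)
        assert e_true < e_flip

    def test_equivariance_of_final_geometry(self, sorbic_cloud, rng):
        # pre-rotating the source changes the returned transform, not the
        # superposed geometry
        vs = 0.5
        tgt = voxel_downsample(sorbic_cloud, vs)
        src = apply_transform(tgt, RigidTransform.random(rng))
        pre = RigidTransform.random(rng)
        src2 = apply_transform(src, pre)

        def final_positions(s):
            fs, ft = _fpfh_for(s, vs), _fpfh_for(tgt, vs)
            g = global_registration(s, tgt, fs, ft, GlobalParams(vs=vs, seed=17))
            c = colored_icp(s, tgt, g.transform, self._params(vs))
            return c.transform.apply(s.positions)

        p1 = final_positions(src)
        p2 = final_positions(src2)  # same physical points, pre-rotated input
        assert np.allclose(p1, p2, atol=1e-6)
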