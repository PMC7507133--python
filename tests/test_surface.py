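import numpy as np
import pytest
from scipy.spatial import cKDTree

from shapecloud import build_surface_cloud, read_cloud, sphere_dots, write_cloud
from shapecloud.chemio import Atom, Molecule
from shapecloud.cloud import RigidTransform
from shapecloud.errors import ContractError
from shapecloud.fixtures import FIXTURE_NAMES, load_fixture
from shapecloud.surface import dots_for_radius


class TestSphereDots:
    def test_all_points_on_sphere(self):
        dots = sphere_dots([1.0, -2.0, 0.5], 1.7, 600)
        assert dots.shape == (600, 3)
        r = np.linalg.norm(dots - [1.0, -2.0, 0.5], axis=1)
        assert np.allclose(r, 1.7, atol=1e-9)

    def test_single_dot(self):
        dots = sphere_dots([0, 0, 0], 2.0, 1)
        assert dots.shape == (1, 3)
        assert np.isclose(np.linalg.norm(dots[0]), 2.0)

    def test_spacing_matches_area_per_dot_estimate(self):
        # quasi-uniform lattice: nearest-dot spacing ~ sqrt(4*pi*r^2/n)
        dots = sphere_dots([0, 0, 0], 1.7, 600)
        d, _ = cKDTree(dots).query(dots, k=2)
        est = np.sqrt(4 * np.pi * 1.7**2 / 600)
        assert abs(d[:, 1].mean() - est) < 0.3 * est

    def test_invalid_arguments(self):
        with pytest.raises(ContractError):
            sphere_dots([0, 0, 0], -1.0, 10)
        with pytest.raises(ContractError):
            sphere_dots([0, 0, 0], 1.0, 0)


def _bare_molecule(elements, positions, radius, cls):
    m = Molecule("toy", [Atom(e, p) for e, p in zip(elements, positions)])
    for a in m.atoms:
        a.radius = radius
        a.cls = cls
    return m


class TestBuildSurface:
    def test_isolated_atom_keeps_every_dot(self):
        mol = _bare_molecule(["H"], [[0, 0, 0]], 1.2, 1)
        cloud = build_surface_cloud(mol)
        assert len(cloud) == dots_for_radius(1.2)
        outward = np.einsum("ij,ij->i", cloud.normal, cloud.positions)
        assert np.all(outward > 0)

    @pytest.mark.parametrize("d_over_2r", [0.3, 0.6, 0.9])
    def test_two_sphere_cap_fraction(self, d_over_2r):
        # exposed fraction of each of two equal spheres at distance d is the
        # spherical-cap area fraction (1 + d/2r) / 2
        r = 1.7
        d = d_over_2r * 2 * r
        mol = _bare_molecule(["C", "C"], [[0, 0, 0], [d, 0, 0]], r, 3)
        cloud = build_surface_cloud(mol, dots_per_atom=1200)
        n_dots = dots_for_radius(r, 1200)
        expected = (1 + d_over_2r) / 2
        for atom in (0, 1):
            frac = np.sum(cloud.parent == atom) / n_dots
            assert abs(frac - expected) < 0.03

    def test_points_on_parent_sphere_and_outside_others(self, sorbic, sorbic_cloud):
        centers, radii = sorbic.positions, sorbic.radii
        on_sphere = np.linalg.norm(
            sorbic_cloud.positions - centers[sorbic_cloud.parent], axis=1
        )
        assert np.allclose(on_sphere, radii[sorbic_cloud.parent], atol=1e-9)
        for j in range(len(sorbic)):
            d = np.linalg.norm(sorbic_cloud.positions - centers[j], axis=1)
            other = sorbic_cloud.parent != j
            assert np.all(d[other] >= radii[j] - 1e-6)

    def test_deterministic(self, sorbic):
        c1 = build_surface_cloud(sorbic)
        c2 = build_surface_cloud(sorbic)
        assert np.array_equal(c1.positions, c2.positions)
        assert np.array_equal(c1.cls, c2.cls)
        assert np.array_equal(c1.normal, c2.normal)

    def test_rigid_equivariance(self, sorbic, sorbic_cloud, rng):
        T = RigidTransform.random(rng)
        moved = sorbic.copy()
        for a, p in zip(moved.atoms, T.apply(sorbic.positions)):
            a.position = p
        cloud_moved = build_surface_cloud(moved)
        # the dot lattice is world-axis anchored, so burial at sphere seams
        # may differ by a few dots; counts agree only statistically
        assert abs(len(cloud_moved) - len(sorbic_cloud)) <= 0.01 * len(sorbic_cloud)
        d1, _ = cKDTree(sorbic_cloud.positions).query(sorbic_cloud.positions, k=2)
        d2, _ = cKDTree(cloud_moved.positions).query(cloud_moved.positions, k=2)
        assert abs(d1[:, 1].mean() - d2[:, 1].mean()) < 0.01

    def test_mean_spacing_of_fixture_surfaces(self):
        # full-resolution surfaces sit near the 0.3 A adjacent-point spacing
        for name in FIXTURE_NAMES:
            cloud = build_surface_cloud(load_fixture(name))
            d, _ = cKDTree(cloud.positions).query(cloud.positions, k=2)
            assert 0.2 <= d[:, 1].mean() <= 0.4, name

    def test_classes_follow_parent_atoms(self, sorbic, sorbic_cloud):
        assert np.array_equal(sorbic_cloud.cls, sorbic.classes[sorbic_cloud.parent])


class TestCloudIO:
    @pytest.mark.parametrize("dialect,binary", [("ply", False), ("ply", True), ("xyzc", False)])
    def test_roundtrip(self, tmp_path, sorbic_cloud, dialect, binary):
        path = tmp_path / f"c.{dialect}"
        write_cloud(sorbic_cloud, path, dialect=dialect, binary=binary)
        back = read_cloud(path)
        assert len(back) == len(sorbic_cloud)
        assert np.array_equal(back.cls, sorbic_cloud.cls)
        tol = 1e-4 if binary else 1e-6
        assert np.allclose(back.positions, sorbic_cloud.positions, atol=tol)
        assert np.allclose(back.normal, sorbic_cloud.normal, atol=1e-3 if binary else 1e-5)

    def test_ply_class_color_map(self, tmp_path):
        cloud = build_surface_cloud(_bare_molecule(["O"], [[0, 0, 0]], 1.52, 2))
        path = tmp_path / "o.ply"
        write_cloud(cloud, path, dialect="ply")
        text = path.read_text()
        assert "255 0 0" in text  # polar class renders red
        cloud1 = build_surface_cloud(_bare_molecule(["H"], [[0, 0, 0]], 1.2, 1))
        write_cloud(cloud1, path, dialect="ply")
        assert "255 255 255" in path.read_text()  # apolar renders white

    def test_malformed_file_raises(self, tmp_path):
        p = tmp_path / "bad.ply"
        p.write_text("ply\nformat ascii 1.0\nelement vertex 1\n")
        with pytest.raises(Exception):
            read_cloud(p)
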