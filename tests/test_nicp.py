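"""NICP registration: initialization, fixpoint, recovery, averaging."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from facemark import (
    AtlasLandmarkIndices,
    FixtureSpec,
    TriangleMesh,
    affine_init,
    apply_rigid,
    average_atlas,
    landmarks_from_atlas,
    make_face_fixture,
    nicp_register,
    rigid_align,
)
from facemark.landmarks import LandmarkSet3D
from facemark.nicp import NICPConfig, apply_affine
from facemark.proximity import SurfaceLocator

IDENTITY_AFFINE = np.hstack([np.eye(3), np.zeros((3, 1))])


def mean_symmetric_distance(verts_a, tris_a, mesh_b):
    _, d1, _ = SurfaceLocator(mesh_b).closest(verts_a)
    _, d2, _ = SurfaceLocator(TriangleMesh(verts_a, tris_a)).closest(mesh_b.vertices)
    return 0.5 * (d1.mean() + d2.mean())


def assert_energy_non_increasing(history):
    for _, group in itertools.groupby(history, key=lambda h: h[0]):
        energies = [h[2] for h in group]
        for a, b in zip(energies, energies[1:]):
            assert b <= a + 1e-9 * max(abs(a), 1.0)


class TestAffineInit:
    def test_exact_affine_recovery(self, coarse_fixture):
        _, lm = coarse_fixture
        rng = np.random.default_rng(0)
        a0 = np.hstack([np.eye(3) + rng.normal(size=(3, 3)) * 0.1,
                        rng.normal(size=(3, 1)) * 20])
        target = LandmarkSet3D.from_array(apply_affine(a0, lm.to_array()))
        assert np.allclose(affine_init(lm, target), a0, atol=1e-9)

    def test_identity_on_equal_landmarks(self, coarse_fixture):
        _, lm = coarse_fixture
        assert np.allclose(affine_init(lm, lm), IDENTITY_AFFINE, atol=1e-9)

    def test_coplanar_configuration_rejected(self):
        rng = np.random.default_rng(1)
        flat = rng.normal(size=(12, 3))
        flat[:, 2] = 0.0
        lm = LandmarkSet3D.from_array(flat)
        with pytest.raises(ValueError, match="coplanar|degenerate"):
            affine_init(lm, lm)

    def test_local_optimality_under_noise(self, coarse_fixture):
        """The least-squares solution beats 1000 random perturbations."""
        _, lm = coarse_fixture
        rng = np.random.default_rng(2)
        target = LandmarkSet3D.from_array(lm.to_array() + rng.normal(size=(12, 3)) * 2)
        sol = affine_init(lm, target)
        best = np.sum((apply_affine(sol, lm.to_array()) - target.to_array()) ** 2)
        for _ in range(1000):
            perturbed = sol + rng.normal(size=(3, 4)) * 0.01
            ssd = np.sum((apply_affine(perturbed, lm.to_array()) - target.to_array()) ** 2)
            assert ssd >= best - 1e-9


class TestNICPRegister:
    def test_self_registration_fixpoint(self, coarse_fixture):
        atlas, _ = coarse_fixture
        result = nicp_register(atlas, atlas, IDENTITY_AFFINE)
        displacement = np.linalg.norm(result.deformed_vertices - atlas.vertices, axis=1)
        assert displacement.mean() < 0.01
        assert_energy_non_increasing(result.history)

    def test_rigid_target_recovery(self, medium_fixture):
        """Affine init + NICP recover a rigidly moved ~2.5k-vertex target."""
        atlas, atlas_lm = medium_fixture
        rot = Rotation.from_euler("zyx", [12, 25, -8], degrees=True).as_matrix()
        target, target_lm = apply_rigid(atlas, atlas_lm, rot, np.array([25.0, -10.0, 40.0]))
        result = nicp_register(atlas, target, affine_init(atlas_lm, target_lm))
        dist = mean_symmetric_distance(result.deformed_vertices, atlas.triangles, target)
        assert dist < 0.1
        assert_energy_non_increasing(result.history)

    def test_improves_on_affine_alone(self, coarse_fixture):
        """Registration onto a smoothly bump-deformed copy ends closer to
        the target surface than the affine initialization."""
        atlas, atlas_lm = coarse_fixture
        units = atlas.vertices / np.linalg.norm(atlas.vertices, axis=1, keepdims=True)
        bump = 8.0 * np.exp(-np.sum((atlas.vertices - [30, 40, 40]) ** 2, axis=1) / (2 * 30**2))
        target = TriangleMesh(atlas.vertices + bump[:, None] * units,
                              atlas.triangles.copy())
        target_lm = atlas_lm  # same nominal positions; init is near-identity
        init = affine_init(atlas_lm, target_lm)
        after_init = mean_symmetric_distance(
            apply_affine(init, atlas.vertices), atlas.triangles, target)
        result = nicp_register(atlas, target, init)
        after_nicp = mean_symmetric_distance(
            result.deformed_vertices, atlas.triangles, target)
        assert after_nicp < after_init

    def test_rigid_equivariance(self, coarse_fixture):
        """Moving atlas-init and target by a common rigid motion moves the
        registration result the same way."""
        atlas, atlas_lm = coarse_fixture
        rng = np.random.default_rng(4)
        units = atlas.vertices / np.linalg.norm(atlas.vertices, axis=1, keepdims=True)
        wobble = 3.0 * np.cos(atlas.vertices @ rng.normal(size=3) * 0.02)
        target = TriangleMesh(atlas.vertices + wobble[:, None] * units, atlas.triangles.copy())
        base = nicp_register(atlas, target, IDENTITY_AFFINE)

        rot = Rotation.from_euler("xyz", [30, -20, 10], degrees=True).as_matrix()
        tr = np.array([12.0, 7.0, -20.0])
        moved_target = target.transformed(rot, tr)
        moved_init = np.hstack([rot, tr[:, None]])
        moved = nicp_register(atlas, moved_target, moved_init)
        expected = base.deformed_vertices @ rot.T + tr
        gap = np.linalg.norm(moved.deformed_vertices - expected, axis=1)
        assert gap.mean() < 0.05

    def test_solver_energy_is_inner_minimum(self, coarse_fixture):
        """The sparse solve attains the global minimum of the quadratic at
        fixed correspondences: random perturbations never do better."""
        atlas, _ = coarse_fixture
        config = NICPConfig(stiffness_schedule=(5.0,), max_inner_iter=1)
        result = nicp_register(atlas, atlas, IDENTITY_AFFINE, config)
        # rebuild the energy at the solved correspondences (= atlas itself)
        import scipy.sparse as sp
        from facemark.nicp import _mesh_edges
        n = atlas.n_vertices
        vh = np.hstack([atlas.vertices, np.ones((n, 1))])
        edges = _mesh_edges(atlas.triangles)
        loc = SurfaceLocator(atlas)

        def energy(x):
            deformed = np.einsum("ni,nij->nj", vh, x.reshape(n, 4, 3))
            u, _, _ = loc.closest(deformed)
            data = np.sum((deformed - u) ** 2)
            diff = x.reshape(n, 4, 3)[edges[:, 0]] - x.reshape(n, 4, 3)[edges[:, 1]]
            return data + 5.0 * np.sum(diff ** 2)

        x_star = np.zeros((n, 4, 3))
        x_star[:, :3, :] = result.transforms[:, :, :3].transpose(0, 2, 1)
        x_star[:, 3, :] = result.transforms[:, :, 3]
        e_star = energy(x_star.reshape(-1))
        rng = np.random.default_rng(5)
        for _ in range(100):
            assert energy((x_star + rng.normal(size=x_star.shape) * 1e-3).reshape(-1)) \
                >= e_star - 1e-6 * max(e_star, 1.0)

    def test_disconnected_atlas_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0],
                          [10, 10, 10], [11, 10, 10], [10, 11, 10]], float)
        tris = np.array([[0, 1, 2], [3, 4, 5]])
        mesh = TriangleMesh(verts, tris)
        with pytest.raises(ValueError, match="connected"):
            nicp_register(mesh, mesh, IDENTITY_AFFINE)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NICPConfig(stiffness_schedule=(1.0, 5.0))
        with pytest.raises(ValueError):
            NICPConfig(gamma=0.0)


class TestLandmarksFromAtlas:
    def test_identity_transforms_return_atlas_vertices(self, coarse_fixture):
        atlas, atlas_lm = coarse_fixture
        idx = AtlasLandmarkIndices.from_landmarks(atlas, atlas_lm)
        result = nicp_register(atlas, atlas, IDENTITY_AFFINE)
        lm = landmarks_from_atlas(result, idx)
        assert set(lm) == set(atlas_lm)
        for name in lm:
            assert np.linalg.norm(lm[name] - atlas.vertices[idx[name]]) < 0.01

    def test_rigid_recovery_moves_landmarks(self, coarse_fixture):
        atlas, atlas_lm = coarse_fixture
        idx = AtlasLandmarkIndices.from_landmarks(atlas, atlas_lm)
        rot = Rotation.from_euler("y", 18, degrees=True).as_matrix()
        tr = np.array([5.0, 2.0, -8.0])
        target, target_lm = apply_rigid(atlas, atlas_lm, rot, tr)
        result = nicp_register(atlas, target, affine_init(atlas_lm, target_lm))
        lm = landmarks_from_atlas(result, idx)
        expected = atlas.vertices[[idx[n] for n in lm]] @ rot.T + tr
        assert np.linalg.norm(lm.to_array() - expected, axis=1).max() < 0.1

    def test_out_of_range_index_rejected(self, coarse_fixture):
        atlas, atlas_lm = coarse_fixture
        result = nicp_register(atlas, atlas, IDENTITY_AFFINE)
        bad = dict.fromkeys(list(atlas_lm), 10**7)
        with pytest.raises((IndexError, ValueError)):
            landmarks_from_atlas(result, AtlasLandmarkIndices(bad))


class TestAverageAtlas:
    def test_identical_inputs_returned(self, coarse_fixture):
        mesh, _ = coarse_fixture
        avg = average_atlas([mesh.copy(), mesh.copy(), mesh.copy()])
        rot, tr = rigid_align(avg.vertices, mesh.vertices)
        assert np.linalg.norm(avg.vertices @ rot.T + tr - mesh.vertices, axis=1).max() < 1e-6

    def test_symmetric_pair_averages_to_midpoint(self, coarse_fixture):
        mesh, _ = coarse_fixture
        units = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
        delta = 2.0 * np.cos(mesh.vertices[:, 1] * 0.05)[:, None] * units
        plus = TriangleMesh(mesh.vertices + delta, mesh.triangles.copy())
        minus = TriangleMesh(mesh.vertices - delta, mesh.triangles.copy())
        avg = average_atlas([plus, minus])
        rot, tr = rigid_align(avg.vertices, mesh.vertices)
        assert np.linalg.norm(avg.vertices @ rot.T + tr - mesh.vertices, axis=1).max() < 1e-6

    def test_rigid_scatter_recovers_shape(self, coarse_fixture):
        mesh, truth = coarse_fixture
        rng = np.random.default_rng(6)
        copies = []
        for _ in range(5):
            rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
            moved, _ = apply_rigid(mesh, truth, rot, rng.normal(size=3) * 30)
            copies.append(moved)
        avg = average_atlas(copies)
        rot, tr = rigid_align(avg.vertices, mesh.vertices)
        assert np.linalg.norm(avg.vertices @ rot.T + tr - mesh.vertices, axis=1).max() < 1e-6

    def test_topology_mismatch_rejected(self, coarse_fixture):
        mesh, _ = coarse_fixture
        other = TriangleMesh(mesh.vertices[:10], [[0, 1, 2]])
        with pytest.raises(ValueError, match="topology"):
            average_atlas([mesh, other])
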