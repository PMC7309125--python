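"""Non-rigid iterative closest point (NICP) surface registration.

The comparison method for sparse landmarking: a facial atlas mesh is
deformed onto a subject scan with one affine transform per atlas vertex,
regularized by penalizing differences between transforms of adjacent
vertices (the locally-affine assumption), annealed over a decreasing
stiffness schedule.  After registration, atlas vertices of known anatomy
are read off as landmarks.

Per stiffness value α the energy minimized is

    E(X) = Σ_i w_i ||X_i v̂_i − u_i||²  +  α Σ_(i,j)∈edges ||(X_i − X_j) G||²_F

with v̂_i the homogeneous (affine-initialized) atlas vertex, u_i the
closest compatible point on the target, w_i ∈ {0, 1} the correspondence
weight, and G = diag(1, 1, 1, γ) weighting the translational column.
Closest-point assignment alternates with an exact sparse linear
least-squares solve for all X_i, so the energy is non-increasing within
an inner loop at fixed correspond­ence weights.

Landmarks initialize the registration (a least-squares affine fit between
atlas and subject landmarks) but by default do not appear in the energy;
a guide-point term is available for atlas-building workflows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .landmarks import LANDMARK_NAMES, LandmarkSet3D
from .mesh import TriangleMesh
from .morphometrics import rigid_align
from .proximity import SurfaceLocator

__all__ = [
    "NICPConfig",
    "DeformedAtlas",
    "AtlasLandmarkIndices",
    "affine_init",
    "nicp_register",
    "landmarks_from_atlas",
    "average_atlas",
]


def _default_schedule() -> tuple[float, ...]:
    return tuple(np.geomspace(50.0, 1.0, 8))


@dataclass(frozen=True)
class NICPConfig:
    """NICP hyperparameters.

    The stiffness schedule anneals from rigid-ish (50) to compliant (1)
    over 8 geometric steps; γ weighs the translational column of each
    per-vertex affine against its linear part (1 ⇒ millimetre translations
    and unit-less linear coefficients are penalized alike, appropriate at
    facial scale).  Correspondences are rejected beyond 20 mm, beyond 60°
    normal disagreement, or (optionally) when they land on the target
    border.  These are conventional values; the recovery and fixpoint
    behavior of the algorithm is robust to them.
    """

    stiffness_schedule: tuple[float, ...] = field(default_factory=_default_schedule)
    gamma: float = 1.0
    max_inner_iter: int = 10
    inner_tol: float = 1e-4
    max_normal_angle_deg: float = 60.0
    max_distance_mm: float = 20.0
    reject_border: bool = True
    landmark_weight: float = 0.0

    def __post_init__(self) -> None:
        sched = tuple(float(a) for a in self.stiffness_schedule)
        if len(sched) == 0 or any(a <= 0 for a in sched):
            raise ValueError("stiffness schedule must be non-empty and positive")
        if any(b >= a for a, b in zip(sched, sched[1:])) and len(sched) > 1:
            if not all(b < a for a, b in zip(sched, sched[1:])):
                raise ValueError("stiffness schedule must be strictly decreasing")
        object.__setattr__(self, "stiffness_schedule", sched)
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class DeformedAtlas:
    """NICP result: the atlas, one total 3×4 affine per atlas vertex
    (including the initialization), the deformed vertex positions, and
    the per-iteration energy history ``(alpha, iteration, energy)``."""

    atlas: TriangleMesh
    transforms: np.ndarray
    deformed_vertices: np.ndarray
    history: list[tuple[float, int, float]]

    def deformed_mesh(self) -> TriangleMesh:
        return TriangleMesh(self.deformed_vertices.copy(), self.atlas.triangles.copy(),
                            None if self.atlas.colors is None else self.atlas.colors.copy())


class AtlasLandmarkIndices(dict):
    """Mapping from the 12 landmark names to atlas vertex indices."""

    def __init__(self, mapping, n_vertices: int | None = None):
        super().__init__()
        missing = set(LANDMARK_NAMES) - set(mapping)
        extra = set(mapping) - set(LANDMARK_NAMES)
        if missing or extra:
            raise ValueError(
                f"expected exactly the 12 landmark names; missing={sorted(missing)}, "
                f"unexpected={sorted(extra)}"
            )
        for name in LANDMARK_NAMES:
            idx = int(mapping[name])
            if n_vertices is not None and not 0 <= idx < n_vertices:
                raise ValueError(f"vertex index {idx} for {name!r} out of range")
            self[name] = idx

    @classmethod
    def from_landmarks(cls, atlas: TriangleMesh, lm: LandmarkSet3D) -> "AtlasLandmarkIndices":
        """Index of the atlas vertex nearest each landmark."""
        idx = {}
        for name in LANDMARK_NAMES:
            idx[name] = int(np.argmin(np.linalg.norm(atlas.vertices - lm[name], axis=1)))
        return cls(idx, n_vertices=atlas.n_vertices)

    @classmethod
    def from_json(cls, path, n_vertices: int | None = None) -> "AtlasLandmarkIndices":
        return cls(json.loads(Path(path).read_text()), n_vertices=n_vertices)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dict(self), indent=1) + "\n")


def affine_init(atlas_lm: LandmarkSet3D, subject_lm: LandmarkSet3D) -> np.ndarray:
    """Least-squares 3×4 affine mapping atlas landmarks onto subject
    landmarks; used to coarsely align the atlas before NICP."""
    p = atlas_lm.to_array()
    q = subject_lm.to_array()
    centered = p - p.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[2] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate landmark configuration: coplanar atlas landmarks")
    design = np.hstack([p, np.ones((len(p), 1))])
    sol, *_ = np.linalg.lstsq(design, q, rcond=None)
    return sol.T  # (3, 4)


def apply_affine(transform: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 3×4 affine to (n, 3) points."""
    transform = np.asarray(transform, float)
    return points @ transform[:, :3].T + transform[:, 3]


def _mesh_edges(triangles: np.ndarray) -> np.ndarray:
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [0, 2]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def _vertex_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a, b, c = (vertices[triangles[:, k]] for k in range(3))
    fn = np.cross(b - a, c - a)
    vn = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(vn, triangles[:, k], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vn / norm


def _border_faces(triangles: np.ndarray) -> np.ndarray:
    """Boolean mask of faces touching a border (single-face) edge."""
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [0, 2]]])
    e.sort(axis=1)
    _, inverse, counts = np.unique(e, axis=0, return_inverse=True, return_counts=True)
    border_vertex = np.zeros(triangles.max() + 1, dtype=bool)
    border_edges = e[counts[inverse] == 1]
    border_vertex[border_edges.ravel()] = True
    return border_vertex[triangles].any(axis=1)


def nicp_register(
    atlas: TriangleMesh,
    target: TriangleMesh,
    init: np.ndarray,
    config: NICPConfig = NICPConfig(),
    atlas_landmark_indices: AtlasLandmarkIndices | None = None,
    target_landmarks: LandmarkSet3D | None = None,
) -> DeformedAtlas:
    """Register the atlas onto the target scan.

    ``init`` is the 3×4 affine (e.g. from :func:`affine_init`) applied to
    the whole atlas before the per-vertex optimization.  The returned
    per-vertex transforms are total: applied to the *original* atlas
    vertices they produce the deformed positions.
    """
    n = atlas.n_vertices
    edges = _mesh_edges(atlas.triangles)
    n_comp, _ = csgraph.connected_components(
        sp.coo_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)),
        directed=False,
    )
    if n_comp != 1:
        raise ValueError(f"atlas mesh must be connected (found {n_comp} components)")

    init = np.asarray(init, float)
    if init.shape != (3, 4):
        raise ValueError("init must be a 3x4 affine transform")
    v_init = apply_affine(init, atlas.vertices)
    vh = np.hstack([v_init, np.ones((n, 1))])  # homogeneous, static

    # data-term design matrix D: row i carries v̂_i at columns 4i..4i+3
    rows = np.repeat(np.arange(n), 4)
    cols = (np.arange(4 * n)).reshape(n, 4).ravel()
    d_mat = sp.csr_matrix((vh.ravel(), (rows, cols)), shape=(n, 4 * n))

    # stiffness matrix: node-arc incidence kron G
    m_inc = sp.coo_matrix(
        (np.concatenate([np.ones(len(edges)), -np.ones(len(edges))]),
         (np.concatenate([np.arange(len(edges))] * 2),
          np.concatenate([edges[:, 0], edges[:, 1]]))),
        shape=(len(edges), n),
    )
    g = sp.diags([1.0, 1.0, 1.0, config.gamma])
    stiff = sp.kron(m_inc, g, format="csr")  # (4e, 4n)

    guide_rows = None
    guide_rhs = None
    if config.landmark_weight > 0:
        if atlas_landmark_indices is None or target_landmarks is None:
            raise ValueError("landmark_weight > 0 requires atlas indices and target landmarks")
        li = np.array([atlas_landmark_indices[k] for k in LANDMARK_NAMES])
        guide_rows = np.sqrt(config.landmark_weight) * d_mat[li]
        guide_rhs = np.sqrt(config.landmark_weight) * target_landmarks.to_array()

    locator = SurfaceLocator(target)
    target_face_normals = target.face_normals()
    border = _border_faces(target.triangles) if config.reject_border else None
    cos_max = np.cos(np.radians(config.max_normal_angle_deg))

    x = np.tile(np.vstack([np.eye(3), np.zeros(3)]), (n, 1))  # (4n, 3), identity
    history: list[tuple[float, int, float]] = []

    for alpha in config.stiffness_schedule:
        a_stiff = np.sqrt(alpha) * stiff
        for it in range(config.max_inner_iter):
            deformed = d_mat @ x
            u, dist, tid = locator.closest(deformed)
            w = dist <= config.max_distance_mm
            normals = _vertex_normals(deformed, atlas.triangles)
            compat = np.einsum("ij,ij->i", normals, target_face_normals[tid]) >= cos_max
            w &= compat
            if border is not None:
                w &= ~border[tid]
            if not w.any():
                raise RuntimeError(
                    "all NICP correspondences rejected; check initialization "
                    "and rejection thresholds"
                )
            wf = w.astype(float)
            wd = sp.diags(wf) @ d_mat
            blocks = [a_stiff, wd]
            rhs = [np.zeros((stiff.shape[0], 3)), wf[:, None] * u]
            if guide_rows is not None:
                blocks.append(guide_rows)
                rhs.append(guide_rhs)
            a_full = sp.vstack(blocks, format="csc")
            b_full = np.vstack(rhs)
            ata = (a_full.T @ a_full).tocsc()
            atb = a_full.T @ b_full
            x_new = spla.spsolve(ata, atb)
            if sp.issparse(x_new):
                x_new = x_new.toarray()
            x_new = np.asarray(x_new).reshape(4 * n, 3)
            # energy at the correspondences used for this solve
            data_res = (d_mat @ x_new) - u
            energy = float(np.sum(wf * np.sum(data_res ** 2, axis=1))
                           + alpha * np.sum((stiff @ x_new) ** 2))
            if guide_rows is not None:
                energy += float(np.sum((guide_rows @ x_new - guide_rhs) ** 2))
            history.append((float(alpha), it, energy))
            change = np.mean(
                np.linalg.norm((x_new - x).reshape(n, 4, 3), axis=(1, 2))
            )
            x = x_new
            if change < config.inner_tol:
                break

    deformed = d_mat @ x
    # compose per-vertex transforms with the global initialization
    per_vertex = x.reshape(n, 4, 3).transpose(0, 2, 1)  # (n, 3, 4)
    lin = per_vertex[:, :, :3] @ init[:, :3]
    tr = np.einsum("nij,j->ni", per_vertex[:, :, :3], init[:, 3]) + per_vertex[:, :, 3]
    total = np.concatenate([lin, tr[:, :, None]], axis=2)
    if not np.all(np.isfinite(deformed)):
        raise RuntimeError("NICP solver produced non-finite vertex positions")
    return DeformedAtlas(atlas=atlas, transforms=total,
                         deformed_vertices=np.asarray(deformed), history=history)


def landmarks_from_atlas(
    deformed: DeformedAtlas, indices: AtlasLandmarkIndices
) -> LandmarkSet3D:
    """Read landmarks off the deformed atlas at known vertex indices."""
    n = len(deformed.deformed_vertices)
    points = {}
    for name in LANDMARK_NAMES:
        idx = indices[name]
        if not 0 <= idx < n:
            raise IndexError(f"atlas vertex index {idx} for {name!r} out of range [0, {n})")
        points[name] = deformed.deformed_vertices[idx]
    return LandmarkSet3D(points)


def average_atlas(
    registered: list[TriangleMesh], tol: float = 1e-8, max_iter: int = 100
) -> TriangleMesh:
    """Average meshes in dense correspondence into an atlas.

    Rigid-body (rotation + translation only, no scaling) Procrustes
    alignment of the dense vertex sets removes pose variation, then each
    vertex is arithmetically averaged.  Topology is copied from the first
    mesh; colors are averaged when every input has them.
    """
    if len(registered) < 1:
        raise ValueError("need at least one mesh")
    topo = registered[0].triangles
    for m in registered[1:]:
        if m.n_vertices != registered[0].n_vertices or not np.array_equal(m.triangles, topo):
            raise ValueError("all meshes must share vertex count and topology")
    configs = [m.vertices.copy() for m in registered]
    mean = configs[0].copy()
    for _ in range(max_iter):
        aligned = []
        for c in configs:
            rot, tr = rigid_align(c, mean)
            aligned.append(c @ rot.T + tr)
        new_mean = np.mean(aligned, axis=0)
        shift = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        configs = aligned
        if shift < tol:
            break
    colors = None
    if all(m.colors is not None for m in registered):
        colors = np.mean([m.colors for m in registered], axis=0)
    return TriangleMesh(mean, topo.copy(), colors)
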