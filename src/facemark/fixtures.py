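"""Synthetic face-like fixtures with painted landmark markers.

Real facial surface scans cannot be redistributed, so every part of the
package is testable on synthetic fixtures: an ellipsoidal "head" with a
Gaussian nose bump and shallow eye-socket depressions, colored skin, and
a small disk of reserved marker color painted around each of the twelve
landmark positions.  The markers drive :class:`~facemark.detect.FixtureMarkerDetector`
through the same render/detect/ray-cast path that real scans traverse
with pretrained 2D models.

The canonical pose matches the scanner frame the pipeline assumes: the
face looks toward +z, +y is up, and the subject's anatomical right is at
−x.  Ground-truth landmarks are exact surface points (the projection of
each painted patch's vertex centroid onto the surface), so recovered
landmarks can be scored against them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .camera import Ray, cast_ray
from .detect import MARKER_COLORS
from .landmarks import LANDMARK_NAMES, LandmarkSet3D
from .mesh import TriangleMesh

__all__ = [
    "FixtureSpec",
    "make_face_fixture",
    "apply_rigid",
    "perturb_landmarks",
    "make_population",
]

#: Canonical outward directions (from the head center) of the twelve
#: landmarks; anatomical right (_r) sits at negative x.
_LANDMARK_DIRECTIONS: dict[str, tuple[float, float, float]] = {
    "en_r": (-0.22, 0.30, 1.00),
    "en_l": (0.22, 0.30, 1.00),
    "ex_r": (-0.60, 0.32, 0.75),
    "ex_l": (0.60, 0.32, 0.75),
    "n":    (0.00, 0.35, 1.00),
    "prn":  (0.00, -0.05, 1.00),
    "sn":   (0.00, -0.28, 1.00),
    "gn":   (0.00, -1.00, 0.45),
    "ch_r": (-0.38, -0.50, 0.85),
    "ch_l": (0.38, -0.50, 0.85),
    "ls":   (0.00, -0.42, 1.00),
    "li":   (0.00, -0.62, 1.00),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic face fixture.

    ``semi_axes`` are the head ellipsoid half-extents in mm (x width,
    y height, z depth); the nose is a radial Gaussian bump of the given
    amplitude/width; eye sockets are shallow Gaussian depressions.
    ``subdivisions`` controls icosphere resolution (5 → ~20k triangles,
    3 → ~1.3k triangles for registration-heavy tests).
    """

    semi_axes: tuple[float, float, float] = (80.0, 110.0, 70.0)
    nose_amplitude: float = 25.0
    nose_width: float = 20.0
    eye_depth: float = 5.0
    eye_width: float = 12.0
    subdivisions: int = 5
    skin_color: tuple[float, float, float] = (0.85, 0.70, 0.60)
    marker_radius: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0 or self.nose_width <= 0 or self.eye_width <= 0:
            raise ValueError("fixture dimensions must be positive")
        if self.marker_radius <= 0:
            raise ValueError("marker radius must be positive")
        if not 1 <= self.subdivisions <= 7:
            raise ValueError("subdivisions must be in [1, 7]")


def _ellipsoid_point(direction: np.ndarray, semi_axes) -> np.ndarray:
    """Intersection of a ray from the origin with the ellipsoid."""
    u = direction / np.linalg.norm(direction)
    a, b, c = semi_axes
    r = 1.0 / np.sqrt((u[0] / a) ** 2 + (u[1] / b) ** 2 + (u[2] / c) ** 2)
    return u * r


def _surface_radii(units: np.ndarray, spec: FixtureSpec) -> np.ndarray:
    """Radial distance of the fixture surface along unit directions."""
    a, b, c = spec.semi_axes
    base = 1.0 / np.sqrt(
        (units[:, 0] / a) ** 2 + (units[:, 1] / b) ** 2 + (units[:, 2] / c) ** 2
    )
    pts = units * base[:, None]
    nose_center = _ellipsoid_point(np.asarray(_LANDMARK_DIRECTIONS["prn"], float),
                                   spec.semi_axes)
    bump = spec.nose_amplitude * np.exp(
        -np.sum((pts - nose_center) ** 2, axis=1) / (2.0 * spec.nose_width ** 2)
    )
    dent = np.zeros(len(pts))
    for side in (-1.0, 1.0):
        eye_center = _ellipsoid_point(np.array([side * 0.40, 0.31, 0.90]), spec.semi_axes)
        dent += spec.eye_depth * np.exp(
            -np.sum((pts - eye_center) ** 2, axis=1) / (2.0 * spec.eye_width ** 2)
        )
    return base + bump - dent


def make_face_fixture(spec: FixtureSpec = FixtureSpec()) -> tuple[TriangleMesh, LandmarkSet3D]:
    """Build the fixture mesh and its exact ground-truth landmarks.

    Deterministic for a given spec.  Raises if the marker patches would
    overlap (marker radius too large for the landmark layout).
    """
    ico = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    units = np.asarray(ico.vertices, float)
    units /= np.linalg.norm(units, axis=1, keepdims=True)
    radii = _surface_radii(units, spec)
    vertices = units * radii[:, None]
    triangles = np.asarray(ico.faces, np.int64)

    colors = np.tile(np.asarray(spec.skin_color, float), (len(vertices), 1))
    bare = TriangleMesh(vertices, triangles)

    # nominal landmark = ray from the head center along the canonical direction
    painted: dict[str, np.ndarray] = {}
    nominal: dict[str, np.ndarray] = {}
    for name in LANDMARK_NAMES:
        direction = np.asarray(_LANDMARK_DIRECTIONS[name], float)
        hit = cast_ray(bare, Ray(origin=np.zeros(3), direction=direction))
        assert hit is not None  # ray from inside a closed surface always hits
        nominal[name] = hit[0]
        dists = np.linalg.norm(vertices - hit[0], axis=1)
        near = np.nonzero(dists < spec.marker_radius)[0]
        if len(near) == 0:
            # coarse meshes: paint at least the nearest vertex so the
            # fixture stays usable for geometry-only (registration) tests
            near = np.array([int(np.argmin(dists))])
        painted[name] = near

    # disjointness: inter-landmark spacing must exceed one marker diameter
    # and no vertex may carry two marker colors
    names = list(LANDMARK_NAMES)
    for i, ni in enumerate(names):
        for nj in names[i + 1:]:
            gap = np.linalg.norm(nominal[ni] - nominal[nj])
            if gap <= 2.0 * spec.marker_radius:
                raise ValueError(
                    f"marker radius {spec.marker_radius} mm too large: landmarks "
                    f"{ni!r} and {nj!r} are only {gap:.1f} mm apart"
                )
            if np.intersect1d(painted[ni], painted[nj]).size:
                raise ValueError(
                    f"marker patches of {ni!r} and {nj!r} overlap at this resolution"
                )

    # ground truth = painted patch centroid projected back to the surface,
    # so the truth coincides with the visual center of each marker blob
    truth: dict[str, np.ndarray] = {}
    for name in LANDMARK_NAMES:
        colors[painted[name]] = MARKER_COLORS[name]
        centroid = vertices[painted[name]].mean(axis=0)
        hit = cast_ray(bare, Ray(origin=np.zeros(3), direction=centroid))
        assert hit is not None
        truth[name] = hit[0]

    mesh = TriangleMesh(vertices, triangles, colors)
    return mesh, LandmarkSet3D(truth)


def apply_rigid(
    mesh: TriangleMesh,
    landmarks: LandmarkSet3D,
    rotation: np.ndarray,
    translation: np.ndarray,
) -> tuple[TriangleMesh, LandmarkSet3D]:
    """Apply one proper rigid motion to a mesh and its landmarks."""
    rotation = np.asarray(rotation, float)
    if rotation.shape != (3, 3) or not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be a 3x3 orthogonal matrix")
    if np.linalg.det(rotation) < 0:
        raise ValueError("improper rotation (reflection) not allowed")
    return mesh.transformed(rotation, translation), landmarks.transformed(rotation, translation)


def perturb_landmarks(lm: LandmarkSet3D, sigma_mm: float, seed: int) -> LandmarkSet3D:
    """Add iid per-axis Gaussian noise (mm) to every landmark.

    Emulates observer placement noise for evaluation tests; deterministic
    given the seed.
    """
    if sigma_mm < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    arr = lm.to_array() + rng.normal(0.0, sigma_mm, size=(12, 3))
    return LandmarkSet3D.from_array(arr)


def make_population(
    n: int,
    deformation_scale: float,
    seed: int,
    spec: FixtureSpec = FixtureSpec(),
    n_modes: int = 10,
) -> list[tuple[TriangleMesh, LandmarkSet3D]]:
    """A population of smoothly deformed fixtures in dense correspondence.

    Each member applies a band-limited radial displacement field — a sum
    of ``n_modes`` random low-frequency cosine modes over the unit
    direction sphere, RMS amplitude ``deformation_scale`` mm — to the
    canonical fixture.  All members share the canonical topology, and the
    ground-truth landmarks ride along with the surface (interpolated on
    their supporting triangles), so the population has exact per-member
    truth.
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    base_mesh, base_lm = make_face_fixture(spec)
    units = base_mesh.vertices / np.linalg.norm(base_mesh.vertices, axis=1, keepdims=True)

    # supporting triangle + barycentric coordinates of each landmark
    bary: dict[str, tuple[int, np.ndarray]] = {}
    bare = TriangleMesh(base_mesh.vertices, base_mesh.triangles)
    for name in LANDMARK_NAMES:
        hit = cast_ray(bare, Ray(origin=np.zeros(3), direction=base_lm[name]))
        assert hit is not None
        point, tri_idx, _ = hit
        a, b, c = base_mesh.vertices[base_mesh.triangles[tri_idx]]
        m = np.stack([b - a, c - a], axis=1)
        uv, *_ = np.linalg.lstsq(m, point - a, rcond=None)
        bary[name] = (tri_idx, np.array([1.0 - uv.sum(), uv[0], uv[1]]))

    rng = np.random.default_rng(seed)
    population = []
    for _ in range(n):
        waves = rng.normal(size=(n_modes, 3))
        waves /= np.linalg.norm(waves, axis=1, keepdims=True)
        freqs = rng.uniform(1.0, 4.0, size=n_modes)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
        amps = rng.normal(size=n_modes)
        f = np.zeros(len(units))
        for w, k, ph, a in zip(waves, freqs, phases, amps):
            f += a * np.cos(k * (units @ w) * np.pi + ph)
        rms = np.sqrt(np.mean(f ** 2))
        if rms > 0:
            f *= deformation_scale / rms
        verts = base_mesh.vertices + f[:, None] * units
        mesh = TriangleMesh(verts, base_mesh.triangles.copy(), base_mesh.colors.copy())
        truth = {}
        for name, (tri_idx, w3) in bary.items():
            truth[name] = w3 @ verts[base_mesh.triangles[tri_idx]]
        population.append((mesh, LandmarkSet3D(truth)))
    return population
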