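"""Virtual pinhole cameras, rendering, and ray casting.

The landmarking algorithm never touches the mesh directly: it looks at it
through virtual pinhole cameras.  A five-camera array around the scan
centroid provides coarse face localization; a frontal camera computed from
seven landmarks provides the refined views; rays through detected 2D
landmark pixels are cast back onto the surface to produce 3D landmarks.

Conventions (used everywhere in the package):

* image origin at the top-left corner, x right, y *down*, pixel centers at
  ``(i + 0.5, j + 0.5)``;
* ``view_angle`` is the full vertical field of view in degrees, pixels are
  square (the horizontal angle follows from the aspect ratio);
* rendering is unlit: a pixel shows the interpolated vertex color of the
  nearest surface point, which keeps the rendering contract deterministic
  for the color-marker detector and for external 2D models alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import LandmarkSet3D
from .mesh import MeshError, TriangleMesh, mesh_centroid

__all__ = [
    "PinholeCamera",
    "Ray",
    "RenderedView",
    "DEFAULT_IMAGE_SIZE",
    "initial_camera_array",
    "frontal_camera",
    "pixel_ray",
    "project_point",
    "cast_ray",
    "render",
]

DEFAULT_IMAGE_SIZE: tuple[int, int] = (512, 512)

_BACKGROUND = np.zeros(3)


@dataclass(frozen=True)
class PinholeCamera:
    """A pinhole camera defined by position, focal point, up vector,
    vertical view angle (degrees) and image size ``(width, height)``."""

    position: np.ndarray
    focal_point: np.ndarray
    up: np.ndarray
    view_angle: float
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, float).reshape(3))
        object.__setattr__(self, "focal_point", np.asarray(self.focal_point, float).reshape(3))
        object.__setattr__(self, "up", np.asarray(self.up, float).reshape(3))
        view = self.focal_point - self.position
        vn = np.linalg.norm(view)
        if vn == 0:
            raise ValueError("camera position equals focal point")
        un = np.linalg.norm(self.up)
        if un == 0:
            raise ValueError("zero up vector")
        cos = abs(np.dot(view / vn, self.up / un))
        if cos > 1.0 - 1e-9:
            raise ValueError("up vector parallel to view direction")
        if not 0.0 < self.view_angle < 180.0:
            raise ValueError("view angle must lie in (0, 180) degrees")
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValueError("image size must be positive")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (forward, right, true_up) in world coordinates."""
        f = self.focal_point - self.position
        f = f / np.linalg.norm(f)
        r = np.cross(f, self.up)
        r = r / np.linalg.norm(r)
        u = np.cross(r, f)
        return f, r, u

    def pixel_scale(self) -> float:
        """World-plane units per pixel at unit distance along forward."""
        h = self.image_size[1]
        return 2.0 * np.tan(np.radians(self.view_angle) / 2.0) / h


@dataclass(frozen=True)
class Ray:
    """A half-line from ``origin`` along unit ``direction``."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, float).reshape(3))
        d = np.asarray(self.direction, float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("zero ray direction")
        object.__setattr__(self, "direction", d / n)


@dataclass
class RenderedView:
    """A rendering: ``image`` (H, W, 3) in [0, 1], ``depth`` (H, W)
    Euclidean hit distances (inf on background), and the camera."""

    image: np.ndarray
    depth: np.ndarray
    camera: PinholeCamera

    def __post_init__(self) -> None:
        w, h = self.camera.image_size
        if self.image.shape != (h, w, 3) or self.depth.shape != (h, w):
            raise ValueError("image/depth dimensions do not match camera.image_size")


# ---------------------------------------------------------------------------
# camera placement
# ---------------------------------------------------------------------------

def initial_camera_array(
    mesh: TriangleMesh,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    distance_mm: float = 600.0,
    view_angle: float = 50.0,
) -> list[PinholeCamera]:
    """The five-camera array used to coarsely locate a face.

    All cameras focus on the mesh centroid with +y up and a wide (50°)
    field of view.  The central camera sits 60 cm along +z from the
    centroid — in the scanner frame the scanner looks along −z, so this is
    the most likely frontal view — and the other four are offset 60 cm
    along +x, +y, −x, −y.  Central camera first.
    """
    c = mesh_centroid(mesh)
    d = distance_mm
    offsets = np.array([
        (0.0, 0.0, d),
        (d, 0.0, d),
        (0.0, d, d),
        (-d, 0.0, d),
        (0.0, -d, d),
    ])
    up = np.array([0.0, 1.0, 0.0])
    return [
        PinholeCamera(position=c + off, focal_point=c, up=up,
                      view_angle=view_angle, image_size=image_size)
        for off in offsets
    ]


def frontal_camera(
    lm: LandmarkSet3D,
    distance_mm: float = 800.0,
    view_angle: float = 20.0,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
) -> PinholeCamera:
    """Place a camera in front of the face described by seven landmarks.

    The outward facial direction is the cross product
    ``(ch_r − ex_l) × (ch_l − ex_r)`` of the two diagonals spanning the
    eye and mouth corners; with anatomical right at −x this points out of
    the face.  The camera sits ``distance_mm`` (default 80 cm) from the
    pronasale along that direction, focused on the pronasale, with a
    narrow 20° view angle.  Camera roll aligns the image vertical with the
    nasion→labiale-superius axis ``n − ls`` so tilted scans render
    upright; only the component of ``n − ls`` perpendicular to the view
    direction is meaningful, so it is orthogonalized before use.
    """
    direction = np.cross(lm["ch_r"] - lm["ex_l"], lm["ch_l"] - lm["ex_r"])
    norm = np.linalg.norm(direction)
    if norm <= 1e-9:
        raise ValueError("degenerate landmark configuration: eye/mouth corners collinear")
    direction = direction / norm
    position = lm["prn"] + distance_mm * direction
    view_dir = -direction  # from camera toward the face
    up_raw = lm["n"] - lm["ls"]
    up = up_raw - np.dot(up_raw, view_dir) * view_dir
    un = np.linalg.norm(up)
    if un <= 1e-9:
        raise ValueError("degenerate landmark configuration: n−ls parallel to view direction")
    return PinholeCamera(position=position, focal_point=lm["prn"], up=up / un,
                         view_angle=view_angle, image_size=image_size)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def pixel_ray(camera: PinholeCamera, pixel: tuple[float, float] | np.ndarray) -> Ray:
    """The world-space ray from the camera through an image point.

    ``pixel`` is a continuous image coordinate; the ray through pixel
    ``(i, j)``'s center is obtained with ``(i + 0.5, j + 0.5)``.
    """
    x, y = float(pixel[0]), float(pixel[1])
    w, h = camera.image_size
    if not (0.0 <= x <= w and 0.0 <= y <= h):
        raise ValueError(f"pixel ({x}, {y}) outside image bounds {w}x{h}")
    f, r, u = camera.basis()
    s = camera.pixel_scale()
    d = f + r * ((x - w / 2.0) * s) - u * ((y - h / 2.0) * s)
    return Ray(origin=camera.position, direction=d)


def project_point(camera: PinholeCamera, p: np.ndarray) -> np.ndarray:
    """Perspective image coordinates of a world point strictly in front of
    the camera.  Inverse of :func:`pixel_ray` up to depth."""
    p = np.asarray(p, float).reshape(3)
    f, r, u = camera.basis()
    d = p - camera.position
    z = np.dot(d, f)
    if z <= 1e-12:
        raise ValueError("point at or behind the camera plane")
    s = camera.pixel_scale()
    w, h = camera.image_size
    x = w / 2.0 + (np.dot(d, r) / z) / s
    y = h / 2.0 - (np.dot(d, u) / z) / s
    return np.array([x, y])


# ---------------------------------------------------------------------------
# ray casting (Möller–Trumbore, vectorized over all triangles, exact)
# ---------------------------------------------------------------------------

def cast_ray(
    mesh: TriangleMesh, ray: Ray, eps: float = 1e-12
) -> tuple[np.ndarray, int, float] | None:
    """First intersection of a ray with the mesh, or ``None``.

    Runs Möller–Trumbore against every triangle and returns
    ``(point, triangle_index, distance)`` for the smallest strictly
    positive distance (first-occurring triangle on exact ties).  A miss is
    a value, not an error.
    """
    if mesh.n_triangles == 0:
        return None
    a, b, c = mesh.triangle_corners()
    d = ray.direction
    e1 = b - a
    e2 = c - a
    pvec = np.cross(d[None, :], e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = ray.origin[None, :] - a
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", d, qvec) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1.0 + 1e-12) & (t > 1e-9)
    if not np.any(hit):
        return None
    t = np.where(hit, t, np.inf)
    idx = int(np.argmin(t))
    dist = float(t[idx])
    return ray.origin + dist * d, idx, dist


# ---------------------------------------------------------------------------
# rendering (software rasterizer with per-pixel exact plane intersection)
# ---------------------------------------------------------------------------

def render(mesh: TriangleMesh, camera: PinholeCamera,
           background: np.ndarray = _BACKGROUND) -> RenderedView:
    """Render the mesh through the camera (unlit vertex colors).

    Visibility is resolved with a depth buffer of Euclidean hit distances.
    For every candidate pixel the depth is computed by intersecting that
    pixel's ray with the triangle's supporting plane, so foreground depths
    agree with :func:`cast_ray` along :func:`pixel_ray` to floating-point
    accuracy.  Colors are perspective-correct barycentric interpolations
    of the vertex colors.  Triangles with any vertex behind the camera are
    skipped (the scan is expected to lie fully in front of every camera in
    this pipeline).
    """
    if mesh.colors is None:
        raise MeshError("rendering requires per-vertex colors")
    w, h = camera.image_size
    image = np.tile(np.asarray(background, float), (h, w, 1))
    depth = np.full((h, w), np.inf)
    if mesh.n_triangles == 0:
        return RenderedView(image=image, depth=depth, camera=camera)

    f, r, u = camera.basis()
    s = camera.pixel_scale()
    origin = camera.position

    dv = mesh.vertices - origin
    z = dv @ f
    infront = z > 1e-9
    zs = np.where(infront, z, 1.0)
    sx = w / 2.0 + (dv @ r) / (zs * s)
    sy = h / 2.0 - (dv @ u) / (zs * s)

    tri = mesh.triangles
    tri_ok = np.all(infront[tri], axis=1)
    txs, tys = sx[tri], sy[tri]
    tri_ok &= (txs.min(axis=1) < w) & (txs.max(axis=1) > 0)
    tri_ok &= (tys.min(axis=1) < h) & (tys.max(axis=1) > 0)
    candidates = np.nonzero(tri_ok)[0]

    verts = mesh.vertices
    colors = mesh.colors
    for ti in candidates:
        i0, i1, i2 = tri[ti]
        ax, ay = sx[i0], sy[i0]
        bx, by = sx[i1], sy[i1]
        cx, cy = sx[i2], sy[i2]
        area = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
        if abs(area) < 1e-12:
            continue
        x0 = max(int(np.floor(min(ax, bx, cx) - 0.5)), 0)
        x1 = min(int(np.ceil(max(ax, bx, cx) + 0.5)), w - 1)
        y0 = max(int(np.floor(min(ay, by, cy) - 0.5)), 0)
        y1 = min(int(np.ceil(max(ay, by, cy) + 0.5)), h - 1)
        if x1 < x0 or y1 < y0:
            continue
        px = np.arange(x0, x1 + 1) + 0.5
        py = (np.arange(y0, y1 + 1) + 0.5)[:, None]
        # signed edge functions; barycentric weights sum to 1
        w0 = ((bx - px) * (cy - py) - (by - py) * (cx - px)) / area
        w1 = ((cx - px) * (ay - py) - (cy - py) * (ax - px)) / area
        w2 = 1.0 - w0 - w1
        inside = (w0 >= -1e-9) & (w1 >= -1e-9) & (w2 >= -1e-9)
        if not inside.any():
            continue
        yy, xx = np.nonzero(inside)
        gx = px[xx]
        gy = (np.arange(y0, y1 + 1) + 0.5)[yy]
        # exact plane intersection along each pixel ray
        dirs = (f[None, :]
                + r[None, :] * ((gx - w / 2.0) * s)[:, None]
                - u[None, :] * ((gy - h / 2.0) * s)[:, None])
        a3, b3, c3 = verts[i0], verts[i1], verts[i2]
        nrm = np.cross(b3 - a3, c3 - a3)
        denom = dirs @ nrm
        valid = np.abs(denom) > 1e-15
        t = np.where(valid, (np.dot(a3 - origin, nrm)) / np.where(valid, denom, 1.0), np.inf)
        dist = t * np.linalg.norm(dirs, axis=1)
        valid &= t > 1e-9
        row = yy + y0
        col = xx + x0
        closer = valid & (dist < depth[row, col])
        if not closer.any():
            continue
        row, col = row[closer], col[closer]
        # perspective-correct color interpolation
        wb = np.stack([w0[inside], w1[inside], w2[inside]], axis=1)[closer]
        zinv = 1.0 / z[[i0, i1, i2]]
        wp = wb * zinv[None, :]
        wp /= wp.sum(axis=1, keepdims=True)
        image[row, col] = wp @ colors[[i0, i1, i2]]
        depth[row, col] = dist[closer]
    return RenderedView(image=image, depth=depth, camera=camera)
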