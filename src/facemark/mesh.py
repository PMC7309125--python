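"""Triangulated surface meshes with per-vertex color.

Meshes are the carrier for facial surface scans, atlases, and synthetic
fixtures.  Coordinates are millimetres throughout; colors are per-vertex
RGB in [0, 1].  PLY (ASCII written; ASCII and binary little-endian read)
is the reference dialect; OBJ with the vertex-color extension
(``v x y z r g b``) is also supported.  Texture-mapped meshes are out of
scope: bake textures to vertex colors upstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TriangleMesh",
    "MeshError",
    "MeshParseError",
    "read_mesh",
    "write_mesh",
    "mesh_centroid",
]


class MeshError(ValueError):
    """Invalid mesh content (violated invariant, empty mesh, ...)."""


class MeshParseError(MeshError):
    """A mesh file could not be parsed as the named format."""


@dataclass
class TriangleMesh:
    """A triangle mesh in millimetres with optional per-vertex RGB color.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in mm.
    triangles : (m, 3) int array
        Vertex-index triples; every index in ``[0, n)``, no repeats
        within a triangle.
    colors : (n, 3) float array, optional
        Per-vertex RGB, each channel in [0, 1].  Required by the
        landmarking pipeline, optional for geometry-only use.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    colors: np.ndarray | None = None
    _vertex_normals: np.ndarray | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.float64).reshape(-1, 3)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        if not np.all(np.isfinite(self.vertices)):
            raise MeshError("non-finite vertex coordinates")
        n = len(self.vertices)
        if len(self.triangles):
            if self.triangles.min() < 0 or self.triangles.max() >= n:
                raise MeshError(
                    f"triangle index out of range [0, {n})"
                )
            t = self.triangles
            if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
                raise MeshError("triangle with repeated vertex index")
        if self.colors is not None:
            if self.colors.shape != (n, 3):
                raise MeshError(
                    f"colors shape {self.colors.shape} != ({n}, 3)"
                )
            if not np.all(np.isfinite(self.colors)):
                raise MeshError("non-finite color values")
            if self.colors.min() < 0.0 or self.colors.max() > 1.0:
                raise MeshError("color channels must lie in [0, 1]")

    # -- derived geometry ------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def has_colors(self) -> bool:
        return self.colors is not None

    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """The three (m, 3) corner arrays of every triangle."""
        v, t = self.vertices, self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    def face_normals(self) -> np.ndarray:
        """(m, 3) unit face normals (right-hand rule on vertex order)."""
        a, b, c = self.triangle_corners()
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def vertex_normals(self) -> np.ndarray:
        """(n, 3) area-weighted unit vertex normals (cached)."""
        if self._vertex_normals is None:
            a, b, c = self.triangle_corners()
            fn = np.cross(b - a, c - a)  # area-weighted
            vn = np.zeros_like(self.vertices)
            for k in range(3):
                np.add.at(vn, self.triangles[:, k], fn)
            norm = np.linalg.norm(vn, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            self._vertex_normals = vn / norm
        return self._vertex_normals

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        """A copy with ``R v + t`` applied to every vertex."""
        v = self.vertices @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return TriangleMesh(v, self.triangles.copy(),
                            None if self.colors is None else self.colors.copy())

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.triangles.copy(),
                            None if self.colors is None else self.colors.copy())


def mesh_centroid(mesh: TriangleMesh) -> np.ndarray:
    """Unweighted mean of vertex positions (mm).

    This is the "centroid" the camera array is anchored to.  It is the
    plain vertex mean, not an area-weighted surface centroid: the camera
    array tolerates tens of millimetres of offset, and the vertex mean is
    cheap and deterministic.
    """
    if mesh.n_vertices == 0:
        raise MeshError("centroid of an empty mesh")
    return mesh.vertices.mean(axis=0)


# ---------------------------------------------------------------------------
# file I/O (trimesh-backed)
# ---------------------------------------------------------------------------

_FORMATS = ("ply", "obj")


def _infer_format(path: Path, format: str | None) -> str:
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = format.lower()
    if format not in _FORMATS:
        raise MeshParseError(f"unsupported mesh format {format!r}; use one of {_FORMATS}")
    return format


def _prescan_text_faces(path: Path, format: str) -> None:
    """Reject non-triangular faces in the text dialects, naming the line.

    trimesh fans polygons into triangles silently; the pipeline contract
    instead requires an explicit error.  ASCII PLY and OBJ are scanned
    line-by-line; binary PLY is trusted to contain triangles.
    """
    raw = path.read_bytes()
    if format == "ply":
        header_end = raw.find(b"end_header")
        if header_end < 0:
            raise MeshParseError(f"{path}: not a PLY file (no end_header)")
        header = raw[:header_end].decode("ascii", errors="replace")
        if "format ascii" not in header:
            return  # binary: no scan
        n_vertex = n_face = 0
        for line in header.splitlines():
            parts = line.split()
            if parts[:2] == ["element", "vertex"]:
                n_vertex = int(parts[2])
            elif parts[:2] == ["element", "face"]:
                n_face = int(parts[2])
        body = raw[header_end:].decode("ascii", errors="replace").splitlines()[1:]
        body = [ln for ln in body if ln.strip()]
        header_lines = raw[: header_end].count(b"\n") + 2
        for i, line in enumerate(body[n_vertex: n_vertex + n_face]):
            count = line.split()[0]
            if count != "3":
                raise MeshParseError(
                    f"{path}: non-triangular face ({count} vertices) at line "
                    f"{header_lines + n_vertex + i}; triangulate before loading"
                )
    else:  # obj
        for lineno, line in enumerate(raw.decode("utf-8", errors="replace").splitlines(), 1):
            if line.startswith("f ") or line.startswith("f\t"):
                n_refs = len(line.split()) - 1
                if n_refs != 3:
                    raise MeshParseError(
                        f"{path}: non-triangular face ({n_refs} vertices) at line "
                        f"{lineno}; triangulate before loading"
                    )


def read_mesh(path: str | Path, format: str | None = None) -> TriangleMesh:
    """Read a PLY or OBJ mesh; vertex colors are loaded when present.

    ``format`` defaults to the file suffix.  Non-triangular faces and
    malformed files raise :class:`MeshParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    format = _infer_format(path, format)
    _prescan_text_faces(path, format)
    try:
        tm = trimesh.load(str(path), file_type=format, process=False, force="mesh")
    except Exception as exc:  # normalize backend errors
        raise MeshParseError(f"{path}: failed to parse as {format}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.vertices) == 0:
        raise MeshParseError(f"{path}: no mesh content found")
    colors = None
    visual = getattr(tm, "visual", None)
    if visual is not None and visual.kind == "vertex":
        rgba = np.asarray(visual.vertex_colors, dtype=np.float64)
        if len(rgba) == len(tm.vertices):
            colors = rgba[:, :3] / 255.0
    try:
        return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), colors)
    except MeshError as exc:
        raise MeshParseError(f"{path}: {exc}") from exc


def write_mesh(mesh: TriangleMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh as ASCII PLY or OBJ; colors are written when present."""
    path = Path(path)
    format = _infer_format(path, format)
    mesh.validate()
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    if mesh.colors is not None:
        rgba = np.empty((mesh.n_vertices, 4), dtype=np.uint8)
        rgba[:, :3] = np.clip(np.round(mesh.colors * 255.0), 0, 255).astype(np.uint8)
        rgba[:, 3] = 255
        tm.visual.vertex_colors = rgba
    if format == "ply":
        data = trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    else:
        text = trimesh.exchange.obj.export_obj(
            tm, include_color=mesh.colors is not None, include_normals=False,
            include_texture=False,
        )
        path.write_text(text)
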