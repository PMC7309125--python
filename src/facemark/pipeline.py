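"""The automatic image-based 3D landmarking pipeline.

Stages: (1) coarse face localization — render the scan from the
five-camera array and run the 2D face detector on each view until one
fires; (2) landmark that view in 2D, map the 68-point output to the 12
anatomical landmarks, and ray-cast each landmark pixel back onto the
surface; (3) compute a frontal camera from seven of the recovered 3D
landmarks, re-render, re-detect, and re-extract — repeated
``n_refinements`` times (default 2, i.e. two frontal-camera computations
with the final landmarks read from the second frontal rendering).

Every returned landmark is a ray-cast surface point, so the output always
lies on the input mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .camera import (
    PinholeCamera,
    RenderedView,
    cast_ray,
    frontal_camera,
    initial_camera_array,
    pixel_ray,
    render,
)
from .detect import (
    BoundingBox2D,
    FaceDetector,
    FaceLandmarker,
    map_68_to_12,
    select_best_box,
)
from .landmarks import LandmarkSet3D
from .mesh import MeshError, TriangleMesh
from .proximity import SurfaceLocator, nearest_point_to_ray

__all__ = [
    "PipelineConfig",
    "FaceNotFoundError",
    "RayMissError",
    "locate_face",
    "landmarks_from_view",
    "run_pipeline",
]


class FaceNotFoundError(RuntimeError):
    """No camera view produced a face detection."""


class RayMissError(RuntimeError):
    """A landmark pixel's ray did not intersect the mesh."""


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable pipeline parameters.

    Defaults follow the scanner-frame geometry the algorithm was designed
    for: a wide-angle (50°) five-camera array 60 cm from the centroid for
    coarse localization, and a narrow (20°) frontal camera 80 cm from the
    pronasale for refinement.  ``ray_miss_policy`` controls what happens
    when a 2D landmark sits a sub-pixel outside the silhouette: ``error``
    raises, ``nearest_point`` (default) snaps to the closest surface point
    to the ray, capped at ``ray_miss_max_mm``.
    """

    image_size: tuple[int, int] = (512, 512)
    n_refinements: int = 2
    array_distance_mm: float = 600.0
    array_view_angle_deg: float = 50.0
    frontal_distance_mm: float = 800.0
    frontal_view_angle_deg: float = 20.0
    ray_miss_policy: str = "nearest_point"
    ray_miss_max_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.n_refinements < 1:
            raise ValueError("n_refinements must be >= 1")
        if self.array_distance_mm <= 0 or self.frontal_distance_mm <= 0:
            raise ValueError("camera distances must be positive")
        for angle in (self.array_view_angle_deg, self.frontal_view_angle_deg):
            if not 0 < angle < 180:
                raise ValueError("view angles must lie in (0, 180)")
        if self.ray_miss_policy not in ("error", "nearest_point"):
            raise ValueError("ray_miss_policy must be 'error' or 'nearest_point'")


def locate_face(
    mesh: TriangleMesh,
    detector: FaceDetector,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[PinholeCamera, RenderedView, BoundingBox2D]:
    """Find the first array camera whose rendering contains a face.

    Cameras are tried central-first (the most likely frontal view in the
    scanner frame), then the +x, +y, −x, −y offsets.  The
    highest-confidence box of the first successful view is returned.
    """
    if mesh.colors is None:
        raise MeshError("face localization requires a mesh with vertex colors")
    cameras = initial_camera_array(
        mesh, image_size=config.image_size,
        distance_mm=config.array_distance_mm,
        view_angle=config.array_view_angle_deg,
    )
    for camera in cameras:
        view = render(mesh, camera)
        boxes = detector.detect_faces(view.image)
        if boxes:
            return camera, view, select_best_box(boxes)
    raise FaceNotFoundError("face not found in any of the five array views")


def landmarks_from_view(
    mesh: TriangleMesh,
    view: RenderedView,
    box: BoundingBox2D,
    landmarker: FaceLandmarker,
    config: PipelineConfig = PipelineConfig(),
    _locator: SurfaceLocator | None = None,
) -> LandmarkSet3D:
    """2D-landmark a rendered view and ray-cast the result onto the mesh."""
    lm68 = landmarker.landmark_face(view.image, box)
    named = map_68_to_12(lm68)
    points = {}
    for name, pixel in named.items():
        ray = pixel_ray(view.camera, pixel)
        hit = cast_ray(mesh, ray)
        if hit is not None:
            points[name] = hit[0]
            continue
        if config.ray_miss_policy == "error":
            raise RayMissError(f"ray through landmark {name!r} missed the mesh")
        locator = _locator if _locator is not None else SurfaceLocator(mesh)
        point, gap = nearest_point_to_ray(locator, ray)
        if gap > config.ray_miss_max_mm:
            raise RayMissError(
                f"ray through landmark {name!r} missed the mesh by {gap:.2f} mm "
                f"(cap {config.ray_miss_max_mm} mm)"
            )
        points[name] = point
    return LandmarkSet3D(points)


def run_pipeline(
    mesh: TriangleMesh,
    detector: FaceDetector,
    landmarker: FaceLandmarker,
    config: PipelineConfig = PipelineConfig(),
) -> LandmarkSet3D:
    """Run the full landmarking algorithm on a colored surface mesh.

    A detected view can still fail landmark extraction (a landmark may be
    occluded at an oblique angle); in that case the remaining array
    cameras are tried in order before giving up.  If a frontal refinement
    fails (no detection, missed rays), the last successful landmark set
    is returned with a warning rather than failing the whole scan.
    """
    if mesh.colors is None:
        raise MeshError("the landmarking pipeline requires a mesh with vertex colors")
    locator = SurfaceLocator(mesh) if config.ray_miss_policy == "nearest_point" else None
    cameras = initial_camera_array(
        mesh, image_size=config.image_size,
        distance_mm=config.array_distance_mm,
        view_angle=config.array_view_angle_deg,
    )
    landmarks = None
    last_error: Exception | None = None
    for camera in cameras:
        view = render(mesh, camera)
        boxes = detector.detect_faces(view.image)
        if not boxes:
            continue
        box = select_best_box(boxes)
        try:
            landmarks = landmarks_from_view(mesh, view, box, landmarker, config,
                                            _locator=locator)
            break
        except (ValueError, RayMissError) as exc:
            last_error = exc
    if landmarks is None:
        if last_error is not None:
            raise FaceNotFoundError(
                f"face detected but landmark extraction failed in every view "
                f"(last error: {last_error})"
            )
        raise FaceNotFoundError("face not found in any of the five array views")
    for _ in range(config.n_refinements):
        try:
            camera = frontal_camera(
                landmarks,
                distance_mm=config.frontal_distance_mm,
                view_angle=config.frontal_view_angle_deg,
                image_size=config.image_size,
            )
            view = render(mesh, camera)
            boxes = detector.detect_faces(view.image)
            if boxes:
                box = select_best_box(boxes)
            else:
                # frontal renderings are face-centered by construction
                w, h = config.image_size
                box = BoundingBox2D(0.0, 0.0, float(w), float(h), confidence=0.0)
            landmarks = landmarks_from_view(
                mesh, view, box, landmarker, config, _locator=locator
            )
        except (ValueError, RayMissError) as exc:
            warnings.warn(
                f"frontal refinement failed ({exc}); keeping landmarks from the "
                "previous view", RuntimeWarning, stacklevel=2,
            )
            break
    return landmarks
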