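"""2D face detection, 68-point landmarking, and the 68-to-12 mapping.

Two interchangeable implementations sit behind the detector/landmarker
interfaces:

* :class:`FixtureMarkerDetector` — finds the reserved marker colors
  painted on synthetic fixture meshes.  Fully deterministic, needs no
  model files, and exercises the exact rendering/back-projection path the
  pipeline uses in production.
* :class:`ExternalModelAdapter` — wraps pretrained 2D models (e.g. a CNN
  face detector plus an ensemble-of-regression-trees landmarker in the
  iBUG-68 scheme) supplied by the caller as plain callables.  No model is
  bundled or downloaded; the package is fully functional without one.

The pipeline assumes at most one face per scan, enforced only by taking
the highest-confidence bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np

from .landmarks import LANDMARK_NAMES

__all__ = [
    "BoundingBox2D",
    "LandmarkSet2D",
    "NamedLandmarks2D",
    "MARKER_COLORS",
    "IBUG68_TO_12",
    "FaceDetector",
    "FaceLandmarker",
    "FixtureMarkerDetector",
    "ExternalModelAdapter",
    "select_best_box",
    "map_68_to_12",
]


@dataclass(frozen=True)
class BoundingBox2D:
    """An axis-aligned detection box in pixel coordinates with a
    confidence score (higher = more confident)."""

    left: float
    top: float
    right: float
    bottom: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (self.left < self.right and self.top < self.bottom):
            raise ValueError("degenerate bounding box (left<right, top<bottom required)")
        if not np.isfinite(self.confidence):
            raise ValueError("non-finite confidence")

    @property
    def center(self) -> np.ndarray:
        return np.array([(self.left + self.right) / 2.0, (self.top + self.bottom) / 2.0])


class LandmarkSet2D:
    """Exactly 68 ordered 2D image points in the iBUG-68 convention."""

    __slots__ = ("points",)

    def __init__(self, points: np.ndarray):
        points = np.asarray(points, float)
        if points.shape != (68, 2):
            raise ValueError(f"expected 68 2D points, got shape {points.shape}")
        if not np.all(np.isfinite(points)):
            raise ValueError("non-finite 2D landmark coordinates")
        self.points = points


class NamedLandmarks2D(dict):
    """Mapping from the 12 landmark names to 2D image points."""

    def __init__(self, mapping):
        super().__init__()
        missing = set(LANDMARK_NAMES) - set(mapping)
        extra = set(mapping) - set(LANDMARK_NAMES)
        if missing or extra:
            raise ValueError(
                f"expected exactly the 12 landmark names; missing={sorted(missing)}, "
                f"unexpected={sorted(extra)}"
            )
        for name in LANDMARK_NAMES:
            p = np.asarray(mapping[name], float).reshape(2)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"non-finite 2D point for {name!r}")
            self[name] = p


#: Reserved fixture marker colors: well-separated saturated RGB values
#: (pairwise Euclidean distance >= 0.5, far from skin and background).
MARKER_COLORS: dict[str, tuple[float, float, float]] = {
    "en_r": (1.0, 0.0, 0.0),
    "en_l": (0.0, 1.0, 0.0),
    "ex_r": (0.0, 0.0, 1.0),
    "ex_l": (1.0, 1.0, 0.0),
    "n":    (1.0, 0.0, 1.0),
    "prn":  (0.0, 1.0, 1.0),
    "sn":   (1.0, 0.5, 0.0),
    "gn":   (0.5, 0.0, 1.0),
    "ch_r": (0.0, 1.0, 0.5),
    "ch_l": (1.0, 0.0, 0.5),
    "ls":   (0.5, 1.0, 0.0),
    "li":   (0.0, 0.5, 1.0),
}

#: 0-based iBUG-68 indices feeding each of the 12 anatomical landmarks.
#: Note that iBUG's "left eye" in image coordinates is the subject's
#: anatomical right.  Nasion (27, top of the nose bridge) and gnathion
#: (8, chin bottom) are proxies: both are type-2 landmarks with inherent
#: positional ambiguity.  Override via the ``mapping`` argument of
#: :func:`map_68_to_12` if a different convention is needed.
IBUG68_TO_12: dict[str, int] = {
    "gn": 8, "ex_r": 36, "en_r": 39, "en_l": 42, "ex_l": 45,
    "n": 27, "prn": 30, "sn": 33, "ch_r": 48, "ch_l": 54,
    "ls": 51, "li": 57,
}


class FaceDetector(Protocol):
    def detect_faces(self, image: np.ndarray) -> list[BoundingBox2D]: ...


class FaceLandmarker(Protocol):
    def landmark_face(self, image: np.ndarray, box: BoundingBox2D) -> LandmarkSet2D: ...


def select_best_box(boxes: list[BoundingBox2D]) -> BoundingBox2D:
    """The box with maximum confidence; first occurrence wins ties."""
    if not boxes:
        raise ValueError("no bounding boxes to select from")
    best = boxes[0]
    for box in boxes[1:]:
        if box.confidence > best.confidence:
            best = box
    return best


def map_68_to_12(
    lm68: LandmarkSet2D, mapping: dict[str, int] = IBUG68_TO_12
) -> NamedLandmarks2D:
    """Extract the 12 named landmarks from an iBUG-68 point set."""
    return NamedLandmarks2D({name: lm68.points[idx] for name, idx in mapping.items()})


class FixtureMarkerDetector:
    """Detector + landmarker for fixture meshes with painted color markers.

    A pixel belongs to a marker when its RGB value lies within
    ``color_tol`` (Euclidean) of that marker's reserved color.  Detection
    returns one box bounding all marker pixels (confidence 1.0) provided
    at least ``min_markers`` distinct marker colors are visible; the
    landmarker places each mapped 68-index at its marker blob centroid and
    parks the unused 56 indices at the box center.
    """

    def __init__(self, min_markers: int = 8, color_tol: float = 0.15,
                 mapping: dict[str, int] = IBUG68_TO_12):
        self.min_markers = min_markers
        self.color_tol = color_tol
        self.mapping = dict(mapping)

    def _marker_masks(self, image: np.ndarray) -> dict[str, np.ndarray]:
        image = np.asarray(image, float)
        masks = {}
        for name, color in MARKER_COLORS.items():
            d2 = np.sum((image - np.asarray(color)) ** 2, axis=-1)
            masks[name] = d2 < self.color_tol ** 2
        return masks

    def detect_faces(self, image: np.ndarray) -> list[BoundingBox2D]:
        masks = self._marker_masks(image)
        visible = [m for m in masks.values() if m.any()]
        if len(visible) < self.min_markers:
            return []
        union = np.logical_or.reduce(visible)
        rows, cols = np.nonzero(union)
        return [BoundingBox2D(left=float(cols.min()), top=float(rows.min()),
                              right=float(cols.max() + 1), bottom=float(rows.max() + 1),
                              confidence=1.0)]

    def landmark_face(self, image: np.ndarray, box: BoundingBox2D) -> LandmarkSet2D:
        masks = self._marker_masks(image)
        missing = [name for name, m in masks.items() if not m.any()]
        if missing:
            raise ValueError(f"fixture markers not visible for landmarks: {sorted(missing)}")
        points = np.tile(box.center, (68, 1))
        for name, idx in self.mapping.items():
            rows, cols = np.nonzero(masks[name])
            points[idx] = [cols.mean() + 0.5, rows.mean() + 0.5]  # pixel centers
        return LandmarkSet2D(points)


class ExternalModelAdapter:
    """Adapter around externally supplied 2D detection/landmarking models.

    ``detect_fn(image) -> [(left, top, right, bottom, confidence), ...]``
    and ``landmark_fn(image, box) -> (68, 2) array`` are plain callables;
    outputs are validated and passed through verbatim.
    """

    def __init__(self, detect_fn: Callable | None = None,
                 landmark_fn: Callable | None = None):
        self.detect_fn = detect_fn
        self.landmark_fn = landmark_fn

    def detect_faces(self, image: np.ndarray) -> list[BoundingBox2D]:
        if self.detect_fn is None:
            raise RuntimeError(
                "ExternalModelAdapter has no detect_fn configured; supply a "
                "pretrained face-detection callable or use FixtureMarkerDetector"
            )
        return [BoundingBox2D(*map(float, raw)) for raw in self.detect_fn(image)]

    def landmark_face(self, image: np.ndarray, box: BoundingBox2D) -> LandmarkSet2D:
        if self.landmark_fn is None:
            raise RuntimeError(
                "ExternalModelAdapter has no landmark_fn configured; supply a "
                "pretrained 68-point landmarker callable or use FixtureMarkerDetector"
            )
        return LandmarkSet2D(np.asarray(self.landmark_fn(image, box), float))
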