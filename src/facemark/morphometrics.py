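"""Procrustes shape statistics and landmark-error reporting.

Implements the evaluation machinery of geometric morphometrics as used
for landmarking studies: centroid size, least-squares rigid alignment,
generalized Procrustes analysis (GPA), Procrustes distance from the mean
shape, and Euclidean landmark-error tables with observer averaging.

The GPA here scales each configuration to unit centroid size *once* and
then applies rigid (rotation + translation, no reflection, no scaling)
transforms inside the iteration; this keeps shape distances comparable
across landmark sets of different absolute size without full-Procrustes
scaling in the loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landmarks import LandmarkSet3D

__all__ = [
    "ShapeSample",
    "GPAResult",
    "ErrorReport",
    "centroid_size",
    "rigid_align",
    "gpa",
    "procrustes_distance_from_mean",
    "landmark_errors",
    "average_over_observers",
]


@dataclass
class ShapeSample:
    """An ordered k-landmark configuration (k >= 3) with unique labels."""

    labels: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.coords = np.asarray(self.coords, float)
        k = len(self.labels)
        if k < 3:
            raise ValueError("a shape sample needs at least 3 landmarks")
        if len(set(self.labels)) != k:
            raise ValueError("duplicate landmark labels")
        if self.coords.shape != (k, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({k}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @classmethod
    def from_landmarks(cls, lm: LandmarkSet3D) -> "ShapeSample":
        return cls(labels=tuple(lm), coords=lm.to_array())


def centroid_size(s: ShapeSample | np.ndarray) -> float:
    """Root summed squared distance of the points from their centroid."""
    coords = s.coords if isinstance(s, ShapeSample) else np.asarray(s, float)
    centered = coords - coords.mean(axis=0)
    size = float(np.sqrt(np.sum(centered ** 2)))
    if size == 0.0:
        raise ValueError("degenerate configuration: all points identical (size 0)")
    return size


def rigid_align(
    source: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Proper rigid transform (R, t) minimizing ||R·source + t − target||².

    SVD-based orthogonal Procrustes solution with det(R) = +1 enforced:
    anatomical landmark configurations are chiral, so reflections are
    never an acceptable alignment.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[0] < 3:
        raise ValueError("source and target must be equal-shape (k>=3, 3) arrays")
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (source - mu_s).T @ (target - mu_t)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate configuration: rank < 2 after centering")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = mu_t - rotation @ mu_s
    return rotation, translation


@dataclass
class GPAResult:
    """Aligned unit-size configurations, their mean shape, per-sample
    Procrustes distances from the mean, and the iteration count."""

    aligned: list[np.ndarray]
    mean_shape: np.ndarray
    distances: np.ndarray
    n_iterations: int
    labels: tuple[str, ...]


def gpa(
    samples: list[ShapeSample], tol: float = 1e-8, max_iter: int = 100
) -> GPAResult:
    """Generalized Procrustes alignment of landmark configurations.

    Each sample is centered and scaled to unit centroid size once.  The
    mean shape is initialized from the first sample; every iteration
    rigidly aligns all samples to the current mean and recomputes it,
    until the mean moves less than ``tol`` in Frobenius norm.  No
    rescaling happens inside the loop.
    """
    if len(samples) < 2:
        raise ValueError("GPA needs at least two samples")
    labels = samples[0].labels
    for s in samples[1:]:
        if s.labels != labels:
            raise ValueError("all samples must share the same labels in the same order")
    configs = []
    for s in samples:
        centered = s.coords - s.coords.mean(axis=0)
        configs.append(centered / centroid_size(s))
    mean = configs[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
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
    distances = np.array([np.linalg.norm(c - mean) for c in configs])
    return GPAResult(aligned=configs, mean_shape=mean, distances=distances,
                     n_iterations=n_iter, labels=labels)


def procrustes_distance_from_mean(result: GPAResult) -> np.ndarray:
    """Per-sample root summed squared distance from the mean shape."""
    return np.array([
        np.sqrt(np.sum((c - result.mean_shape) ** 2)) for c in result.aligned
    ])


@dataclass
class ErrorReport:
    """Euclidean landmark-distance statistics between two landmark sets.

    ``distances`` is the (n_subjects, n_landmarks) matrix everything else
    derives from.  Standard deviations use the sample (n−1) convention.
    """

    labels: tuple[str, ...]
    distances: np.ndarray

    @property
    def per_landmark_mean(self) -> np.ndarray:
        return self.distances.mean(axis=0)

    @property
    def per_landmark_sd(self) -> np.ndarray:
        if self.distances.shape[0] < 2:
            return np.zeros(self.distances.shape[1])
        return self.distances.std(axis=0, ddof=1)

    @property
    def per_subject_mean(self) -> np.ndarray:
        return self.distances.mean(axis=1)

    @property
    def overall_mean(self) -> float:
        return float(self.distances.mean())

    @property
    def overall_sd(self) -> float:
        if self.distances.size < 2:
            return 0.0
        return float(self.distances.std(ddof=1))

    def to_dataframe(self) -> pd.DataFrame:
        """Per-landmark mean (SD) rows plus an Overall row, in mm."""
        rows = [
            {"landmark": name, "mean_mm": m, "sd_mm": s}
            for name, m, s in zip(self.labels, self.per_landmark_mean, self.per_landmark_sd)
        ]
        rows.append({"landmark": "Overall", "mean_mm": self.overall_mean,
                     "sd_mm": self.overall_sd})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")

    def to_json(self) -> dict:
        return {
            "per_landmark": {
                name: {"mean_mm": float(m), "sd_mm": float(s)}
                for name, m, s in zip(self.labels, self.per_landmark_mean,
                                      self.per_landmark_sd)
            },
            "overall": {"mean_mm": self.overall_mean, "sd_mm": self.overall_sd},
            "per_subject_mean_mm": [float(v) for v in self.per_subject_mean],
        }


def _distance_matrix(a: list[LandmarkSet3D], b: list[LandmarkSet3D]) -> np.ndarray:
    if len(a) != len(b):
        raise ValueError(f"landmark set lists differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty landmark set lists")
    rows = []
    for lm_a, lm_b in zip(a, b):
        if tuple(lm_a) != tuple(lm_b):
            raise ValueError("landmark name mismatch between sets")
        rows.append(np.linalg.norm(lm_a.to_array() - lm_b.to_array(), axis=1))
    return np.array(rows)


def landmark_errors(a: list[LandmarkSet3D], b: list[LandmarkSet3D]) -> ErrorReport:
    """Per-subject, per-landmark Euclidean distances between two landmark
    set lists (e.g. a method's output vs. one observer's ground truth)."""
    return ErrorReport(labels=tuple(a[0]), distances=_distance_matrix(a, b))


def average_over_observers(
    method: list[LandmarkSet3D],
    obs1: list[LandmarkSet3D],
    obs2: list[LandmarkSet3D],
) -> ErrorReport:
    """Error report against two observers' ground truths.

    Each subject/landmark distance is the mean of the distances to the
    two observers' placements, aggregated exactly as in
    :func:`landmark_errors`.
    """
    d1 = _distance_matrix(method, obs1)
    d2 = _distance_matrix(method, obs2)
    return ErrorReport(labels=tuple(method[0]), distances=0.5 * (d1 + d2))
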