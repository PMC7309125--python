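"""The twelve anatomical facial landmarks and their file formats.

The landmark set covers the central facial substructures: the eye corners
(endocanthion ``en``, exocanthion ``ex``), the nasal midline (nasion ``n``,
pronasale ``prn``, subnasale ``sn``), the mouth (cheilion ``ch``, labiale
superius ``ls``, labiale inferius ``li``) and the chin (gnathion ``gn``).
Suffixes ``_r``/``_l`` denote the subject's anatomical right/left.

Files are CSV with header ``name,x,y,z`` (mm, 6 decimals) or JSON
``{"name": [x, y, z], ...}``.
"""

from __future__ import annotations

import csv
import json
from collections.abc import Mapping
from pathlib import Path

import numpy as np

__all__ = [
    "LANDMARK_NAMES",
    "LandmarkSet3D",
    "read_landmarks",
    "write_landmarks",
]

#: Canonical order of the twelve landmark names.
LANDMARK_NAMES: tuple[str, ...] = (
    "en_r", "en_l", "ex_r", "ex_l", "n", "prn",
    "sn", "gn", "ch_r", "ch_l", "ls", "li",
)


class LandmarkSet3D(Mapping):
    """An ordered mapping from the 12 landmark names to 3D points in mm.

    Always contains exactly the names in :data:`LANDMARK_NAMES`, in that
    order; iteration, :meth:`to_array` and file output all use it.
    """

    __slots__ = ("_points",)

    def __init__(self, points: Mapping[str, np.ndarray]):
        missing = set(LANDMARK_NAMES) - set(points)
        extra = set(points) - set(LANDMARK_NAMES)
        if missing or extra:
            raise ValueError(
                f"landmark set must contain exactly the 12 names; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        pts = {}
        for name in LANDMARK_NAMES:
            p = np.asarray(points[name], dtype=np.float64).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"non-finite coordinates for landmark {name!r}")
            pts[name] = p
        self._points = pts

    def __getitem__(self, name: str) -> np.ndarray:
        return self._points[name]

    def __iter__(self):
        return iter(LANDMARK_NAMES)

    def __len__(self) -> int:
        return 12

    def to_array(self) -> np.ndarray:
        """(12, 3) array in canonical name order."""
        return np.array([self._points[n] for n in LANDMARK_NAMES])

    @classmethod
    def from_array(cls, coords: np.ndarray) -> "LandmarkSet3D":
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != (12, 3):
            raise ValueError(f"expected (12, 3) coordinates, got {coords.shape}")
        return cls(dict(zip(LANDMARK_NAMES, coords)))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet3D":
        """``R x + t`` applied to every landmark."""
        arr = self.to_array() @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return LandmarkSet3D.from_array(arr)

    def __repr__(self) -> str:
        return f"LandmarkSet3D({len(self)} landmarks)"


def write_landmarks(lm: LandmarkSet3D, path: str | Path, format: str | None = None) -> None:
    """Write landmarks as CSV (``name,x,y,z``, 6 decimals) or JSON."""
    path = Path(path)
    format = (format or path.suffix.lstrip(".")).lower()
    if format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "x", "y", "z"])
            for name in LANDMARK_NAMES:
                x, y, z = lm[name]
                w.writerow([name, f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"])
    elif format == "json":
        payload = {name: [round(float(c), 6) for c in lm[name]] for name in LANDMARK_NAMES}
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValueError(f"unsupported landmark format {format!r} (use csv or json)")


def read_landmarks(path: str | Path, format: str | None = None) -> LandmarkSet3D:
    """Read a landmark file written by :func:`write_landmarks`."""
    path = Path(path)
    format = (format or path.suffix.lstrip(".")).lower()
    if format == "csv":
        points = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or [f.strip() for f in reader.fieldnames[:4]] != ["name", "x", "y", "z"]:
                raise ValueError(f"{path}: expected CSV header 'name,x,y,z'")
            for row in reader:
                points[row["name"]] = np.array(
                    [float(row["x"]), float(row["y"]), float(row["z"])]
                )
        return LandmarkSet3D(points)
    if format == "json":
        payload = json.loads(Path(path).read_text())
        return LandmarkSet3D({k: np.asarray(v, float) for k, v in payload.items()})
    raise ValueError(f"unsupported landmark format {format!r} (use csv or json)")
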