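"""Regression targets and bounding boxes from per-frame hyoid annotations.

Raters mark the anterior point of the hyoid bone plus the C2 and C4 vertebral
landmarks on every video frame.  The pipeline here (a) re-expresses the
anterior point in a patient-intrinsic vertebral frame — origin at C4,
superior axis along C4->C2, unit length |C2-C4| — which corrects rigid
per-frame patient motion and normalises anatomy across participants, (b)
removes each swallow's starting offset so the target describes movement, and
(c) min-max scales the two axes to [0, 1] using training-set extrema only.

Image coordinates follow the video convention (origin top-left, y down); the
vertebral frame flips that so superior displacement is positive, and takes
the patient as facing image-left so anterior displacement is positive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HyoidAnnotation",
    "BoundingBox",
    "TargetScaler",
    "box_side_from_diagonal",
    "standardize_by_vertebra",
    "pixels_from_standardized",
    "remove_offset",
    "trajectory_to_boxes",
    "DEFAULT_BOX_SIDE",
]

#: Square box side from the 49-px mean anterior-posterior hyoid diagonal.
DEFAULT_BOX_SIDE = 35


@dataclass
class HyoidAnnotation:
    """One rater's frame-by-frame annotation of a swallow.

    ``anterior``, ``c2`` and ``c4`` are (n_frames, 2) pixel coordinate arrays
    (x, y); landmarks may move frame to frame with the patient.
    """

    anterior: np.ndarray
    c2: np.ndarray
    c4: np.ndarray
    rater_id: str = "rater0"

    def __post_init__(self) -> None:
        self.anterior = np.asarray(self.anterior, dtype=float)
        self.c2 = np.atleast_2d(np.asarray(self.c2, dtype=float))
        self.c4 = np.atleast_2d(np.asarray(self.c4, dtype=float))
        n = self.anterior.shape[0]
        if self.anterior.ndim != 2 or self.anterior.shape[1] != 2:
            raise ValueError("anterior must have shape (n_frames, 2)")
        for name in ("c2", "c4"):
            arr = getattr(self, name)
            if arr.shape == (1, 2) and n > 1:   # static landmark broadcast
                arr = np.repeat(arr, n, axis=0)
                setattr(self, name, arr)
            if getattr(self, name).shape != (n, 2):
                raise ValueError(f"{name} must match anterior frame count")

    @property
    def n_frames(self) -> int:
        return self.anterior.shape[0]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned square approximating the hyoid body on one frame."""

    center: tuple[float, float]
    side: float = DEFAULT_BOX_SIDE

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("box side must be positive")

    @property
    def area(self) -> float:
        return self.side ** 2


def box_side_from_diagonal(diagonal: float) -> int:
    """Side length (integer pixels) of a square with the given diagonal."""
    if diagonal <= 0:
        raise ValueError("diagonal must be positive")
    return int(round(diagonal / math.sqrt(2.0)))


def _vertebral_axes(c2: np.ndarray, c4: np.ndarray):
    """Per-frame unit axes and lengths of the C2-C4 referential frame.

    Returns (u, v, L): ``v`` points C4->C2 (superior), ``u`` is the in-plane
    perpendicular chosen so a patient facing image-left gets positive anterior
    displacement, ``L`` = |C2-C4| in pixels.
    """
    diff = c2 - c4
    L = np.linalg.norm(diff, axis=1)
    if np.any(L == 0):
        raise ValueError("degenerate vertebral axis: C2 == C4")
    v = diff / L[:, None]
    u = np.column_stack([v[:, 1], -v[:, 0]])
    return u, v, L


def standardize_by_vertebra(ann: HyoidAnnotation) -> np.ndarray:
    """Anterior point in vertebral coordinates, shape (n_frames, 2).

    Column 0 is anterior displacement, column 1 superior, both in units of
    the participant's vertebral length.  Invariant to rigid per-frame
    translation and rotation of the whole image.
    """
    u, v, L = _vertebral_axes(ann.c2, ann.c4)
    rel = ann.anterior - ann.c4
    x = np.einsum("ij,ij->i", rel, u) / L
    y = np.einsum("ij,ij->i", rel, v) / L
    return np.column_stack([x, y])


def pixels_from_standardized(std: np.ndarray, c2: np.ndarray,
                             c4: np.ndarray) -> np.ndarray:
    """Inverse of :func:`standardize_by_vertebra` given the landmark tracks."""
    std = np.asarray(std, dtype=float)
    c2 = np.atleast_2d(np.asarray(c2, dtype=float))
    c4 = np.atleast_2d(np.asarray(c4, dtype=float))
    if c2.shape[0] == 1:
        c2 = np.repeat(c2, std.shape[0], axis=0)
        c4 = np.repeat(c4, std.shape[0], axis=0)
    u, v, L = _vertebral_axes(c2, c4)
    return c4 + (std[:, :1] * u + std[:, 1:] * v) * L[:, None]


def remove_offset(trajectory: np.ndarray) -> np.ndarray:
    """Subtract the first frame so the swallow starts at the origin."""
    traj = np.asarray(trajectory, dtype=float)
    if traj.shape[0] < 1:
        raise ValueError("trajectory is empty")
    return traj - traj[0]


@dataclass
class TargetScaler:
    """Per-axis min-max scaler for 2-D target trajectories.

    Extrema are taken over all frames of all training swallows.  Test
    trajectories outside the training range scale outside [0, 1] and are not
    clipped; ``unscale`` inverts ``scale`` exactly.
    """

    minimum: np.ndarray | None = None
    maximum: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.minimum is not None

    def fit(self, trajectories: list[np.ndarray]) -> "TargetScaler":
        if not trajectories:
            raise ValueError("training set is empty")
        stacked = np.vstack([np.asarray(t, dtype=float) for t in trajectories])
        self.minimum = stacked.min(axis=0)
        self.maximum = stacked.max(axis=0)
        if np.any(self.maximum <= self.minimum):
            raise ValueError("degenerate target axis: no variation in training set")
        return self

    def scale(self, traj: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("scaler has not been fitted")
        return (np.asarray(traj, dtype=float) - self.minimum) / (
            self.maximum - self.minimum)

    def unscale(self, scaled: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("scaler has not been fitted")
        return np.asarray(scaled, dtype=float) * (
            self.maximum - self.minimum) + self.minimum

    def to_json(self) -> str:
        if not self.fitted:
            raise ValueError("scaler has not been fitted")
        return json.dumps({"minimum": self.minimum.tolist(),
                           "maximum": self.maximum.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "TargetScaler":
        obj = json.loads(text)
        return cls(np.asarray(obj["minimum"]), np.asarray(obj["maximum"]))


def build_target(ann: HyoidAnnotation) -> np.ndarray:
    """Standardize by vertebral frame then remove the starting offset."""
    return remove_offset(standardize_by_vertebra(ann))


def trajectory_to_boxes(trajectory: np.ndarray,
                        side: float = DEFAULT_BOX_SIDE) -> list[BoundingBox]:
    """One axis-aligned square box centred on each frame's pixel point."""
    traj = np.asarray(trajectory, dtype=float)
    return [BoundingBox((float(x), float(y)), side) for x, y in traj]
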