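"""Rigid-body least-squares superposition and RMSD-based model comparison.

Implements the proper-rotation Kabsch fit (reflections excluded, so peptide
chirality is preserved), pairwise RMSD after optimal superposition, whole-
model RMSD matrices, centroid (representative frame) selection, and
best-of-K comparison of candidate models against a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import AssemblyModel, ModelValidationError, require_same_layout

__all__ = [
    "RigidTransform",
    "RmsdMatrix",
    "DegenerateGeometryError",
    "kabsch_fit",
    "rmsd_after_fit",
    "model_rmsd_matrix",
    "centroid_model",
    "best_model_rmsd",
]


class DegenerateGeometryError(ValueError):
    """Raised when a point set is too degenerate for a unique rigid fit."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation: x -> R x + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    @property
    def rotation_angle(self) -> float:
        """Rotation magnitude in degrees."""
        return float(np.degrees(Rotation.from_matrix(self.rotation).magnitude()))

    def screw_parameters(self) -> tuple[np.ndarray | None, float, float]:
        """Decompose into (axis, angle_deg, rise).

        ``rise`` is the translation component along the rotation axis (the
        screw invariant). For a (near-)pure translation the axis is the
        translation direction and the angle is ~0.
        """
        rot = Rotation.from_matrix(self.rotation)
        angle = float(np.degrees(rot.magnitude()))
        if angle < 1e-9:
            norm = float(np.linalg.norm(self.translation))
            axis = self.translation / norm if norm > 0 else None
            return axis, 0.0, norm
        axis = rot.as_rotvec()
        axis = axis / np.linalg.norm(axis)
        rise = float(self.translation @ axis)
        if rise < 0:  # orient the axis so the screw advances forward
            axis, rise = -axis, -rise
        return axis, angle, rise


@dataclass
class RmsdMatrix:
    """Symmetric pairwise RMSD matrix with zero diagonal (Angstrom)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.values = v
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-6):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _as_points(points, name: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return pts


def _check_nondegenerate(pts: np.ndarray, name: str) -> None:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0 or s[1] / s[0] <= 1e-12:
        raise DegenerateGeometryError(
            f"{name} is collinear (or coincident); the rotation about the "
            "line is undetermined"
        )


def kabsch_fit(mobile, target) -> RigidTransform:
    """Least-squares proper rotation + translation mapping mobile onto target.

    Point sets must have equal counts (>= 3) with assumed 1:1 correspondence.
    """
    mobile = _as_points(mobile, "mobile")
    target = _as_points(target, "target")
    if len(mobile) != len(target):
        raise ValueError("point sets must have equal counts")
    if len(mobile) < 3:
        raise ValueError("at least 3 points are required for a rigid fit")
    _check_nondegenerate(mobile, "mobile")
    _check_nondegenerate(target, "target")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    # align_vectors returns the proper rotation (Kabsch with the sign of the
    # smallest singular value corrected), never a reflection
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    r = rot.as_matrix()
    return RigidTransform(rotation=r, translation=tc - r @ mc)


def rmsd(a, b) -> float:
    """Plain coordinate RMSD without superposition."""
    a = _as_points(a, "a")
    b = _as_points(b, "b")
    if a.shape != b.shape:
        raise ValueError("point sets must have equal shapes")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_after_fit(a, b) -> float:
    """RMSD between two point sets after optimal rigid superposition."""
    t = kabsch_fit(a, b)
    return rmsd(t.apply(a), b)


def model_rmsd_matrix(models: Sequence[AssemblyModel],
                      labels: Sequence[str] | None = None) -> RmsdMatrix:
    """All-CA pairwise RMSD-after-fit matrix over whole models."""
    models = list(models)
    if len(models) < 2:
        raise ModelValidationError("need at least 2 models for a matrix")
    require_same_layout(models)
    if labels is None:
        labels = [m.label or f"model{i}" for i, m in enumerate(models)]
    coords = [m.ca_coords() for m in models]
    n = len(models)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = rmsd_after_fit(coords[i], coords[j])
    return RmsdMatrix(labels=list(labels), values=values)


def centroid_model(frames: Sequence[AssemblyModel]) -> tuple[int, AssemblyModel]:
    """Frame minimizing the mean RMSD-after-fit to all other frames.

    This is the representative ("central cluster") structure of a trajectory
    window treated as a single cluster. Ties break to the lowest index.
    """
    frames = list(frames)
    if not frames:
        raise ModelValidationError("empty frame list")
    if len(frames) == 1:
        return 0, frames[0]
    matrix = model_rmsd_matrix(frames)
    mean_to_others = matrix.values.sum(axis=1) / (len(frames) - 1)
    idx = int(np.argmin(mean_to_others))
    return idx, frames[idx]


def best_model_rmsd(candidates: Sequence[AssemblyModel],
                    reference: AssemblyModel) -> tuple[int, float]:
    """Candidate with the lowest all-CA RMSD-after-fit to the reference.

    Fibrils carry no intrinsic chain labeling, so each candidate is compared
    both in its given chain order and with the order reversed; the lower
    RMSD counts.
    """
    candidates = list(candidates)
    if not candidates:
        raise ModelValidationError("empty candidate list")
    require_same_layout([reference] + candidates)
    ref = reference.ca_coords()
    best_idx, best_val = 0, np.inf
    for i, cand in enumerate(candidates):
        fwd = rmsd_after_fit(cand.ca_coords(), ref)
        rev = rmsd_after_fit(cand.reversed_chains().ca_coords(), ref)
        val = min(fwd, rev)
        if val < best_val:
            best_idx, best_val = i, val
    return best_idx, float(best_val)
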