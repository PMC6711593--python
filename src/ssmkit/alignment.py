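"""Landmark-based rigid alignment.

Alignment is rigid (rotation + translation) by default. Uniform scaling is
available via ``with_scale`` but off by default: downstream shape models are
meant to capture absolute size variation, so size must not be normalized
away. Reflections are always suppressed (det(R) forced to +1) — left/right
anatomy must never flip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConvergenceError, DegenerateConfigurationError
from .geometry_io import CorrespondedShapeSet, LandmarkSet, TriMesh

__all__ = [
    "RigidTransform",
    "fit_rigid",
    "alignment_residual",
    "apply_transform",
    "generalized_procrustes",
]


@dataclass(frozen=True, eq=False)
class RigidTransform:
    """y = scale * R @ x + t, with R proper orthonormal."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1 (no reflections)")
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "scale", float(self.scale))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ (self.scale * self.rotation).T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        s = 1.0 / self.scale
        return RigidTransform(Rinv, -s * Rinv @ self.translation, s)

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``inner`` first, then ``self``."""
        s = self.scale * inner.scale
        R = self.rotation @ inner.rotation
        t = self.scale * self.rotation @ inner.translation + self.translation
        return RigidTransform(R, t, s)

    # JSON serialization: row-major rotation, translation, scale
    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.ravel().tolist(),
            "translation": self.translation.tolist(),
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            np.asarray(d["rotation"], dtype=np.float64).reshape(3, 3),
            np.asarray(d["translation"], dtype=np.float64),
            float(d.get("scale", 1.0)),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _check_nondegenerate(centered: np.ndarray, label: str) -> None:
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] <= 0 or s[1] <= 1e-10 * max(s[0], 1.0):
        raise DegenerateConfigurationError(
            f"{label} points are collinear or coincident; cannot fix a rotation"
        )


def fit_rigid(
    source_points: np.ndarray, target_points: np.ndarray, with_scale: bool = False
) -> RigidTransform:
    """Least-squares rigid (optionally similarity) transform source → target.

    Minimizes sum ||T(s_i) - t_i||^2 over proper rotations (Kabsch/Umeyama);
    reflections are suppressed. Requires >= 3 non-collinear points.
    """
    src = np.asarray(source_points, dtype=np.float64).reshape(-1, 3)
    tgt = np.asarray(target_points, dtype=np.float64).reshape(-1, 3)
    if src.shape != tgt.shape:
        raise ValueError(f"point sets differ in shape: {src.shape} vs {tgt.shape}")
    k = src.shape[0]
    if k < 3:
        raise DegenerateConfigurationError(f"need at least 3 points, got {k}")
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    S0, T0 = src - sc, tgt - tc
    _check_nondegenerate(S0, "source")
    _check_nondegenerate(T0, "target")
    H = S0.T @ T0
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if with_scale:
        scale = float(np.trace(D @ np.diag(s)) / np.sum(S0 * S0))
    else:
        scale = 1.0
    t = tc - scale * R @ sc
    return RigidTransform(R, t, scale)


def alignment_residual(
    transform: RigidTransform, source_points: np.ndarray, target_points: np.ndarray
) -> float:
    """RMS distance between transformed source and target (diagnostic)."""
    diff = transform.apply(source_points) - np.asarray(target_points, np.float64)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def apply_transform(obj, transform: RigidTransform):
    """Apply a transform pointwise to a TriMesh, LandmarkSet or (n,3) array."""
    if isinstance(obj, TriMesh):
        return obj.with_vertices(transform.apply(obj.vertices))
    if isinstance(obj, LandmarkSet):
        return obj.with_points(transform.apply(obj.points))
    return transform.apply(np.asarray(obj, dtype=np.float64))


def _canonical_rotation(config: np.ndarray) -> np.ndarray:
    """Rotation mapping a centered configuration into a canonical frame:
    principal axes onto xyz, signs fixed by third moments, det +1.

    Makes the GPA output orientation independent of any common rigid
    transform applied to all inputs (up to configurations with degenerate
    inertia or vanishing third moments)."""
    c = config - config.mean(axis=0)
    _w, V = np.linalg.eigh(c.T @ c)
    V = V[:, ::-1]  # descending variance
    m3 = ((c @ V) ** 3).sum(axis=0)
    signs = np.where(m3 >= 0, 1.0, -1.0)
    V = V * signs
    if np.linalg.det(V) < 0:
        V[:, int(np.argmin(np.abs(m3)))] *= -1
    return V.T


def generalized_procrustes(
    shape_set: CorrespondedShapeSet,
    landmark_names=None,
    *,
    with_scale: bool = False,
    tol: float = 1e-8,
    max_iters: int = 100,
):
    """Iteratively align all specimens to their evolving mean landmark
    configuration; only the chosen landmarks drive the alignment, but the
    fitted transform is applied to the full vertex set and every landmark.

    Returns ``(aligned_set, mean_configuration)``; the mean configuration is
    centered at the origin and rotated into a canonical principal-axes
    frame, so the output does not depend on the inputs' common pose.
    """
    if shape_set.n_specimens < 2:
        raise DegenerateConfigurationError("GPA needs at least 2 specimens")
    names = tuple(landmark_names) if landmark_names is not None else shape_set.landmark_names
    if len(names) < 3:
        raise DegenerateConfigurationError(
            f"GPA needs at least 3 landmarks, got {len(names)}"
        )
    configs = [ls.subset(names).points for ls in shape_set.landmarks]
    mean = configs[0] - configs[0].mean(axis=0)
    transforms = None
    shift = np.inf
    for _ in range(max_iters):
        transforms = [fit_rigid(cfg, mean, with_scale=with_scale) for cfg in configs]
        aligned = np.stack([T.apply(cfg) for T, cfg in zip(transforms, configs)])
        new_mean = aligned.mean(axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iters} iterations "
            f"(last mean shift {shift:.3e} mm)",
            residual=shift,
        )
    canon = RigidTransform(_canonical_rotation(mean), np.zeros(3))
    transforms = [canon.compose(T) for T in transforms]
    mean = canon.apply(mean)
    meshes = tuple(
        apply_transform(m, T) for m, T in zip(shape_set.meshes, transforms)
    )
    landmarks = tuple(
        apply_transform(ls, T) for ls, T in zip(shape_set.landmarks, transforms)
    )
    aligned_set = CorrespondedShapeSet(meshes, landmarks, dict(shape_set.region_masks))
    return aligned_set, mean
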