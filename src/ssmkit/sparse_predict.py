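"""Predict a full shape (surface + all landmarks) from sparse observed
landmarks.

The score solve minimizes

    ||Phi_S b - (y - mu_S)||^2 + rho * sum_k b_k^2 / lambda_k

where the subscript ``S`` selects the observed landmarks' rows out of the
shape vector. Neither term is normalized by point count or component count;
``rho`` is defined against this convention, so rescale it if you change the
number of observed points by orders of magnitude.

Observation-frame handling: observed landmarks are rigidly aligned to the
model frame by alternating (i) a rigid fit of the observations onto the
current predicted landmark positions (initialized at the mean's landmarks)
with (ii) the regularized score solve, iterated to a fixed point. One-shot
alignment to the mean is the special case ``max_align_iters=1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .alignment import RigidTransform, fit_rigid
from .errors import InsufficientLandmarksError, RankDeficiencyError, UnknownLandmarkError
from .geometry_io import LandmarkSet, TriMesh
from .shape_model import ShapeModel, n_components_for_variance

__all__ = [
    "PredictionConfig",
    "PredictedShape",
    "selection_rows",
    "solve_scores",
    "score_objective",
    "predict_from_landmarks",
    "predicted_landmarks",
    "predicted_mesh",
]

# relative floor on eigenvalues entering the Mahalanobis term; keeps the
# prior finite on numerically-null modes
EIGENVALUE_FLOOR_REL = 1e-10
_EIGENVALUE_FLOOR_ABS = 1e-12


@dataclass(frozen=True)
class PredictionConfig:
    """Settings for sparse-landmark prediction.

    ``n_pcs=None`` selects the smallest number of components explaining
    ``variance_fraction`` of the model variance (default 0.95).
    """

    rho: float = 0.5
    n_pcs: int | None = None
    variance_fraction: float = 0.95
    max_align_iters: int = 20
    align_tol: float = 1e-6

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError(f"rho must be nonnegative, got {self.rho}")
        if self.n_pcs is not None and self.n_pcs < 1:
            raise ValueError(f"n_pcs must be >= 1, got {self.n_pcs}")
        if not 0.0 < self.variance_fraction <= 1.0:
            raise ValueError(
                f"variance_fraction must be in (0, 1], got {self.variance_fraction}"
            )
        if self.max_align_iters < 1:
            raise ValueError("max_align_iters must be >= 1")
        if not self.align_tol > 0:
            raise ValueError("align_tol must be positive")

    def resolve_n_pcs(self, model: ShapeModel) -> int:
        if self.n_pcs is not None:
            return min(self.n_pcs, model.n_components)
        return n_components_for_variance(model, self.variance_fraction)


@dataclass(frozen=True, eq=False)
class PredictedShape:
    """Output of a sparse-landmark prediction.

    ``shape`` lives in the model frame; ``transform`` maps model frame →
    observation frame. ``landmark_residuals`` are the per-observed-landmark
    fit distances in mm.
    """

    shape: np.ndarray
    scores: np.ndarray
    transform: RigidTransform
    landmark_residuals: dict
    model: ShapeModel


def selection_rows(model: ShapeModel, observed_names) -> np.ndarray:
    """Row indices (3 per landmark, observation order) of the observed
    landmarks inside the model's shape vector."""
    return model.layout.rows_for(tuple(observed_names))


def _floored_eigenvalues(model: ShapeModel, n_pcs: int) -> np.ndarray:
    lam = model.eigenvalues[:n_pcs].copy()
    floor = max(EIGENVALUE_FLOOR_REL * (lam[0] if lam.size else 0.0),
                _EIGENVALUE_FLOOR_ABS)
    return np.maximum(lam, floor)


def solve_scores(
    model: ShapeModel,
    observed_points: np.ndarray,
    rows: np.ndarray,
    config: PredictionConfig,
) -> np.ndarray:
    """Closed-form minimizer of the regularized landmark-fit objective.

    ``observed_points`` are in the model frame, shaped (m, 3) or flat (3m,),
    ordered consistently with ``rows``.
    """
    y = np.asarray(observed_points, dtype=np.float64).ravel()
    rows = np.asarray(rows, dtype=np.int64).ravel()
    if y.shape[0] != rows.shape[0]:
        raise ValueError(
            f"{y.shape[0]} observed coordinates but {rows.shape[0]} selection rows"
        )
    n_pcs = config.resolve_n_pcs(model)
    Phi = model.components[rows, :n_pcs]
    d = y - model.mean[rows]
    if config.rho == 0.0:
        if np.linalg.matrix_rank(Phi, tol=1e-10 * max(1.0, abs(Phi).max())) < n_pcs:
            raise RankDeficiencyError(
                f"rho=0 with rank-deficient system: {Phi.shape[0]} constraint rows "
                f"cannot determine {n_pcs} components"
            )
        b, *_ = np.linalg.lstsq(Phi, d, rcond=None)
        return b
    lam = _floored_eigenvalues(model, n_pcs)
    A = Phi.T @ Phi + config.rho * np.diag(1.0 / lam)
    return scipy.linalg.solve(A, Phi.T @ d, assume_a="pos")


def score_objective(
    model: ShapeModel,
    scores: np.ndarray,
    observed_points: np.ndarray,
    rows: np.ndarray,
    config: PredictionConfig,
) -> float:
    """Value of the objective being minimized (diagnostic / testing)."""
    b = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(observed_points, dtype=np.float64).ravel()
    n_pcs = b.size
    Phi = model.components[np.asarray(rows).ravel(), :n_pcs]
    resid = Phi @ b - (y - model.mean[np.asarray(rows).ravel()])
    lam = _floored_eigenvalues(model, n_pcs)
    return float(resid @ resid + config.rho * np.sum(b * b / lam))


def predict_from_landmarks(
    model: ShapeModel,
    observed: LandmarkSet,
    config: PredictionConfig | None = None,
) -> PredictedShape:
    """Reconstruct the full shape from a sparse observed landmark set.

    Alternates rigid alignment of the observations to the current predicted
    landmark positions with the regularized score solve, until the predicted
    landmark positions move less than ``config.align_tol`` (RMS, mm).
    """
    config = config or PredictionConfig()
    for name in observed.names:
        if name not in model.layout.landmark_names:
            raise UnknownLandmarkError(
                f"observed landmark {name!r} not in model; valid names: "
                f"{list(model.layout.landmark_names)}"
            )
    if len(observed) < 3:
        raise InsufficientLandmarksError(
            f"need at least 3 observed landmarks for alignment, got {len(observed)}"
        )
    rows = selection_rows(model, observed.names)
    n_pcs = config.resolve_n_pcs(model)
    obs = observed.points
    target = model.mean[rows].reshape(-1, 3)
    b = np.zeros(n_pcs)
    transform = RigidTransform.identity()
    for _ in range(config.max_align_iters):
        transform = fit_rigid(obs, target)
        y = transform.apply(obs)
        b = solve_scores(model, y, rows, config)
        new_target = (model.mean[rows] + model.components[rows, :n_pcs] @ b).reshape(-1, 3)
        change = float(np.sqrt(np.mean(np.sum((new_target - target) ** 2, axis=1))))
        target = new_target
        if change < config.align_tol:
            break
    shape = model.mean + model.components[:, :n_pcs] @ b
    y = transform.apply(obs)
    residuals = {
        name: float(np.linalg.norm(y[i] - target[i]))
        for i, name in enumerate(observed.names)
    }
    return PredictedShape(shape, b, transform.inverse(), residuals, model)


def predicted_landmarks(prediction: PredictedShape, names) -> LandmarkSet:
    """Extract landmarks (observed or unobserved, e.g. joint centers) from a
    prediction, mapped into the observation frame."""
    names = tuple(names)
    rows = prediction.model.layout.rows_for(names)
    pts = prediction.shape[rows].reshape(-1, 3)
    return LandmarkSet(names, prediction.transform.apply(pts), "predicted")


def predicted_mesh(prediction: PredictedShape) -> TriMesh:
    """The predicted surface in the observation frame."""
    verts = prediction.model.layout.vertex_part(prediction.shape)
    return TriMesh(prediction.transform.apply(verts), prediction.model.faces, "predicted")
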