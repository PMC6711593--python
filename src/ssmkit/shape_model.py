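"""PCA statistical shape model over stacked vertex + landmark coordinates.

A specimen is flattened into one shape vector of length
``3 * (n_vertices + n_landmarks)``, ordered ``[all vertices xyz..., all
landmarks xyz...]``. Landmark coordinates enter the model exactly like
vertex coordinates (no differential weighting).

Conventions (documented because they set the scale of downstream
regularization): the sample covariance divides by ``n - 1``, so eigenvalues
are in mm^2 on that scale; eigenvector signs are fixed by flipping each
component so its largest-magnitude entry is positive.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import CorrespondenceError, ModelFormatError, UnknownLandmarkError
from .geometry_io import CorrespondedShapeSet, LandmarkSet, TriMesh

__all__ = [
    "ShapeLayout",
    "ShapeModel",
    "shape_vector",
    "build_ssm",
    "n_components_for_variance",
    "reconstruct",
    "project",
    "save_model",
    "load_model",
    "merge_shape_sets",
]

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ShapeLayout:
    """Index map between a flat shape vector and vertices / named landmarks."""

    n_vertices: int
    landmark_names: tuple

    def __post_init__(self):
        object.__setattr__(self, "landmark_names", tuple(self.landmark_names))

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_names)

    @property
    def dim(self) -> int:
        return 3 * (self.n_vertices + self.n_landmarks)

    def landmark_rows(self, name: str) -> np.ndarray:
        """The 3 contiguous rows holding one landmark's xyz."""
        try:
            i = self.landmark_names.index(name)
        except ValueError:
            raise UnknownLandmarkError(
                f"unknown landmark {name!r}; valid names: {list(self.landmark_names)}"
            ) from None
        base = 3 * (self.n_vertices + i)
        return np.arange(base, base + 3)

    def rows_for(self, names) -> np.ndarray:
        if len(names) == 0:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([self.landmark_rows(n) for n in names])

    def vertex_part(self, vec: np.ndarray) -> np.ndarray:
        return np.asarray(vec)[: 3 * self.n_vertices].reshape(-1, 3)

    def landmark_part(self, vec: np.ndarray) -> np.ndarray:
        return np.asarray(vec)[3 * self.n_vertices:].reshape(-1, 3)

    def to_dict(self) -> dict:
        return {"n_vertices": self.n_vertices,
                "landmark_names": list(self.landmark_names)}

    @classmethod
    def from_dict(cls, d: dict) -> "ShapeLayout":
        return cls(int(d["n_vertices"]), tuple(d["landmark_names"]))


@dataclass(frozen=True, eq=False)
class ShapeModel:
    """Fitted statistical shape model: mean, eigenvectors, eigenvalues."""

    mean: np.ndarray
    components: np.ndarray  # (dim, k), orthonormal columns
    eigenvalues: np.ndarray  # (k,), mm^2, non-increasing
    n_training: int
    layout: ShapeLayout
    faces: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=np.float64).ravel()
        comp = np.asarray(self.components, dtype=np.float64)
        lam = np.asarray(self.eigenvalues, dtype=np.float64).ravel()
        if mean.shape[0] != self.layout.dim:
            raise ModelFormatError(
                f"mean length {mean.shape[0]} != layout dim {self.layout.dim}"
            )
        if comp.shape != (self.layout.dim, lam.shape[0]):
            raise ModelFormatError(
                f"components shape {comp.shape} inconsistent with layout/eigenvalues"
            )
        if lam.size and (np.any(lam < -1e-12) or np.any(np.diff(lam) > 1e-12)):
            raise ModelFormatError("eigenvalues must be nonnegative and non-increasing")
        if comp.size:
            gram = comp.T @ comp
            if not np.allclose(gram, np.eye(comp.shape[1]), atol=1e-8):
                raise ModelFormatError("component columns are not orthonormal")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "components", comp)
        object.__setattr__(self, "eigenvalues", np.maximum(lam, 0.0))
        object.__setattr__(self, "faces", np.asarray(self.faces, dtype=np.int64))

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def mean_mesh(self) -> TriMesh:
        return TriMesh(self.layout.vertex_part(self.mean), self.faces, "mean")

    def mean_landmarks(self) -> LandmarkSet:
        return LandmarkSet(self.layout.landmark_names,
                           self.layout.landmark_part(self.mean), "mean")


def shape_vector(mesh: TriMesh, landmarks: LandmarkSet, landmark_names=None) -> np.ndarray:
    """Flatten one specimen into the model's vector layout."""
    names = tuple(landmark_names) if landmark_names is not None else landmarks.names
    pts = landmarks.subset(names).points
    return np.concatenate([mesh.vertices.ravel(), pts.ravel()])


def _fix_signs(components: np.ndarray) -> np.ndarray:
    # deterministic across LA backends: largest-|entry| of each column positive
    if components.size == 0:
        return components
    idx = np.argmax(np.abs(components), axis=0)
    signs = np.sign(components[idx, np.arange(components.shape[1])])
    signs[signs == 0] = 1.0
    return components * signs


def build_ssm(shape_set: CorrespondedShapeSet, landmark_names=None) -> ShapeModel:
    """Fit the PCA model on an aligned shape set.

    The caller is responsible for prior alignment (e.g. via
    :func:`ssmkit.alignment.generalized_procrustes`). The mean is the
    arithmetic mean of shape vectors; eigenvectors/eigenvalues come from a
    thin SVD of the centered data, eigenvalues scaled as sample covariance
    (divide by n - 1). All ``n - 1`` possible components are retained.
    """
    n = shape_set.n_specimens
    if n < 2:
        raise CorrespondenceError(f"need at least 2 specimens to build a model, got {n}")
    names = tuple(landmark_names) if landmark_names is not None else shape_set.landmark_names
    X = np.stack([
        shape_vector(m, ls, names)
        for m, ls in zip(shape_set.meshes, shape_set.landmarks)
    ])
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, Xc.shape[1])
    lam = (s[:k] ** 2) / (n - 1)
    comp = _fix_signs(Vt[:k].T)
    layout = ShapeLayout(shape_set.n_vertices, names)
    return ShapeModel(mean, comp, lam, n, layout, shape_set.faces)


def n_components_for_variance(model: ShapeModel, fraction: float) -> int:
    """Smallest k whose leading eigenvalues explain >= ``fraction`` of the
    total variance."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    lam = model.eigenvalues
    total = float(lam.sum())
    if total <= 0.0:
        return 1
    ratios = np.cumsum(lam) / total
    k = int(np.searchsorted(ratios, fraction - 1e-12, side="left")) + 1
    return min(k, lam.size)


def reconstruct(model: ShapeModel, scores: np.ndarray) -> np.ndarray:
    """x = mean + components[:, :m] @ scores."""
    b = np.asarray(scores, dtype=np.float64).ravel()
    if b.size > model.n_components:
        raise ValueError(
            f"{b.size} scores but model has {model.n_components} components"
        )
    return model.mean + model.components[:, : b.size] @ b


def project(model: ShapeModel, shape: np.ndarray, n_pcs: int | None = None) -> np.ndarray:
    """b = components[:, :n_pcs].T @ (x - mean)."""
    x = np.asarray(shape, dtype=np.float64).ravel()
    if x.shape[0] != model.layout.dim:
        raise ModelFormatError(
            f"shape vector length {x.shape[0]} != model dim {model.layout.dim}"
        )
    m = model.n_components if n_pcs is None else int(n_pcs)
    if not 0 <= m <= model.n_components:
        raise ValueError(f"n_pcs must be in [0, {model.n_components}], got {m}")
    return model.components[:, :m].T @ (x - model.mean)


# ---------------------------------------------------------------------------
# serialization: one zip container holding raw arrays + JSON metadata


def save_model(model: ShapeModel, path) -> None:
    buf = io.BytesIO()
    np.savez_compressed(
        buf,
        mean=model.mean,
        components=model.components,
        eigenvalues=model.eigenvalues,
        faces=model.faces,
    )
    meta = {
        "format_version": _MODEL_FORMAT_VERSION,
        "n_training": model.n_training,
        "layout": model.layout.to_dict(),
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("arrays.npz", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta, indent=1))


def load_model(path) -> ShapeModel:
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            arrays = np.load(io.BytesIO(zf.read("arrays.npz")))
            version = meta.get("format_version")
            if version != _MODEL_FORMAT_VERSION:
                raise ModelFormatError(
                    f"{path}: unsupported model format version {version!r}"
                )
            return ShapeModel(
                arrays["mean"],
                arrays["components"],
                arrays["eigenvalues"],
                int(meta["n_training"]),
                ShapeLayout.from_dict(meta["layout"]),
                arrays["faces"],
            )
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, ValueError) as exc:
        if isinstance(exc, ModelFormatError):
            raise
        raise ModelFormatError(f"{path}: corrupt or truncated model file ({exc})") from exc


# ---------------------------------------------------------------------------
# combined two-bone sets


def merge_shape_sets(
    a: CorrespondedShapeSet, b: CorrespondedShapeSet
) -> CorrespondedShapeSet:
    """Concatenate two bones specimen-wise into a single corresponded set.

    Vertices and faces of ``b`` are appended after ``a``'s (face indices
    offset); the landmark list is the union, with names present in both
    taken from ``a`` (shared joint centers are counted once). Region masks
    of ``b`` are re-indexed; name clashes get a ``b:`` prefix.
    """
    if a.n_specimens != b.n_specimens:
        raise CorrespondenceError(
            f"sets have {a.n_specimens} vs {b.n_specimens} specimens"
        )
    if a.specimen_ids != b.specimen_ids:
        raise CorrespondenceError("specimen ids differ between the two sets")
    off = a.n_vertices
    extra = [n for n in b.landmark_names if n not in a.landmark_names]
    meshes, landmarks = [], []
    for ma, mb, la, lb in zip(a.meshes, b.meshes, a.landmarks, b.landmarks):
        verts = np.vstack([ma.vertices, mb.vertices])
        faces = np.vstack([ma.faces, mb.faces + off])
        meshes.append(TriMesh(verts, faces, ma.specimen_id))
        names = la.names + tuple(extra)
        pts = np.vstack([la.points, lb.subset(extra).points]) if extra else la.points
        landmarks.append(LandmarkSet(names, pts, la.specimen_id))
    masks = dict(a.region_masks)
    for rname, idx in b.region_masks.items():
        key = rname if rname not in masks else f"b:{rname}"
        masks[key] = np.asarray(idx, dtype=np.int64) + off
    return CorrespondedShapeSet(tuple(meshes), tuple(landmarks), masks)
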