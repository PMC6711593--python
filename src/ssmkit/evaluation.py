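"""Surface/landmark error metrics and the leave-one-out experiment.

Surface error direction: by default distances run from the *true* surface's
vertices to the *predicted* surface; a symmetric option averages both
directions. Aggregation over specimens reports the mean of per-specimen
means; the SD is across specimens. Because the "maximum" column of a
summary table is ambiguous, both the mean of per-specimen maxima
(``max``, i.e. mean_of_max) and the max of per-specimen means
(``max_of_means``) are emitted, labeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .alignment import generalized_procrustes
from .errors import SSMKitError
from .geometry_io import CorrespondedShapeSet, LandmarkSet, TriMesh
from .shape_model import ShapeModel, build_ssm, merge_shape_sets
from .sparse_predict import (
    PredictionConfig,
    predict_from_landmarks,
    predicted_landmarks,
    predicted_mesh,
)

__all__ = [
    "point_to_surface",
    "SurfaceDistance",
    "surface_error",
    "landmark_error",
    "LandmarkErrorSummary",
    "DesignRow",
    "LandmarkSetDesign",
    "pelvis_design",
    "femur_design",
    "design_from_yaml",
    "LOOResult",
    "fit_excluding",
    "run_loo",
    "report",
    "read_report",
]


# ---------------------------------------------------------------------------
# point-to-surface distance (exact w.r.t. the piecewise-linear surface)


def _point_segment_dist2(p, a, b):
    # a, b: (t, 3); p: (3,)
    d = b - a
    dd = np.einsum("ij,ij->i", d, d)
    t = np.einsum("ij,ij->i", p - a, d) / np.where(dd > 0, dd, 1.0)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[:, None] * d
    diff = p - closest
    return np.einsum("ij,ij->i", diff, diff)


def _point_triangles_dist(p, a, b, c):
    """Exact distance from point ``p`` to each triangle (a[i], b[i], c[i])."""
    ab, ac, ap = b - a, c - a, p - a
    n = np.cross(ab, ac)
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", ap, ab)
    d21 = np.einsum("ij,ij->i", ap, ac)
    denom = d00 * d11 - d01 * d01
    ok = denom > 1e-300
    safe = np.where(ok, denom, 1.0)
    v = (d11 * d20 - d01 * d21) / safe
    w = (d00 * d21 - d01 * d20) / safe
    inside = ok & (v >= 0.0) & (w >= 0.0) & (v + w <= 1.0)
    nn = np.einsum("ij,ij->i", n, n)
    plane = np.abs(np.einsum("ij,ij->i", ap, n)) / np.sqrt(np.where(nn > 0, nn, 1.0))
    edge2 = np.minimum(
        _point_segment_dist2(p, a, b),
        np.minimum(_point_segment_dist2(p, b, c), _point_segment_dist2(p, c, a)),
    )
    return np.where(inside, plane, np.sqrt(edge2))


class SurfaceDistance:
    """Reusable accelerated exact point-to-mesh distance queries.

    A vertex KD-tree yields an achievable upper bound; a triangle-centroid
    KD-tree prunes to the candidate triangles that could beat it.
    """

    def __init__(self, mesh: TriMesh):
        if mesh.n_faces == 0:
            raise SSMKitError("empty mesh: surface distance requires triangles")
        tris = mesh.vertices[mesh.faces]
        self._a, self._b, self._c = tris[:, 0], tris[:, 1], tris[:, 2]
        self._centroids = tris.mean(axis=1)
        self._radii = np.linalg.norm(
            tris - self._centroids[:, None, :], axis=2
        ).max(axis=1)
        self._rmax = float(self._radii.max())
        self._vtree = cKDTree(mesh.vertices)
        self._ctree = cKDTree(self._centroids)

    def query(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        upper, _ = self._vtree.query(pts)
        out = np.empty(pts.shape[0])
        for i, (p, u) in enumerate(zip(pts, upper)):
            cand = self._ctree.query_ball_point(p, u + self._rmax + 1e-9)
            cand = np.asarray(cand, dtype=np.int64)
            if cand.size:
                keep = (
                    np.linalg.norm(self._centroids[cand] - p, axis=1)
                    - self._radii[cand]
                    <= u + 1e-9
                )
                cand = cand[keep]
            if cand.size == 0:
                out[i] = u  # u is achieved at a mesh vertex
                continue
            d = _point_triangles_dist(p, self._a[cand], self._b[cand], self._c[cand])
            out[i] = min(float(d.min()), float(u))
        return out


def point_to_surface(points: np.ndarray, mesh: TriMesh) -> np.ndarray:
    """Euclidean distance from each point to the nearest point on the mesh
    (vertex, edge or triangle interior)."""
    return SurfaceDistance(mesh).query(points)


# ---------------------------------------------------------------------------
# error metrics


def _resolve_region(truth: TriMesh, region, region_masks=None) -> np.ndarray:
    if isinstance(region, str):
        if region == "whole":
            return np.arange(truth.n_vertices)
        if region_masks is None or region not in region_masks:
            raise SSMKitError(f"unknown region {region!r}")
        mask = np.asarray(region_masks[region], dtype=np.int64)
    else:
        mask = np.asarray(region, dtype=np.int64)
    if mask.size == 0:
        raise SSMKitError("empty region mask")
    return mask


def surface_error(
    predicted: TriMesh,
    truth: TriMesh,
    region="whole",
    region_masks=None,
    symmetric: bool = False,
) -> tuple[float, float]:
    """(mean, max) distance from the true surface's region vertices to the
    predicted surface. With ``symmetric=True`` the reverse direction
    (predicted region vertices → true surface) is averaged in (means
    averaged, maxima maxed)."""
    mask = _resolve_region(truth, region, region_masks)
    d = SurfaceDistance(predicted).query(truth.vertices[mask])
    mean, mx = float(d.mean()), float(d.max())
    if symmetric:
        d2 = SurfaceDistance(truth).query(predicted.vertices[mask])
        mean = 0.5 * (mean + float(d2.mean()))
        mx = max(mx, float(d2.max()))
    return mean, mx


@dataclass(frozen=True)
class LandmarkErrorSummary:
    per_name: dict
    mean: float
    sd: float


def landmark_error(
    predicted: LandmarkSet, truth: LandmarkSet, names=None
) -> LandmarkErrorSummary:
    """Pointwise Euclidean distances per landmark plus mean and sample SD
    (SD over names; 0.0 when fewer than 2 names)."""
    names = tuple(names) if names is not None else predicted.names
    errs = {
        n: float(np.linalg.norm(predicted.point(n) - truth.point(n))) for n in names
    }
    vals = np.array(list(errs.values()))
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return LandmarkErrorSummary(errs, float(vals.mean()), sd)


# ---------------------------------------------------------------------------
# experimental design


@dataclass(frozen=True)
class DesignRow:
    """One predictor-set row. ``names=None`` means all model landmarks;
    ``combined=True`` predicts from the merged two-bone model."""

    label: str
    names: tuple | None = None
    combined: bool = False

    def resolve_names(self, available) -> tuple:
        if self.names is None:
            return tuple(available)
        return tuple(self.names)


@dataclass(frozen=True)
class LandmarkSetDesign:
    rows: tuple

    def __post_init__(self):
        rows = tuple(self.rows)
        if not rows:
            raise SSMKitError("design has no rows")
        labels = [r.label for r in rows]
        if len(set(labels)) != len(labels):
            raise SSMKitError("duplicate design row labels")
        object.__setattr__(self, "rows", rows)

    def validate(self, available_names) -> None:
        avail = set(available_names)
        for row in self.rows:
            if row.names is not None:
                unknown = [n for n in row.names if n not in avail]
                if unknown:
                    raise SSMKitError(
                        f"design row {row.label!r} uses unknown landmarks {unknown}"
                    )
                if not row.names:
                    raise SSMKitError(f"design row {row.label!r} is empty")


_PELVIS_N1 = ("RIAS", "LIAS", "RICT", "LICT")
_PELVIS_N2 = _PELVIS_N1 + ("RIPS", "LIPS")
_PELVIS_N3 = _PELVIS_N2 + ("RIPJ", "LIPJ")
_PELVIS_N4 = _PELVIS_N3 + ("RHJC", "LHJC")
_PELVIS_N5 = _PELVIS_N3 + ("RIIT", "LIIT")
_PELVIS_N6 = _PELVIS_N5 + ("RHJC", "LHJC")
_PELVIS_N7 = _PELVIS_N6 + ("LSJC",)


def pelvis_design(include_combined: bool = True) -> LandmarkSetDesign:
    """The 13-landmark pelvis design: nested rows N1..N7 plus the optional
    combined-model row N8 predicting from all landmarks of both bones."""
    rows = [
        DesignRow("N1", _PELVIS_N1),
        DesignRow("N2", _PELVIS_N2),
        DesignRow("N3", _PELVIS_N3),
        DesignRow("N4", _PELVIS_N4),
        DesignRow("N5", _PELVIS_N5),
        DesignRow("N6", _PELVIS_N6),
        DesignRow("N7", _PELVIS_N7),
    ]
    if include_combined:
        rows.append(DesignRow("N8", None, combined=True))
    return LandmarkSetDesign(tuple(rows))


def femur_design(include_combined: bool = True) -> LandmarkSetDesign:
    rows = [
        DesignRow("N1", ("RFTC", "RFLE", "RFME")),
        DesignRow("N2", ("RFTC", "RFLE", "RFME", "RHJC")),
    ]
    if include_combined:
        rows.append(DesignRow("N3", None, combined=True))
    return LandmarkSetDesign(tuple(rows))


def design_from_yaml(path) -> LandmarkSetDesign:
    """Load a design from YAML: ``rows: [{label, landmarks: [...]|all,
    combined: bool}, ...]``."""
    obj = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    rows = []
    for entry in obj["rows"]:
        lms = entry.get("landmarks", "all")
        names = None if lms in ("all", None) else tuple(lms)
        rows.append(DesignRow(str(entry["label"]), names,
                              bool(entry.get("combined", False))))
    return LandmarkSetDesign(tuple(rows))


# ---------------------------------------------------------------------------
# leave-one-out harness


@dataclass(eq=False)
class LOOResult:
    """Per-specimen records plus aggregate views of a leave-one-out run."""

    surface: pd.DataFrame
    landmarks: pd.DataFrame
    failures: list = field(default_factory=list)
    row_order: tuple = ()

    _SURFACE_COLS = ("specimen_id", "design_row", "region", "mean_error", "max_error")
    _LANDMARK_COLS = ("specimen_id", "design_row", "name", "error", "held_out")

    def _ordered(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.row_order and len(df):
            df = df.copy()
            df["design_row"] = pd.Categorical(
                df["design_row"], categories=list(self.row_order), ordered=True
            )
        return df

    def surface_table(self) -> pd.DataFrame:
        """Per (design row, region): mean of per-specimen means, mean of
        per-specimen maxima, and max of per-specimen means."""
        if not len(self.surface):
            return pd.DataFrame(
                columns=["design_row", "region", "mean", "max", "max_of_means"]
            )
        g = self._ordered(self.surface).groupby(
            ["design_row", "region"], observed=True, sort=True
        )
        out = g.agg(
            mean=("mean_error", "mean"),
            max=("max_error", "mean"),
            max_of_means=("mean_error", "max"),
        ).reset_index()
        out["design_row"] = out["design_row"].astype(str)
        return out

    def landmark_table(self) -> pd.DataFrame:
        """Predictor landmarks: mean/SD over specimens of per-specimen mean
        error. Held-out landmarks: per-name mean/SD over specimens."""
        if not len(self.landmarks):
            return pd.DataFrame(columns=["design_row", "group", "mean", "sd"])
        df = self._ordered(self.landmarks)
        parts = []
        pred = df[~df["held_out"]]
        if len(pred):
            per_spec = pred.groupby(
                ["design_row", "specimen_id"], observed=True
            )["error"].mean()
            agg = per_spec.groupby("design_row", observed=True).agg(["mean", "std"])
            parts.append(
                pd.DataFrame({
                    "design_row": agg.index.astype(str),
                    "group": "ALs",
                    "mean": agg["mean"].values,
                    "sd": agg["std"].fillna(0.0).values,
                })
            )
        held = df[df["held_out"]]
        if len(held):
            agg = held.groupby(["design_row", "name"], observed=True)["error"].agg(
                ["mean", "std"]
            ).reset_index()
            parts.append(
                pd.DataFrame({
                    "design_row": agg["design_row"].astype(str),
                    "group": agg["name"],
                    "mean": agg["mean"].values,
                    "sd": agg["std"].fillna(0.0).values,
                })
            )
        return pd.concat(parts, ignore_index=True)

    def to_table(self) -> pd.DataFrame:
        """One wide row per design row, mirroring a summary results table."""
        if not len(self.surface) and not len(self.landmarks):
            return pd.DataFrame(columns=["design_row"])
        st = self.surface_table()
        wide = None
        if len(st):
            wide = st.pivot(index="design_row", columns="region",
                            values=["mean", "max", "max_of_means"])
            wide.columns = [f"{region}_{stat}" for stat, region in wide.columns]
        lt = self.landmark_table()
        if len(lt):
            lw = lt.pivot(index="design_row", columns="group", values=["mean", "sd"])
            lw.columns = [f"{grp}_{stat}" for stat, grp in lw.columns]
            wide = lw if wide is None else wide.join(lw, how="outer")
        order = [r for r in self.row_order if r in wide.index]
        if order:
            wide = wide.reindex(order)
        return wide.reset_index().rename(columns={"index": "design_row"})


def fit_excluding(
    shape_set: CorrespondedShapeSet,
    index: int,
    landmark_names=None,
    *,
    gpa_tol: float = 1e-8,
) -> ShapeModel:
    """GPA-align all specimens except ``index`` on the given landmarks and
    fit the model on them; the excluded specimen contributes nothing."""
    training = shape_set.excluding(index)
    aligned, _ = generalized_procrustes(training, landmark_names, tol=gpa_tol)
    return build_ssm(aligned)


def run_loo(
    shape_set: CorrespondedShapeSet,
    design: LandmarkSetDesign,
    config: PredictionConfig | None = None,
    heldout_names=(),
    companion: CorrespondedShapeSet | None = None,
) -> LOOResult:
    """Leave-one-out evaluation over every specimen and design row.

    For each fold the model (GPA alignment + PCA) is rebuilt from the n-1
    remaining specimens, using only that row's predictor landmarks for the
    alignment; the left-out specimen is then predicted from its raw
    landmarks alone. Sub-step failures are recorded per cell and the run
    continues.

    ``companion`` supplies the second bone for ``combined`` design rows;
    errors are always evaluated on ``shape_set``'s bone.
    """
    config = config or PredictionConfig()
    heldout_names = tuple(heldout_names)
    design.validate(shape_set.landmark_names)
    merged = None
    if any(r.combined for r in design.rows):
        if companion is None:
            raise SSMKitError("combined design rows require a companion shape set")
        merged = merge_shape_sets(shape_set, companion)
    nv = shape_set.n_vertices
    regions = {"whole": np.arange(nv), **shape_set.region_masks}
    surface_rows, lm_rows, failures = [], [], []
    for i, sid in enumerate(shape_set.specimen_ids):
        truth_mesh, truth_lms = shape_set.specimen(i)
        for row in design.rows:
            base = merged if row.combined else shape_set
            names = row.resolve_names(base.landmark_names)
            try:
                model = fit_excluding(base, i, names)
                obs = base.landmarks[i].subset(names)
                pred = predict_from_landmarks(model, obs, config)
                full = predicted_mesh(pred)
                pmesh = TriMesh(full.vertices[:nv], shape_set.faces, sid)
                dist = SurfaceDistance(pmesh)
                for rname, mask in regions.items():
                    d = dist.query(truth_mesh.vertices[mask])
                    surface_rows.append(
                        (sid, row.label, rname, float(d.mean()), float(d.max()))
                    )
                pred_names = [n for n in names if n in truth_lms.names]
                plm = predicted_landmarks(pred, pred_names)
                for n in pred_names:
                    lm_rows.append((
                        sid, row.label, n,
                        float(np.linalg.norm(plm.point(n) - truth_lms.point(n))),
                        False,
                    ))
                missing = [
                    n for n in heldout_names
                    if n not in names and n in truth_lms.names
                ]
                if missing:
                    hlm = predicted_landmarks(pred, missing)
                    for n in missing:
                        lm_rows.append((
                            sid, row.label, n,
                            float(np.linalg.norm(hlm.point(n) - truth_lms.point(n))),
                            True,
                        ))
            except Exception as exc:  # noqa: BLE001 - per-cell robustness
                failures.append(
                    {"specimen_id": sid, "design_row": row.label, "error": str(exc)}
                )
    return LOOResult(
        pd.DataFrame(surface_rows, columns=list(LOOResult._SURFACE_COLS)),
        pd.DataFrame(lm_rows, columns=list(LOOResult._LANDMARK_COLS)),
        failures,
        tuple(r.label for r in design.rows),
    )


def report(result: LOOResult, path) -> str:
    """Write the aggregate wide table as CSV; returns it human-readable."""
    df = result.to_table()
    df.to_csv(path, index=False)
    return df.to_string(index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path)
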