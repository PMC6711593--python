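"""Mesh and landmark I/O with cross-specimen correspondence validation.

Meshes are triangle surfaces in millimetres. Vertex indexing is 0-based
internally; the OBJ reader/writer converts from/to OBJ's 1-based indices at
the boundary. Landmarks may lie off the surface (joint centers do) and are
never projected onto it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import CorrespondenceError, LandmarkFormatError, MeshFormatError

__all__ = [
    "TriMesh",
    "LandmarkSet",
    "CorrespondedShapeSet",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "read_region_masks",
    "write_region_masks",
    "assemble_shape_set",
    "read_shape_set",
    "write_shape_set",
    "weld_vertices",
]

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True, eq=False)
class TriMesh:
    """A triangulated surface for one specimen.

    Parameters
    ----------
    vertices : (n, 3) float array, millimetres.
    faces : (m, 3) int array of 0-based vertex indices.
    specimen_id : label carried through the pipeline.
    """

    vertices: np.ndarray
    faces: np.ndarray
    specimen_id: str = ""

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshFormatError(f"vertices must be (n, 3); got shape {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshFormatError(f"faces must be (m, 3) triangles; got shape {f.shape}")
        if f.shape[0] == 0:
            raise MeshFormatError("mesh has no faces; surfaces require at least one triangle")
        if not np.isfinite(v).all():
            bad = int(np.argwhere(~np.isfinite(v).all(axis=1))[0, 0])
            raise MeshFormatError(f"non-finite coordinate at vertex {bad}")
        if f.min() < 0 or f.max() >= v.shape[0]:
            bad = int(np.argwhere((f < 0) | (f >= v.shape[0]))[0, 0])
            raise MeshFormatError(
                f"face {bad} references vertex index outside [0, {v.shape[0]}): {f[bad].tolist()}"
            )
        degen = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        if degen.any():
            bad = int(np.argwhere(degen)[0, 0])
            raise MeshFormatError(f"degenerate triangle {bad}: {f[bad].tolist()}")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        return TriMesh(vertices, self.faces, self.specimen_id)


@dataclass(frozen=True, eq=False)
class LandmarkSet:
    """Named 3D anatomical points for one specimen (on- or off-surface)."""

    names: tuple
    points: np.ndarray
    specimen_id: str = ""

    def __post_init__(self):
        names = tuple(str(n) for n in self.names)
        pts = np.ascontiguousarray(np.asarray(self.points, dtype=np.float64))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise LandmarkFormatError(f"points must be (m, 3); got shape {pts.shape}")
        if len(names) != pts.shape[0]:
            raise LandmarkFormatError(
                f"{len(names)} names but {pts.shape[0]} points"
            )
        if len(set(names)) != len(names):
            seen, dup = set(), None
            for n in names:
                if n in seen:
                    dup = n
                    break
                seen.add(n)
            raise LandmarkFormatError(f"duplicate landmark name: {dup!r}")
        if not np.isfinite(pts).all():
            bad = int(np.argwhere(~np.isfinite(pts).all(axis=1))[0, 0])
            raise LandmarkFormatError(f"non-finite coordinate for landmark {names[bad]!r}")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise LandmarkFormatError(
                f"landmark {name!r} not in set {list(self.names)}"
            ) from None

    def point(self, name: str) -> np.ndarray:
        return self.points[self.index(name)]

    def subset(self, names: Sequence[str]) -> "LandmarkSet":
        idx = [self.index(n) for n in names]
        return LandmarkSet(tuple(names), self.points[idx], self.specimen_id)

    def with_points(self, points: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(self.names, points, self.specimen_id)


@dataclass(frozen=True, eq=False)
class CorrespondedShapeSet:
    """Stack of specimens sharing one template topology and landmark naming."""

    meshes: tuple
    landmarks: tuple
    region_masks: dict = field(default_factory=dict)

    def __post_init__(self):
        meshes = tuple(self.meshes)
        lms = tuple(self.landmarks)
        if len(meshes) == 0:
            raise CorrespondenceError("empty shape set")
        if len(meshes) != len(lms):
            raise CorrespondenceError(
                f"{len(meshes)} meshes but {len(lms)} landmark sets"
            )
        ref = meshes[0]
        for m in meshes[1:]:
            if m.n_vertices != ref.n_vertices:
                raise CorrespondenceError(
                    f"specimen {m.specimen_id!r}: {m.n_vertices} vertices, "
                    f"expected {ref.n_vertices} (from {ref.specimen_id!r})"
                )
            if not np.array_equal(m.faces, ref.faces):
                raise CorrespondenceError(
                    f"specimen {m.specimen_id!r}: face array differs from "
                    f"{ref.specimen_id!r}"
                )
        names = lms[0].names
        for ls in lms[1:]:
            if ls.names != names:
                raise CorrespondenceError(
                    f"specimen {ls.specimen_id!r}: landmark names {list(ls.names)} "
                    f"differ from {list(names)}"
                )
        for m, ls in zip(meshes, lms):
            if m.specimen_id != ls.specimen_id:
                raise CorrespondenceError(
                    f"mesh {m.specimen_id!r} paired with landmarks {ls.specimen_id!r}"
                )
        masks = {}
        for rname, idx in dict(self.region_masks).items():
            arr = np.asarray(idx, dtype=np.int64).ravel()
            if arr.size == 0:
                raise CorrespondenceError(f"region {rname!r} is empty")
            if arr.min() < 0 or arr.max() >= ref.n_vertices:
                raise CorrespondenceError(
                    f"region {rname!r} has vertex index outside [0, {ref.n_vertices})"
                )
            masks[rname] = arr
        object.__setattr__(self, "meshes", meshes)
        object.__setattr__(self, "landmarks", lms)
        object.__setattr__(self, "region_masks", masks)

    @property
    def n_specimens(self) -> int:
        return len(self.meshes)

    @property
    def n_vertices(self) -> int:
        return self.meshes[0].n_vertices

    @property
    def faces(self) -> np.ndarray:
        return self.meshes[0].faces

    @property
    def landmark_names(self) -> tuple:
        return self.landmarks[0].names

    @property
    def specimen_ids(self) -> tuple:
        return tuple(m.specimen_id for m in self.meshes)

    def specimen(self, i: int):
        return self.meshes[i], self.landmarks[i]

    def subset(self, indices: Iterable[int]) -> "CorrespondedShapeSet":
        idx = list(indices)
        return CorrespondedShapeSet(
            tuple(self.meshes[i] for i in idx),
            tuple(self.landmarks[i] for i in idx),
            dict(self.region_masks),
        )

    def excluding(self, index: int) -> "CorrespondedShapeSet":
        return self.subset(i for i in range(self.n_specimens) if i != index)


def assemble_shape_set(
    meshes: Sequence[TriMesh],
    landmarks: Sequence[LandmarkSet],
    regions: Mapping[str, Sequence[int]] | None = None,
) -> CorrespondedShapeSet:
    """Validate and bundle corresponded specimens.

    Raises :class:`CorrespondenceError` naming the offending specimen on any
    topology, landmark-name or region-mask violation.
    """
    if len(meshes) != len(landmarks):
        raise CorrespondenceError(
            f"{len(meshes)} meshes but {len(landmarks)} landmark sets"
        )
    return CorrespondedShapeSet(tuple(meshes), tuple(landmarks), dict(regions or {}))


# ---------------------------------------------------------------------------
# mesh formats

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _read_ply(path: Path) -> TriMesh:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise MeshFormatError(f"{path}: missing 'ply' magic")
        fmt = None
        elements = []  # [name, count, [(prop_name, kind), ...]]
        while True:
            line = fh.readline()
            if not line:
                raise MeshFormatError(f"{path}: unexpected EOF in header")
            tok = line.decode("ascii", "replace").split()
            if not tok or tok[0] == "comment":
                continue
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                elements.append([tok[1], int(tok[2]), []])
            elif tok[0] == "property":
                if not elements:
                    raise MeshFormatError(f"{path}: property before element")
                if tok[1] == "list":
                    elements[-1][2].append(
                        (tok[4], ("list", _PLY_DTYPES[tok[2]], _PLY_DTYPES[tok[3]]))
                    )
                else:
                    elements[-1][2].append((tok[2], ("scalar", _PLY_DTYPES[tok[1]])))
            elif tok[0] == "end_header":
                break
        if fmt == "ascii":
            data = _read_ply_ascii(fh, elements, path)
        elif fmt == "binary_little_endian":
            data = _read_ply_binary(fh, elements, path)
        else:
            raise MeshFormatError(f"{path}: unsupported PLY format {fmt!r}")
    return _ply_to_mesh(data, path)


def _read_ply_ascii(fh, elements, path):
    tokens = fh.read().decode("ascii", "replace").split()
    pos = 0
    data = {}
    for name, count, props in elements:
        rows = []
        for _ in range(count):
            row = {}
            for pname, kind in props:
                try:
                    if kind[0] == "scalar":
                        row[pname] = float(tokens[pos])
                        pos += 1
                    else:
                        n = int(tokens[pos])
                        pos += 1
                        row[pname] = [float(tokens[pos + j]) for j in range(n)]
                        pos += n
                except (IndexError, ValueError) as exc:
                    raise MeshFormatError(
                        f"{path}: truncated or malformed element {name!r}"
                    ) from exc
            rows.append(row)
        data[name] = rows
    return data


def _read_ply_binary(fh, elements, path):
    buf = fh.read()
    off = 0
    data = {}
    for name, count, props in elements:
        if all(kind[0] == "scalar" for _, kind in props):
            dt = np.dtype([(pn, "<" + kind[1]) for pn, kind in props])
            need = dt.itemsize * count
            if off + need > len(buf):
                raise MeshFormatError(f"{path}: truncated element {name!r}")
            arr = np.frombuffer(buf, dt, count, off)
            off += need
            data[name] = [
                {pn: float(arr[pn][i]) for pn, _ in props} for i in range(count)
            ]
        else:
            rows = []
            for _ in range(count):
                row = {}
                for pname, kind in props:
                    try:
                        if kind[0] == "scalar":
                            dt = np.dtype("<" + kind[1])
                            row[pname] = float(np.frombuffer(buf, dt, 1, off)[0])
                            off += dt.itemsize
                        else:
                            cdt = np.dtype("<" + kind[1])
                            n = int(np.frombuffer(buf, cdt, 1, off)[0])
                            off += cdt.itemsize
                            idt = np.dtype("<" + kind[2])
                            row[pname] = np.frombuffer(buf, idt, n, off).tolist()
                            off += idt.itemsize * n
                    except ValueError as exc:
                        raise MeshFormatError(
                            f"{path}: truncated element {name!r}"
                        ) from exc
                rows.append(row)
            data[name] = rows
    return data


def _ply_to_mesh(data, path) -> TriMesh:
    if "vertex" not in data or "face" not in data:
        raise MeshFormatError(f"{path}: PLY must contain vertex and face elements")
    try:
        verts = np.array(
            [[r["x"], r["y"], r["z"]] for r in data["vertex"]], dtype=np.float64
        )
    except KeyError as exc:
        raise MeshFormatError(f"{path}: vertex element lacks x/y/z") from exc
    faces = []
    for i, row in enumerate(data["face"]):
        idx = row.get("vertex_indices", row.get("vertex_index"))
        if idx is None:
            raise MeshFormatError(f"{path}: face element lacks vertex_indices")
        if len(idx) != 3:
            raise MeshFormatError(
                f"{path}: face {i} has {len(idx)} vertices; only triangles supported"
            )
        faces.append([int(v) for v in idx])
    if verts.size == 0:
        verts = verts.reshape(0, 3)
    try:
        return TriMesh(verts, np.asarray(faces, dtype=np.int64).reshape(-1, 3),
                       specimen_id=path.stem)
    except MeshFormatError as exc:
        raise MeshFormatError(f"{path}: {exc}") from None


def _write_ply(mesh: TriMesh, path: Path, binary: bool = False) -> None:
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\n"
        "property double y\n"
        "property double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(mesh.vertices, "<f8").tobytes())
            for tri in mesh.faces:
                fh.write(np.uint8(3).tobytes())
                fh.write(np.ascontiguousarray(tri, "<i4").tobytes())
        else:
            lines = [
                " ".join(_FLOAT_FMT % c for c in v) for v in mesh.vertices
            ]
            lines += ["3 %d %d %d" % tuple(t) for t in mesh.faces]
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


def _read_obj(path: Path) -> TriMesh:
    verts, faces = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            if tok[0] == "v":
                if len(tok) < 4:
                    raise MeshFormatError(f"{path}:{lineno}: vertex needs 3 coordinates")
                verts.append([float(c) for c in tok[1:4]])
            elif tok[0] == "f":
                if len(tok) != 4:
                    raise MeshFormatError(
                        f"{path}:{lineno}: face has {len(tok) - 1} vertices; "
                        "only triangles supported"
                    )
                tri = []
                for t in tok[1:]:
                    raw = int(t.split("/")[0])
                    if raw == 0:
                        raise MeshFormatError(
                            f"{path}:{lineno}: OBJ face indices are 1-based; "
                            "index 0 is invalid"
                        )
                    tri.append(raw - 1 if raw > 0 else len(verts) + raw)
                faces.append(tri)
    try:
        return TriMesh(np.asarray(verts, dtype=np.float64).reshape(-1, 3),
                       np.asarray(faces, dtype=np.int64).reshape(-1, 3),
                       specimen_id=path.stem)
    except MeshFormatError as exc:
        raise MeshFormatError(f"{path}: {exc}") from None


def _write_obj(mesh: TriMesh, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for v in mesh.vertices:
            fh.write("v %s %s %s\n" % tuple(_FLOAT_FMT % c for c in v))
        for t in mesh.faces:
            fh.write("f %d %d %d\n" % (t[0] + 1, t[1] + 1, t[2] + 1))


def weld_vertices(
    triangles: np.ndarray, tol: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Merge duplicated corner vertices of a triangle soup.

    ``triangles`` is (t, 3, 3); vertices closer than ``tol`` on every axis
    (exact bit-equality when ``tol == 0``) collapse to the first occurrence.
    Returns (vertices, faces) in first-appearance order.
    """
    tris = np.asarray(triangles, dtype=np.float64)
    verts: list = []
    faces = np.empty((tris.shape[0], 3), dtype=np.int64)
    seen: dict = {}
    for i, tri in enumerate(tris):
        for j, p in enumerate(tri):
            key = tuple(p) if tol <= 0 else tuple(np.round(p / tol).astype(np.int64))
            k = seen.get(key)
            if k is None:
                k = len(verts)
                seen[key] = k
                verts.append(p)
            faces[i, j] = k
    return np.asarray(verts, dtype=np.float64), faces


def _read_stl(path: Path, weld_tol: float = 0.0) -> TriMesh:
    raw = path.read_bytes()
    tris = None
    if len(raw) >= 84:
        n = int(np.frombuffer(raw, "<u4", 1, 80)[0])
        if len(raw) == 84 + 50 * n:
            body = np.frombuffer(
                raw, np.dtype([("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]),
                n, 84,
            )
            tris = body["v"].astype(np.float64)
    if tris is None:
        text = raw.decode("ascii", "replace")
        if not text.lstrip().startswith("solid"):
            raise MeshFormatError(f"{path}: neither valid binary nor ASCII STL")
        coords = []
        for lineno, line in enumerate(text.splitlines(), 1):
            tok = line.split()
            if tok[:1] == ["vertex"]:
                if len(tok) != 4:
                    raise MeshFormatError(f"{path}:{lineno}: vertex needs 3 coordinates")
                coords.append([float(c) for c in tok[1:4]])
        if len(coords) == 0 or len(coords) % 3:
            raise MeshFormatError(
                f"{path}: {len(coords)} vertex lines; expected a positive multiple of 3"
            )
        tris = np.asarray(coords, dtype=np.float64).reshape(-1, 3, 3)
    verts, faces = weld_vertices(tris, weld_tol)
    try:
        return TriMesh(verts, faces, specimen_id=path.stem)
    except MeshFormatError as exc:
        raise MeshFormatError(f"{path}: {exc}") from None


def _write_stl(mesh: TriMesh, path: Path) -> None:
    tris = mesh.vertices[mesh.faces]
    normals = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, norms, out=np.zeros_like(normals), where=norms > 0)
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f"solid {mesh.specimen_id or 'mesh'}\n")
        for tri, nrm in zip(tris, normals):
            fh.write(" facet normal %s %s %s\n" % tuple(_FLOAT_FMT % c for c in nrm))
            fh.write("  outer loop\n")
            for p in tri:
                fh.write("   vertex %s %s %s\n" % tuple(_FLOAT_FMT % c for c in p))
            fh.write("  endloop\n")
            fh.write(" endfacet\n")
        fh.write(f"endsolid {mesh.specimen_id or 'mesh'}\n")


def _mesh_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = path.suffix.lower().lstrip(".")
    if fmt not in ("ply", "obj", "stl"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r} for {path}")
    return fmt


def read_mesh(
    path, format: str | None = None, *, stl_weld_tol: float = 0.0
) -> TriMesh:
    """Read a PLY (ascii or binary little-endian), OBJ or STL triangle mesh.

    Vertex order is preserved exactly as stored, except for STL whose
    per-facet vertex soup is welded back into shared vertices
    (``stl_weld_tol`` controls the welding tolerance; 0 = exact).
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such mesh file: {path}")
    fmt = _mesh_format(path, format)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "obj":
        return _read_obj(path)
    return _read_stl(path, stl_weld_tol)


def write_mesh(
    mesh: TriMesh, path, format: str | None = None, *, binary: bool = False
) -> None:
    """Write a mesh; the file reads back into an equal mesh (STL aside from
    vertex sharing, which :func:`read_mesh` restores by welding)."""
    path = Path(path)
    fmt = _mesh_format(path, format)
    if fmt == "ply":
        _write_ply(mesh, path, binary=binary)
    elif fmt == "obj":
        _write_obj(mesh, path)
    else:
        _write_stl(mesh, path)


# ---------------------------------------------------------------------------
# landmarks and regions


def _landmark_format(path: Path, format: str | None) -> str:
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("csv", "json"):
        raise LandmarkFormatError(f"unsupported landmark format {fmt!r} for {path}")
    return fmt


def read_landmarks(path, format: str | None = None) -> LandmarkSet:
    """Read landmarks from CSV (``name,x,y,z`` header required) or JSON.

    Order is preserved as in the file; duplicate names and missing
    coordinates raise :class:`LandmarkFormatError` with the row number.
    """
    path = Path(path)
    if not path.exists():
        raise LandmarkFormatError(f"no such landmark file: {path}")
    fmt = _landmark_format(path, format)
    names, pts = [], []
    specimen_id = path.stem.removesuffix(".landmarks").removesuffix("_landmarks")
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = [h.strip().lower() for h in next(reader)]
            except StopIteration:
                raise LandmarkFormatError(f"{path}: empty file") from None
            if header[:4] != ["name", "x", "y", "z"]:
                raise LandmarkFormatError(
                    f"{path}: header must be name,x,y,z; got {header}"
                )
            for rowno, row in enumerate(reader, 2):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) < 4:
                    raise LandmarkFormatError(
                        f"{path}: row {rowno}: expected 4 fields, got {len(row)}"
                    )
                names.append(row[0].strip())
                try:
                    pts.append([float(row[1]), float(row[2]), float(row[3])])
                except ValueError:
                    raise LandmarkFormatError(
                        f"{path}: row {rowno}: missing or non-numeric coordinate"
                    ) from None
    else:
        obj = json.loads(path.read_text(encoding="utf-8"))
        if isinstance(obj, dict):
            specimen_id = obj.get("specimen_id", specimen_id)
            rows = obj.get("landmarks", [])
        else:
            rows = obj
        for rowno, row in enumerate(rows, 1):
            try:
                names.append(str(row["name"]))
                pts.append([float(row["x"]), float(row["y"]), float(row["z"])])
            except (KeyError, TypeError, ValueError):
                raise LandmarkFormatError(
                    f"{path}: entry {rowno}: needs name,x,y,z"
                ) from None
    try:
        return LandmarkSet(tuple(names), np.asarray(pts, np.float64).reshape(-1, 3),
                           specimen_id)
    except LandmarkFormatError as exc:
        raise LandmarkFormatError(f"{path}: {exc}") from None


def write_landmarks(landmarks: LandmarkSet, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = _landmark_format(path, format)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "x", "y", "z"])
            for n, p in zip(landmarks.names, landmarks.points):
                writer.writerow([n] + [_FLOAT_FMT % c for c in p])
    else:
        obj = {
            "specimen_id": landmarks.specimen_id,
            "landmarks": [
                {"name": n, "x": p[0], "y": p[1], "z": p[2]}
                for n, p in zip(landmarks.names, landmarks.points)
            ],
        }
        path.write_text(json.dumps(obj, indent=1) + "\n", encoding="utf-8")


def read_region_masks(path) -> dict:
    """Read ``{region_name: [vertex indices]}`` from JSON."""
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(obj, dict):
        raise LandmarkFormatError(f"{path}: region file must be a JSON object")
    return {str(k): np.asarray(v, dtype=np.int64) for k, v in obj.items()}


def write_region_masks(masks: Mapping[str, Sequence[int]], path) -> None:
    obj = {k: np.asarray(v, dtype=np.int64).tolist() for k, v in masks.items()}
    Path(path).write_text(json.dumps(obj) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# directory layout used by the CLI and fixtures


def write_shape_set(
    shape_set: CorrespondedShapeSet, out_dir, mesh_format: str = "ply"
) -> dict:
    """Write one ``<id>.<fmt>`` + ``<id>.landmarks.csv`` per specimen, plus
    ``regions.json`` when masks are present. Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"meshes": [], "landmarks": [], "regions": None}
    for mesh, lms in zip(shape_set.meshes, shape_set.landmarks):
        mp = out / f"{mesh.specimen_id}.{mesh_format}"
        lp = out / f"{mesh.specimen_id}.landmarks.csv"
        write_mesh(mesh, mp)
        write_landmarks(lms, lp)
        paths["meshes"].append(mp)
        paths["landmarks"].append(lp)
    if shape_set.region_masks:
        rp = out / "regions.json"
        write_region_masks(shape_set.region_masks, rp)
        paths["regions"] = rp
    return paths


def read_shape_set(in_dir) -> CorrespondedShapeSet:
    """Load a directory written by :func:`write_shape_set`."""
    root = Path(in_dir)
    meshes, landmarks = [], []
    mesh_paths = sorted(
        p for p in root.iterdir() if p.suffix.lower() in (".ply", ".obj", ".stl")
    )
    if not mesh_paths:
        raise MeshFormatError(f"no mesh files in {root}")
    for mp in mesh_paths:
        meshes.append(read_mesh(mp))
        lp = mp.with_suffix("").with_suffix(".landmarks.csv")
        if not lp.exists():
            lp = root / f"{mp.stem}_landmarks.csv"
        if not lp.exists():
            raise LandmarkFormatError(f"no landmark file for specimen {mp.stem!r}")
        landmarks.append(read_landmarks(lp))
    regions = {}
    rp = root / "regions.json"
    if rp.exists():
        regions = read_region_masks(rp)
    return assemble_shape_set(meshes, landmarks, regions)
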