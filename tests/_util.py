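"""Shared helpers for the test suite (independent oracles live here or in
the tests that use them)."""

import numpy as np
from scipy.spatial.transform import Rotation

from ssmkit.alignment import RigidTransform
from ssmkit.geometry_io import TriMesh


def random_rigid(rng, max_trans=50.0):
    R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
    t = rng.uniform(-max_trans, max_trans, size=3)
    return RigidTransform(R, t)


def random_blob_mesh(rng, n_vertices=80):
    """Small random star-shaped closed mesh (valid TriMesh) for IO tests."""
    from ssmkit.synthetic_shapes import _sphere_for

    dirs, faces = _sphere_for(n_vertices)
    radius = 10.0 + rng.uniform(-1.0, 1.0, size=len(dirs))
    return TriMesh(dirs * radius[:, None], faces, "blob")


def brute_force_point_mesh_distance(point, mesh):
    """Independent scalar all-triangles scan: exact distance from one point
    to the mesh, no acceleration, no shared code with the package path."""
    best = np.inf
    for tri in mesh.faces:
        a, b, c = mesh.vertices[tri]
        best = min(best, _scalar_point_triangle(point, a, b, c))
    return best


def _scalar_point_triangle(p, a, b, c):
    # Ericson, "Real-Time Collision Detection", closest point on triangle
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return np.linalg.norm(p - a)
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return np.linalg.norm(p - b)
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return np.linalg.norm(p - (a + v * ab))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return np.linalg.norm(p - c)
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return np.linalg.norm(p - (a + w * ac))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return np.linalg.norm(p - (b + w * (c - b)))
    denom = 1.0 / (va + vb + vc)
    v, w = vb * denom, vc * denom
    return np.linalg.norm(p - (a + v * ab + w * ac))
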