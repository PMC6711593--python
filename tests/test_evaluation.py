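import numpy as np
import pandas as pd
import pytest

from _util import brute_force_point_mesh_distance, random_blob_mesh, random_rigid
from ssmkit.errors import SSMKitError
from ssmkit.evaluation import (
    DesignRow,
    LandmarkSetDesign,
    LOOResult,
    design_from_yaml,
    femur_design,
    fit_excluding,
    landmark_error,
    pelvis_design,
    point_to_surface,
    read_report,
    report,
    run_loo,
    surface_error,
)
from ssmkit.geometry_io import CorrespondedShapeSet, LandmarkSet, TriMesh
from ssmkit.alignment import apply_transform
from ssmkit.sparse_predict import PredictionConfig
from ssmkit.synthetic_shapes import default_family, sample_family


# ---------------------------------------------------------------------------
# point_to_surface


def test_point_on_vertex_zero(rng):
    mesh = random_blob_mesh(rng)
    d = point_to_surface(mesh.vertices[[3, 17]], mesh)
    assert np.abs(d).max() <= 1e-12


def test_point_above_triangle_interior():
    mesh = TriMesh(
        [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 0.0]], [[0, 1, 2]]
    )
    h = 2.5
    d = point_to_surface([[2.0, 2.0, h]], mesh)
    assert abs(d[0] - h) <= 1e-12


def test_point_to_surface_matches_brute_force(rng):
    mesh = random_blob_mesh(rng, n_vertices=30)  # ~50 triangles
    pts = rng.normal(scale=12.0, size=(40, 3))
    fast = point_to_surface(pts, mesh)
    for p, d in zip(pts, fast):
        assert abs(d - brute_force_point_mesh_distance(p, mesh)) <= 1e-9


def test_point_to_surface_inside_and_far(rng):
    mesh = random_blob_mesh(rng)
    far = np.array([[100.0, 0.0, 0.0]])
    d = point_to_surface(far, mesh)
    assert abs(d[0] - brute_force_point_mesh_distance(far[0], mesh)) <= 1e-9


# ---------------------------------------------------------------------------
# surface_error


def test_surface_error_identical(rng):
    mesh = random_blob_mesh(rng)
    mean, mx = surface_error(mesh, mesh)
    assert mean <= 1e-12 and mx <= 1e-12


def _flat_patch(n=6):
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return TriMesh(verts, faces)


def test_surface_error_normal_offset_patch():
    truth = _flat_patch()
    predicted = TriMesh(truth.vertices + [0.0, 0.0, 2.0], truth.faces)
    mean, mx = surface_error(predicted, truth)
    assert abs(mean - 2.0) <= 1e-6
    assert abs(mx - 2.0) <= 1e-6


def test_region_mean_below_whole_max(rng):
    for _ in range(5):
        truth = random_blob_mesh(rng)
        predicted = TriMesh(
            truth.vertices + rng.normal(scale=0.5, size=truth.vertices.shape),
            truth.faces,
        )
        region = rng.choice(truth.n_vertices, size=10, replace=False)
        _wmean, wmax = surface_error(predicted, truth)
        rmean, _rmax = surface_error(predicted, truth, region=region)
        assert rmean <= wmax + 1e-12


def test_surface_error_unknown_region(rng):
    mesh = random_blob_mesh(rng)
    with pytest.raises(SSMKitError, match="unknown region"):
        surface_error(mesh, mesh, region="nope")
    with pytest.raises(SSMKitError, match="empty"):
        surface_error(mesh, mesh, region=np.array([], dtype=int))


def test_surface_error_symmetric_option(rng):
    truth = random_blob_mesh(rng)
    predicted = TriMesh(truth.vertices * 1.05, truth.faces)
    m_dir, _ = surface_error(predicted, truth)
    m_sym, _ = surface_error(predicted, truth, symmetric=True)
    assert m_sym > 0 and abs(m_sym - m_dir) < m_dir  # same order of magnitude


# ---------------------------------------------------------------------------
# landmark_error


def test_landmark_error_identical(rng):
    lm = LandmarkSet(("A", "B"), rng.normal(size=(2, 3)), "s")
    summary = landmark_error(lm, lm)
    assert summary.mean == 0.0
    assert all(v == 0.0 for v in summary.per_name.values())


def test_landmark_error_345():
    a = LandmarkSet(("P",), [[0.0, 0.0, 0.0]], "s")
    b = LandmarkSet(("P",), [[3.0, 4.0, 0.0]], "s")
    summary = landmark_error(a, b)
    assert abs(summary.per_name["P"] - 5.0) <= 1e-12
    assert summary.sd == 0.0


def test_landmark_error_matches_two_pass_oracle(rng):
    names = tuple("LM%d" % i for i in range(9))
    a = LandmarkSet(names, rng.normal(size=(9, 3)) * 30, "s")
    b = LandmarkSet(names, rng.normal(size=(9, 3)) * 30, "s")
    summary = landmark_error(a, b)
    # independent two-pass mean/SD
    ds = [float(np.sqrt(sum((a.point(n)[i] - b.point(n)[i]) ** 2 for i in range(3))))
          for n in names]
    mean = sum(ds) / len(ds)
    sd = (sum((d - mean) ** 2 for d in ds) / (len(ds) - 1)) ** 0.5
    assert abs(summary.mean - mean) <= 1e-12
    assert abs(summary.sd - sd) <= 1e-12


# ---------------------------------------------------------------------------
# designs


def test_pelvis_design_structure():
    d = pelvis_design()
    assert [r.label for r in d.rows] == ["N1", "N2", "N3", "N4", "N5", "N6", "N7", "N8"]
    assert d.rows[0].names == ("RIAS", "LIAS", "RICT", "LICT")
    assert len(d.rows[6].names) == 13
    assert d.rows[7].combined and d.rows[7].names is None


def test_femur_design_structure():
    d = femur_design(include_combined=False)
    assert d.rows[0].names == ("RFTC", "RFLE", "RFME")
    assert d.rows[1].names[-1] == "RHJC"


def test_design_validation():
    d = LandmarkSetDesign((DesignRow("X", ("RIAS", "NOPE")),))
    with pytest.raises(SSMKitError, match="NOPE"):
        d.validate(("RIAS", "LIAS"))


def test_design_from_yaml(tmp_path):
    p = tmp_path / "design.yaml"
    p.write_text(
        "rows:\n"
        "- {label: N1, landmarks: [RIAS, LIAS, RICT]}\n"
        "- {label: N2, landmarks: all}\n"
        "- {label: N3, combined: true}\n"
    )
    d = design_from_yaml(p)
    assert d.rows[0].names == ("RIAS", "LIAS", "RICT")
    assert d.rows[1].names is None
    assert d.rows[2].combined


# ---------------------------------------------------------------------------
# run_loo


def _identical_family(n=3, seed=0):
    spec = default_family("pelvislike", n_specimens=n, n_modes=2,
                          noise_sd=0.0, seed=seed, n_vertices=200,
                          rigid_jitter_rot=0.0, rigid_jitter_trans=0.0)
    template_set, _ = sample_family(spec)
    mesh0, lm0 = template_set.specimen(0)
    meshes = tuple(TriMesh(mesh0.vertices, mesh0.faces, f"S{i:03d}") for i in range(n))
    lms = tuple(LandmarkSet(lm0.names, lm0.points, f"S{i:03d}") for i in range(n))
    return CorrespondedShapeSet(meshes, lms, dict(template_set.region_masks))


def test_loo_identical_specimens_zero_error():
    ss = _identical_family()
    design = pelvis_design(include_combined=False)
    result = run_loo(ss, design, PredictionConfig())
    assert not result.failures
    assert result.surface["mean_error"].max() <= 1e-6
    assert result.surface["max_error"].max() <= 1e-6
    assert result.landmarks["error"].max() <= 1e-6


def test_loo_model_ignores_left_out_specimen(noisy_family, rng):
    ss, _ = noisy_family
    m1 = fit_excluding(ss, 4, ss.landmark_names)
    scrambled_mesh = TriMesh(
        rng.permutation(ss.meshes[4].vertices), ss.faces, ss.meshes[4].specimen_id
    )
    meshes = list(ss.meshes)
    meshes[4] = scrambled_mesh
    ss2 = CorrespondedShapeSet(tuple(meshes), ss.landmarks, dict(ss.region_masks))
    m2 = fit_excluding(ss2, 4, ss2.landmark_names)
    assert np.array_equal(m1.mean, m2.mean)
    assert np.array_equal(m1.components, m2.components)
    assert np.array_equal(m1.eigenvalues, m2.eigenvalues)


def test_loo_errors_invariant_to_global_rigid_transform(rng):
    spec = default_family("pelvislike", n_specimens=5, n_modes=3,
                          noise_sd=0.3, seed=7, n_vertices=200)
    ss, _ = sample_family(spec)
    design = LandmarkSetDesign((
        DesignRow("four", ("RIAS", "LIAS", "RICT", "LICT")),
        DesignRow("all", None),
    ))
    cfg = PredictionConfig(align_tol=1e-9, max_align_iters=40)
    r1 = run_loo(ss, design, cfg)
    T = random_rigid(rng)
    moved = CorrespondedShapeSet(
        tuple(apply_transform(m, T) for m in ss.meshes),
        tuple(apply_transform(l, T) for l in ss.landmarks),
        dict(ss.region_masks),
    )
    r2 = run_loo(moved, design, cfg)
    assert not r1.failures and not r2.failures
    assert np.abs(
        r1.surface["mean_error"].to_numpy() - r2.surface["mean_error"].to_numpy()
    ).max() <= 1e-6
    assert np.abs(
        r1.landmarks["error"].to_numpy() - r2.landmarks["error"].to_numpy()
    ).max() <= 1e-6


def test_loo_heldout_joint_centers_reported_when_absent(noisy_family):
    ss, _ = noisy_family
    design = LandmarkSetDesign((
        DesignRow("surf", tuple(n for n in ss.landmark_names
                                if n not in ("RHJC", "LHJC", "LSJC"))),
        DesignRow("all", None),
    ))
    result = run_loo(ss.subset(range(5)), design, PredictionConfig(),
                     heldout_names=("RHJC", "LSJC"))
    held = result.landmarks[result.landmarks["held_out"]]
    assert set(held["design_row"]) == {"surf"}
    assert set(held["name"]) == {"RHJC", "LSJC"}
    # table emits a row per held-out name for that design row only
    lt = result.landmark_table()
    assert set(lt[lt["group"] == "RHJC"]["design_row"]) == {"surf"}


def test_loo_combined_requires_companion(noisy_family):
    ss, _ = noisy_family
    design = LandmarkSetDesign((DesignRow("comb", None, combined=True),))
    with pytest.raises(SSMKitError, match="companion"):
        run_loo(ss, design)


def test_loo_records_failures_and_continues(noisy_family):
    ss, _ = noisy_family
    small = ss.subset(range(4))
    design = LandmarkSetDesign((
        DesignRow("bad", ("RIAS", "LIAS", "RICT")),  # nearly OK
        DesignRow("good", None),
    ))
    # force failure in the "bad" row by making its landmarks collinear
    lms = []
    for l in small.landmarks:
        pts = l.points.copy()
        i0, i1, i2 = (l.index("RIAS"), l.index("LIAS"), l.index("RICT"))
        pts[i1] = pts[i0] + np.array([1.0, 0.0, 0.0])
        pts[i2] = pts[i0] + np.array([2.0, 0.0, 0.0])
        lms.append(LandmarkSet(l.names, pts, l.specimen_id))
    broken = CorrespondedShapeSet(small.meshes, tuple(lms), dict(small.region_masks))
    result = run_loo(broken, design, PredictionConfig())
    assert len(result.failures) == 4  # every specimen's "bad" cell
    assert set(f["design_row"] for f in result.failures) == {"bad"}
    assert set(result.surface["design_row"]) == {"good"}


# ---------------------------------------------------------------------------
# reporting


def test_report_empty_result(tmp_path):
    empty = LOOResult(
        pd.DataFrame(columns=list(LOOResult._SURFACE_COLS)),
        pd.DataFrame(columns=list(LOOResult._LANDMARK_COLS)),
    )
    p = tmp_path / "out.csv"
    report(empty, p)
    text = p.read_text().strip()
    assert text == "design_row"  # header only


def test_report_round_trip(tmp_path, noisy_family):
    ss, _ = noisy_family
    design = LandmarkSetDesign((DesignRow("all", None),))
    result = run_loo(ss.subset(range(4)), design, PredictionConfig())
    p = tmp_path / "out.csv"
    report(result, p)
    back = read_report(p)
    table = result.to_table()
    assert list(back.columns) == list(table.columns)
    num = table.select_dtypes("number")
    assert np.allclose(back[num.columns].to_numpy(), num.to_numpy(), atol=1e-9)


def test_aggregate_equals_mean_of_specimen_rows(noisy_family):
    ss, _ = noisy_family
    design = LandmarkSetDesign((DesignRow("all", None),))
    result = run_loo(ss.subset(range(4)), design, PredictionConfig())
    st = result.surface_table()
    whole = st[(st["design_row"] == "all") & (st["region"] == "whole")]
    manual = result.surface[result.surface["region"] == "whole"]["mean_error"].mean()
    assert abs(whole["mean"].iloc[0] - manual) <= 1e-9
    # both "maximum" aggregations emitted and consistent with the records
    assert abs(
        whole["max"].iloc[0]
        - result.surface[result.surface["region"] == "whole"]["max_error"].mean()
    ) <= 1e-9
    assert abs(
        whole["max_of_means"].iloc[0]
        - result.surface[result.surface["region"] == "whole"]["mean_error"].max()
    ) <= 1e-9
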