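# ssmkit

Statistical shape modelling of bones from sparse anatomical landmarks:

- build a **PCA shape model** from corresponded triangle meshes (identical
  vertex count/topology across specimens) carrying named anatomical
  landmarks — including off-surface joint centers;
- **reconstruct a full 3D surface** (and unobserved landmarks such as joint
  centers) from a small set of palpated landmarks, via a
  Mahalanobis-regularized least-squares fit in PC space alternated with
  rigid landmark alignment;
- run the **leave-one-out evaluation harness**: rebuild the model on n−1
  specimens per fold, predict the held-out specimen from its landmarks
  only, and report per-region surface errors, predictor-landmark errors and
  held-out joint-center errors;
- generate **synthetic corresponded families** (pelvis-like / femur-like
  templates, smooth orthonormal deformation modes with a known spectrum,
  per-vertex noise, rigid jitter) so everything is testable without any
  external data.

## Layout

| module | contents |
| --- | --- |
| `ssmkit.geometry_io` | `TriMesh`, `LandmarkSet`, `CorrespondedShapeSet`; PLY (ascii + binary LE) / OBJ / STL readers and writers; landmark CSV/JSON; region-mask JSON |
| `ssmkit.alignment` | `RigidTransform`, Kabsch/Umeyama `fit_rigid`, generalized Procrustes (`generalized_procrustes`) with canonical output orientation |
| `ssmkit.shape_model` | `build_ssm`, `n_components_for_variance`, `reconstruct`/`project`, model save/load, two-bone `merge_shape_sets` |
| `ssmkit.sparse_predict` | `solve_scores` (closed form), `predict_from_landmarks`, `predicted_landmarks`/`predicted_mesh`, `PredictionConfig` |
| `ssmkit.evaluation` | exact accelerated `point_to_surface`, `surface_error`, `landmark_error`, predictor-set designs, `run_loo`, CSV `report` |
| `ssmkit.synthetic_shapes` | `make_template`, `FamilySpec`, `sample_family`, deterministic `fixture_suite` |

Conventions worth knowing (documented in the module docstrings):
millimetres throughout; 0-based vertex indexing; covariance divides by
n−1 (this sets the scale against which the regularization weight `rho` is
defined); neither objective term is normalized by point or component
count; alignment is rigid (no scaling) by default so absolute size stays
in the model; surface error runs truth → predicted by default.

## CLI

```sh
# synthesize a corresponded family into a directory
ssmkit simulate --kind pelvislike --n 38 --modes 6 --noise 0.5 --seed 7 --out data/

# GPA-align + fit the shape model
ssmkit fit --shapes data/ --out model.ssm

# predict a surface and all landmarks from observed landmarks
ssmkit predict --model model.ssm --landmarks obs.csv --rho 0.5 --variance 0.95 \
    --out pred.ply --landmarks-out pred_lm.csv

# leave-one-out experiment over a YAML design
ssmkit loo --shapes data/ --design design.yaml --rho 0.5 --variance 0.95 \
    --heldout RHJC --heldout LSJC --out results.csv
```

A design YAML names one predictor set per row:

```yaml
rows:
- {label: N1, landmarks: [RIAS, LIAS, RICT, LICT]}
- {label: all, landmarks: all}
- {label: combined, combined: true}   # needs --companion <other bone dir>
```

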