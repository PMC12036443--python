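# velflow

Time-parameterized velocity flow transformation models for corresponding
point-set series.

Developmental brain atlases (e.g. the mouse DevCCF stages E11.5 through
P56) sample a continuous growth trajectory at a handful of discrete ages.
Pairwise registrations connect neighbouring stages, but they cannot answer
"where is this structure at an age *between* two atlases?".  `velflow`
closes that gap: given K ≥ 2 point sets in one-to-one correspondence, each
tagged with a chronological age, it fits a regularized, time-varying
velocity field v(x, t) over normalized time [0, 1].  Numerical integration
of the fitted field yields a diffeomorphic mapping Φ_{t0→t1} between **any**
two continuous times in the spanned interval — for transforming points,
warping images, or synthesizing *virtual templates* at ages the atlas
never sampled.  The same machinery applies to any ordered corresponding
point-set series (cyclic motion, longitudinal cohorts, …).

## The model

The velocity field is stored as N slices at integration points
τ_i = i/(N − 1).  Optimization is coordinate descent over the slices: at
each τ_i the two chronologically adjacent point sets are warped to τ_i
under the current field, their residuals r_j (anchored at pair midpoints,
scaled by 1/(t_b − t_a) into velocity units) are smoothed into a dense
update U_i by a confidence-weighted multilevel B-spline scattered-data
approximation, and slice i is updated v_i ← v_i + δ·U_i.  Convergence is
tracked by the average displacement error (weighted mean of ‖r_j‖ averaged
over integration points).  Chronological ages are log-transformed before
normalization so that ratios of age map to equal normalized gaps.  See
`docs/methods.md` for the full account.

## Worked example

Fit a flow to a synthetic radial-expansion series with known ground truth:

```python
import numpy as np
from velflow import (FitConfig, FlowSpec, GridGeometry, VelocityFlowModel,
                     generate_flow_series)

geometry = GridGeometry(size=(32, 32, 32), spacing=(1.0, 1.0, 1.0),
                        origin=(0.0, 0.0, 0.0))
spec = FlowSpec(kind="radial_expansion", n_points=300, n_times=4,
                expansion_rate=0.10, seed=13)
series, truth = generate_flow_series(spec, geometry)

model = VelocityFlowModel(series, geometry,
                          FitConfig(n_integration_points=5,
                                    max_iterations=50))
result = model.fit()
print(result.summary())

moved = result.transform_points(series.sets[0], 0.0, 1.0)
err = np.linalg.norm(moved.coords - series.sets[-1].coords, axis=1)
print(f"\nmean endpoint matching error: {err.mean():.4f} voxels")
```

Output:

```
Velocity Flow Transformation Model
==================================================
point sets (K):            4
points per set (M):        300
spatial dimensions (D):    3
grid size:                 (32, 32, 32)
grid spacing:              (1.0, 1.0, 1.0)
integration points (N):    5
step size (delta):         0.2
iterations run:            50 (budget 50)
initial avg displacement:  0.293463
final avg displacement:    0.00264915
final median error/slice:  0.00249, 0.00254, 0.00209, 0.0017, 0.00171

mean endpoint matching error: 0.0082 voxels
```

The initial average displacement error (0.29 voxels — the mismatch of the
raw point sets warped to each integration time under a zero field) drops
by two orders of magnitude over 50 iterations, and flowing the first point
set to t = 1 lands within 0.008 voxels of the true endpoint positions:
the fitted field has recovered the generating expansion.  The results
object can then produce displacement fields (`result.displacement(0, 0.5)`),
warp images, or average warped volumes into a virtual template at any
intermediate time.

## Command line

The same workflow is available as a CLI:

```bash
velflow simulate --kind translation --translation 2,0,0 --n-points 200 \
        --grid 64,64,64 --out-dir sim/
velflow fit sim/points_00.csv sim/points_01.csv \
        --times "[11.5, 46.5]" --grid 64,64,64 --out model.nii.gz
velflow transform model.nii.gz --points sim/points_00.csv \
        --t0 0 --t1 1 --out moved.csv
```

Subcommands: `simulate`, `sample-labels`, `fit`, `transform`,
`virtual-template`, `invert`.  Raw chronological days are accepted wherever
normalized times are (`--t0-day/--t1-day`), resolved through the time map
stored in the model sidecar.  Point sets are CSV (`id,x,y,z[,weight]`);
fields are 5-D vector NIfTI-1 (velocity models carry a JSON sidecar with
the integration times, configuration and convergence trace).

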