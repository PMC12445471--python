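# cortexdev

Depth-resolved cortical maturation analysis as a tested, reusable pipeline:

- **Equi-volume depth binning** (`cortexdev.depth`): closed-form equi-volume
  depth surfaces for a linearly tapering column, 6-bin and 7-bins-trimmed-to-5
  configurations, depth-bin assignment.
- **Surface hierarchy axes** (`cortexdev.hierarchy`): graph-geodesic distance
  from association-region seed vertices (k-means cluster subsampling),
  parcel-level axis scores, tripartition into sensorimotor / middle /
  association groups, best-overlap label mapping, axis correlation.
- **Ratio tables** (`cortexdev.tables`): ratio computation with masking,
  two-point affine reference calibration, parcel x depth-bin aggregation,
  age-balanced subject subsampling.
- **Trajectory GAMs** (`cortexdev.gam`): penalized rank-3 age smooth (linear
  null space + curvature penalty) with REML smoothing selection, optional
  subject random intercepts for longitudinal designs, nested-model age tests,
  signed partial R², first-derivative simultaneous 95% confidence bands via
  Gaussian posterior simulation, plateau-age detection with right-censoring,
  Benjamini–Hochberg FDR.
- **Comparison layer** (`cortexdev.report`): depth-wise slope ANOVAs,
  slope-versus-hierarchy smooth gradients, plateau proportions and timing,
  deep–superficial slope gaps, 4:1 cross-species age scaling, and a
  `run_pipeline` orchestrator with a reproducibility manifest.
- **Synthetic cortex** (`cortexdev.synthetic`): icosphere meshes, contiguous
  parcellations, saturating-exponential ground-truth trajectories with
  configurable depth and hierarchy gradients, and seeded cross-sectional
  (human-like) / longitudinal (macaque-like) measurement-table generators —
  so the whole pipeline is testable with known ground truth and no downloads.

## CLI

```sh
cortexdev demo-config --seed 1 --out demo.yaml   # built-in demo pipeline config
cortexdev run --config demo.yaml --out results/  # full pipeline + manifest

cortexdev simulate --design examples/design_human.yaml --truth examples/truth.yaml --seed 1 --out sim/
cortexdev layers --n-bins 7 --trim --geometry geom.csv --out bins.csv
cortexdev hierarchy --mesh m.off --labels labels.txt --region-mask mask.txt \
    --n-clusters 100 --fraction 0.1 --seed 1 --out axis.csv
cortexdev tables calibrate|aggregate|subsample ...
cortexdev fit --table sim/table.csv --random-intercept subject --out fits/
```

Meshes are read/written as OFF or GIFTI; tables as CSV; truths, run metadata
and manifests as JSON.

## Conventions

- Depth fraction ρ = 0 at the inner (white) boundary; depth bin 1 is the
  deepest bin. All binning outputs carry an explicit `direction` field.
- Geodesic axis scores increase away from the association seeds (larger =
  more sensorimotor-like); `HierarchyAxis.orientation` records this, and
  `sa_rank()` gives the normalized sensorimotor→association rank.
- T1w/T2w-style ratio values are in arbitrary units; calibration parameters
  are always written to JSON sidecars.
- Every stochastic step takes an explicit seed; pipeline reruns with the same
  config are byte-identical (hashes in `manifest.json`).
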