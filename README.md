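# stimmap

Score-based mapping of deep-brain-stimulation outcomes at three levels of
description, exercised end to end on synthetic cohorts with planted ground
truth:

* **Fiber filtering** (`stimmap.fiber_filtering`) — each streamline of a
  normative tractogram is weighted by the peak electric-field magnitude a
  patient's stimulation assigns to it; fibers suprathreshold in enough
  patients receive the Spearman correlation between weight and clinical
  improvement, and an unseen field is scored by rank-correlating its fiber
  weights against that R profile.
* **Sweetspot mapping** (`stimmap.sweetspot`) — voxel-wise Spearman
  correlation of field magnitudes with improvements on a cohort coverage
  mask, with optional hemispheric mirroring, E-field × map outcome
  estimation, and cluster peak / centre-of-gravity extraction.
* **Network mapping** (`stimmap.network_mapping`) — field-seeded Fisher-z
  connectivity fingerprints against a voxel-timeseries connectome,
  voxel-wise R-map models, spatial-similarity scoring, and term-map
  decoding.

Shared infrastructure: an analytic point-source E-field model standing in
for an FEM solver (`stimmap.efield`), cross-validation / permutation
testing / prediction metrics (`stimmap.validation` — note MAE here is the
**median** absolute error), probe-level event-contrast analysis with
Benjamini–Hochberg FDR (`stimmap.flashback`), and a fully deterministic
synthetic study generator (`stimmap.synthetic`).

## Command line

The `stimmap` entry point groups one subcommand family per analysis
level:

```sh
stimmap synth all --out study --seed 1           # write a synthetic study
stimmap cohort validate study/cohort.csv
stimmap fibers fit --cohort study/cohort.csv \
    --tractogram study/tractogram.trk --out model.json
stimmap fibers score --model model.json \
    --efield study/efields/synth000.nii --tractogram study/tractogram.trk
stimmap sweetspot fit --cohort study/cohort.csv --out rmap.nii
stimmap sweetspot clusters --map rmap.nii --out clusters.csv
stimmap validate --level sweetspot --design loo \
    --cohort study/cohort.csv --out cv.json
stimmap flashback fit --probes probes.csv \
    --tractogram study/tractogram.trk --out flashback.csv
```

Volumes are NIfTI-1, tractograms TRK/TCK, cohorts and probes CSV;
connectomes are stored as a NIfTI mask plus a flat float32 timeseries
matrix with a JSON sidecar.

## Conventions

* Improvement is baseline-denominated percent change with positive =
  cognitive improvement (deficit score decreased).
* Voxel indices are 0-based; world coordinates are template mm with
  `world = affine @ [i, j, k, 1]`; the mid-sagittal plane is x = 0.
* Threshold comparisons are inclusive (`>=`); E-field magnitudes are V/mm
  (0.2 V/mm = 200 V/m).
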