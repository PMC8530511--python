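# rpemorph

3D morphometry of epithelial flattening during optic-cup folding.

During vertebrate eye development the retinal pigment epithelium (RPE) — the
outer layer of the optic vesicle — converts from a thick pseudostratified
sheet into a squamous monolayer while the vesicle folds into a cup. In fast
developers (zebrafish) this happens almost without cell division: cells
flatten and spread, the tissue surface doubles while its volume barely grows.
`rpemorph` re-implements the quantitative side of that analysis as a tested,
scriptable pipeline for anyone measuring curved epithelial sheets in 3D
fluorescence time-lapse data:

- **Phantoms with ground truth** (`rpemorph.phantom`) — partial spherical
  shells with prescribed thickness/surface trajectories, folding two-channel
  cups with exact linear volume growth and a prescribed invagination angle,
  and labelled-nuclei stacks with an exact positive fraction. Every stack
  ships with its analytic truth, so the whole pipeline is testable without
  microscopy data.
- **Segmentation** (`rpemorph.preprocess`) — median filter, white top-hat
  background-ramp removal (image minus its grey-scale opening),
  median-intensity cutoff (voxels strictly below the pooled median are
  zeroed), grey-scale closing for nuclear channels, and the max → Gaussian →
  min consolidation pass used before convex hulls.
- **Tissue metrics** (`rpemorph.morpho`) — volume as foreground voxel count ×
  voxel volume; surface as the graph area of a least-squares quadratic
  `x = f(y, z)` over the sheet (the y–z plane is the plane of the cup hinges);
  thickness `= V/S`; discretization of the anterior–posterior extent into 7
  equal-width blocks with exclusion of the rim-contaminated (CMZ) anterior
  blocks from 20 hpf on; convex-hull whole-eye volume.
- **Kinetics** (`rpemorph.kinetics`) — OLS volume-vs-time slopes over closed
  windows, fold-changes, slope ratios.
- **Cell metrics** (`rpemorph.cell_metrics`) — shoelace apical areas,
  apico-basal lengths, contralateral normalization, invagination angles.
- **Proliferation** (`rpemorph.proliferation`) — BrdU/Ki67-style positive
  fractions from centres or from image channels (threshold → close → 26-connected
  components → overlap scoring), plus the cross-species proliferation-vs-
  cell-height summary.
- **I/O + CLI** (`rpemorph.io`, `rpemorph.cli`) — multi-page TIFF with JSON
  spacing sidecars (spacing is never guessed), YAML-configured end-to-end runs
  with full provenance. Subcommands: `phantom`, `segment`, `morpho`,
  `kinetics`, `cells`, `prolif`, `run`.

## Worked example

Measure a flattening epithelial sheet whose true thickness falls from 24 µm
to 8 µm while its surface doubles (1.1 → 2.2 × 10³ µm²), imaged at
0.62 × 0.62 × 1.37 µm voxels with noise and a background ramp:

```python
from rpemorph.phantom import flattening_trajectory_spec
from rpemorph.pipeline import RunConfig, run_pipeline

res = run_pipeline(RunConfig(phantom=flattening_trajectory_spec(seed=1)))
s = res.summary  # per-frame metrics of the CMZ-retained tissue
print(s[["time_hpf", "volume_um3", "surface_um2", "thickness_um"]].head(3))
th17 = s.loc[s.time_hpf == 17.0, "thickness_um"].item()
th21 = s.loc[s.time_hpf == 21.0, "thickness_um"].item()
print(f"flattening fold {th17/th21:.2f}; "
      f"surface fold {s.surface_um2.iloc[-1]/s.surface_um2.iloc[0]:.2f}")
```

prints

```
   time_hpf    volume_um3  surface_um2  thickness_um
0      17.0  26325.607092  1102.721254     23.873311
1      17.5  26545.737596  1214.075899     21.864974
2      18.0  26379.323148  1329.899935     19.835570
flattening fold 3.66; surface fold 2.00
```

The measured thickness at 17 hpf (23.87 µm vs. 24 µm truth) and the surface
fold of 2.00 show the segmentation → V/S chain recovering the stated world to
within ~1% per frame; the flattening fold of 3.66 — more than threefold — is
the value the CMZ-excluded analysis reports, because from 20 hpf the one or
two anterior-most blocks (the arising proliferative rim) are dropped from
tissue metrics. `res.truth_errors` tabulates measured-vs-true error per frame.

The numbered drivers under `analysis/` run the same stages as a narrative:
`01_simulate_phantoms.py` (stated-world stacks + truth),
`02_measure_morphometrics.py` (flattening and surface folds),
`03_growth_kinetics.py` (slope recovery, whole-eye vs RPE ratio),
`04_cell_shape.py` (hexagonal apical areas, A-B ratios, invagination angles),
`05_proliferation.py` (cycling fractions, cross-species rank correlation);
tables land under `results/`, bulky stacks under `scratch/`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly generated labelled-nuclei phantoms, the percentage
of marker-positive nuclei recovered by the image-based segmentation-and-count
route at the two reported species settings (a 200-nucleus stack at the
zebrafish 17-hpf fraction and a 100-nucleus stack at the medaka optic-vesicle
fraction) and writes them as JSON.
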