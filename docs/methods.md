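# Methods

## The measurement model

The package quantifies a curved epithelial sheet (the nascent RPE) and the
whole eye primordium from 3D fluorescence stacks with anisotropic voxel
spacing. All measurements are in physical units; arrays are `(z, y, x)` with
spacing `(sx, sy, sz)` µm and voxel centres at `index × spacing`.

**Volume** is the foreground voxel count times the voxel volume. **Surface**
is the graph area of a full quadratic `x = c0 + c1·y + c2·z + c3·y² + c4·yz +
c5·z²` fitted by least squares to all foreground voxel centres; the y–z plane
is the plane of the optic-cup hinges, so the sheet is single-valued in x.
**Thickness** is volume/surface — the operational mean thickness of a curved
sheet. For a spherical shell of mid-radius R and thickness t this identity is
exact up to a curvature factor `1 + t²/(12R²)`, i.e. ≤ 1% for t/R ≤ 0.35.

### Area integration footprint (a deliberate deviation)

Integrating `sqrt(1 + (∂x/∂y)² + (∂x/∂z)²)` over *every* (y, z) column of the
projected mask systematically overestimates the mid-surface area: the
projected footprint of a shell extends to its outer radius, an excess of
roughly `(1 + t/2R)²`, which biases V/S thickness low by ~t/R (−15% at
t/R = 0.2). By default the integration therefore drops *partial columns* —
columns whose x-extent is below half the median column extent — which are the
rim cut-face columns that only graze the sheet. The quadratic fit itself
always uses every foreground voxel. With trimming, thickness errors on test
shells are ~1–2% up to t/R = 0.2 (the untrimmed behaviour is available with
`trim_partial_columns=False`).

### Blocks and CMZ exclusion

The anterior–posterior extent of the z-projected foreground bounding box is
split into 7 equal-width x-intervals ("equivalent blocks", read geometrically
since block volumes are then compared); voxels are binned by centre
x-coordinate with exact integer arithmetic, so block volumes sum to the whole
volume identically. From 20 hpf the most anterior block — where the
proliferative ciliary marginal zone (CMZ) reporter signal arises — is dropped
from tissue metrics, and the two most anterior blocks on later frames. Which
end of x is anterior is configuration (`anterior="+x"` matches the phantoms,
whose shell opening faces +x); it must be stated explicitly for real data.

Note that the pipeline's headline thickness series is the CMZ-*retained*
tissue, as in the original analysis. On the flattening phantom (true fold
exactly 3.0) the retained series reports a fold of ≈3.6: the rim exclusion
removes genuinely present tissue on late frames. Whole-tissue metrics (block
0) recover truth within ~1% per frame; both are emitted.

### Convex hull

Whole-eye ("H2B") volume is the convex hull of the foreground voxel *region*:
the hull is taken over voxel cube corners (centre ± spacing/2), so the hull
of a solid box equals the box volume and the hull volume is never below the
voxel volume of the same mask. Masks with fewer than 4 non-coplanar voxels
are rejected. The max-filter → Gaussian blur → min-filter consolidation pass
(`hull_prefilter`) is applied to nuclear channels before hulling.

## Segmentation chain

`isolate → median filter → white top-hat → median-intensity cutoff`.

- **Isolation** stands in for the semi-manual 3D structure extraction of the
  original workflow, which has no algorithmic description: voxels outside a
  supplied mask (for phantoms, the ground-truth mask) are zeroed before
  filtering. This step is load-bearing: a global median cutoff on an
  un-isolated image keeps ~half of any continuous background by construction.
- **Median filter** default kernel 3×3×1 (in-plane, respecting z-anisotropy).
- **Top-hat** = image − grey-scale opening. The SE must be *wider than the
  thickest tissue* or the opening retains the sheet's core and the
  subtraction deletes the signal; the default is a 25-px in-plane box
  (≈31 µm > the 24 µm starting thickness), z-size matched in physical units.
  A box SE is used (separable rank filters; an exact ellipsoid footprint is
  available) — for removing smooth ramps the SE shape is immaterial.
- **Threshold**: the cutoff is the median intensity, pooled over the whole
  series by default (per-frame available). Voxels strictly below the cutoff
  become background; ties are kept; zero-valued voxels are never foreground
  (volume counts voxels *above* zero). On an all-equal image everything is
  retained — a documented property of the "strictly lower" rule.

Nuclear channels instead use a grey-scale closing (default 1 px in-plane,
z-radius = physical equivalent, which may round to 0) to fill gaps between
nuclei without bridging distinct ones, then Otsu's threshold — a median
cutoff is degenerate on sparse nuclei images. Nuclei are 26-connected
components; a nucleus is marker-positive when ≥ 50% of its voxels overlap the
thresholded marker channel (the original counts were manual; the overlap
threshold is this package's choice).

## Phantoms: the stated world

Generator defaults encode the documented conditions; where the literature
states no value, a realistic one was chosen once and is not revisited.

| Parameter | Default | Rationale |
|---|---|---|
| voxel spacing | (0.62, 0.62, 1.37) µm | acquisition pitch of the source videos |
| foreground amplitude | 100 | pipeline only thresholds; texture unnecessary |
| noise sd | 5 | realistic for an 8-bit-scale confocal signal of 100 |
| background ramp | 20, linear along x per frame | "smooth background ramp", direction unstated |
| frame interval | 0.5 hr | typical time-lapse cadence; unstated in the source |
| nucleus radius / gap | 3 µm / 2 µm | packed nuclei, no sizes given; the 2 µm hard-core gap guarantees separate 26-connected components at the default pitch |
| cup rim fraction | 0.8 | hinge circle at 0.8 R, a mid-folding cup profile |

The **flattening trajectory** (`flattening_trajectory_spec`) is the canonical
world for tissue-level tests: between 17 and 22 hpf the sheet flattens
linearly from 24 µm to 8 µm (by 21 hpf) while its mid-surface area doubles
from 1.1 × 10³ to 2.2 × 10³ µm². Because the optic vesicle is still nearly
flat at 17 hpf and folds into a cup, the shell's mid-radius shrinks from
200 µm (quasi-planar) to 60 µm across the series, with per-frame angular
coverage set so the mid-surface area follows the prescribed trajectory
exactly. Shells are rendered apex-pinned so the sheet stays registered across
frames, like a stabilized time-lapse.

**Cup sequences** realize a prescribed invagination angle by indenting a ball
with a second sphere passing through the hinge circle; at fixed angle
parameters the geometry is similar across frames, so the eye volume scales as
R³ and the radius realizing an exact linear volume law is closed-form. Truth
records the prescribed volumes, angles, and the vertex/hinge landmark points
(collinear at 180°). **Nuclei stacks** place hard-core spheres by rejection
sampling (bounded retry budget) and put exactly `round(fraction × n)` of them
(half rounds up) in the labelled channel, so the true positive percentage is
exact for every seed.

What the phantoms do **not** emulate: optical PSF and depth attenuation,
photobleaching, cell-resolved membrane texture, rim-involution cell flow, and
real CMZ signal contamination (the excluded anterior blocks contain ordinary
tissue). A green pipeline test therefore establishes correctness of the
measurement chain on idealized geometry, not robustness to optical artefacts.

## Kinetics

Growth is fitted as an OLS line of volume vs time over a closed window
(boundary frames included; windows like "17 to 22 hpf" carry no stated
convention). No robust or weighted variants — the underlying trends are
linear. Slope recovery on noisy series is assessed as the mean over 25 seeded
replicate series: at a realistic 1% volume jitter a single short series
determines a small slope (0.47 × 10³ µm³/hr over 3 hr) only to ~20%, so the
replicate mean is the meaningful estimator-level statement.

## Numerical choices

- Quadratic fits use mean-centred (y, z) coordinates for conditioning;
  rank < 6 raises a degeneracy error rather than silently regularizing.
- Block binning uses integer arithmetic (`(ix − ix_min)·n // span`), immune
  to floating-point boundary ties.
- Median/threshold ties are kept as foreground (strictly-below rule).
- All randomness flows through `numpy.random.default_rng` with per-frame
  seeds derived via `SeedSequence`; generators are bit-reproducible and
  pipeline reruns produce byte-identical CSVs.
- Degenerate inputs raise typed errors (`GeometryError`, `SpacingError`,
  `EmptyRegionError`, ...): empty masks, zero surfaces, coincident points,
  missing spacing metadata (isotropy is never assumed).

## Known limitations

- V/S thickness remains a *mean* over the retained footprint; strongly tilted
  or folded sheets that are not single-valued in x violate the fit's premise.
- The quadratic surface cannot follow rim curvature of deep cups
  (half-angle ≳ 60°); tissue metrics are intended for the sheet-like stages.
- The CMZ exclusion schedule is time-triggered (20 hpf), not signal-triggered.
- Isolation quality bounds everything downstream; with no isolation and a
  continuous background the median cutoff is uninformative by construction.
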