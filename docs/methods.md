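# Methods

This note documents the models, parameter choices and numerical decisions
behind `ttquant`, and what the synthetic benchmark does and does not
demonstrate.

## Cell geometry

**Alignment.** The annotated long axis is rotated horizontal with a single
in-plane rigid transform shared by all slices of a stack (no 3D rotation:
confocal stacks are acquired with the cell roughly in-plane, and a shared 2D
transform keeps slices mutually aligned). Of the two 180°-equivalent
rotations the smaller absolute angle is used. Intensities are resampled with
linear interpolation (configurable), masks with nearest-neighbour. The frame
is trimmed to the transformed outline's bounding box plus a 10-px margin; if
the outline leaves the canvas the frame is zero-padded and the cell is
flagged in the log.

**Segmentation.** The rough outline is refined with a morphological
Chan–Vese active contour (region-based energy; `smoothing=1`,
`lambda1=lambda2=1`, `max_iter=500`). A region-based energy was chosen over
edge-based snakes because membrane staining is frequently broken, which
edge-based evolution leaks through. Convergence is declared when the mask
changes by 0 pixels over 5 consecutive iterations; because the discrete flow
typically terminates in a period-2 limit cycle of boundary pixels on noisy
data, stability is assessed against the state two iterations back. The
smoothing operator alternates between two morphological compositions via
library-global state, which is re-phased before every segmentation so
results do not depend on call order within a process. The largest connected
component is kept and holes are filled; a collapse to an empty mask or a
contrast-free image is a per-cell error.

**Masks.** The sarcolemmal band is the set difference between the cell mask
and the cell eroded `w_mem` times with the 4-connected cross, giving an
exact partition (membrane ∪ cytosol = cell, membrane ∩ cytosol = ∅). The
default band width is 0.5 µm (≈ sarcolemmal staining thickness at confocal
resolution), converted to pixels via the voxel size, minimum 1 px. For
phantom benchmarking the band is widened to 1.5 µm because the phantom's
membrane rectangle is drawn 1.05 µm (7 px) thick: a thinner band leaves the
bright inner rim of the membrane inside the cytosol where it would be
counted as structure.

## Adaptive binarization

A pixel `p` in the cytosol is structure iff

```
I(p) > μ_w(p) + s·σ_w(p)      and      I(p) > μ_w(p) + k_n·σ_noise
```

where `μ_w`, `σ_w` are mean and SD over a square window (default 3 µm,
rounded to an odd pixel count) computed **from cytosolic pixels only** via
masked normalized convolution — pixels outside the cytosol never enter any
window's statistics, so the dark exterior and bright membrane do not bias
thresholds near the border. Defaults: `s = 1.0`, minimum object size 4 px
(despeckling), per-slice for stacks (axial and lateral PSFs differ, and
per-slice thresholds keep 2D and 3D analyses comparable). Ties at the
threshold are background, so constant regions are deterministically empty.

The second condition is a noise floor: `σ_noise` is the MAD-based SD of
cytosolic intensities (`1.4826·median(|I − median(I)|)`), and `k_n = 4`.
Without it, any rule of the form `mean + s·sd` marks the upper ~16% tail of
the noise in structure-free windows (where `σ_w` collapses to the noise SD),
inflating density estimates precisely in sparse cells. In windows containing
structure `σ_w ≫ σ_noise` and the floor is inactive. Both conditions are
built from affine-equivariant statistics, so the output is exactly invariant
under `I → aI + b` (a > 0): binarization is unbiased by staining brightness
and, because the criterion is purely local, by overall structure abundance.
On fixed-noise phantoms differing only in line dropout the detected density
matches the true density to < 0.01 across the full 0–21% range.

The window default of 3 µm is ≈ 1.5× sarcomere spacing: large enough that a
window between tubules still samples local background, small enough to track
uneven illumination. Fallback modes: global threshold at `k·mean` cytosolic
fluorescence, and acceptance of pre-binarized (two-valued) images.

Density is the structure fraction of the cytosol, pooled over slices,
measured before skeletonization so tubule-width changes are visible in it;
comparing density before vs after skeletonization separates width changes
from network loss.

## Skeleton and orientation

The structure map is closed with a `(2r+1)²` square element (default r = 1;
a radius-1 Euclidean disk is a cross and cannot bridge single-pixel axial
gaps) and thinned per-slice with Lee's topology-preserving method, which
keeps endpoints better than iterative boundary erosion (a 50-px bar thins
to ≈ 48–50 px rather than 47). Any residual 2×2 foreground block has one
corner removed so one-pixel width is strict.

Each skeleton pixel is classified from the skeleton pixels within Chebyshev
radius 3 on its own branch: the principal direction of the neighbour offsets
(leading eigenvector of the 2×2 second-moment matrix, computed in closed
form) gives an angle θ ∈ [0°, 90°] to the long axis. With the default 45°
cutoff the nearer axis wins (θ = 45° ties go to transverse). Junction pixels
— crossing number ≥ 3, i.e. three or more distinct neighbour groups around
the 8-ring — and isolated pixels are ambiguous; the crossing number is used
rather than raw degree because the four arm pixels adjacent to every
crossing have degree ≥ 3 and would otherwise be misflagged. Branches are the
8-connected components left after junction removal. Ambiguous pixels are
excluded from the transverse/longitudinal numerators but kept in the
denominator, so the three fractions sum to 1; on dense phantom grids they
are ≈ 2% of the skeleton.

## Distance maps

Distances are exact Euclidean distance transforms (Felzenszwalb-type, via
`scipy.ndimage.distance_transform_edt`) in physical units: per-slice with
(dy, dx) sampling in 2D, with full anisotropic (dz, dy, dx) sampling in 3D.
Property tests verify exact agreement (≤ 1e-9 µm) with brute-force
nearest-target search. Distance is measured through space rather than
geodesically within the cytosol, matching its use as a proxy for Ca²⁺
diffusion distance from release sites; geodesic distance is a non-goal. The
default target set is skeleton ∪ membrane (nearest release site or surface
membrane); if no structure is detected the map falls back to
membrane-only and the cell is flagged. "Deviation" in the metrics table is
the population SD of the distance distribution (MAD or other spreads would
also be defensible; SD is the most common reading and is stated in the
column name). Out-of-domain voxels are NaN in float outputs; renderings use
a fixed physical scale (default 0–3 µm) so colours are comparable across
images.

## Co-localization

Binary Manders-style overlap: `|A ∩ dilate(B, t)| / |A|` and its mirror,
with dilation tolerance t (default 1 px ≈ registration slack between
channels). The same pair is computed on transverse-only and
longitudinal-only skeleton subsets. Fractions with an empty reference set
are NaN, never 0 — "no structure" is a different finding from "no overlap".
Intensity-correlation coefficients are out of scope.

## Phantom generator

Phantoms emulate the published benchmark design: 1024×1024 px at
6.67 px/µm; a 900×200 px membrane rectangle drawn 7 px thick; vertical
(transverse) lines advancing along the long axis with iid
Normal(1.8, 0.3) µm steps, horizontal (longitudinal) lines with
Normal(5.6, 1.2) µm steps (steps clipped at 2 px; the clip is ≥ 4 SD from
both means), each candidate line drawn iff a uniform draw exceeds the
orientation's dropout probability. Line thickness is 2 px (~0.3 µm; only
the membrane thickness is prescribed by the design, tubule-line thickness
is a generator choice). Intensities: background 10, structure 110, membrane
200 on an 8-bit-like scale; constant across lines. Noise is a Gaussian
field (default SD = 20 = 20% of structure–background contrast) convolved
with a circular averaging filter (radius 2 px), added and clipped to
[0, 255]. Everything is deterministic given the seed.

Ground truth counts drawn structure pixels inside the cell divided by the
cell area, where "cell area" is the interior enclosed by the membrane ring
(the region where tubules can exist — the closest analogue of the cytosolic
compartment the pipeline measures over). Crossing pixels count once in the
total density and are split 50/50 between the orientation fractions.

The default benchmark grid is 37 (p_drop_t, p_drop_l) pairs covering
transverse-only, longitudinal-only, dense-both and near-empty cells, i.e.
true total densities from 0 to ~21%. Estimated per-orientation densities
allocate the raw density by the classified skeleton fractions after
renormalizing away ambiguous pixels. With default noise, recovery over the
grid achieves Pearson r ≥ 0.995 for total/transverse/longitudinal density
with slopes 0.91–1.01, and no phantom fails — including the sparse,
irregular cells where regularity-based tools produce no output.

**What phantoms do not emulate:** optics (no PSF, so line edges are crisp),
photobleaching, intensity variation along tubules, curved or branching
tubules, 3D structure (phantoms are single-plane), and realistic
sarcolemmal staining texture. Passing the benchmark therefore demonstrates
correctness of the measurement chain on known geometry and robustness to
abundance/brightness/noise variation — not segmentation performance on hard
real-world staining, which should be checked per dataset (the sensitivity,
window and membrane-band parameters are exposed for that reason).

## Numerical and degenerate-input conventions

- Strict inequality at every threshold; constant images give empty maps.
- Zero-variance cytosol: empty structure map with a warning flag.
- Empty skeleton: orientation fractions 0 with a flag; distance maps fall
  back to membrane targets.
- Erosion emptying the cell ("cell too thin") and windows larger than the
  cytosol are hard per-cell errors; other cells in the image proceed.
- Metrics are written with 9 significant digits; re-reading reproduces
  values to better than 1e-6 relative.
- All randomness (phantom geometry, dropout, noise) flows from a single
  integer seed per phantom; identical seeds give byte-identical output.

## Problem sizes

Default-scale phantoms (1024×1024) are used throughout testing and
benchmarking; the 37-cell recovery benchmark runs the full pipeline per
cell and completes in under a minute on one CPU. Distance-transform
equivalence is property-tested on grids up to 64×64×4 against an
exhaustive-search oracle.
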