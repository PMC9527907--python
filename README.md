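# ttquant

Automated quantification of t-tubule and dyadic-protein organization in
cardiomyocyte fluorescence images.

## The problem

In cardiomyocytes, invaginations of the surface membrane (t-tubules) and the
dyadic proteins decorating them form networks that are mostly transverse to
the cell's long axis, with a variable longitudinal component. These
structures remodel during cardiac disease, and quantifying that remodelling
from confocal/Airyscan images is error-prone with global thresholds (biased
by overall staining abundance) or FFT regularity measures (which assume
regular, continuous structure). `ttquant` is for researchers who need
per-cell measurements of structure **density**, **orientation composition**,
**distance maps** and **co-localization** that remain valid for sparse and
irregular structures, in isolated cells or multi-cell tissue sections, in 2D
or anisotropic 3D.

## The method

For each annotated cell (long-axis endpoints + rough outline in a JSON
sidecar):

1. **Align** — rotate the long axis horizontal, trim to the outline.
2. **Segment** — refine the rough outline with a region-based (Chan–Vese)
   active contour; split the cell mask into a sarcolemmal band and cytosol.
3. **Binarize** — adaptive local threshold over the cytosol: pixel *p* is
   structure iff *I(p) > μ_w(p) + s·σ_w(p)*, with window statistics computed
   from cytosolic pixels only (masked normalized convolution) and an
   affine-equivariant noise floor that keeps structure-free regions empty.
   The rule is exactly invariant under *I → aI + b* (a > 0), so it is
   unbiased by staining brightness and by structure abundance. Raw density
   = |structure| / |cytosol| is measured **before** skeletonization, so
   tubule dilation is reflected in it.
4. **Skeletonize & orient** — morphological closing, thinning to 1-px
   width, then per-pixel orientation from the principal direction of
   same-branch neighbours: transverse (⊥ long axis), longitudinal (∥), or
   ambiguous (junctions/isolated points).
5. **Distance maps** — exact Euclidean distance (µm) from every cytosolic
   voxel to the nearest skeleton/membrane voxel, per-slice in 2D or with
   anisotropic (dx, dy, dz) sampling in 3D; mean/median/max/SD summarize
   the map, a proxy for Ca²⁺-release synchrony.
6. **Co-localization** — Manders-style binary overlap fractions between two
   channels, overall and restricted to transverse-only / longitudinal-only
   skeletons, with a dilation tolerance.

A phantom generator produces synthetic cardiomyocytes (900×200 px membrane
rectangle in a 1024×1024 frame at 6.67 px/µm; transverse lines every
1.8 ± 0.3 µm, longitudinal every 5.6 ± 1.2 µm, per-line random dropout,
filtered Gaussian noise) with exact ground-truth densities and orientation
fractions, so every stage is benchmarkable without external data.

## Worked example

```python
from ttquant import PhantomSpec, generate_phantom, PipelineConfig, analyze_phantom

ph = generate_phantom(PhantomSpec(seed=3))          # noisy phantom + ground truth
est = analyze_phantom(ph, PipelineConfig(membrane_width_um=1.5))
r = est["result"].report
print(ph.truth["density_total"], r.density_raw)
```

Output for this seed:

```
truth:  density_total=0.2118  fraction_t=0.7674  fraction_l=0.2326
est:    density_raw=0.2144    density_skeleton=0.1086
        fraction_transverse=0.7442  fraction_longitudinal=0.2343  fraction_ambiguous=0.0215
        distance mean=0.394  median=0.300  max=1.349  sd=0.269 µm
```

The estimated density (0.214) recovers the generator's exact pixel-count
density (0.212); the skeleton density is lower because thinning removes
tubule width; the orientation split matches the drawn line composition, with
~2% of skeleton pixels at junctions labelled ambiguous; and the mean
cytosolic point lies ~0.4 µm from the nearest tubule or membrane, as
expected for a nearly complete 1.8 µm transverse grid.

From the shell:

```bash
ttquant phantom --n 37 --seed 7 --out phantoms/       # images + truth CSV
ttquant run --image cell.tif --annotations cell.json --out results/
ttquant benchmark --n 37 --seed 7 --out bench/        # recovery statistics
```

`ttquant run` writes a tab-separated `metrics.tsv` (density, orientation
fractions, distance statistics per cell) plus per-cell TIFF artifacts:
binarized map, whole/transverse/longitudinal skeletons, and the 32-bit
float distance map in µm (suitable for 3D rendering in external viewers).

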