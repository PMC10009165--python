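# filamorph

Quantification of septin and Cdc42ep1 filament structures in
fluorescence microscopy, with companion metrics for cell migration and
actin contractility.

Septins assemble into higher-order structures — diffuse puncta, short
fragments, stress-fiber-aligned filaments, rings and large aggregates —
whose balance shifts under perturbations such as Septin7 knockdown or
forchlorfenuron treatment. `filamorph` is for cell biologists and image
analysts who want to turn 16-bit live-cell frames of such markers into
per-image class compositions, and to score the migratory phenotypes
(nuclear-track speed and persistence) that go with them.

## The pipeline

For each frame the package computes:

1. **Cell mask** — manual raw-intensity threshold, hole filling,
   morphological opening (disk, radius 7 px), removal of components
   below 5,000 px.
2. **Background subtraction** — the image minus its Gaussian blur
   (σ = 5 px), negatives clamped, so one structure threshold covers
   bright and dim regions.
3. **Structure objects** — channel threshold (2,000 counts for septin,
   1,500 for Cdc42ep1) on the subtracted image, restricted to the cell
   mask; objects outside the 10–400 px size window are dropped; the
   outer boundary of each survivor is traced (holes ignored).
4. **74 morphometric measures per object** — ten region properties
   (Area … Solidity), mean/SD of the boundary-to-nearest-neighbor
   distance and of the internal intensity, 30 rotation-invariant
   Fourier boundary amplitudes |c<sub>±k</sub>| (k = 1…15) of the
   complex boundary signal z = x + iy, and 30 amplitudes |d<sub>k</sub>|
   of the distance profile along the boundary. Objects whose truncated
   Fourier reconstruction misses the boundary by more than 0.1 px on
   average are excluded.
5. **Classification** — column z-scoring, PCA to the smallest basis
   explaining 90% of variance, DBSCAN (ε = 2, minPts = 3 by default),
   an optional refinement that splits large-object classes along their
   most bimodal principal component (bimodality coefficient
   (γ₁² + 1)/κ > 5/9; 2-component GMM or Otsu split), and merging of
   fine classes into three interpretable groups by co-alignment of
   their area-fraction loading vectors.
6. **Area fractions** — per image, the total area of each merged class
   over the total area of all classified objects (DBSCAN noise reported
   separately).

Migration and contractility metrics: greedy nearest-neighbor track
linking, the >5-frame track filter, speed (mean step / Δt, µm/min),
directionality ratio (net displacement / path length), rose histograms,
relative stress-fiber length r(t) = L(t)/L(0) and its slope, Pearson
colocalization over a whole-cell mask (no threshold), and focal
adhesion area/circularity (4πA/P²).

Because no imaging data are deposited with this kind of study, the
package ships a synthetic-microscopy generator (`filamorph.simgen`)
that draws all five structure classes with known ground truth over a
realistic cell background with Poisson–Gaussian noise, plus
persistent-random-walk trajectories, shortening-fiber series and image
pairs with prescribed pixel correlation. Every stage of the pipeline is
validated against this ground truth.

## Worked example

```python
import filamorph as fm
from filamorph import pipeline as pl

scenes = fm.simgen.gen_channel_batch("septin", n_scenes=5, seed=1000)
cfg = fm.PipelineConfig(dbscan_eps=2.5, merged_k=3, seed=0)
res = pl.run_classification(scenes, cfg)
print("PCA components kept:", res.pca.n_kept)
print(res.profiles_frame().round(3).to_string(index=False))
print(pl.evaluate_classification(scenes, res, cfg))
```

prints

```
PCA components kept: 11
 image_id  defined  noise_fraction  class_0_fraction  class_1_fraction  class_2_fraction
scene_000     True           0.144             0.386             0.432             0.182
scene_001     True           0.045             0.597             0.092             0.311
scene_002     True           0.078             0.277             0.242             0.481
scene_003     True           0.146             0.490             0.314             0.196
scene_004     True           0.133             0.547             0.158             0.294
{'purity': 0.857, 'max_fraction_error': 0.297, 'noise_fraction': 0.052}
```

Each row is one image: the area share of the three merged structure
classes among classified objects (summing to 1) and the area share of
unclassified (DBSCAN-noise) objects. The evaluation line scores the run
against the generator's ground truth: 86% of classified objects land in
a merged class whose majority matches their true class; about 5% of
objects are left unclassified; the largest per-image deviation between
estimated and generated class-area fractions is 0.30 (see
`docs/methods.md` for why fraction recovery is the pipeline's weak
point).

A command-line interface mirrors the library:

```bash
filamorph simulate --kind scenes --n 3 --seed 1 --out-dir scenes/
filamorph classify scenes/scene_000/image.tif --channel septin --out-dir out/
filamorph track tracks.csv --out-dir out/
```

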