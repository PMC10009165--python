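# Methods

## Scope and model

`filamorph` implements an image-analysis pipeline for classifying
subcellular filament structures (septin or Cdc42ep1 markers) in 16-bit
fluorescence frames, and the trajectory/contractility metrics that
accompany such studies. The pipeline is unsupervised: objects are
described by 74 morphometric measures, embedded with PCA, clustered
with DBSCAN, optionally refined, and merged into a small number of
interpretable classes; images are summarized by per-class area
fractions. No labeled training data are involved, so the whole chain
is validated on synthetic scenes with known ground truth.

## Segmentation

* Cell mask: `pixels >= cell_threshold` (thresholds are inherently
  per-image because background levels vary; an Otsu suggestion is
  logged but never auto-applied), hole filling, binary opening with a
  disk of radius 7 px, removal of components under 5,000 px.
  Thresholding is inclusive (`>=`) throughout.
* Local background: the image minus its Gaussian blur (σ = 5 px,
  reflective padding), clamped at zero. This flattens the cell-interior
  gradient so a single structure threshold (2,000 counts septin /
  1,500 Cdc42ep1) covers bright and dim regions.
* Structures: 8-connected components (background 4-connected) of the
  thresholded subtracted image. A component with more than half of its
  pixels outside the cell mask is dropped entirely; otherwise it is
  clipped to the mask — robust to the ~1 px edge erosion the opening
  applies. The inclusive 10–400 px size window is then applied.
* Boundaries: Moore-neighbor tracing of each object's outer boundary
  (holes contribute none), returned in counter-clockwise cyclic order
  in the (x, y) = (col, row) frame. Coordinates are 0-based (row, col),
  origin top-left.

## Features

Ten region properties (Area, ConvexArea, Eccentricity, EquivDiameter,
Extent, FilledArea, MajorAxisLength, MinorAxisLength, Perimeter,
Solidity), four context measures (mean/SD of the minimal distance from
boundary points to the nearest other object, computed per object from a
distance transform of the other objects; mean/SD of internal
intensity, measured on the background-subtracted image by default),
30 boundary-shape Fourier amplitudes and 30 distance-profile Fourier
amplitudes: 74 in total. The source text counts "72 measures" while
naming ten region properties plus 4 + 30 + 30 others; we implement all
ten named properties and document the discrepancy rather than guess
which two to drop.

Numerical conventions that matter:

* Ellipse-equivalent axes use second central moments plus 1/12 (the
  unit-pixel-square convention), so a single pixel has
  Major = Minor = 2/√3 and eccentricity 0, and eccentricity stays
  strictly below 1 for 1-px-wide lines.
* Perimeter is the cyclic polyline length of the traced boundary — no
  Crofton correction; the digitization bias (a digital disk's polygon
  runs ~3% long) is accepted and documented.
* Boundaries are resampled to 128 arc-length-uniform points before any
  DFT so mode indices are comparable across objects. The resampling is
  anchored at the boundary vertex farthest from the centroid — a
  rotation-covariant anchor, which makes the amplitude moduli of an
  object and its lattice-rotated copy agree to machine precision
  rather than to interpolation error.
* Shape amplitudes are |c(+k)|, |c(−k)| for k = 1…15 of z = x + iy
  with the translation mode discarded; distance amplitudes are
  |d(k)| for k = 0…29 of the boundary-to-neighbor distance profile
  sampled at the same points (d0 duplicates the mean-distance feature
  by design; the duplication is harmless after standardization).
* The truncated-series reconstruction error (mean point distance)
  drives the 0.1 px exclusion rule. This bounds how elongated or
  wiggly an object can be and still be analyzed: with 15 harmonics even
  a straight 100-px-long, 3-px-wide rod reconstructs no better than
  ~0.14 px. The synthetic filament class is therefore kept below
  ~20 px so that exclusions on default scenes are rare (<1%).
* Lone objects (no neighbor in the frame) get the image diagonal as a
  sentinel distance and are flagged in the logs.
* Standardization is column-wise z-scoring (population SD);
  zero-variance columns are dropped with a warning; the fitted
  parameters are stored so held-out objects can be projected.

## Classification

PCA keeps the smallest leading basis explaining 90% of variance.
DBSCAN runs in that space with ε = 2 and minPts = 3 by default (a
point's own membership counts toward minPts); `eps="auto"` estimates ε
from the knee of the sorted k-distance curve. Unreachable points are
noise (label −1) and are excluded from area fractions, with their area
share reported separately.

Refinement (off by default; enabled for Cdc42ep1-type data, where
small round and elongated objects co-cluster): among the five classes
with the largest mean object area, each class's most bimodal principal
component is found with the bimodality coefficient
b = (skewness² + 1)/kurtosis (Pearson kurtosis; Gaussian b = 1/3,
cutoff 5/9). Of the eligible classes the two most populated are split
by a two-component Gaussian mixture on that PC (10 restarts, fixed
seed); the rest at the Otsu threshold of the PC values — parameter-free
and deterministic. Classes under six members are never split.

Merging: PCA on the images × fine-classes area-fraction matrix; each
fine class is a unit loading vector over the leading components and
the vectors are grouped by average-linkage hierarchical clustering on
cosine distance. Two design choices depart from the plainest scheme,
both for robustness: (i) the loading space has max(2, k−1) dimensions
— two components can resolve at most three mixture directions, so
k = 3 uses the classical (PC1, PC2) plane and larger k gets the extra
dimensions it needs; (ii) fine classes holding under 1% of total
object area are attached post hoc to the nearest major group, because
their loading directions are statistically unstable and otherwise
bridge unrelated groups. Merged-class names (dots/small clusters,
fragments, filaments/aggregates or rings) are advisory metadata ranked
by mean object area, never used in computation.

## Dynamics metrics

Speed is the mean frame-to-frame displacement over the frame interval
(not net displacement over total time — persistence is reported
separately as the directionality ratio, net displacement over path
length). Tracks must persist for strictly more than 5 frames (25 min
at the default 5-min interval). Track linking is greedy mutual-nearest-
neighbor within a displacement gate, no gap closing — a deliberately
simple stand-in for interactive tracking tools; detections are inputs.
Fiber analysis uses r(t) = L(t)/L(0) with the least-squares slope as
the per-fiber shortening rate; for mask input the length is the
longest geodesic path of the skeleton, an automated replacement for
manual line tracing. Colocalization is the Pearson correlation over
all masked pixels with no intensity threshold. Adhesion circularity is
4πA/P² with the perimeter measured on the low-pass (15-harmonic)
smoothed contour offset outward by half a pixel: the raw staircase
polygon would push a digital disk to ~0.91 and small objects above 1,
while the smoothed contour keeps a disk within digitization tolerance
of 1. Adhesions can be filtered to those whose 1-px dilation touches a
supplied fiber mask.

## Synthetic scenes: what they emulate, and what they do not

A scene is one cell: a smooth bright ellipse (interior offset drawn
from the 12,000–24,000 count range where manual cell thresholds live)
over a dim exterior with a weak linear gradient, imaged with Poisson
shot noise (gain 2 counts/photon) plus Gaussian read noise (SD 50).
Structures are placed inside with ≥2 px clearance (no touching by
default). Defaults: 512² px at 0.1 µm/px; 40 dots (r = 2.0–2.6 px),
20 fragments (6–10 px rods), 8 filaments (14–18 px, straight),
6 rings (outer diameter 0.49–1.35 µm, 2 px thick) and 4 aggregates
(lobed blobs, r = 4–7 px), each ~8,000 counts above background with
class-dependent brightness (aggregates brightest, dots dimmest) and
±10% per-object jitter.

The generator is built as a *classification validation substrate*, so
its classes are deliberately well-defined prototypes rather than
continuous morphological continua: each class draws from a small set
of characteristic sizes (three dot radii, three fragment lengths, one
filament length, five ring diameters spanning the configured range);
elongated structures and lattices share one scene-wide orientation
(emulating the persistent alignment of stress-fiber-associated
arrays); and the classes occupy characteristic spatial arrangements —
filaments in a central parallel bundle, fragments and rings on
regularly spaced lattices at intermediate radii, dots scattered
peripherally, mirroring the central-to-peripheral organization of
these structures in migrating cells. These choices give the
neighbor-distance features class structure instead of pure placement
noise.

Consequences for interpretation: passing tests show the pipeline
recovers *well-separated* morphology classes end to end — correct
segmentation, features, clustering, merging and bookkeeping. They do
not show that real septin images, where morphology varies continuously
and classes overlap, would be recovered at the same purity. Two
further limitations are intrinsic and documented rather than hidden:

* **Density imbalance.** After global standardization the Fourier
  blocks of the largest objects in a dataset carry order-one spread
  per column (their own boundary digitization and neighbor-context
  variability dominate those columns' variance). Large, rare classes
  therefore sit in more diffuse regions of feature space than compact
  puncta, and DBSCAN — one global density scale — loses a
  class-correlated share of them to noise. On synthetic batches the
  object-noise share is ~5% (filament-type batches) to ~20%
  (ring-type batches), concentrated in the larger classes.
* **Fraction bias.** Because the lost objects are not missing at
  random, per-image area fractions over classified objects deviate
  from the generated fractions by more than their sampling error: the
  largest per-image class-fraction error is typically 0.15–0.35 even
  when merged-class purity is high. Area-fraction *differences between
  conditions* remain interpretable (the bias is shared), but absolute
  fraction recovery should not be expected at the ±0.10 level.

The generator does not simulate optical blur (PSF), 3-D structure,
multichannel bleed-through, or photobleaching.

Other defaults: trajectory ensembles use 5-min frames for 4 h
(49 frames) at 0.90 µm/min (the control migration speed regime), with
persistence entering as the support of the uniform heading increment
(persistence 1 → straight lines exactly); fiber movies use 5-s frames
for 5 min with a 24 µm starting length; colocalization pairs are
jointly Gaussian pixel fields mapped affinely into the 16-bit range.

## Validation batches

End-to-end validation runs two five-scene batches mirroring the two
marker vocabularies: septin-like scenes (dots, fragments, filaments;
no refinement) and Cdc42ep1-like scenes (dots, fragments, rings;
refinement on), mixture proportions drawn per scene from Dirichlet(3)
— the variation that makes merging identifiable. These batches use
ε = 2.5: the synthetic feature scale sits slightly above the default
operating point, and ε, like the manual intensity thresholds, is a
per-dataset input. Problem sizes (≈90 objects per 440² px scene, ten
scenes per run) keep a full validation run around ten seconds.

## Determinism

Every generator is a pure function of (parameters, seed); one global
seed drives all stochastic stages (GMM restarts included), and a run
manifest records the config, input checksums, seed and per-stage
counts. Two runs with the same manifest produce byte-identical CSV
artifacts.
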