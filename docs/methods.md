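# Methods

`hevcells` labels tissue compartments (epithelium vs connective stroma) in
haematoxylin-and-eosin (H&E) brightfield images without any annotated
training data.  The method has three parts: a morphology-driven partition of
the stained tissue into nucleus-centred *virtual cells* (v-cells), a
63-dimensional colour/shape description of each v-cell, and a consensus over
many base clusterings of those descriptors.  This note records the model,
its assumptions, the tunable parameters, and the numerical and design
choices made where more than one reasonable option existed.

## Stain separation

H&E dyes absorb light subtractively (Beer–Lambert), so per-pixel RGB
transmittance `v` is converted to optical density `OD = −log((v + ε)/255)`
and unmixed by solving the 3×3 linear system given by the dye absorbance
directions.  The default basis is the standard published H&E pair
(H ≈ (0.65, 0.70, 0.29), E ≈ (0.07, 0.99, 0.11), unit-normalised) with the
residual direction as their normalised cross product; users can override
the matrix in the config when their scanner's dye colours are calibrated.
Choices:

* ε = 1 grey level bounds the density of saturated (v = 0) pixels; it
  biases recovered densities by `log(1 + e^OD/255)`, under 1.5% for
  densities ≤ 1, which is below the 8-bit quantisation floor of the input.
* All arithmetic is double precision; the stain image is quantised to
  8-bit (`255·exp(−d)` per stain) only when materialised, because the
  downstream colour statistics are defined on 8-bit transmittance.
* Negative unmixed densities (colours outside the dye gamut, mostly noise
  on bright background) are clipped to zero.
* Stain-vector estimation from the image itself (Macenko-style) is out of
  scope; the basis is an input.

## Virtual-cell segmentation

1. **Crop.** A grey version of the image is thresholded, specks are removed
   by binary opening by reconstruction, and the image is cut to the
   bounding box of the surviving foreground.
2. **Tissue mask.** Foreground = pixels whose `min(H, E)` transmittance is
   at or below Huang's fuzzy-entropy global threshold (256-bin histogram;
   ties resolved toward the lower threshold).  Using the channel minimum
   means a pixel stained by *either* dye counts as tissue; the residual
   channel plays no part.
3. **Nuclear seeds.** Nuclei are basins of depth ≥ h in the haematoxylin
   transmittance channel.  The h-minima transform (greyscale reconstruction
   by erosion of `g + h` over `g`) fills shallower basins; the regional
   minima that survive — flat plateaus covering the dark 8-connected region
   within depth h of each basin bottom — are the seeds.  Thresholding the
   h-concave residue at > 0 instead would mark basins of *every* depth and
   make the seed count independent of h, defeating h's role as the
   detail/over-segmentation control, so the regional-minima reading is
   used.  The image border is treated as an outlet (the image is padded at
   its minimum before reconstruction): a flat image has no basins, and
   regions that can drain to the border at their own level are not minima.
   Seeds smaller than e erosions (3×3 structuring element) are then deleted
   by binary opening by reconstruction, which removes small components
   without deforming the survivors.
4. **Watershed.** Mask pixels are assigned to exclusive zones of influence
   of the seeds by marker-controlled watershed.  The default flooding
   surface is the haematoxylin channel itself (nuclei are its basins); a
   pure geodesic-influence-zone mode (`watershed_mode: distance`) floods
   the distance transform instead.  No dam lines are kept, so the v-cells
   exactly tile the mask; mask islands containing no seed are attached to
   the nearest labelled region so the tiling is total.  Each seed keeps the
   id of its enclosing v-cell, which is what pairs nuclei with v-cells
   downstream.

Defaults h = 30 grey levels and e = 3 erosions are the method's tuned
operating point.  Connectivity is 8-connected throughout; labels are
row-major with 0 reserved for background.

## Features

Each v-cell contributes 63 features: 11 intensity statistics (mode, median,
mean, average deviation, standard deviation, min, max, variance, skewness,
excess kurtosis, Shannon entropy of the 256-bin histogram in bits) on each
of the three stain channels, 22 shape descriptors of the v-cell and 8 of
its nucleus.  Statistics are computed on transmittance as stored in the
stain image.  Geometric conventions:

* perimeter = length of the boundary polygon through boundary-pixel
  centres (Moore trace; diagonal steps weighted √2).  On digital discs this
  lands circularity at 0.90–0.95 and on squares exactly at the 4(a−1)
  closed form; no single digital estimator is unbiased for both.
* the convex hull is built over the *corners* of the boundary pixels, so
  the hull polygon contains the whole pixel region and solidity never
  exceeds 1.
* feret = maximal distance between hull vertices; breadth = largest hull
  extent perpendicular to the feret axis; MinR = distance from the binary
  centroid to the nearest boundary pixel; MaxR = distance to the farthest
  region pixel.
* one-pixel regions are treated as unit squares (perimeter 4, area 1), and
  any ratio with a zero denominator is reported as 0 so that NaNs never
  reach the clustering stage.

Because the features mix pixel counts, intensities and dimensionless
ratios, columns are z-standardised before clustering.  The 63-column set is
fixed; re-running a feature-subset search is out of scope.

## Ensemble, selection, consensus

Five base clusterers, all with k = 2, build a 31-member ensemble:
k-means ×10 and diagonal-covariance Gaussian-mixture EM ×10 (random
initialisations; the per-run count of initial candidate centres is drawn
uniformly from [10, 200] and the best start by inertia/likelihood is
kept), unsupervised LVQ ×4 (learning rates 0.05/0.07/0.09/0.1, 100 epochs,
linearly decaying rate; runs restart five times from fresh random
prototype rows and the restart with the lowest quantisation error is kept,
because plain winner-take-all strands a prototype roughly half the time on
2-cluster data), MDB ×1 (k-means followed by naive-Bayes Gaussian
reassignment with a variance floor of 1e-6 of the global feature variance,
posterior ties to the lower index), and agglomerative hierarchical
clustering ×6 (complete and average linkage × Euclidean, Manhattan and
Minkowski p = 3 distances, precomputed).  "Mean" linkage is read as
average linkage, and p = 3 is chosen to make the Minkowski run distinct
from the Euclidean one.  All stochastic runs draw their seeds from one
configured generator.

**Selection.**  Each member's mean Rand index against the rest of the
original ensemble must fall in the moderate-diversity band [D1, D2] =
[0.5, 0.9]: near-duplicates (similarity > D2) add no information, and
erratic members (< D1) can corrupt the consensus.  Rejected stochastic
members are re-run with new seeds (up to 5 attempts) and the replacement
is screened against the *original* ensemble, since the similarity measure
is defined over it; deterministic configurations (the AH grid) cannot
produce new solutions and are removed without replacement.

**Evidence accumulation (EAC).**  The co-association matrix counts, for
each v-cell pair, the fraction of members grouping them together; the
consensus is an average-linkage hierarchical cut of `1 − M` into two
clusters (complete linkage is available by option).  Cost is O(n²).

**Voting.**  Cluster labels are arbitrary symbols, so members are first
aligned to a reference — chosen as the member with the highest mean Rand
index against the ensemble, the most consensual anchor — by rendering each
cluster as the pixel set of its member v-cells and matching clusters of
maximal Jaccard overlap; with k = 2 this is one swap decision per member.
The overlap is computed by area-weighted set arithmetic over v-cell areas,
which equals the literal pixel-set Jaccard because v-cells are disjoint (a
rasterising mode exists for conformance testing).  Aligned labels are
combined by per-v-cell majority vote; vote ties follow the member with the
highest ensemble similarity, and residual ties take the lower label.  No
pairwise n×n structure is built, so the cost is linear in n.

## Evaluation

Pixel-level gold standards (background/epithelium/stroma) are transferred
to v-cells by majority pixel class, ties broken epithelium > stroma >
background.  The report holds: the Rand index over v-cell pairs
(background v-cells excluded — clustering only ever sees tissue);
precision, recall and F1 computed pixel-wise with epithelium as the
positive class after mapping the two anonymous clusters onto the classes
by maximal pixel overlap; and the Jaccard index of the predicted vs gold
epithelium pixel sets.  Under this convention F1 is the Dice coefficient
of the same sets, so Jaccard ≤ F1 always holds.

## Synthetic study conditions

The generator emulates exactly the structure the method exploits, at the
default conditions used throughout the tests: a 512×512 image, a bright
background (density 0.02), a circular core split into blobby compartments
by a smoothed Gaussian field, epithelium with dense round nuclei
(18 per 10⁴ px², minor semi-axis 4.5–6 px, eccentricity ≤ 1.25, diffuse
H/E densities 0.45/0.25) and stroma with sparse elongated nuclei
(8 per 10⁴ px², eccentricity 1.5–2.2, H/E 0.12/0.55), nuclear haematoxylin
density 1.3, and Gaussian RGB noise with σ = 2 grey levels.  Nuclei are
dart-thrown with a minimum spacing so neighbouring nuclei do not merge
into one seed — the method does not claim to split merged nuclei.  These
settings yield ≥ 200 nuclei per core and nuclear basins ≈ 100 grey levels
deep, comfortably above h = 30.

What the generator does *not* emulate — staining variability between
laboratories, out-of-focus regions, touching/overlapping nuclei, texture
within compartments, and annotation noise in the gold standard — bounds
what passing tests show: they demonstrate the pipeline's correctness and
its behaviour under the stated conditions, not clinical-grade accuracy on
real tissue micro-arrays.

## Problem sizes and numerical notes

The test suite and the acceptance script run at desk scale: 512 px cores
with ~230 v-cells end-to-end, n = 500 planted-feature studies for
consensus robustness, and exhaustive oracle enumeration at n ≤ 8 objects.
On such fixtures the full pipeline takes seconds.  Degenerate inputs are
defined, not left to chance: constant histograms raise a
degenerate-threshold error, empty masks a no-tissue error, seedless masks
an empty-partition error, and empty selections an empty-ensemble error.

## Known limitations

* Members that are mediocre *and* mutually consistent (e.g. ten EM runs
  converging to the same optimum) can sit inside the diversity band and
  outvote a minority of accurate members; EAC is less sensitive to this
  than voting because co-association averages over pairs.  The same
  asymmetry appears on some synthetic seeds.
* Seed detection treats the image border as an outlet, so nuclei cut by
  the crop boundary may lose their seed.
* The perimeter estimator is the boundary-pixel polygon; dimensionless
  shape ratios of small regions (≲ 5 px across) are coarse, which is why
  one-pixel fallbacks are defined explicitly.
* k is fixed at 2 everywhere; multi-class consensus (bipartite matching
  for k > 2) is out of scope.
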