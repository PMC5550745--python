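# Methods

`gliamorph` quantifies the shape of individual microglial cells from binary
silhouettes and classifies them into morphotypes. Microglia change shape with
activation state — ramified surveillant cells de-ramify through hypertrophied
and bushy intermediates toward compact or polarized reactive forms — so a
reproducible shape-to-morphotype mapping is a proxy read-out of activation.
This note records the models, conventions and numerical choices behind each
stage, and what the synthetic validation does and does not establish.

## Input representation

All measurements operate on a `BinaryCellImage`: a filled silhouette (one
8-connected foreground component, interior holes filled) paired with its
outline (foreground pixels 4-adjacent to background, image border counting as
background). Rasters are row-major with origin top-left. The physical pixel
side defaults to 0.115 µm (pixel area 0.013 µm²), matching 60x oil-immersion
slide-scanner acquisition.

For grayscale crops, preprocessing is: optional Gaussian smoothing, fixed
global threshold (dark-on-light polarity by default, reused across a cohort),
morphological closing plus marker-based component selection to isolate the
cell, then hole filling and outline extraction. The closing radius replaces
the manual join/clear pixel editing of interactive workflows; manual edits are
not reproducible, a fixed structuring element is.

## The 15 descriptors

Pixel-based measures follow the conventions of box-counting tools for stained
cells: `cell_area` = foreground pixel count x pixel area; `cell_perimeter` =
outline pixel count x pixel side. The pixel-count perimeter underestimates
smooth boundaries by up to ~10% (a digitized disk has roughness ≈ 0.9); a
Freeman chain-code estimator (`perimeter_estimator="chain"`) is provided when
geometric accuracy matters more than convention fidelity. Circularity is
4πA/P²; on a mathematical circle's analytic area and perimeter it is exactly 1.

Convex-hull measures use the hull of the foreground *pixel squares* (each
pixel contributes its four corners). This guarantees hull area ≥ pixel-count
area, hence density = area/CHA ≤ 1, and makes a digitized square of side s
span exactly s√2. From the hull polygon: area, perimeter, circularity
(4π·CHA/CHP²), maximum span (largest vertex-pair distance, exhaustive over
vertices), span ratio CHSR (max span over the maximal caliper width
perpendicular to it), minimal enclosing circle diameter (via the rotating-
swipe algorithm in shapely), and radii from the area centroid — mean and max
over vertices, min as the perpendicular distance to the nearest edge, so the
max/min ratio of a square is √2 (corner over edge midpoint) and of a disk 1.
Shapes with collinear foreground (1-px lines) are rejected as degenerate.

### Box counting: fractal dimension and lacunarity

D is estimated by covering the outline with grids of box side eps = 2, 4, 8,
... up to 45% of the shorter image side (at least four scales required), and
regressing ln N(eps) on ln(eps); D is minus the slope, averaged over 12
random grid origins drawn uniformly from [0, eps)² with a fixed seed. Grids
are *periodic*: a box pushed over the image edge by the offset wraps around.
Without wrapping, the offset splits edge boxes and inflates counts at large
eps, biasing D of a filled plane to ~1.90; with wrapping D(plane) = 2 and
D(line) = 1 exactly, while cells padded away from the border are unaffected.

Lacunarity is the mean over the same (scale, grid) sweep of (sigma/mu)² of the
foreground mass per occupied box (a `cv` flag reports plain sigma/mu). Only
occupied boxes enter the statistics; a fully filled frame therefore scores ~0
and patterns with differently sized gaps score high. Averaging over the 12
grid origins makes both statistics robust to translation (shifting a cell by
a few pixels moves lacunarity by <10%).

One grid realization (seeded from the cohort master seed) is shared by all
cells of a cohort: a cohort is measured under a single protocol, and
independent per-cell grids would add between-cell measurement noise to D and
lacunarity.

## Descriptor screening: the multimodality index

MMI = (M3² + 1) / (M4 + 3(n−1)²/((n−2)(n−3))), with M3 the sample skewness
and M4 the sample *excess* kurtosis (biased moment estimators g1, g2). The
finite-n term tends to 3, giving asymptotic values 5/9 for a uniform
distribution, 1/3 for a normal, and 1 for a symmetric two-point mixture —
which is why values strictly above 0.55 (just under the uniform reference)
flag a descriptor as multimodal and therefore informative for separating
subpopulations. The excess-kurtosis convention is what makes the 0.55 cut
meaningful; a raw-kurtosis mode exists behind a flag. MMI is exactly
location-scale invariant.

## Clustering and cluster-count selection

Selected descriptors are z-scored (sample sd, stored for projecting new
cells) and clustered by agglomerative Ward (scipy linkage; merge cost =
increase in total within-cluster sum of squares, Euclidean metric). Clusters
are renumbered by descending size, ties by ascending centroid norm, so
"Cluster 1" is always the most abundant morphotype.

Two independent procedures choose k over the range 2–9:

- **Thorndike ("sudden flattening")**: the mean distance of cells to their
  cluster centroid is evaluated for k−1 through k+1 around every candidate.
  The chosen k minimizes the slope ratio drop(k→k+1)/drop(k−1→k). A
  candidate counts as a genuine elbow only if the slope falls to under a
  third, the decline into k is at least an average step of the curve, and
  every later drop stays below half the decline into k. Curves with no such
  point (e.g. a single Gaussian) return the smallest k with a low-confidence
  flag. A simpler rule — the largest second difference of the curve including
  the k=1 point — always selects k=2 on clustered data because the first
  split dominates; the ratio rule is the operational form of "a marked
  decline in slope".
- **Variance ratio criterion** (Calinski–Harabasz):
  VRC_k = (SSB/SSW)·(N−k)/(k−1), maximized over the range; ties go to the
  smaller k, SSW = 0 yields an infinity sentinel with a warning. SSB + SSW
  equals the total sum of squares to machine precision.

The pipeline's reported k is the VRC argmax; the Thorndike choice is kept
alongside and the two agree on all tested synthetic cohorts.

## Discriminant characterization

Canonical LDA solves the generalized eigenproblem Sb·a = lambda·Sw·a (pooled
within-class scatter Sw, between-class Sb), yielding min(g−1, p) functions
ordered by eigenvalue. Raw coefficients are scaled so each score has unit
pooled within-class variance; constants center scores on the grand mean (the
pooled mean projects to the origin); standardized coefficients are raw times
the pooled within-class sd; proportion of trace is each eigenvalue's share of
the sum. For two classes LD1 coincides with Fisher's discriminant direction.
Overall separation: Wilks λ = prod 1/(1+lambda_i) with Bartlett's
chi² = −(N−1−(p+g)/2)·ln λ on df = p(g−1). Honest accuracy is leave-one-out:
every cell classified by a model refit without it, classification by nearest
class centroid in discriminant space under equal priors (equivalent to the
linear classification functions). A near-singular Sw receives a ridge of
1e-8·trace(Sw)/p with a warning; identical class means yield a degenerate
model with uniform proportion of trace, flagged.

## PCA subdivision into sub-types

The descriptors *not* selected for clustering are submitted to
correlation-matrix PCA (eigendecomposition of the correlation matrix;
loadings = eigenvector x sqrt(eigenvalue) = correlation between descriptor
and score; signs fixed so each component's dominant descriptor loads
positively; eigenvalues sum to p). One representative descriptor per retained
component is chosen by maximal absolute loading (PC2 excludes PC1's pick); a
`"paper"` preset instead returns the maximum-span / hull-circularity pair
used in the published scheme, which preferred those for discriminator potency
over the top-loading descriptor.

Each cluster is split in two at the cohort mean (z = 0) of its sub-typing
descriptor — maximum span for clusters 1 and 3, hull circularity for 2 and 4
by default, both configurable. The split is validated by a two-sample test on
that descriptor (Student's t when both sides pass Shapiro normality and
Levene homoscedasticity at 0.05, Mann–Whitney U otherwise) at alpha = 0.001;
clusters with fewer than two members on either side stay unsplit with a
warning. On tightly clustered synthetic cohorts whole clusters often sit on
one side of the cohort mean — the unsplit path is then the correct outcome,
not a failure.

## The morphotype decision tree

Five threshold rules distil the analysis into a classifier: span ratio above
theta1 → Cluster 4 (the published value 1.93 is available as a preset with
provenance "paper"); otherwise circularity routes Cluster 2 against the rest,
then hull area separates Clusters 1 and 3; finally each cluster's sub-type
cut assigns Type x.1 (at or below) or x.2 (above). All comparisons are
strictly greater, so a cell exactly on a threshold takes the lower branch,
and raising a cell's span ratio can move it into, never out of, Cluster 4.

Fitted thresholds minimize 1-D misclassification between the node's class
groups over midpoints of consecutive distinct values; among equal-error cuts
the middle of the best run is taken, so perfectly separated groups get the
midpoint between the class-conditional extremes. Node orientation (which
class sits on the greater side of nodes 2 and 3) comes from the class means.
A node whose best cut still misclassifies over half of a class is flagged
non-separable. The tree stores its training agreement; on fresh
same-distribution cohorts agreement stays within ~0.1 of it.

## The synthetic cohort: what it emulates and what it does not

The generator renders a cell as an elliptical soma plus branches grown as
one-pixel-step random walks with Gaussian heading jitter (tortuosity), a
thickness drawn per branch, multiplicative per-step taper, and per-step
thickness jitter that emulates the bumpy membrane outline of stained
processes (without it, silhouette boundaries are unrealistically smooth and
box-counting dimensions come out too low). Primaries can spawn up to three
secondaries, secondaries one tertiary. Every cell derives its generator from
(master seed, cell index), so cohorts are order-independent and any cell can
be regenerated alone.

The four presets (in `presets.yaml`, not code) encode the canonical
morphologies; numbers were calibrated so the ramified outline dimension lands
in the range reported for microglia (~1.2–1.45; achieved mean ≈ 1.24) and so
the four populations are genuinely separable: hypertrophied cells get a
rod-like polarized soma (axis ratio 1.5) and amoeboid cells an elongated blob
(2.8), which keeps the four cluster centroids off a single line in descriptor
space — mirroring the high span ratio of reactive morphotypes. The default
study cohort holds 160 cells (60 ramified / 45 bushy / 35 hypertrophied / 20
amoeboid) with region x treatment x time tags: surveillant forms in saline
strata, de-ramified forms in treated strata. Unequal abundances make the
size-ordered cluster numbering stable, with the reactive morphotype as the
rarest (Cluster 4).

Passing the recovery tests on this cohort shows the pipeline's statistics are
implemented correctly and can recover a known 4-morphotype structure from
silhouettes alone. It does not show that real tissue yields four clusters:
real micrographs add staining heterogeneity, overlapping cells, out-of-focus
branches and true biological continua between forms, none of which the
generator models (nor does it model 3-D structure or motility).

## Problem sizes and numerical notes

The standard validation cohort is 160 cells at 768² px; a full pipeline run
(generation, measurement with 12-grid box counting, clustering, leave-one-out
LDA, PCA, tree) completes in well under a minute on one core, and the test
suite uses the same cohort once per session plus smaller cohorts elsewhere.
All randomness flows from explicit integer seeds (numpy SeedSequence); reruns
are bit-identical on numeric artifacts. Box-count regressions require ≥ 4
scales and report per-placement R². Degenerate inputs (empty masks, constant
descriptor columns, singleton classes, single clusters, collinear shapes)
raise typed errors or warnings as documented per function.
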