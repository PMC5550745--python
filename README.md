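# gliamorph

Morphometric profiling and morphotype classification of microglial cells
from binary silhouettes.

Microglia — the resident immune cells of the brain — change shape with
activation state: ramified "surveillant" cells de-ramify through
hypertrophied and bushy intermediates toward compact or polarized reactive
forms. `gliamorph` turns single-cell silhouettes (synthetic, or binarized
crops of IBA1-stained micrographs) into an objective morphotype assignment:

1. **15 shape descriptors** per cell: box-counting fractal dimension *D*
   (slope of ln N(ε) vs ln ε over a power series of box sizes, averaged over
   12 random grid placements), lacunarity Λ (mean (σ/µ)² of the pixel mass
   per box), area, perimeter, circularity CC = 4πA/P², and convex-hull
   measures (area CHA, perimeter, circularity CHC, span ratio CHSR, maximum
   span MSACH, bounding-circle diameter, centroid-radius statistics,
   density = A/CHA, roughness).
2. **Multimodality screening**: descriptors with
   MMI = (M3²+1)/(M4 + 3(n−1)²/((n−2)(n−3))) strictly above 0.55 (M3
   skewness, M4 excess kurtosis) are multimodal and enter the clustering.
3. **Ward hierarchical clustering** on z-scored descriptors, with the
   cluster count chosen by the Thorndike elbow (sudden flattening of the
   within-cluster-distance curve) and the variance ratio criterion
   VRC_k = (SSB/SSW)·(N−k)/(k−1).
4. **Canonical discriminant analysis** of the clusters: standardized
   coefficients, proportion of trace, Wilks' λ with Bartlett's χ²,
   leave-one-out cross-validated accuracy, territorial-map coordinates.
5. **Correlation PCA** of the remaining descriptors selects one high-loading
   descriptor per component and splits each cluster into two sub-types at
   the cohort mean, validated by a two-sample test (p < 0.001).
6. **A threshold decision tree** (CHSR → CC → CHA, then one sub-type cut per
   cluster) that assigns any measured cell to one of 4 clusters and 8 Types;
   the published first-node cut (CHSR > 1.93 → Cluster 4) is available as a
   preset.

A first-class synthetic generator renders labeled silhouettes of the four
canonical archetypes (soma + random-walk branches with controllable size,
branch count/length/thickness, tortuosity and membrane roughness), so the
entire pipeline is testable end-to-end with no image downloads.

## Worked example

```python
from gliamorph import default_cohort
from gliamorph.workflow import PipelineConfig, run_pipeline

result = run_pipeline(default_cohort(seed=42, scale=0.4), PipelineConfig(seed=42))
```

(= `examples/04_full_pipeline.py`; 64 cells, a few seconds) prints

```
cells analysed        : 64
chosen k              : 4
Wilks lambda          : 0.0009 (chi2=392.1, df=30)
LOO accuracy          : 95.3%
proportion of trace   : [85.1, 11.6, 3.3] %
tree training agreement: 0.984
tree node 1: convex_hull_span_ratio > 2.06 -> Cluster 4
```

Both cluster-count procedures recover the four generating archetypes
(`chosen k = 4`); Wilks' λ ≈ 0 with a high leave-one-out accuracy means the
clusters are genuinely separated in descriptor space rather than an artifact
of the clustering step, and LD1 carries ~85% of the discriminative variance.
The fitted tree reproduces the cluster labels for 98% of training cells from
three thresholds.

Per-archetype descriptor means (`examples/01_render_archetypes.py`) show the
activation gradient the descriptors encode — complexity (D, perimeter,
lacunarity) falls and compactness (density, CC) rises from surveillant to
reactive, while the polarized reactive form stands out in span ratio:

```
archetype           D  lacun  perim(um)  density     CC   CHSR
ramified        1.233  0.357      227.6    0.337  0.049   1.10
hypertrophied   1.166  0.299      124.9    0.408  0.121   1.27
bushy           1.045  0.248       61.1    0.647  0.473   1.22
amoeboid        0.995  0.146       48.8    0.983  0.795   2.78
```

The other example scripts cover box-counting calibration
(`02_box_counting.py`: D(line)=1.000, D(plane)=2.000), descriptor screening
and k-selection (`03_select_and_cluster.py`), and classifying unseen cells
with a fitted tree (`05_classify_new_cells.py`).

A thin CLI mirrors the stages for shell use:

```sh
gliamorph simulate --seed 42 --outdir masks/
gliamorph features --masks masks/ --seed 42 --out features.csv
gliamorph cluster --features features.csv --out labels.csv
gliamorph pipeline --seed 42 --outdir artifacts/   # everything at once
```

Cohorts can be described in YAML (`seed`, `image_size_px`, `pixel_size_um`,
and `entries:` with `archetype` — a preset name or inline parameters —
`n_cells`, `region`, `treatment`, `time_h`).

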