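# Methods

`morphoscale` implements a multi-scale morphometry pipeline for single
mouse neurons: image-domain detection of somas, neurites and boutons;
curation of automatically traced dendrites; local-morphology
"microenvironments"; whole-morphology typing; sub-neuronal structures
(arbors, hubs, primary tracts); and a cross-scale diversity/stereotypy
(DS) summary. Because the original whole-brain datasets are peta-voxel
scale, every input is emulated by a seeded synthetic generator with
planted ground truth, and validation is phrased as recovery of what was
planted. This note records the models, the conventions chosen where the
protocol leaves latitude, and what the synthetic tests do and do not show.

## Data model and morphometric features

Skeletons are rooted SWC trees (id, structure code, x/y/z in μm, radius,
parent). Branches run between consecutive critical points
(root/bifurcation/tip); root branches have order 1; multifurcations are
treated as k−1 stacked bifurcations over the children sorted by node id,
which makes angle and asymmetry features deterministic.

The 22 whole-neuron features follow the widely used global-morphometry
conventions: counts (nodes, stems, bifurcations, branches, tips), overall
extents, total length, membrane surface (Σ 2πr·ℓ over compartments),
volume (Σ πr²·ℓ), maximum Euclidean/path distance to the soma, maximum
branch order, mean branch contraction (chord/arc ∈ (0,1]), mean
fragmentation (compartments per branch), mean parent–daughter radius
ratio, mean local and remote bifurcation amplitudes (degrees), and a
box-counting Hausdorff dimension. The box counting uses four dyadic box
sizes below the bounding-cube edge, with the skeleton densely resampled at
half the finest box size so counts follow the curve rather than the node
placement; the dimension is the least-squares slope of log N vs log(1/s).
Soma surface is 4πr² of the root; average diameter is the node mean of 2r.

Local features (10): branch length, order and contraction; bifurcation
Euclidean and path distance to the soma; partition asymmetry
|n₁−n₂|/(n₁+n₂−2) (0 for a (1,1) split); local and remote amplitude; and
local and remote tilt. Tilt uses the reversed parent direction (soma-ward
vector at the bifurcation), so a straight continuation reads 180°, and
reports the smaller of the two daughter angles.

`resample_tree` has two modes: `subdivide` (default) splits edges longer
than the target spacing into equal pieces and is exactly idempotent;
`uniform` redistributes nodes at uniform arc length per branch and is used
wherever node *density* must reflect geometry (spatial density counts,
hub detection).

## Synthetic data generation

The generators are pure functions of a `SynthSpec` and a seed, and every
dataset carries a ground-truth ledger (class labels, soma centres, bouton
arc positions, module assignments) consumed only by tests.

* **Toy atlas** — an ellipsoidal brain mask Voronoi-tiled into connected
  regions (slivers produced by voxelisation are re-attached to their
  dominant neighbour), grouped into compound areas by a coarser Voronoi
  over the region centres. Default 12 regions / 4 areas in a 64³ volume at
  25 μm.
* **Morphologies** — stochastic segment growth: Gamma-distributed branch
  lengths, per-μm bifurcation rate (branch-end split probability
  min(1, rate·ℓ)), direction persistence with Gaussian jitter, order cap.
  Dendrites grow locally (basal stems, optional apical); the axon is laid
  out as a primary tract steered toward a projection-target region with
  dense arbors (five local subtrees each) planted at waypoints along the
  distal part of the tract. Four default class regimes loosely mirror
  cortical ET/IT, thalamic and striatal archetypes and are deliberately
  distinct in branch length, bifurcation rate, straightness, arbor count,
  stem count and projection target — the generator's purpose is planted,
  recoverable class structure. No class projects to its own home region.
* **Volumes** — somas are parabolic-profile bright spheres, neurites
  Gaussian-profile tubes, boutons Gaussian bumps; additive Gaussian noise
  with sd = amplitude/SNR on a 16-bit scale. SNR means peak amplitude over
  noise sd throughout. The soma-field generator scatters non-overlapping
  spheres (radius 8 voxels, ≥24 voxels apart).
* **Profiles** — per-node intensity (8-bit scale) and radius along the
  axon with planted Gaussian bouton bumps (σ = 1.5 μm arc length, radius
  factor 2.5, amplitude +100). Planted positions sit ≥3 μm inside branches
  at least 20 μm long, since a bouton at a branch junction has no
  well-defined within-branch arc position.
* **Density matrices** — regions × brains, planted modules share a
  per-brain latent loading scaled by per-region gains plus Gaussian noise
  at 1/SNR of the signal sd; remaining regions are independent; columns
  normalised to sum to 1. Default 40 regions, 8 modules of 3–6 regions,
  50 brains, SNR 10.

The generators emulate the *statistical* structure the analysis assumes —
clustered somas, per-class growth regimes, tube-plus-bump image signal,
correlated region modules. They do not model optics (no PSF), axial
anisotropy (isotropic by default), registration error, labelling
variability or biological within-type covariance beyond the planted
regimes; passing tests therefore demonstrate correctness and recoverability
of the algorithms under controlled conditions, not expected performance on
real micrographs.

## Image detectors

**Foreground threshold.** Per block, `0.9·min(max(μ+1.5σ, 400), 1000)` on
the 16-bit intensity distribution; the floor, ceiling and scales are
config, not hard-coded.

**Neurite salience.** The block is Gaussian-smoothed (σ = 1 voxel), the
5³ local mean is subtracted and the result clamped at zero; 16³ cuboids
are scored by the intensity-weighted PCA anisotropy
(S₁−S₂)/(S₁+S₂)·(S₁−S₃)/(S₁+S₃) of their foreground voxels (score 0 when
fewer than 3), and the salience is the denoised image times the upsampled
score map. The final mask thresholds salience at 0.1×thresh; blocks whose
maximum is below 300 are skipped. Isotropic noise cuboids score ≈0, which
is what makes the 0.1×thresh cut usable at realistic noise levels.

**Soma detection.** 16-bit blocks below a max-intensity prefilter (250)
are skipped; the rest are z-scored, mapped to 0–255, lightly smoothed and
binarised at their 99th percentile. The grayscale distance transform
(GSDT) then assigns each foreground voxel its Euclidean distance to the
nearest background voxel weighted by the mean intensity (relative to the
mean foreground intensity) interpolated along the straight path to that
voxel. Bright deep interiors thus score above their geometric depth; on a
uniform-intensity mask the transform equals the plain Euclidean distance
transform exactly, which is the property the implementation is tested
against. Normalising by the mean foreground intensity keeps the value
scale distance-like regardless of where the percentile threshold falls —
the 5–30 candidate window is interpreted in these voxel-distance-like
units (config). Candidates are local GSDT maxima inside the window,
thinned by non-maximum suppression (radius 8 voxels, deliberately smaller
than the 15-voxel duplicate rule so both stages act), then refined by
mean-shift (15-voxel window, voxels below μ+σ zero-clipped); refined pairs
within 15 voxels whose midpoint intensity falls below their mean centre
intensity are merged.

**Profiles.** Per-node trilinear intensity plus a local radius estimate:
the largest sphere whose mean surface intensity (42 Fibonacci directions)
stays at or above half the centre intensity.

## Dendrite curation

Each filter is an independent pass over the raw tree iterated to a fixed
point (hence idempotent); the curated tree is the node-set intersection of
all passes, reconnected as the rooted component, and discarded below 20
nodes. Branch angles use the convention angle(parent end→start,
child start→end), so 180° is a straight continuation.

* geometry: child branches turning <80° against the parent or with mean
  radius >1.5× the parent branch's mean radius are removed with subtrees
  (mean-of-branch radii; the per-node alternative is noisier).
* crossovers: multifurcations and consecutive bifurcations within 5
  voxels. Children <80° are removed. A "mediocre" child (80–100°) that
  subtends >150° with a sibling forms a through-going line crossing the
  structure — such pairs belong to another process and are removed; a
  mediocre child without such a partner is kept.
* foreign somas: clusters of nodes with radius >5 px whose projected area
  exceeds 500 px² (outside a 50 px guard around the true soma) mark a
  second soma. The root→foreign path is cut at the position minimising the
  per-edge length-weighted deviation-angle integral (each edge's angle to
  the radial line from its nearer soma); ties keep the side with more
  nodes.
* winding: root-to-branch-end path/Euclidean ratio strictly above 3
  (per-branch alternative behind a flag).
* consensus: primary nodes without a reference-tracer node within 5
  voxels are pruned with descendants; disagreeing roots warn and skip.

## Population modules

Region co-occurrence uses Spearman correlation of region rows over brains
(constant rows → 0 with a warning). Target-correlated sets collect, per
region, the partners with ρ ≥ 0.8. Initial modules come from average
linkage on 1−ρ: the dendrogram is cut where consecutive merge heights jump
the most (the first diverging level); clusters above 15 regions are re-cut
recursively, clusters below 3 join their most-correlated module — a
deterministic mechanisation of the size-banded dendrogram walk. Tight
modules drop regions occurring fewer than twice across the target sets and
keep modules with ≥2 survivors, with the mean within-module ρ attached as
the consistency score (reported, not thresholded).

## Microenvironments

Each local dendrite is a 24-vector: 18 of the 22 whole-neuron features
(the four size/count features Nodes, SomaSurface, AverageDiameter and
Surface excluded) plus the PCA explained-variance ratios of PC1–3 and the
sum-normalised |PC1| loadings. A microenvironment fuses the target with up
to five most feature-similar neighbours (Euclidean distance of
population-z-scored vectors, z-scoring over the whole population) inside a
sphere of radius D = 249 μm; weights are exp(−dᵢ/D) normalised to 1, and
the fused vector is the weighted sum of raw member vectors (hence always
inside the member-wise hull). A data-driven estimator of D (median
5th-neighbour distance) is provided. mRMR feature selection is the MID
variant: features z-scored, discretised into 5 equal-width bins, greedy
max(relevance − mean redundancy) with mutual information. The RGB map
min-max scales three selected features to 0–255 at soma voxels, optionally
mirroring the high hemisphere across the mid-plane of axis 0; histogram
equalisation is excluded from quantitative outputs. Region clustering is
K-Means on z-scored concatenations of per-region feature means and
variances.

## Morphotypes

The 47-vector is 7 global features (Stems, Branches, OverallWidth/
Height/Depth, OverallVolume as bounding-box volume — config switch to the
compartment-sum sense — and Length) plus min/max/mean/sd of the 10 local
features. Similarity is cosine(f_i, f_j) on z-scored vectors times
exp(−d_ij/d_norm) with d_norm the maximum pairwise soma distance; negative
cosines are clamped to 0 in the spectral affinity (affinities must be
non-negative). Spectral clustering uses the normalised Laplacian with
seeded k-means assignment; disconnected affinity graphs are clustered
component-wise with a warning. Cluster-pair separability uses the standard
silhouette (b−a)/max(a,b) on soma positions (singletons score 0), and
cluster pairs are characterised by mRMR top-3 features with per-cluster
hit rates.

## Sub-neuronal structures

**Arbors.** Axons are split by spectral clustering on exp(−d/σ) node
affinities (σ = 50 μm) with tree connectivity enforced afterwards
(minority components re-attach to their tree-neighbour's label); basal and
apical dendrites stay whole. Features per arbor: branch count, PCA-rotated
bounding-box volume, maximal spatial density (nodes within 20 μm, on
uniform-resampled geometry), and the soma distance of the max-density node
(>750 μm → distal). Axonal arbors are labelled A1, A2, … by increasing
soma distance. The automatic arbor count is the largest Laplacian eigengap
(k ∈ [1,4]) computed over *dense-packed* axon nodes only — nodes with at
least 30% of the maximum neighbour count within 50 μm after uniform 10 μm
resampling. Arbors are dense by definition; without the pre-screen the
sparse connecting tract dominates the spectrum and the count is
unrecoverable. Regional counts are majority votes with ties broken small.

**Hubs.** Axons are uniformly resampled at 80 μm in 25 μm atlas space;
nodes with more than 70 neighbours (self included) within a 500 μm sphere
are written into a voxel image, dilated with a 10³ kernel and labelled;
connected components are the hubs.

**Tracts.** The primary tract is the longest root-to-tip axonal path
after iteratively removing terminal branches shorter than the
second-longest axonal branch (threshold frozen from the original
decomposition); the current longest path is protected so the trunk itself
is never dismantled. Tracts are resampled to 200 arc-uniform points.
Group radius profiles project, per arc percentile, the tract points onto
their top-2 PCA plane and take the 75th percentile of distances to the
centre; the pattern compares terminal-end vs soma-end mean radii (first
and last 10% of arc): ratio <0.8 convergent, >1.25 divergent, else
parallel (config). Projection vectors accumulate axonal edge lengths (mm)
into the atlas region of each edge midpoint, background excluded.

## Boutons

Candidates are radius-profile peaks on axonal branches (≥20 μm) with an
intensity peak within 2 μm of arc, at least 1.5× the median surrounding
shaft radius (±10 μm arc, ±2 μm core excluded), and 8-bit intensity above
120; duplicates within 5 voxels keep the brighter. TEB (terminaux) means
within 5 μm of a terminal tip along the branch, else EPB (en passant) —
the τ = 5 μm convention is explicit since the types are named without a
printed criterion. Summaries per neuron: bouton count, TEB ratio, mean and
sd of inter-bouton distance (arc to the soma-ward predecessor), mean and
max distance to soma — the six radar features, min-max scaled to 0–100
across groups. Branch-level statistics: bouton vs null branches with
length/order/curviness (1 − chord/arc), bifurcation types by bouton
presence in the two children (B0/B1/B2), and within-branch quartile
occupancy against the uniform expectation 0.25.

## Cross-scale features and the DS matrix

The 84-dim vector concatenates z-scored blocks: microenvironment (18
fused morphometrics), full morphology (the same 18 on the whole neuron),
arbors (apical — zeros when absent —, basal, axonal A1 and A2, forced to
two axonal arbors for comparability, × 4 features), boutons (the 6 radar
features) and tract motif (6 summary scalars plus a 20-point
distance-to-soma trajectory profile). The exact published composition
beyond 18+18 is not printed; block sizes are configurable and a
composition hash accompanies outputs. The DS entry for types U, V is the
mean Pearson correlation (dims as observations) over all cross-type neuron
pairs; the diagonal averages intra-type pairs with self-pairs excluded;
zero-variance vectors are excluded with a warning; singleton types yield a
missing diagonal. Per-scale DS matrices restrict to one block. Scale
distances are 1 − Pearson between vectorised upper triangles; moment
summaries report mean, sd, skewness and excess kurtosis of intra-type
distributions (flagged unstable below 4 samples or at zero variance).
Distance-vs-correlation bins pairwise vector correlations against soma
distance and against the Euclidean distance between projection vectors,
with a linear fit restricted to a configurable range (defaults scale the
published 4 mm / 24 mm windows down proportionally on toy atlases).

## Problem sizes and determinism

Everything runs on seeded `numpy` Generators; clusterings take explicit
seeds; the end-to-end pipeline is byte-identical across reruns of one
seed. Validation problem sizes are toy-scale by design: 30-sphere 128³
soma fields, 20 neurons × 20 boutons, 40-region/50-brain density matrices
over 20 seeds, 60-neuron typing over 10 seeds, and 60-neuron cross-scale
populations over 10 seeds — chosen so the planted structure is at realistic
contrast while the whole suite remains reproducible on a laptop.

## Known limitations

* The detectors are desk-scale (≤256³ blocks); whole-brain tiling is a
  thin loop and not optimised, and there is no pyramid/streaming I/O.
* The GSDT definition (straight-path line integral) is a package
  convention; graded intensities along strongly curved geodesics would be
  weighted differently by a true geodesic transform.
* The crossover mediocre-angle rule and the TEB distance are explicit
  conventions where the protocol names intent without a formula.
* Generator realism is statistical, not biophysical (no growth-cone
  mechanics, no PSF); absolute detector numbers on real volumes will be
  lower than on the synthetic fields.
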