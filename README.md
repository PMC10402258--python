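# morphoscale

Multi-scale morphometry of single neurons, for computational
neuroanatomists working with whole-brain light-microscopy reconstructions
(SWC skeletons, labelled atlas volumes, small 3-D image blocks).

Modern brain-wide imaging yields neurons at several scales at once — the
population density of neurites across atlas regions, the local dendritic
neighbourhood of each cell, the full axo-dendritic morphology, dense
axonal arbors and long projection tracts, and micron-scale boutons.
`morphoscale` implements a coherent pipeline across all of them:

* **core** — SWC I/O, a rooted `NeuronTree` model, branch decomposition,
  the 22 classic whole-neuron morphometrics and 10 local
  branch/bifurcation features, resampling, PCA shape descriptors.
* **imaging** — neurite segmentation with PCA-anisotropy salience, soma
  detection via a grayscale distance transform with non-maximum
  suppression and mean-shift refinement, and intensity/radius profile
  sampling along skeletons.
* **curation** — consensus merging of two tracer outputs and geometric
  pruning filters (branch angle/radius, crossover resolution, foreign-soma
  cuts, winding paths) for local dendrite reconstructions.
* **popmodules** — cross-brain Spearman correlation of region neurite
  densities, target-correlated region sets, and data-driven region modules.
* **microenv** — dendritic microenvironments: spatial-proximity-weighted
  fusion of each neuron's 24-dim feature vector with its most similar
  neighbours (weights `w_i = exp(−d_i/D)/Σ_j exp(−d_j/D)`), mRMR feature
  selection, RGB feature maps, region clustering.
* **morphotype** — 47-dim full-morphology vectors, spatially tuned
  similarity `S_ij = cos(f_i, f_j)·exp(−d_ij/d_norm)`, spectral
  clustering, silhouette separability, per-pair discriminating features.
* **subneuronal** — axonal arbor decomposition with automatic arbor
  counts, population structural hubs, primary axonal tracts with
  convergent/divergent/parallel radius profiles, projection vectors.
* **boutons** — axonal varicosity detection from intensity/radius
  profiles, TEB/EPB typing, radial and branch-level statistics.
* **ds** — 84-dim cross-scale vectors and the Diversity-and-Stereotypy
  matrix: DS(U,V) = mean Pearson correlation over neuron pairs of types U
  and V (diagonal = stereotypy within a type, off-diagonal = diversity
  across types).
* **synth** — seeded generators for every input the pipeline consumes
  (toy atlas, grown morphologies with planted class structure, rendered
  volumes, profiles with planted boutons, density matrices with planted
  modules), each with a ground-truth ledger.

## Worked example

```python
import numpy as np, pandas as pd
from sklearn.metrics import adjusted_rand_score
from morphoscale import synth, core, popmodules as pm, morphotype as mt

spec = synth.SynthSpec(seed=7)
atlas = synth.make_toy_atlas(spec)
trees = synth.grow_population(spec, atlas, n_per_class=15)

lm = core.lmeasure_features(trees[0])
print(f"first neuron: {int(lm['Nodes'])} nodes, {int(lm['Branches'])} branches, "
      f"total length {lm['Length']/1000:.2f} mm")

md, planted = synth.make_density_matrix(spec)
mc = pm.correlation_map(md)
tight = pm.tight_modules(pm.initial_modules(mc), pm.target_correlated_sets(mc), mc)
print(f"recovered {len(tight)} tight modules; consistency "
      f"{min(tight.consistency):.2f}-{max(tight.consistency):.2f}")

ids = [t.metadata['neuron_id'] for t in trees]
f47 = pd.DataFrame([mt.features47(t) for t in trees], index=ids)
pos = np.array([t.soma_xyz for t in trees])
labels = mt.spectral_cluster(mt.similarity_matrix(f47, pos), k=4, seed=7)
truth = [t.metadata['class_index'] for t in trees]
print(f"morphotype ARI vs planted classes: {adjusted_rand_score(truth, labels):.2f}")
```

prints

```
first neuron: 769 nodes, 208 branches, total length 7.68 mm
recovered 8 tight modules; consistency 0.98-0.99
morphotype ARI vs planted classes: 1.00
```

The 8 recovered modules are exactly the 8 planted correlated region
blocks of the density matrix, with within-module mean Spearman
correlation ("consistency") near 1 at the default noise level, and the
spectral morphotypes reproduce the four planted growth regimes perfectly
(adjusted Rand index 1.0).

## Command line

Every stage has a subcommand (`morphoscale synth | detect-somas |
segment-neurites | curate-dendrites | modules | microenv | morphotype |
arbors | tracts | hubs | boutons | ds`), and

```bash
morphoscale pipeline --seed 0 --out runs/demo
```

chains them end to end on synthetic data, writing CSV/JSON/SWC outputs
plus a manifest; reruns with the same seed are byte-identical.

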