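# spatialflow

Spatially consistent low-dimensional embeddings for spatial transcriptomics
(ST) data, with domain segmentation and a pseudo-Spatiotemporal Map (pSM)
derived from them.

ST assays measure a gene-expression profile for every cell or spot *and* its
position in the tissue. Cells of the same type can sit in very different
tissue regions while being transcriptionally similar, so an embedding that
looks only at expression scrambles spatial organization. `spatialflow` trains
a graph neural encoder whose latent space respects both signals: nearby
embeddings mean similar expression **and** spatial proximity. It is aimed at
anyone analyzing Visium / Stereo-seq / Slide-seq-style matrices who wants
spatial domains and a spatiotemporal ordering of cells without histology
images or annotations.

## Method

1. **Preprocessing.** Genes detected in < 3 cells and cells expressing < 100
   genes are removed; counts are scaled to 10 000 per cell and
   log1p-transformed; the top 3 000 highly variable genes are kept
   (dispersion = variance/mean, normalized within 20 equal-frequency bins of
   mean expression as |dispersion − bin median| / bin MAD).

2. **Spatial expression graph (SEG).** Nodes carry the feature matrix
   `X`; edges come from the 1-skeleton of the alpha complex of the cell
   coordinates at radius δ (the mean k-nearest-neighbor distance, k = 15):
   cells i, j are adjacent iff their Voronoi cells, each intersected with a
   ball B(r, δ), touch. A plain union-symmetrized kNN graph is available as
   an alternative.

3. **Spatially regularized deep graph infomax.** A two-layer GCN
   (symmetric-normalized propagation, PReLU activations, 50-dimensional
   latent space) encodes the SEG into embeddings `H = {h_i}`. A bilinear
   discriminator `D(h, s) = σ(hᵀ Θ s)` — with summary vector
   `s = σ(mean_i h_i)` — is trained to tell true embeddings from those of an
   expression-permuted graph (same adjacency, shuffled features). The
   minimized objective is

   ```
   L = −(1/2N) [ Σ_i log D(h_i, s) + Σ_j log(1 − D(h̃_j, s)) ]
       + γ · mean_{(i,j)} d̂ˢ_ij · (1 − d̂ᶻ_ij)
   ```

   where `d̂ˢ` and `d̂ᶻ` are max-normalized spatial and embedding distances.
   The penalty (γ = 0.1 by default) pushes spatially distant cells apart in
   latent space. Above 10 000 cells the penalty is evaluated on a fixed-size
   random subset of cell pairs per step, making its cost constant in N.
   Training uses Adam (lr 0.001), at most 1 000 epochs, early stopping after
   100 epochs with patience 50; the model is pure NumPy/SciPy with
   analytically derived gradients (verified against finite differences in
   the test suite), fully reproducible from one seed.

4. **Downstream.** Domains: Leiden clustering of the 50-nearest-neighbor
   graph in embedding space (optionally bisection-searching the resolution to
   hit a target domain count). pSM: diffusion pseudotime from the cell with
   the largest summed embedding distance to all others, scaled to [0, 1].
   Markers: per-domain one-vs-rest Wilcoxon rank-sum tests with
   Benjamini–Hochberg correction (cutoff 0.01). Segmentations are scored
   against references with the adjusted Rand index.

Because no external download is assumed, the package ships synthetic-tissue
generators (negative-binomial counts on jittered spatial grids) with planted
layers, marker genes and expression gradients, used by the whole test suite.

## Worked example

```python
from spatialflow import simulate_layered_tissue, TrainConfig, train
from spatialflow.preprocess import preprocess
from spatialflow.spatial_graph import build_graph
from spatialflow.downstream import (adjusted_rand_index, compute_psm,
                                    segment_domains, select_root)

tissue = simulate_layered_tissue(seed=0)          # 3 layers x 200 cells, 300 genes
features, filtered = preprocess(tissue.dataset)   # filter -> log-normalize -> HVGs
seg = build_graph(features, filtered.coords)      # alpha-complex spatial graph
result = train(seg, TrainConfig(gamma=0.1, max_epochs=300, seed=0))
labels = segment_domains(result.embeddings.H, target_k=3, seed=0)
print(adjusted_rand_index(labels, tissue.layer_labels))
```

Output, with the intermediate quantities the run reports:

```
SEG: 600 cells, 1690 edges, delta=1.701
best epoch 294, final total loss 0.0340
ARI vs planted layers: 0.98
pSM vs layer order |rho|: 0.943
```

The graph has ~5.6 edges per cell (alpha radius 1.7 grid units); training
converges near the epoch cap; the Leiden segmentation recovers the three
planted layers almost perfectly (ARI 0.98, where 1 is a perfect match and 0
is chance), and the pSM orders cells along the planted layer sequence
(|Spearman ρ| 0.94).

The same pipeline is available from the shell:

```sh
spatialflow simulate layered --outdir data --seed 0
spatialflow run --counts data/matrix.mtx --genes data/genes.tsv \
    --barcodes data/barcodes.tsv --coords data/coordinates.csv --outdir out
spatialflow evaluate --domains out/domains.csv --annotation data/ground_truth.csv
```

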