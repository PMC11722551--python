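# mcist

Multiscale cell–cell interactive spatial transcriptomics analysis: spatial
domain detection that pairs an ensemble of **topological PCA** embeddings of
the gene-expression space with a spatial embedding, plus the downstream
differential-expression and co-expression-network analysis of the detected
domains.

## Who this is for

Spatial transcriptomics assigns each capture spot (or segmented cell) an
expression profile and a 2-D tissue coordinate. A central task is *spatial
domain detection*: partitioning spots into contiguous regions of coherent
expression, e.g. cortical layers or tumor compartments. Cell–cell
communication is multiscale — short-range contact as well as intermediate-
and long-range signaling — yet most domain-detection methods consider a
single neighborhood scale. `mcist` models multiscale cell–cell interactions
in gene-expression space explicitly and combines them with a spatial
representation.

## The method

For an expression matrix `X ∈ R^{M×N}` (M genes, N spots):

1. **Multiscale interaction graphs.** Build kNN graphs over spots in
   expression space at several neighbor counts `k = 15, 12, 9, 6`
   (OR-symmetrized, optionally Gaussian-kernel weighted,
   `W_ij = exp(−‖x_i − x_j‖² / η)`). Decreasing `k` induces a nested
   filtration; the unweighted graph Laplacian `L_k` of each scale is a
   persistent Laplacian, and the multiplicity of its zero eigenvalue is the
   number of connected components (β₀) at that scale.
2. **Accumulated spectral graph.** `L_P = Σ_k ζ_k L_k`, with binary weights
   ζ turning each scale on or off (the largest scale is always on; four
   scales give the 8 ensemble combinations).
3. **Topological PCA.** Solve

   `min_{U,Q} ‖X − UQᵀ‖₂,₁ + β‖Q‖₂,₁ + γ·Tr(Qᵀ L_P Q)  s.t. QᵀQ = I_m`

   by IRLS alternating minimization; the embedding `Q ∈ R^{N×m}` preserves
   multiscale co-connectivity while the L2,1 norms suppress noisy genes.
4. **Ensemble consensus.** Each of the 8 embeddings is concatenated with a
   spatial embedding (an external deep-learning latent space, or the
   built-in spatially-smoothed PCA baseline), clustered (full-covariance
   Gaussian mixture or count-tuned Leiden), and the labelings pooled into a
   co-association matrix `C`; average-linkage agglomerative clustering of
   `1 − C` at the annotation count gives the consensus domains.
5. **RSI selection.** When a single embedding is wanted (e.g. trajectory
   analysis), the Residue-Similarity Index — a label-aware, ground-truth-free
   quality score — picks the best of the 8 candidates.
6. **Downstream.** Welch's t-test (raw p ≤ 0.05) finds genes differentially
   expressed between two domains; the largest connected component of the
   thresholded Pearson co-expression network of those genes is reported as
   the coherent program for enrichment tools.

A negative-binomial layered-tissue simulator with known domains makes every
stage testable without downloads.

## Worked example

```python
import mcist

ds = mcist.simulate_layered_tissue(mcist.PRESETS["easy"], seed=0)
x = mcist.preprocess(ds.x)
cfg = mcist.RunConfig(n_clusters=4, seeds=(0, 1, 2))
results = mcist.run_mcist_multi(x, ds.coords, cfg)
report = mcist.evaluate(results, ds.truth)
print(f"spots: {x.n_spots}, genes: {x.n_genes}")
print(f"ARI {report['ari_mean']:.3f} +/- {report['ari_sd']:.3f}")
print(f"NMI {report['nmi_mean']:.3f} +/- {report['nmi_sd']:.3f}")
```

prints

```
spots: 400, genes: 200
ARI 0.993 +/- 0.000
NMI 0.990 +/- 0.000
```

i.e. on a simulated 20×20 tissue with four layers the consensus domains
agree almost perfectly with the generating labels, stably across clustering
seeds (adjusted Rand index and normalized mutual information of 1.0 would
be exact agreement).

The same pipeline is available from the shell:

```bash
mcist simulate --preset easy --seed 0 --out data/
mcist run --counts data/matrix.mtx --coords data/coords.tsv \
      --truth data/truth.csv --n-clusters 4 --seeds 0..2 --out out/
mcist deg --counts data/matrix.mtx --labels out/domains.csv \
      --group-a 0 --group-b 1 --out deg/
```

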