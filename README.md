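# spectrasvg

Frequency-domain detection of spatially variable genes in spatial
transcriptomics.

## The problem

Spatial transcriptomics assays measure gene expression counts at thousands of
spatial locations. A central analysis question is which genes are *spatially
variable* — whose expression depends on location rather than varying as
unstructured noise. Kernel-based tests answer this well but cost O(n²)–O(n³)
per gene in the number of locations; count data are also extremely sparse and
zero-inflated, which breaks Gaussian assumptions.

`spectrasvg` scores each gene by projecting its expression onto a multi-scale
**random Fourier feature** embedding of the coordinates. Because the features
approximate a Gaussian kernel at several bandwidths, the squared projection is
a spectral analogue of a kernel score statistic — but it is computed by sparse
linear algebra in O(nnz · D) per gene, where nnz is the number of nonzero
counts and D the (fixed) number of features.

## The model

- **Basis.** D random Fourier features `z_k(s) = sqrt(2/D) cos(ω_k·s + b_k)`
  with frequencies drawn from Gaussian spectral densities at L bandwidths,
  log-spaced between a local scale (median nearest-neighbour distance) and a
  global scale (reciprocal Fiedler value of a k-NN graph Laplacian).
- **Channels.** Each gene is tested through three transforms of its counts:
  presence/absence (binary), within-gene ranks of the nonzeros, and the raw
  counts. This keeps power under heavy zero-inflation.
- **Null.** Under exchangeability of expression across locations, each
  per-scale statistic `T_ℓ = Σ_k v_k²` has closed-form mean and variance
  (including an excess-kurtosis correction for counts); a Satterthwaite
  scaled-χ² approximation gives a per-scale p-value.
- **Combination.** Per-scale p-values from all channels, plus a parametric
  linear-trend score test, are combined with the Cauchy combination test,
  which is calibrated under arbitrary dependence.
- **Output.** Combined p-value, Benjamini–Hochberg q-value, per-channel
  p-values and a fold-enrichment effect size per gene.

## Worked example

```python
import numpy as np
from spectrasvg import SpatialVariabilityTest, simulate_dataset

# 5 hotspot-patterned genes + 5 unstructured genes on a 40x40 grid
ds = simulate_dataset(n_svg=5, n_null=5, family="hotspot", effect_size=2.0,
                      sparsity_mode="poisson_50", grid_side=40, seed=0)

est = SpatialVariabilityTest(random_state=0)        # D=500 features, L=7 scales
res = est.fit(ds.coords).transform(ds.counts, gene_ids=ds.gene_ids)
print(res[["gene_id", "n_expressed", "p_combined", "q_value", "effect_size"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))
```

Output:

```
gene_id  n_expressed  p_combined  q_value  effect_size
  svg_0          815    1.17e-16  3.9e-16         5.22
  svg_1          798    1.56e-16  3.9e-16         5.04
  svg_2          808    2.33e-16 4.67e-16         5.22
  svg_3          821    5.76e-17  3.9e-16         7.18
  svg_4          822    1.17e-16  3.9e-16         6.12
 null_0          839       0.546    0.682            1
 null_1          817       0.082    0.137         1.48
 null_2          814       0.914    0.993        0.853
 null_3          767       0.191    0.273         1.25
 null_4          835       0.993    0.993        0.742
```

All five patterned genes separate from the unstructured ones by ~15 orders of
magnitude. The fitted bandwidth ladder on this grid runs from the lattice
spacing to the graph-spectral scale:

```python
est.local_scale_, est.global_scale_   # (1.0, 13.117)
np.round(est.ladder_.sigma, 3)
# [ 1.     1.536  2.358  3.622  5.562  8.541 13.117]
```

## Command line

```bash
spectrasvg simulate --design power --family gradient --grid-side 50 \
    --genes 400 --replicates 1 --sparsity 0.5 --seed 0 --out-dir sim/
spectrasvg run --counts sim/rep0.mtx --coords sim/coords.tsv \
    --seed 1 --out results.tsv
spectrasvg evaluate --results results.tsv --labels sim/rep0.labels.tsv \
    --out summary.tsv
spectrasvg permute --counts sim/rep0.mtx --coords sim/coords.tsv \
    --scheme block --block-grid 6 --seed 2 --out-dir permuted/
```

Counts travel as Matrix Market `.mtx` files with a `.genes.txt` sidecar (or
dense TSV/CSV tables with a gene-ID index column); coordinates as two-column
delimited text; results as TSV.

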