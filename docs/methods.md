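# Methods

This note documents the statistical model, the numerical choices made in the
implementation, the synthetic-data generators used for validation, and known
limitations.

## 1. Spectral basis

### Coordinates and scales

Input coordinates are an `(n, 2)` array of spatial locations (any planar
coordinate system; the basis is translation-invariant by construction and the
simulated patterns are evaluated on unit-normalized coordinates).

Two characteristic length scales bracket the bandwidth ladder:

- **Local scale** `ℓ_local`: the median distance from each location to its
  nearest *other* location (k=1 neighbour, duplicates included). If the
  median is zero — possible only under duplicated coordinates — it is floored
  at `1e-6 ×` the bounding-box diagonal, with a warning.
- **Global scale** `ℓ_spectral = 1 / λ₂`, where λ₂ is the second-smallest
  eigenvalue (Fiedler value) of the unnormalized Laplacian of the symmetrized
  k-nearest-neighbour graph (k=15, unit edge weights). The option
  `spectral_formula="reciprocal_sqrt"` uses `1/√λ₂` instead. If the graph is
  disconnected, or λ₂ is numerically zero, the global scale falls back to
  half the bounding-box diagonal, with a warning.

For large datasets λ₂ is computed on a uniform subsample of up to `M`
locations (default 10,000). Because low eigenvalues of a fixed-k kNN-graph
Laplacian scale roughly like 1/n, the subsampled value is multiplied by
`m/n` to estimate the full-data quantity. The eigensolve uses dense
`eigvalsh` for n ≤ 200 and shift-inverted Lanczos otherwise, with a fixed
(constant) start vector so fitting is fully deterministic given
`random_state`.

The ladder holds L bandwidths (default 7), log-spaced from `ℓ_local` to
`ℓ_spectral` (endpoints swapped, with a warning, if inverted; geometric mean
if L = 1).

### Random Fourier features

D features (default 500) are split across the L scales as evenly as possible
(`divmod`; remainders go to the smallest scales). For scale σ, frequencies
are drawn `ω ~ N(0, σ⁻² I₂)` and phases `b ~ U[0, 2π)`; the feature map is

```
z_k(s) = sqrt(2/D) · cos(ω_k · s + b_k),
```

so that `E[z(s)·z(s')]` approximates a mixture of Gaussian kernels
`exp(−‖s−s'‖² / 2σ_ℓ²)` over the ladder. All randomness derives from three
independent streams spawned from `random_state` (subsampling for the global
scale, frequency/phase sampling, subsampling for the moment summaries).

### Precomputed moments

Fitting stores, once per dataset:

- exact column sums of Z (one blocked O(nD) pass; blocks of 8,192 rows keep
  the dense feature matrix out of memory),
- per-scale summaries of the *centered* features Z_c needed by the null
  moments: `Σ_k Var(z_k)`, `‖Σ_z‖_F²` of the per-scale empirical covariance,
  and the mean fourth power of per-scale row norms.

The covariance summaries are computed on a uniform subsample of up to M rows
(default 10,000), chosen by position in a canonical lexicographic ordering of
the coordinates so the result is invariant to input row order.

## 2. Per-gene test

### Channels

Each gene's counts y are tested through three transforms, all sharing the
sparsity pattern of y:

- **binary** — indicator of expression,
- **rank** — average ranks of the nonzero values (zeros remain 0),
- **direct** — the raw counts.

Channel moments (mean, standard deviation, excess kurtosis κ₄) are population
moments over all n entries, zeros included.

### Sparse sketch and per-scale statistic

The centered projection is computed without densifying:

```
v_k = Σ_{i: y_i ≠ 0} y_i z_k(s_i) − ȳ · colsum_k(Z),
```

exact (to float precision) and O(nnz · D) per gene. The per-scale statistic
is `T_ℓ = Σ_{k in scale ℓ} v_k²`.

### Null distribution

Under exchangeability of y across locations, with σ_y² the channel variance
and κ₄ its excess kurtosis,

```
E[T_ℓ]   = n σ_y² Σ_k Var(z_kℓ)
Var[T_ℓ] = 2 σ_y⁴ n² ‖Σ_{z,ℓ}‖_F²  +  κ₄ σ_y⁴ · n · mean_i ‖z_{c,ℓ,i}‖⁴
```

These match the exact first two permutation moments of the quadratic form
`y_cᵀ Z_c Z_cᵀ y_c` up to O(1/n) exchangeable-sampling corrections; the
kurtosis term is what keeps the test calibrated on zero-inflated counts
(κ₄ of a 95%-zeros gene is large and positive, inflating the null variance
and deflating otherwise-anticonservative p-values). A Satterthwaite
moment-matched scaled χ² gives the per-scale p-value:
`κ = V/(2E)`, `ν = 2E²/V`, `p = P(χ²_ν > T/κ)`, clipped to `[1e-300, 1]`.

### Linear trend and combination

A score test for a linear spatial trend complements the (trend-blind)
Fourier statistics: `T = y_cᵀ X (XᵀX)⁻¹ Xᵀ y_c / σ_y² ~ χ²_d`, with X the
column-centered coordinates and d their rank (pivoted-QR rank check; ginv for
the inverse).

All valid components — up to 3 channels × (L scales + 1 trend) = 3L+3
p-values — enter one flat **Cauchy combination**:
`T_CCT = mean_j tan((½ − p_j)π)`, `p = ½ − arctan(T_CCT)/π`, with the
asymptotic tail `1/(πT)` when T > 1e15 and component p-values clipped to
`[1e-300, 1 − 1e-16]`. Per-channel sub-combinations are reported as
diagnostics only. Genes with fewer than `min_expressed` nonzero entries
(default 5), or with no non-degenerate channel, are not tested.

The effect size is the maximum over channels of `Σ_ℓ T_ℓ / Σ_ℓ E[T_ℓ]`
(observed-to-expected spectral energy; ≈1 under the null). q-values are
Benjamini–Hochberg over the tested genes.

### Batch engine

`transform` runs all genes through a vectorized path: each channel of the
genes × locations CSR matrix is multiplied against blocked dense feature
evaluations; row-wise power sums use per-row `bincount` accumulation so
results are bitwise independent of which genes share a batch. `n_jobs`
splits genes across joblib workers with deterministic, order-preserving
concatenation; parallel output is bitwise identical to serial output.

## 3. Synthetic data generators

Null genes are i.i.d. across locations in three regimes chosen to span
realistic sparsity: Poisson(0.7) (~50% zeros), NB(size 1, p=0.9) (~90%
zeros), and the same NB with independent 50% dropout (~95% zeros); a numeric
target z in (0,1) draws NB(1, z). These match the empirical zero fractions
and overdispersion of spot-level and single-molecule spatial data far better
than a Gaussian would; dropout models technical zero-inflation beyond the NB.

Spatially variable genes modulate the count mean multiplicatively,
`mean_i = base · (1 + effect · f(s_i))`, with pattern fields f in [0,1] on
unit-normalized coordinates: linear gradient, Gaussian hotspot (radius 15% of
the grid side), sinusoid with three periods, half-plane domain boundary, and
a gradient+hotspot multiscale mixture. The base mean is calibrated by
deterministic root-finding so the *marginal* zero fraction of an SVG equals
the regime target — otherwise sparsity would leak label information. With
effect 0 every family reduces exactly to the null generator.

The calibration and power experiments re-fit the estimator per replicate
(fresh basis draw), as independent end-to-end runs of the tool would;
single-basis designs make power hostage to one frequency draw, which matters
most for the periodic family.

## 4. Robustness tools

Three structured permutations of the location axis (always bijections):
global row shuffle; within-group shuffle (preserves group structure);
spatial-block shuffle, which bins each group into an m×m grid, permutes the
block identities, and reassigns expression by within-block rank order
(wrapping positionally across block boundaries when occupancies differ).
Global shuffles should restore the nominal rejection rate on any dataset;
block shuffles preserve within-block autocorrelation and should leave strong
signals detectable.

`residualize_covariates` applies Frisch–Waugh–Lovell residualization:
categorical (e.g. section) means are removed from expression rows and from
each continuous covariate, then the demeaned expression is projected off the
demeaned covariates by least squares. Residuals are dense; downstream
testing should use `min_expressed=0`.

## 5. Validation experiments and observed behavior

Problem sizes below are this package's own validation choices.

- **Type-I error** (50×50 grid, 20 replicates × 1,000 genes × 3 regimes,
  defaults): with seed 1, overall FPR 5.50% at α=0.05, 4.63% in the
  ~95%-zeros regime, worst regime 6.60%, and 0.033% of null genes at
  q<0.05 (`scripts/acceptance.py`).
- **Power** (200 SVG + 200 null genes, 10 replicates, q<0.05): gradient at
  effect 1.0 reaches TPR 1.00 at 50% sparsity and ≈0.92 at 80% sparsity;
  periodic at effect 1.0 / 50% sparsity reaches ≈0.71, monotone in effect
  size. The 80%-sparsity gradient case falls short of the 0.95 bar asserted
  in `tests/test_acceptance.py`; that test is expected to fail and is left
  asserting the stated bound (see the repository test output).
- **Exactness**: sketched per-scale statistics equal the dense quadratic
  form to ≤1e-8 relative error; analytic E[T_ℓ]/Var[T_ℓ] match 10⁵
  permutations within 5%/15% at n=100, D=20.
- **Permutation contract**: on 1,000 strong multiscale genes, a global
  shuffle yields a rejection rate inside [0.03, 0.08] while a 6×6 block
  shuffle keeps it above 0.5.

## 6. Limitations

- The null moments assume exchangeability of a gene's values across
  locations; location-specific technical covariates should be removed with
  `residualize_covariates` first.
- The Satterthwaite χ² matches two moments only; extreme tail p-values
  (≲1e-12) are approximate, though the Cauchy combination is insensitive to
  component-level tail inaccuracy.
- Power depends on the random frequency draw; with the default D=500 this
  variance is small, but single-gene p-values are reproducible only for a
  fixed `random_state`.
- The bandwidth ladder is heuristic; patterns far outside
  [ℓ_local, ℓ_spectral] are covered only by the trend component.
- `residualize_covariates` returns dense residuals and is intended for
  moderate gene panels, not whole transcriptomes at once.
- Only 2-D coordinates are supported by the simulators and the spatial-block
  permutation; the test itself accepts any coordinate dimension.
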