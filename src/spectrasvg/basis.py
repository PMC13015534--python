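"""Multi-scale random Fourier feature basis for spatial coordinates.

Spatial locations are embedded with the random Fourier feature map of a
Gaussian kernel: z(s)_k = sqrt(2/D) * cos(w_k' s + b_k), where the
frequencies w_k are drawn from the kernel's spectral density N(0, sigma^-2 I)
(Bochner's theorem) and the phases b_k are uniform on [0, 2pi).  Inner
products of these features approximate exp(-||s - s'||^2 / (2 sigma^2))
without ever forming an n x n kernel matrix.

A ladder of L bandwidths, log-spaced between a local scale (median
nearest-neighbour distance) and a global scale (reciprocal of the graph
Laplacian's Fiedler value), makes the embedding sensitive to spatial
structure from cellular neighbourhoods up to tissue-wide gradients.  The
D features are split across the ladder by ``divmod(D, L)``.

The module also precomputes the centering and null-moment summaries that
every gene-level test reuses: exact feature column sums (one O(nD) pass)
and subsampled per-scale variance, Frobenius and fourth-moment terms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csgraph
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import NearestNeighbors, kneighbors_graph

logger = logging.getLogger(__name__)

__all__ = [
    "BandwidthLadder",
    "SpectralBasis",
    "BasisMoments",
    "validate_coordinates",
    "estimate_local_scale",
    "estimate_global_scale",
    "build_bandwidth_ladder",
    "allocate_features",
    "sample_basis",
    "evaluate_features",
    "iter_feature_blocks",
    "compute_basis_moments",
]

DEFAULT_BLOCK_SIZE = 8192


def validate_coordinates(coords, min_points: int = 2) -> np.ndarray:
    """Coerce to an (n, d) float array of finite spatial locations."""
    pts = np.asarray(coords, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError(
            f"coordinates must be an (n, d>=2) array, got shape {pts.shape}"
        )
    if pts.shape[0] < min_points:
        raise ValueError(f"need at least {min_points} locations, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates contain non-finite values")
    return pts


def _bbox_diagonal(coords: np.ndarray) -> float:
    span = coords.max(axis=0) - coords.min(axis=0)
    return float(np.sqrt(np.sum(span**2)))


@dataclass(frozen=True)
class BandwidthLadder:
    """Ascending, log-spaced Gaussian kernel bandwidths (length units)."""

    sigma: np.ndarray
    local_scale: float
    global_scale: float

    @property
    def n_scales(self) -> int:
        return len(self.sigma)


@dataclass(frozen=True)
class SpectralBasis:
    """Sampled frequencies and phases of the multi-scale feature map.

    Feature k belongs to bandwidth scale ``scale_of_feature[k]`` and its
    frequency row was drawn from N(0, sigma_l^-2 I).  Features are stored
    contiguously by scale.
    """

    frequencies: np.ndarray  # (D, d), units 1/length
    phases: np.ndarray  # (D,), radians in [0, 2pi)
    scale_of_feature: np.ndarray  # (D,) int
    ladder: BandwidthLadder
    seed: int

    @property
    def n_features(self) -> int:
        return self.frequencies.shape[0]

    @property
    def n_scales(self) -> int:
        return self.ladder.n_scales

    @property
    def scale_counts(self) -> np.ndarray:
        return np.bincount(self.scale_of_feature, minlength=self.n_scales)

    @property
    def scale_offsets(self) -> np.ndarray:
        """Start index of each scale's contiguous feature block."""
        return np.concatenate([[0], np.cumsum(self.scale_counts)[:-1]])


@dataclass(frozen=True)
class BasisMoments:
    """Centering and null-moment summaries of the feature matrix Z.

    ``column_sums`` (1'Z) is exact over all n rows; the per-scale variance,
    Frobenius and fourth-moment summaries are estimated on a uniform row
    subsample of size min(n, M) using column means derived from the exact
    sums.
    """

    column_sums: np.ndarray  # (D,)
    column_means: np.ndarray  # (D,)
    per_scale_sum_var: np.ndarray  # (L,)  sum_k Var(z_k) within scale
    per_scale_frob_sq: np.ndarray  # (L,)  ||Zc'Zc / n||_F^2 within scale
    per_scale_mean_row_fourth: np.ndarray  # (L,)  mean_i ||z_{c,l,i}||^4
    subsample_size: int
    n_locations: int = field(default=0)


def estimate_local_scale(coords) -> float:
    """Median distance from each location to its nearest other location.

    Captures the fine-grained spacing of the point cloud.  Floored at
    1e-6 x the bounding-box diagonal so duplicated coordinates cannot
    produce a zero bandwidth.
    """
    pts = validate_coordinates(coords, min_points=2)
    nn = NearestNeighbors(n_neighbors=2).fit(pts)
    dist, _ = nn.kneighbors(pts)
    med = float(np.median(dist[:, 1]))
    floor = 1e-6 * _bbox_diagonal(pts)
    if med <= floor:
        warnings.warn(
            "median nearest-neighbour distance is ~0 (duplicate coordinates?); "
            "flooring the local scale",
            stacklevel=2,
        )
        med = max(floor, np.finfo(float).tiny)
    return med


def estimate_global_scale(
    coords,
    knn_k: int = 15,
    subsample_size: int = 10_000,
    seed: int = 0,
    formula: str = "reciprocal",
) -> float:
    """Characteristic tissue-wide length scale from the Fiedler value.

    Builds a symmetric unweighted k-nearest-neighbour graph on (a uniform
    subsample of) the locations, forms the unnormalized Laplacian L = Deg - A
    and returns 1 / lambda_2 (or 1 / sqrt(lambda_2) with
    ``formula="reciprocal_sqrt"``), lambda_2 being the second-smallest
    eigenvalue.  A disconnected graph (lambda_2 ~ 0) falls back to half the
    coordinate bounding-box diagonal.
    """
    pts = validate_coordinates(coords, min_points=3)
    if formula not in ("reciprocal", "reciprocal_sqrt"):
        raise ValueError(f"unknown spectral formula {formula!r}")
    n_full = pts.shape[0]
    n = n_full
    if n > subsample_size:
        rng = np.random.default_rng(seed)
        pts = pts[np.sort(rng.choice(n, size=subsample_size, replace=False))]
        n = subsample_size
    k = min(knn_k, n - 1)
    adj = kneighbors_graph(pts, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T)  # symmetric, unit weights
    n_comp, _ = csgraph.connected_components(adj, directed=False)
    fallback = 0.5 * _bbox_diagonal(pts)
    if n_comp > 1:
        logger.warning(
            "k-NN graph disconnected (%d components); falling back to half "
            "the bounding-box diagonal (%.4g)",
            n_comp,
            fallback,
        )
        return fallback
    lap = csgraph.laplacian(adj, normed=False).tocsc().astype(np.float64)
    if n <= 200:
        eigvals = np.linalg.eigvalsh(lap.toarray())
        lam2 = float(eigvals[1])
    else:
        # shift-invert around 0 finds the smallest eigenvalues of the PSD Laplacian
        # fixed start vector keeps the Lanczos iteration deterministic
        v0 = np.full(lap.shape[0], 1.0 / np.sqrt(lap.shape[0]))
        vals = eigsh(
            lap, k=2, sigma=-1e-8, which="LM", v0=v0, return_eigenvectors=False
        )
        lam2 = float(np.sort(vals)[1])
    if lam2 <= 1e-12:
        logger.warning(
            "Fiedler value ~0; falling back to half the bounding-box diagonal"
        )
        return fallback
    # low eigenvalues of a fixed-k kNN Laplacian scale like 1/n (neighbourhood
    # radius^2 ~ k/n), so a subsampled lambda_2 is rescaled to target the
    # full-data value
    lam2 *= n / n_full
    return 1.0 / lam2 if formula == "reciprocal" else 1.0 / np.sqrt(lam2)


def build_bandwidth_ladder(local: float, global_: float, n_scales: int) -> BandwidthLadder:
    """L log-spaced bandwidths from the local to the global scale inclusive."""
    if not (np.isfinite(local) and np.isfinite(global_)) or local <= 0 or global_ <= 0:
        raise ValueError("bandwidth endpoints must be positive and finite")
    if n_scales < 1:
        raise ValueError("need at least one scale")
    if global_ < local:
        logger.warning(
            "global scale %.4g < local scale %.4g; swapping", global_, local
        )
        local, global_ = global_, local
    if n_scales == 1:
        sigma = np.array([np.sqrt(local * global_)])
    else:
        sigma = np.geomspace(local, global_, n_scales)
    return BandwidthLadder(sigma=sigma, local_scale=local, global_scale=global_)


def allocate_features(n_features: int, n_scales: int) -> np.ndarray:
    """Split D features across L scales: floor(D/L) each, remainder to the first."""
    if n_scales < 1 or n_features < n_scales:
        raise ValueError(
            f"need n_features >= n_scales >= 1, got D={n_features}, L={n_scales}"
        )
    q, r = divmod(n_features, n_scales)
    counts = np.full(n_scales, q, dtype=np.int64)
    counts[:r] += 1
    return counts


def sample_basis(
    ladder: BandwidthLadder, n_features: int, seed: int, n_dims: int = 2
) -> SpectralBasis:
    """Draw the random frequencies and phases of the multi-scale feature map.

    Deterministic given the seed.  Within scale l the frequency rows are
    N(0, sigma_l^-2 I); phases are uniform on [0, 2pi).
    """
    counts = allocate_features(n_features, ladder.n_scales)
    rng = np.random.default_rng(seed)
    freq_blocks = [
        rng.normal(0.0, 1.0 / sig, size=(c, n_dims))
        for sig, c in zip(ladder.sigma, counts)
    ]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_features)
    scale_of_feature = np.repeat(np.arange(ladder.n_scales), counts)
    return SpectralBasis(
        frequencies=np.vstack(freq_blocks),
        phases=phases,
        scale_of_feature=scale_of_feature,
        ladder=ladder,
        seed=seed,
    )


def evaluate_features(basis: SpectralBasis, coords, rows=None) -> np.ndarray:
    """Rows of the feature matrix: z_ik = sqrt(2/D) cos(w_k' s_i + b_k).

    Entries are bounded by sqrt(2/D) in absolute value.  Callers needing the
    whole matrix on large data should use :func:`iter_feature_blocks` so the
    full n x D array is never materialized.
    """
    pts = validate_coordinates(coords)
    if rows is not None:
        pts = pts[np.asarray(rows)]
    d = basis.frequencies.shape[1]
    proj = pts[:, :d] @ basis.frequencies.T + basis.phases
    np.cos(proj, out=proj)
    proj *= np.sqrt(2.0 / basis.n_features)
    return proj


def iter_feature_blocks(basis: SpectralBasis, coords, block_size: int = DEFAULT_BLOCK_SIZE):
    """Yield (row_slice, Z_block) with peak memory O(block_size x D)."""
    pts = validate_coordinates(coords)
    n = pts.shape[0]
    for start in range(0, n, block_size):
        sl = slice(start, min(start + block_size, n))
        yield sl, evaluate_features(basis, pts[sl])


def _canonical_order(coords: np.ndarray) -> np.ndarray:
    """Row order invariant to input permutation (lexicographic on coordinates)."""
    return np.lexsort(coords.T[::-1])


def compute_basis_moments(
    basis: SpectralBasis,
    coords,
    subsample_size: int = 10_000,
    seed: int = 0,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> BasisMoments:
    """Exact column sums plus subsampled per-scale null-moment summaries.

    The column sums 1'Z are accumulated over all n rows in blocks (exact
    centering is required for calibration: subsampled centering error enters
    the quadratic statistic at scale (ybar * n * delta)^2).  The per-scale
    variance sum, covariance Frobenius norm and mean fourth moment are
    estimated on min(n, M) rows drawn uniformly without replacement — by
    position in a canonical (lexicographic) row order so the estimates are
    invariant to row permutation of the input.
    """
    if subsample_size < 2:
        raise ValueError("subsample_size must be >= 2")
    pts = validate_coordinates(coords)
    n, D = pts.shape[0], basis.n_features
    L = basis.n_scales

    column_sums = np.zeros(D)
    for _, zb in iter_feature_blocks(basis, pts, block_size):
        column_sums += zb.sum(axis=0)
    column_means = column_sums / n

    m = min(n, subsample_size)
    if m == n:
        sub_idx = np.arange(n)
    else:
        order = _canonical_order(pts)
        rng = np.random.default_rng(seed)
        sub_idx = order[np.sort(rng.choice(n, size=m, replace=False))]

    sum_var = np.zeros(L)
    frob_sq = np.zeros(L)
    mean_row_fourth = np.zeros(L)
    offsets = basis.scale_offsets
    counts = basis.scale_counts
    zc = evaluate_features(basis, pts, rows=sub_idx) - column_means
    for ell in range(L):
        blk = zc[:, offsets[ell] : offsets[ell] + counts[ell]]
        sum_var[ell] = np.mean(blk**2, axis=0).sum()
        cov = blk.T @ blk / m
        frob_sq[ell] = np.sum(cov**2)
        mean_row_fourth[ell] = np.mean(np.sum(blk**2, axis=1) ** 2)

    return BasisMoments(
        column_sums=column_sums,
        column_means=column_means,
        per_scale_sum_var=sum_var,
        per_scale_frob_sq=frob_sq,
        per_scale_mean_row_fourth=mean_row_fourth,
        subsample_size=m,
        n_locations=n,
    )
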