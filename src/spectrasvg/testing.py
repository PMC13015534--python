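"""Per-gene three-part spatial variability test.

For one gene with expression vector y over n locations, three channels are
tested — binary presence/absence, within-gene ranks of the nonzero values,
and the raw counts — against the multi-scale random Fourier features of the
coordinates.  Each channel yields a quadratic statistic per bandwidth scale,

    T_l = || (y - ybar 1)' Z_l ||^2 ,

computed by sparse sketching (touching only the nonzero entries of y, with
centering handled through the precomputed column sums of Z), plus a linear
spatial trend score test against the centered coordinates.  Null moments of
T_l use a kurtosis-corrected Satterthwaite approximation,

    E[T_l]   = n sigma_y^2 sum_k Var(z_kl)
    Var[T_l] = 2 sigma_y^4 n^2 ||Sigma_{z,l}||_F^2
               + kappa4 sigma_y^4 sum_i ||z_{c,l,i}||^4 ,

where kappa4 is the gene's excess kurtosis; the correction is what keeps
p-values calibrated for heavily zero-inflated counts.  T_l is referred to a
scaled chi-square with kappa = Var/(2E), nu = 2E^2/Var.  The 3L + 3
component p-values are merged with the Cauchy combination test and adjusted
genome-wide by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from joblib import Parallel, delayed
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .basis import (
    BasisMoments,
    SpectralBasis,
    build_bandwidth_ladder,
    compute_basis_moments,
    estimate_global_scale,
    estimate_local_scale,
    evaluate_features,
    sample_basis,
    validate_coordinates,
)

logger = logging.getLogger(__name__)

CHANNELS = ("binary", "rank", "direct")

# clipping bounds for the Cauchy combination (tan singularities at 0 and 1)
_P_LO = 1e-300
_P_HI = 1.0 - 1e-16

__all__ = [
    "ChannelVector",
    "GeneTestResult",
    "SpatialVariabilityTest",
    "channel_transform",
    "sparse_sketch",
    "per_scale_statistic",
    "null_moments",
    "satterthwaite_pvalue",
    "linear_trend_test",
    "cauchy_combine",
    "spatial_effect_size",
    "test_gene",
    "benjamini_hochberg",
    "run_dataset",
]


# ---------------------------------------------------------------------------
# channel transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelVector:
    """One gene's expression under one channel transform, in sparse form.

    Mean, standard deviation and excess kurtosis are taken over all n
    entries including the implicit zeros (population moments, ddof=0).
    """

    indices: np.ndarray
    values: np.ndarray
    n: int
    mean: float
    sd: float
    excess_kurtosis: float
    channel: str

    @property
    def nnz(self) -> int:
        return len(self.indices)


def _sparse_moments(values: np.ndarray, n: int):
    """(mean, sd, excess kurtosis) of a length-n vector given its nonzeros."""
    s1 = float(values.sum())
    s2 = float((values**2).sum())
    s3 = float((values**3).sum())
    s4 = float((values**4).sum())
    mean = s1 / n
    var = max(s2 / n - mean**2, 0.0)
    # sum over ALL entries of (y - mean)^4; zeros contribute (n - nnz) mean^4
    mu4 = (s4 - 4 * mean * s3 + 6 * mean**2 * s2 - 4 * mean**3 * s1 + n * mean**4) / n
    if var > 0:
        kurt = mu4 / var**2 - 3.0
    else:
        kurt = 0.0
    return mean, float(np.sqrt(var)), kurt


def channel_transform(gene_counts, channel: str, n: int | None = None) -> ChannelVector:
    """Transform a nonnegative count vector into one of the three channels.

    binary: 1 at expressed positions; rank: nonzero entries replaced by their
    average ranks among the nonzeros (zeros untouched); direct: the raw
    counts.  An all-zero or constant vector comes back with sd = 0 and must
    be skipped by the caller.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    if sp.issparse(gene_counts):
        row = sp.csr_matrix(gene_counts)
        if row.shape[0] != 1:
            raise ValueError("expected a single gene vector")
        n = row.shape[1]
        idx, vals = row.indices.copy(), row.data.astype(np.float64)
    else:
        arr = np.asarray(gene_counts, dtype=np.float64).ravel()
        n = len(arr) if n is None else n
        idx = np.flatnonzero(arr)
        vals = arr[idx]
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise ValueError("counts must be nonnegative and finite")
    # drop explicit zeros so nnz means "expressed"
    keep = vals != 0
    idx, vals = idx[keep], vals[keep]
    if channel == "binary":
        vals = np.ones_like(vals)
    elif channel == "rank":
        vals = stats.rankdata(vals, method="average")
    mean, sd, kurt = _sparse_moments(vals, n)
    return ChannelVector(
        indices=idx, values=vals, n=n, mean=mean, sd=sd,
        excess_kurtosis=kurt, channel=channel,
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def sparse_sketch(
    cv: ChannelVector,
    basis: SpectralBasis,
    coords,
    moments: BasisMoments,
) -> np.ndarray:
    """Centered projection v = (y - ybar 1)' Z touching only nonzeros of y.

    v_k = sum_{i: y_i != 0} y_i z_ik  -  ybar * (1'Z)_k, which equals the
    dense doubly-centered product exactly; cost O(nnz * D).
    """
    pts = validate_coordinates(coords)
    if cv.n != pts.shape[0]:
        raise ValueError(
            f"channel vector has n={cv.n} but coordinates have {pts.shape[0]} rows"
        )
    if len(moments.column_sums) != basis.n_features:
        raise ValueError("moments were computed for a different basis")
    if cv.nnz == 0:
        return np.zeros(basis.n_features)
    z_nz = evaluate_features(basis, pts, rows=cv.indices)
    return cv.values @ z_nz - cv.mean * moments.column_sums


def per_scale_statistic(v: np.ndarray, scale_of_feature: np.ndarray) -> np.ndarray:
    """T_l = sum of v_k^2 over the features of scale l; sums to ||v||^2."""
    v = np.asarray(v, dtype=np.float64)
    return np.bincount(scale_of_feature, weights=v**2)


def null_moments(cv: ChannelVector, moments: BasisMoments, n: int):
    """Kurtosis-corrected (E[T_l], Var[T_l]) per scale for one channel."""
    if cv.sd <= 0:
        raise ValueError("degenerate channel (sd = 0); skip it")
    var_y = cv.sd**2
    e = n * var_y * moments.per_scale_sum_var
    v = (
        2.0 * var_y**2 * n**2 * moments.per_scale_frob_sq
        + cv.excess_kurtosis * var_y**2 * n * moments.per_scale_mean_row_fourth
    )
    return e, np.maximum(v, 1e-300)


def satterthwaite_pvalue(T, E, V):
    """Upper-tail p from moment matching T ~ kappa * chisq_nu.

    kappa = V / (2E), nu = 2 E^2 / V.  Works elementwise on arrays.
    """
    T = np.asarray(T, dtype=np.float64)
    E = np.asarray(E, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if np.any(E <= 0) or np.any(V <= 0):
        raise ValueError("moment matching needs E > 0 and V > 0")
    kappa = V / (2.0 * E)
    nu = 2.0 * E**2 / V
    p = stats.chi2.sf(T / kappa, nu)
    return np.clip(p, _P_LO, 1.0)


def _linear_design(coords):
    """Centered coordinate design, its quadratic-form inverse and rank."""
    pts = validate_coordinates(coords)
    xc = pts - pts.mean(axis=0)
    # drop dependent columns via a pivoted QR rank check
    from scipy.linalg import qr as _qr

    _, r, piv = _qr(xc, mode="economic", pivoting=True)
    rdiag = np.abs(np.diag(r))
    tol = max(xc.shape) * np.finfo(float).eps * (rdiag.max() if rdiag.size else 0.0)
    rank = int(np.sum(rdiag > tol))
    keep = np.sort(piv[:rank])
    if len(keep) < xc.shape[1]:
        logger.warning(
            "coordinate design rank-deficient; testing %d of %d columns",
            len(keep), xc.shape[1],
        )
    xc = xc[:, keep]
    if xc.shape[1] == 0:
        raise ValueError("coordinate design has rank 0 (all points identical)")
    ginv = np.linalg.inv(xc.T @ xc)
    return xc, ginv


def linear_trend_test(cv: ChannelVector, coords) -> float:
    """Score test of a linear spatial trend in one channel.

    T = y_c' X (X'X)^-1 X' y_c / sigma_y^2 with X the column-centered
    coordinates, referred to chi-square with d = rank(X) degrees of freedom.
    """
    if cv.sd <= 0:
        raise ValueError("degenerate channel (sd = 0); skip it")
    xc, ginv = _linear_design(coords)
    # y_c'X = y'X since X is column-centered; touch only the nonzeros
    b = cv.values @ xc[cv.indices] if cv.nnz else np.zeros(xc.shape[1])
    t = float(b @ ginv @ b) / cv.sd**2
    return float(np.clip(stats.chi2.sf(t, xc.shape[1]), _P_LO, 1.0))


def cauchy_combine(p) -> float:
    """Cauchy combination of K dependent p-values.

    T = mean tan((1/2 - p_j) pi); under the null T is standard Cauchy for
    any dependence, so the combined p is 1/2 - arctan(T)/pi (asymptotically
    1/(pi T) for very large T).
    """
    p = np.asarray(p, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("need at least one p-value to combine")
    p = np.clip(p, _P_LO, _P_HI)
    t = float(np.mean(np.tan((0.5 - p) * np.pi)))
    if t > 1e15:
        out = 1.0 / (np.pi * t)
    else:
        out = 0.5 - np.arctan(t) / np.pi
    return float(np.clip(out, _P_LO, 1.0))


def spatial_effect_size(observed, expected) -> float:
    """Max over channels of (sum_l T_l) / (sum_l E[T_l]).

    A continuous, non-saturating ranking score: 1 under the null, larger for
    genes whose spatial projections exceed their null expectation.
    """
    obs = np.asarray(observed, dtype=np.float64).ravel()
    exp = np.asarray(expected, dtype=np.float64).ravel()
    ok = exp > 0
    if not np.any(ok):
        return 0.0
    return float(np.max(obs[ok] / exp[ok]))


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up BH q-values (monotone, order-preserving with p)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# batch engine
# ---------------------------------------------------------------------------


def _row_power_sums(data: np.ndarray, indptr: np.ndarray, power: int) -> np.ndarray:
    # per-row accumulation (no cross-row carry) so results are independent of
    # which other genes share the batch
    n_rows = len(indptr) - 1
    row_ids = np.repeat(np.arange(n_rows), np.diff(indptr))
    return np.bincount(row_ids, weights=data**power, minlength=n_rows)


def _csr_channel(Y: sp.csr_matrix, channel: str) -> sp.csr_matrix:
    """Channel transform applied row-wise to a genes x locations CSR matrix."""
    if channel == "direct":
        data = Y.data.astype(np.float64)
    elif channel == "binary":
        data = np.ones_like(Y.data, dtype=np.float64)
    else:  # rank
        data = np.empty_like(Y.data, dtype=np.float64)
        for g in range(Y.shape[0]):
            lo, hi = Y.indptr[g], Y.indptr[g + 1]
            if hi > lo:
                data[lo:hi] = stats.rankdata(Y.data[lo:hi], method="average")
    return sp.csr_matrix((data, Y.indices, Y.indptr), shape=Y.shape)


def _batch_channel_stats(C: sp.csr_matrix):
    """Vectorized (mean, var, kappa4) over all n entries for every gene row."""
    n = C.shape[1]
    s1 = _row_power_sums(C.data, C.indptr, 1)
    s2 = _row_power_sums(C.data, C.indptr, 2)
    s3 = _row_power_sums(C.data, C.indptr, 3)
    s4 = _row_power_sums(C.data, C.indptr, 4)
    mean = s1 / n
    var = np.maximum(s2 / n - mean**2, 0.0)
    mu4 = (s4 - 4 * mean * s3 + 6 * mean**2 * s2 - 4 * mean**3 * s1 + n * mean**4) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        kurt = np.where(var > 0, mu4 / np.maximum(var, 1e-300) ** 2 - 3.0, 0.0)
    return mean, var, kurt


def _cauchy_combine_rows(p: np.ndarray) -> np.ndarray:
    """Rowwise Cauchy combination ignoring NaN components."""
    pc = np.clip(p, _P_LO, _P_HI)
    terms = np.tan((0.5 - pc) * np.pi)
    terms[np.isnan(p)] = np.nan
    valid = np.sum(~np.isnan(p), axis=1)
    with np.errstate(invalid="ignore"):
        t = np.nansum(terms, axis=1) / np.maximum(valid, 1)
    t[valid == 0] = np.nan  # all components filtered: no combined p-value
    out = 0.5 - np.arctan(t) / np.pi
    big = t > 1e15
    out[big] = 1.0 / (np.pi * t[big])
    out[np.isnan(t)] = np.nan
    return np.clip(out, _P_LO, 1.0)


def _project_batch(C: sp.csr_matrix, mean: np.ndarray, ctx) -> np.ndarray:
    """Centered projections (Y - mean 1')Z for a batch, blocked over rows of Z."""
    G = C.shape[0]
    V = np.zeros((G, ctx.basis.n_features))
    n = ctx.coords.shape[0]
    csc = None
    if n > ctx.block_size:
        csc = C.tocsc()
    for start in range(0, n, ctx.block_size):
        sl = slice(start, min(start + ctx.block_size, n))
        zb = evaluate_features(ctx.basis, ctx.coords[sl])
        if csc is not None:
            V += csc[:, sl] @ zb
        else:
            V += C @ zb
    V -= mean[:, None] * ctx.moments.column_sums[None, :]
    return V


class _TestContext:
    """Fitted state shared by every gene test (read-only)."""

    def __init__(self, basis, moments, coords, xc, ginv, min_expressed, block_size):
        self.basis = basis
        self.moments = moments
        self.coords = coords
        self.xc = xc
        self.ginv = ginv
        self.min_expressed = min_expressed
        self.block_size = block_size
        self.scale_starts = basis.scale_offsets


def _test_batch(Y: sp.csr_matrix, ctx: _TestContext) -> dict:
    """Run the full three-part test on a genes x locations count batch."""
    G, n = Y.shape
    L = ctx.basis.n_scales
    nnz = np.diff(Y.indptr)

    p_comp = np.full((G, 3, L + 1), np.nan)  # per channel: L scales + trend
    t_sum = np.zeros((G, 3))
    e_sum = np.zeros((G, 3))
    channel_ok = np.zeros((G, 3), dtype=bool)

    for c, channel in enumerate(CHANNELS):
        C = _csr_channel(Y, channel)
        mean, var, kurt = _batch_channel_stats(C)
        ok = var > 0
        channel_ok[:, c] = ok
        if not np.any(ok):
            continue
        V = _project_batch(C, mean, ctx)
        T = np.add.reduceat(V**2, ctx.scale_starts, axis=1)  # (G, L)
        E = n * var[:, None] * ctx.moments.per_scale_sum_var[None, :]
        W = (
            2.0 * (var**2)[:, None] * n**2 * ctx.moments.per_scale_frob_sq[None, :]
            + kurt[:, None]
            * (var**2)[:, None]
            * n
            * ctx.moments.per_scale_mean_row_fourth[None, :]
        )
        W = np.maximum(W, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            kap = W / (2.0 * np.maximum(E, 1e-300))
            nu = 2.0 * E**2 / W
            p_scale = stats.chi2.sf(T / kap, nu)
        p_comp[ok, c, :L] = np.clip(p_scale[ok], _P_LO, 1.0)
        # linear trend score test
        B = C @ ctx.xc  # = y_c'X since X is column-centered
        t_lin = np.einsum("gi,ij,gj->g", B, ctx.ginv, B) / np.maximum(var, 1e-300)
        p_lin = np.clip(stats.chi2.sf(t_lin, ctx.xc.shape[1]), _P_LO, 1.0)
        p_comp[ok, c, L] = p_lin[ok]
        t_sum[:, c] = T.sum(axis=1)
        e_sum[:, c] = np.where(ok, E.sum(axis=1), 0.0)

    tested = (nnz >= ctx.min_expressed) & channel_ok.any(axis=1)
    p_combined = _cauchy_combine_rows(p_comp.reshape(G, -1))
    p_combined[~tested] = np.nan

    per_channel_p = np.column_stack(
        [_cauchy_combine_rows(p_comp[:, c, :]) for c in range(3)]
    )
    per_channel_p[~tested] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(e_sum > 0, t_sum / np.maximum(e_sum, 1e-300), np.nan)
    effect = np.where(tested, np.nanmax(np.where(e_sum > 0, ratios, -np.inf), axis=1), 0.0)
    effect = np.where(np.isfinite(effect), effect, 0.0)

    return {
        "n_expressed": nnz.astype(np.int64),
        "tested": tested,
        "p_combined": p_combined,
        "p_channel": per_channel_p,
        "effect_size": effect,
        "p_components": p_comp,
        "t_sum": t_sum,
        "e_sum": e_sum,
    }


# ---------------------------------------------------------------------------
# per-gene result and wrapper
# ---------------------------------------------------------------------------


@dataclass
class GeneTestResult:
    """All statistics the test produces for one gene."""

    tested: bool
    n_expressed: int
    combined_p: float
    effect_size: float
    per_channel_p: dict
    component_p: np.ndarray  # (3, L+1): scales then linear trend, NaN = skipped
    q_value: float = np.nan


def test_gene(gene_counts, basis, coords, moments, min_expressed: int = 5) -> GeneTestResult:
    """Run the full three-part multi-scale test on a single gene."""
    pts = validate_coordinates(coords)
    if sp.issparse(gene_counts):
        row = sp.csr_matrix(gene_counts)
    else:
        row = sp.csr_matrix(np.asarray(gene_counts, dtype=np.float64).reshape(1, -1))
    if row.shape[1] != pts.shape[0]:
        raise ValueError("gene vector length does not match coordinate count")
    xc, ginv = _linear_design(pts)
    ctx = _TestContext(basis, moments, pts, xc, ginv, min_expressed, 8192)
    out = _test_batch(row, ctx)
    return GeneTestResult(
        tested=bool(out["tested"][0]),
        n_expressed=int(out["n_expressed"][0]),
        combined_p=float(out["p_combined"][0]),
        effect_size=float(out["effect_size"][0]),
        per_channel_p=dict(zip(CHANNELS, out["p_channel"][0])),
        component_p=out["p_components"][0],
    )


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class SpatialVariabilityTest(BaseEstimator):
    """Frequency-domain test for spatially variable genes.

    ``fit`` consumes the n x 2 spatial coordinates: it picks the bandwidth
    ladder adaptively (median nearest-neighbour distance up to the Fiedler
    length scale), samples the multi-scale random Fourier basis and
    precomputes the exact centering sums and subsampled null-moment
    summaries.  ``transform`` then scores a genes x locations count matrix
    and returns a tidy results table.

    Parameters
    ----------
    n_features : int, default 500
        Number of random Fourier features D.
    n_scales : int, default 7
        Number of log-spaced kernel bandwidths L.
    subsample : int, default 10_000
        Rows used for the null-moment summaries (column sums stay exact).
    knn_k : int, default 15
        Neighbours of the graph used for the Fiedler length scale.
    min_expressed : int, default 5
        Genes with fewer expressing locations are reported untested.
    spectral_formula : {"reciprocal", "reciprocal_sqrt"}
        Map from the Fiedler value lambda_2 to the global length scale.
    block_size : int, default 8192
        Rows of Z evaluated at a time; peak memory is O(block_size * D).
    n_jobs : int, default 1
        Gene-level parallelism (results identical for any worker count).
    random_state : int, default 0
        Seeds the basis draw and the moment subsample.

    Attributes
    ----------
    local_scale_, global_scale_ : float
    ladder_ : BandwidthLadder
    basis_ : SpectralBasis
    moments_ : BasisMoments
    n_locations_ : int
    """

    def __init__(
        self,
        n_features: int = 500,
        n_scales: int = 7,
        subsample: int = 10_000,
        knn_k: int = 15,
        min_expressed: int = 5,
        spectral_formula: str = "reciprocal",
        block_size: int = 8192,
        n_jobs: int = 1,
        random_state: int = 0,
    ):
        self.n_features = n_features
        self.n_scales = n_scales
        self.subsample = subsample
        self.knn_k = knn_k
        self.min_expressed = min_expressed
        self.spectral_formula = spectral_formula
        self.block_size = block_size
        self.n_jobs = n_jobs
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None):
        """Build the spatial basis and null-moment summaries from coordinates."""
        pts = validate_coordinates(X, min_points=3)
        ss = np.random.SeedSequence(self.random_state)
        seeds = [int(s) for s in ss.generate_state(3, dtype=np.uint32) >> np.uint32(1)]
        self.local_scale_ = estimate_local_scale(pts)
        self.global_scale_ = estimate_global_scale(
            pts,
            knn_k=self.knn_k,
            subsample_size=self.subsample,
            seed=seeds[0],
            formula=self.spectral_formula,
        )
        self.ladder_ = build_bandwidth_ladder(
            self.local_scale_, self.global_scale_, self.n_scales
        )
        self.basis_ = sample_basis(
            self.ladder_, self.n_features, seed=seeds[1], n_dims=pts.shape[1]
        )
        self.moments_ = compute_basis_moments(
            self.basis_, pts, subsample_size=self.subsample,
            seed=seeds[2], block_size=self.block_size,
        )
        self._coords = pts
        self._xc, self._ginv = _linear_design(pts)
        self.n_locations_ = pts.shape[0]
        logger.info(
            "fitted basis: n=%d, D=%d, ladder=%s, allocation=%s",
            pts.shape[0], self.n_features,
            np.array2string(self.ladder_.sigma, precision=3),
            self.basis_.scale_counts.tolist(),
        )
        return self

    def _context(self) -> _TestContext:
        return _TestContext(
            self.basis_, self.moments_, self._coords, self._xc, self._ginv,
            self.min_expressed, self.block_size,
        )

    # -- testing ------------------------------------------------------------

    def transform(self, Y, gene_ids=None) -> pd.DataFrame:
        """Test every row of a genes x locations count matrix.

        Returns a DataFrame with combined and per-channel p-values, BH
        q-values (over tested genes) and the spatial effect size.
        """
        if not hasattr(self, "basis_"):
            raise RuntimeError("fit the estimator on coordinates first")
        Y = sp.csr_matrix(Y) if not sp.issparse(Y) else Y.tocsr()
        if Y.shape[1] != self.n_locations_:
            raise ValueError(
                f"count matrix has {Y.shape[1]} locations but the fitted "
                f"coordinates have {self.n_locations_}"
            )
        if Y.nnz and (Y.data.min() < 0 or not np.all(np.isfinite(Y.data))):
            raise ValueError("counts must be nonnegative and finite")
        ctx = self._context()
        G = Y.shape[0]
        if self.n_jobs != 1 and G > 1:
            splits = np.array_split(np.arange(G), min(abs(self.n_jobs) * 4, G))
            parts = Parallel(n_jobs=self.n_jobs)(
                delayed(_test_batch)(Y[idx], ctx) for idx in splits if len(idx)
            )
            out = {
                k: np.concatenate([p[k] for p in parts])
                for k in parts[0]
            }
        else:
            out = _test_batch(Y, ctx)

        if gene_ids is None:
            gene_ids = [f"gene_{i}" for i in range(G)]
        df = pd.DataFrame(
            {
                "gene_id": list(gene_ids),
                "n_expressed": out["n_expressed"],
                "p_combined": out["p_combined"],
                "q_value": np.nan,
                "effect_size": out["effect_size"],
                "p_binary": out["p_channel"][:, 0],
                "p_rank": out["p_channel"][:, 1],
                "p_direct": out["p_channel"][:, 2],
                "tested": out["tested"],
            }
        )
        mask = df["tested"].to_numpy()
        if mask.any():
            df.loc[mask, "q_value"] = benjamini_hochberg(
                df.loc[mask, "p_combined"].to_numpy()
            )
        n_skipped = int((~mask).sum())
        if n_skipped:
            logger.info("skipped %d/%d genes below min_expressed=%d or degenerate",
                        n_skipped, G, self.min_expressed)
        return df

    def fit_transform(self, X, Y, gene_ids=None) -> pd.DataFrame:
        return self.fit(X).transform(Y, gene_ids=gene_ids)


def run_dataset(counts, coords, gene_ids=None, **params) -> pd.DataFrame:
    """Fit the basis on ``coords`` and test every gene row of ``counts``."""
    est = SpatialVariabilityTest(**params)
    return est.fit(coords).transform(counts, gene_ids=gene_ids)
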