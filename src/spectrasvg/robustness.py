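"""Structured permutation nulls and covariate residualization.

Three permutation schemes probe how detections track preserved spatial
organization: a global row permutation destroys all spatial structure (the
classic empirical null); within-group permutation shuffles locations only
inside each group (e.g. tissue section), preserving between-group structure;
spatial block permutation bins each group into an m x m grid and permutes
expression between blocks, preserving within-block autocorrelation.

Residualization removes confounders before testing: Frisch-Waugh-Lovell
demeaning for a categorical fixed effect, followed by ordinary least-squares
projection onto the demeaned continuous covariates.  Residuals are dense, so
downstream testing should use ``min_expressed=0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

PERMUTATION_KINDS = ("global_row", "within_group", "spatial_block")

__all__ = [
    "PermutationScheme",
    "permute_assignment",
    "permutation_fpr",
    "residualize_covariates",
]


@dataclass(frozen=True)
class PermutationScheme:
    """Specification of one structured shuffle of the location axis."""

    kind: str
    block_grid: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.kind not in PERMUTATION_KINDS:
            raise ValueError(f"unknown permutation kind {self.kind!r}")
        if self.kind == "spatial_block" and self.block_grid < 2:
            raise ValueError("spatial_block needs block_grid >= 2")


def _block_ids(pts: np.ndarray, m: int) -> np.ndarray:
    """Equal-width m x m binning of 2-D points within their bounding box."""
    lo = pts.min(axis=0)
    span = np.maximum(pts.max(axis=0) - lo, 1e-12)
    bins = np.minimum((m * (pts - lo) / span).astype(int), m - 1)
    return bins[:, 0] * m + bins[:, 1]


def permute_assignment(
    scheme: PermutationScheme,
    coords=None,
    group_labels=None,
    n: int | None = None,
) -> np.ndarray:
    """A bijection pi on location indices; apply as ``counts[:, pi]``.

    global_row: uniform over all n! permutations.  within_group: uniform
    within each label class, identity across classes.  spatial_block: within
    each group, locations are binned into an m x m grid (empty blocks
    dropped), the block identities are permuted, and expression is reassigned
    by within-block rank order — concatenating blocks in permuted order onto
    the original concatenation, wrapping positionally across block boundaries
    when occupancies differ, so the result is always a bijection.
    """
    rng = np.random.default_rng(scheme.seed)
    if scheme.kind == "global_row":
        if n is None:
            if coords is None:
                raise ValueError("need n or coords for global_row")
            n = np.asarray(coords).shape[0]
        return rng.permutation(n)

    if scheme.kind == "within_group":
        if group_labels is None:
            raise ValueError("within_group permutation requires group labels")
        labels = np.asarray(group_labels)
        perm = np.arange(len(labels))
        for g in np.unique(labels):
            idx = np.flatnonzero(labels == g)
            perm[idx] = idx[rng.permutation(len(idx))]
        return perm

    # spatial_block
    if coords is None:
        raise ValueError("spatial_block permutation requires coordinates")
    pts = np.asarray(coords, dtype=np.float64)
    n = pts.shape[0]
    labels = (
        np.zeros(n, dtype=int) if group_labels is None else np.asarray(group_labels)
    )
    perm = np.arange(n)
    for g in np.unique(labels):
        gidx = np.flatnonzero(labels == g)
        blocks = _block_ids(pts[gidx], scheme.block_grid)
        uniq = np.unique(blocks)  # empty blocks never appear
        members = [gidx[blocks == b] for b in uniq]  # canonical (index) order
        occupancies = np.array([len(m_) for m_ in members])
        if occupancies.min() != occupancies.max():
            logger.info(
                "group %r: unequal block occupancies (%d..%d); positional wrap",
                g, occupancies.min(), occupancies.max(),
            )
        order = rng.permutation(len(uniq))
        dest = np.concatenate(members)
        src = np.concatenate([members[b] for b in order])
        perm[dest] = src
    return perm


def permutation_fpr(counts, coords, scheme: PermutationScheme, tester,
                    group_labels=None, alpha: float = 0.05) -> float:
    """Fraction of genes with p < alpha after the structured shuffle.

    ``tester`` is a fitted SpatialVariabilityTest (fitted on ``coords``).
    For the global scheme this is the empirical false positive rate.
    """
    counts = sp.csr_matrix(counts)
    perm = permute_assignment(scheme, coords=coords, group_labels=group_labels,
                              n=counts.shape[1])
    res = tester.transform(counts[:, perm])
    ok = res["tested"].to_numpy()
    if not ok.any():
        return float("nan")
    return float(np.mean(res.loc[ok, "p_combined"].to_numpy() < alpha))


def residualize_covariates(
    expression,
    categorical=None,
    continuous=None,
) -> np.ndarray:
    """Frisch-Waugh-Lovell residualization of a genes x locations matrix.

    Category means are removed from the expression rows and from each
    continuous covariate; the demeaned expression is then projected off the
    demeaned continuous covariates by least squares.  Residuals have zero
    mean within every category and zero correlation with every continuous
    covariate.  Returns a dense array.
    """
    E = np.asarray(
        expression.toarray() if sp.issparse(expression) else expression,
        dtype=np.float64,
    )
    if E.ndim != 2:
        raise ValueError("expression must be 2-D (genes x locations)")
    n = E.shape[1]
    if not np.all(np.isfinite(E)):
        raise ValueError("expression contains non-finite values")

    labels = (
        np.zeros(n, dtype=int) if categorical is None else np.asarray(categorical)
    )
    if len(labels) != n:
        raise ValueError("categorical covariate length mismatch")
    X = None
    if continuous is not None:
        X = np.asarray(continuous, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n or not np.all(np.isfinite(X)):
            raise ValueError("continuous covariates must be (n, q) and finite")
        X = X.copy()

    for g in np.unique(labels):
        idx = labels == g
        E[:, idx] -= E[:, idx].mean(axis=1, keepdims=True)
        if X is not None:
            X[idx] -= X[idx].mean(axis=0, keepdims=True)

    if X is not None:
        scale = np.sqrt(np.mean(X**2, axis=0))
        keep = scale > 1e-12 * max(scale.max(), 1.0)
        if not keep.all():
            logger.warning(
                "dropping %d constant covariate(s) after demeaning",
                int((~keep).sum()),
            )
        X = X[:, keep]
        if X.shape[1]:
            beta, *_ = np.linalg.lstsq(X, E.T, rcond=None)
            E -= (X @ beta).T
    return E
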