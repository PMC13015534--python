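"""Synthetic spatial-expression data: null regimes, pattern families and
calibration/power experiments.

Null genes are spatially unstructured counts on a square grid in one of three
sparsity regimes: Poisson(0.7) (~50% zeros), NB(size 1, p = 0.9) (~90%
zeros), and the same NB followed by independent 50% dropout (~95% zeros); a
numeric zero-fraction target z draws NB(1, z).  Spatially variable genes
modulate the count mean multiplicatively with a pattern field f(s) in [0, 1]:

    mean_i = base_mean * (1 + effect_size * f(s_i)),

where the base mean is calibrated once (deterministically) so that the
marginal zero fraction still hits the regime's target, keeping SVG and null
genes comparable in sparsity.  Effect size 0 reduces every family exactly to
the null generator.

Pattern families (on grid coordinates normalized to the unit square):
gradient = x; hotspot = Gaussian bump at the grid centre with radius 15% of
the grid side; periodic = (1 + sin(2 pi * 3 x)) / 2 (three full periods);
domain_boundary = step at x = 1/2; multiscale = gradient + hotspot rescaled
back to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq

from .testing import SpatialVariabilityTest

PATTERN_FAMILIES = ("gradient", "hotspot", "periodic", "domain_boundary", "multiscale")
NULL_REGIMES = ("poisson_50", "nb_90", "nb_dropout_95")

__all__ = [
    "PatternSpec",
    "SimulatedDataset",
    "PATTERN_FAMILIES",
    "NULL_REGIMES",
    "grid_coordinates",
    "simulate_null_gene",
    "pattern_field",
    "simulate_pattern_gene",
    "simulate_dataset",
    "calibration_experiment",
    "power_experiment",
]


def grid_coordinates(side: int) -> np.ndarray:
    """side x side integer lattice, row-major, as float (n, 2) coordinates."""
    if side < 2:
        raise ValueError("grid side must be >= 2")
    xx, yy = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)


def _zero_target(mode) -> float:
    if mode == "poisson_50":
        return float(np.exp(-0.7))
    if mode == "nb_90":
        return 0.9
    if mode == "nb_dropout_95":
        return 0.95
    z = float(mode)
    if not 0.0 < z < 1.0:
        raise ValueError(f"zero-fraction target must be in (0,1), got {mode!r}")
    return z


def simulate_null_gene(n: int, mode, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. spatially unstructured counts in the given sparsity regime."""
    if mode == "poisson_50":
        return rng.poisson(0.7, n)
    if mode == "nb_90":
        return rng.negative_binomial(1, 0.9, n)
    if mode == "nb_dropout_95":
        x = rng.negative_binomial(1, 0.9, n)
        x[rng.random(n) < 0.5] = 0
        return x
    z = _zero_target(mode)
    return rng.negative_binomial(1, z, n)


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of one simulated spatially variable gene."""

    family: str
    effect_size: float
    sparsity_mode: object = "nb_90"  # regime name or zero-fraction target
    grid_side: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.family not in PATTERN_FAMILIES:
            raise ValueError(f"unknown pattern family {self.family!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")


@dataclass
class SimulatedDataset:
    """Counts, coordinates and ground-truth SVG labels for one replicate."""

    counts: sp.csr_matrix  # genes x locations
    coords: np.ndarray
    labels: np.ndarray  # 1 = spatially variable, 0 = null
    gene_ids: list = field(default_factory=list)


def pattern_field(family: str, coords: np.ndarray) -> np.ndarray:
    """Spatial intensity surface f(s) in [0, 1] on unit-normalized coordinates."""
    pts = np.asarray(coords, dtype=np.float64)
    span = np.maximum(pts.max(axis=0) - pts.min(axis=0), 1e-12)
    u = (pts - pts.min(axis=0)) / span
    x = u[:, 0]
    if family == "gradient":
        return x
    if family == "hotspot":
        r = 0.15
        d2 = np.sum((u[:, :2] - 0.5) ** 2, axis=1)
        return np.exp(-d2 / (2 * r**2))
    if family == "periodic":
        return 0.5 * (1.0 + np.sin(2 * np.pi * 3 * x))
    if family == "domain_boundary":
        return (x > 0.5).astype(np.float64)
    if family == "multiscale":
        f = x + pattern_field("hotspot", coords)
        return f / f.max()
    raise ValueError(f"unknown pattern family {family!r}")


def _marginal_zero_fraction(base_mean, f, effect, mode) -> float:
    """Mean over locations of P(count = 0) under the modulated model."""
    mean_i = base_mean * (1.0 + effect * f)
    if mode == "poisson_50":
        p0 = np.exp(-mean_i)
    else:
        p0 = 1.0 / (1.0 + mean_i)  # NB size 1: P(0) = p = 1/(1+mean)
        if mode == "nb_dropout_95":
            p0 = 0.5 + 0.5 * p0
    return float(np.mean(p0))


def _calibrate_base_mean(f: np.ndarray, effect: float, mode) -> float:
    """Base mean such that the marginal zero fraction hits the regime target.

    Deterministic root-find; with effect 0 it returns the regime's own base
    mean exactly (0.7 for the Poisson regime, (1-z)/z for NB regimes).
    """
    target = _zero_target(mode)
    g = lambda m: _marginal_zero_fraction(m, f, effect, mode) - target
    lo, hi = 1e-9, 1e6
    if g(lo) < 0 or g(hi) > 0:  # pragma: no cover - unreachable for valid targets
        raise ValueError("cannot calibrate base mean for this regime")
    return brentq(g, lo, hi, xtol=1e-12, rtol=1e-12)


def simulate_pattern_gene(spec: PatternSpec, coords: np.ndarray,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Counts whose mean follows base_mean * (1 + effect * f(s)) per location."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    f = pattern_field(spec.family, coords)
    mode = spec.sparsity_mode
    base = _calibrate_base_mean(f, spec.effect_size, mode)
    mean_i = base * (1.0 + spec.effect_size * f)
    if mode == "poisson_50":
        x = rng.poisson(mean_i)
    else:
        p_i = 1.0 / (1.0 + mean_i)
        x = rng.negative_binomial(1, p_i)
        if mode == "nb_dropout_95":
            x[rng.random(len(x)) < 0.5] = 0
    return x


def simulate_dataset(
    n_svg: int,
    n_null: int,
    family: str,
    effect_size: float,
    sparsity_mode,
    grid_side: int = 50,
    seed: int = 0,
) -> SimulatedDataset:
    """One replicate: n_svg patterned genes followed by n_null unstructured ones."""
    coords = grid_coordinates(grid_side)
    rng = np.random.default_rng(seed)
    n = coords.shape[0]
    rows = []
    spec = PatternSpec(family=family, effect_size=effect_size,
                       sparsity_mode=sparsity_mode, grid_side=grid_side, seed=seed)
    for _ in range(n_svg):
        rows.append(simulate_pattern_gene(spec, coords, rng))
    for _ in range(n_null):
        rows.append(simulate_null_gene(n, sparsity_mode, rng))
    counts = sp.csr_matrix(np.asarray(rows, dtype=np.int64))
    labels = np.concatenate([np.ones(n_svg, dtype=int), np.zeros(n_null, dtype=int)])
    gene_ids = [f"svg_{i}" for i in range(n_svg)] + [f"null_{i}" for i in range(n_null)]
    return SimulatedDataset(counts=counts, coords=coords, labels=labels,
                            gene_ids=gene_ids)


def _fit_tester(coords, seed, **tester_params) -> SpatialVariabilityTest:
    est = SpatialVariabilityTest(random_state=seed, **tester_params)
    return est.fit(coords)


def calibration_experiment(
    n_replicates: int = 20,
    genes_per_replicate: int = 1000,
    regimes=NULL_REGIMES,
    grid_side: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    **tester_params,
) -> pd.DataFrame:
    """Type-I-error study: replicated all-null datasets per sparsity regime.

    Returns one row per regime plus a pooled ``overall`` row, with the
    fraction of tested genes at p < alpha (FPR) and at q < 0.05 (an FDR
    proxy, every gene being null).  Each replicate is analyzed end to end
    with its own fit (its own basis draw), as independent runs of the tool
    would be.
    """
    coords = grid_coordinates(grid_side)
    ss = np.random.SeedSequence([seed, 101])
    rows = []
    pooled_p, pooled_q = [], []
    for regime in regimes:
        n_sig = n_q = n_tested = 0
        for child in ss.spawn(n_replicates):
            rng = np.random.default_rng(child)
            fit_seed = int(child.generate_state(1, dtype=np.uint32)[0] >> 1)
            counts = sp.csr_matrix(
                np.asarray(
                    [simulate_null_gene(coords.shape[0], regime, rng)
                     for _ in range(genes_per_replicate)],
                    dtype=np.int64,
                )
            )
            est = _fit_tester(coords, fit_seed, **tester_params)
            res = est.transform(counts)
            ok = res["tested"].to_numpy()
            p = res.loc[ok, "p_combined"].to_numpy()
            q = res.loc[ok, "q_value"].to_numpy()
            n_tested += int(ok.sum())
            n_sig += int((p < alpha).sum())
            n_q += int((q < 0.05).sum())
            pooled_p.append(p)
            pooled_q.append(q)
        rows.append(
            {"regime": regime, "n_tests": n_tested,
             "fpr": n_sig / max(n_tested, 1), "fdr_q05": n_q / max(n_tested, 1)}
        )
    p_all = np.concatenate(pooled_p)
    q_all = np.concatenate(pooled_q)
    rows.append(
        {"regime": "overall", "n_tests": len(p_all),
         "fpr": float(np.mean(p_all < alpha)), "fdr_q05": float(np.mean(q_all < 0.05))}
    )
    return pd.DataFrame(rows)


def power_experiment(
    families=PATTERN_FAMILIES,
    effect_sizes=(0.3, 0.5, 1.0),
    sparsity_levels=(0.5, 0.8, 0.95),
    n_svg: int = 200,
    n_null: int = 200,
    n_replicates: int = 10,
    grid_side: int = 50,
    seed: int = 0,
    **tester_params,
) -> pd.DataFrame:
    """Detection-power study over pattern families, effects and sparsity.

    TPR is the fraction of true SVGs with q < 0.05 (BH within each
    replicate's own gene set); FDR is the fraction of rejections that are
    null genes.  Each replicate is an independent end-to-end run (fresh
    basis draw), so power averages over the random feature sampling.
    """
    coords = grid_coordinates(grid_side)
    ss = np.random.SeedSequence([seed, 202])
    rows = []
    for family in families:
        for effect in effect_sizes:
            for zfrac in sparsity_levels:
                tp = fp = n_svg_tested = n_rej = 0
                children = ss.spawn(n_replicates)
                for child in children:
                    rep_seed, fit_seed = (
                        int(s) for s in child.generate_state(2, dtype=np.uint32) >> np.uint32(1)
                    )
                    ds = simulate_dataset(
                        n_svg, n_null, family, effect, zfrac,
                        grid_side=grid_side, seed=rep_seed,
                    )
                    est = _fit_tester(coords, fit_seed, **tester_params)
                    res = est.transform(ds.counts, gene_ids=ds.gene_ids)
                    ok = res["tested"].to_numpy()
                    rej = ok & (res["q_value"].to_numpy() < 0.05)
                    is_svg = ds.labels == 1
                    tp += int((rej & is_svg).sum())
                    fp += int((rej & ~is_svg).sum())
                    n_svg_tested += int((ok & is_svg).sum())
                    n_rej += int(rej.sum())
                rows.append(
                    {
                        "family": family,
                        "effect_size": effect,
                        "sparsity": zfrac,
                        "tpr": tp / max(n_svg_tested, 1),
                        "fdr": fp / max(n_rej, 1),
                        "n_svg_tested": n_svg_tested,
                    }
                )
    return pd.DataFrame(rows)
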