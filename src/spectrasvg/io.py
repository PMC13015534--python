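"""Readers and writers for the formats the tool touches.

Counts travel as Matrix Market coordinate files (genes x locations or the
transpose, auto-resolved against the coordinate table length) with plain-text
gene-ID sidecars, or as small dense delimited tables whose first column holds
gene IDs.  Coordinates are two numeric columns of delimited text, one row per
location, in the same order as the count matrix's location axis.  Results are
TSV with 6-significant-digit floats.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "gene_id", "n_expressed", "p_combined", "q_value", "effect_size",
    "p_binary", "p_rank", "p_direct", "tested",
]

__all__ = [
    "read_coordinates",
    "read_counts",
    "write_counts",
    "write_results",
    "read_results",
]


def _has_header(path: Path, sep: str) -> bool:
    with open(path) as fh:
        first = fh.readline()
    for tok in first.strip().split(sep):
        try:
            float(tok)
        except ValueError:
            return True
    return False


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_coordinates(path) -> np.ndarray:
    """Two numeric columns (x, y), optional header, one row per location."""
    path = Path(path)
    sep = _sep_for(path)
    header = 0 if _has_header(path, sep) else None
    df = pd.read_csv(path, sep=sep, header=header)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two coordinate columns")
    coords = df.iloc[:, :2].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise ValueError(f"{path}: non-finite coordinates")
    return coords


def _dedupe(ids) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for g in ids:
        g = str(g)
        if g in seen:
            seen[g] += 1
            out.append(f"{g}.{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    return out


def _validate_counts(mat: sp.csr_matrix, path):
    bad = ~np.isfinite(mat.data) | (mat.data < 0)
    if bad.any():
        coo = mat.tocoo()
        k = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: invalid count {mat.data[k]!r} at "
            f"(row {coo.row[k]}, col {coo.col[k]})"
        )


def read_counts(path, n_locations: int, gene_ids_path=None,
                orientation: str = "auto"):
    """Load a nonnegative count matrix as genes x locations CSR.

    Orientation is resolved by matching an axis to ``n_locations``; a square
    matrix requires an explicit ``orientation`` of "genes_by_locations" or
    "locations_by_genes".  Duplicate gene IDs get deterministic ".k" suffixes.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = sp.csr_matrix(mmread(path))
        ids = None
        if gene_ids_path is None:
            cand = path.with_suffix(".genes.txt")
            gene_ids_path = cand if cand.exists() else None
        if gene_ids_path is not None:
            ids = [ln.strip() for ln in open(gene_ids_path) if ln.strip()]
    else:
        sep = _sep_for(path)
        header = 0 if _has_header(path, sep) else None
        df = pd.read_csv(path, sep=sep, header=header, index_col=0)
        mat = sp.csr_matrix(df.to_numpy(dtype=np.float64))
        ids = [str(i) for i in df.index]

    if orientation == "auto":
        if mat.shape[0] == mat.shape[1]:
            raise ValueError(
                f"{path}: square matrix; pass orientation explicitly"
            )
        if mat.shape[1] == n_locations:
            pass
        elif mat.shape[0] == n_locations:
            logger.info("%s: transposing to genes x locations", path)
            mat = sp.csr_matrix(mat.T)
        else:
            raise ValueError(
                f"{path}: neither axis ({mat.shape}) matches the "
                f"{n_locations} coordinate rows"
            )
    elif orientation == "locations_by_genes":
        mat = sp.csr_matrix(mat.T)
    elif orientation != "genes_by_locations":
        raise ValueError(f"unknown orientation {orientation!r}")
    if mat.shape[1] != n_locations:
        raise ValueError(
            f"{path}: {mat.shape[1]} locations vs {n_locations} coordinate rows"
        )
    _validate_counts(mat, path)
    if ids is None:
        ids = [f"gene_{i}" for i in range(mat.shape[0])]
    if len(ids) != mat.shape[0]:
        raise ValueError(f"{path}: {len(ids)} gene IDs for {mat.shape[0]} genes")
    return mat, _dedupe(ids)


def write_counts(counts, gene_ids, prefix):
    """Write counts as <prefix>.mtx with a <prefix>.genes.txt sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mmwrite(str(prefix.with_suffix(".mtx")), sp.coo_matrix(counts))
    with open(prefix.with_suffix(".genes.txt"), "w") as fh:
        fh.write("\n".join(str(g) for g in gene_ids) + "\n")


def write_results(results: pd.DataFrame, path):
    """Results TSV with floats at 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = results.loc[:, RESULT_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing result columns {sorted(missing)}")
    return df
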