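"""Genomic relationship matrix, principal components, and a Haseman-Elston check.

The GRM follows VanRaden's first method: with dosage matrix X (N x M), allele
frequencies p_j, and Z = X - 2p,

    G = Z Z' / sum_j 2 p_j (1 - p_j).

SNPs with minor allele frequency at or below the cutoff (default 0.5%) are
excluded before building G.  Principal components are eigenvectors of G
itself, ordered by decreasing eigenvalue.  The Haseman-Elston regression is a
lightweight method-of-moments heritability estimate used to validate
synthetic data: the slope of y_i * y_j (standardized phenotypes) on the
off-diagonal G_ij estimates the SNP heritability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.linalg import eigsh

from .errors import InvalidConfigError, IdMismatchError
from .panel import HaplotypePanel


@dataclass
class GRM:
    ids: list[str]
    matrix: np.ndarray
    n_snps: int

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise InvalidConfigError("GRM dimension does not match ids")


@dataclass
class PCSet:
    """Top-k principal components: (N, k) vectors and descending eigenvalues."""

    ids: list[str]
    vectors: np.ndarray
    eigenvalues: np.ndarray

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


def compute_grm(
    panel: HaplotypePanel,
    maf_min: float = 0.005,
    snp_indices: np.ndarray | None = None,
    chunk: int = 4096,
) -> GRM:
    """VanRaden method-1 GRM from a phased panel.

    ``snp_indices`` restricts the computation to a subset of SNPs (e.g. a
    thinned marker set); the MAF filter is strict (MAF > maf_min retained).
    SNP chunks keep the centered-dosage matrix small.
    """
    n = panel.n_individuals
    indices = (
        np.arange(panel.n_snps) if snp_indices is None else np.asarray(snp_indices)
    )
    g = np.zeros((n, n))
    denom = 0.0
    used = 0
    for lo in range(0, len(indices), chunk):
        idx = indices[lo : lo + chunk]
        d = panel.dosages(idx)
        p = d.mean(axis=0) / 2.0
        maf = np.minimum(p, 1 - p)
        keep = maf > maf_min
        if not keep.any():
            continue
        z = d[:, keep] - 2 * p[keep]
        g += z @ z.T
        denom += float(np.sum(2 * p[keep] * (1 - p[keep])))
        used += int(keep.sum())
    if used == 0:
        raise InvalidConfigError("no SNPs survive the MAF filter")
    g /= denom
    return GRM(list(panel.ids), g, used)


def top_pcs(grm: GRM, k: int = 10) -> PCSet:
    """First k eigenvectors of the GRM, in order of decreasing eigenvalue."""
    n = len(grm.ids)
    if k >= n:
        raise InvalidConfigError("k must be smaller than the number of individuals")
    if n > 600 and k < n - 1:
        # Lanczos with a fixed start vector keeps results deterministic.
        v0 = np.full(n, 1.0 / np.sqrt(n))
        vals, vecs = eigsh(grm.matrix, k=k, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
    else:
        vals, vecs = np.linalg.eigh(grm.matrix)
        order = np.argsort(vals)[::-1][:k]
    return PCSet(list(grm.ids), vecs[:, order], vals[order])


def he_regression(
    grm: GRM, phenotypes: pd.DataFrame
) -> tuple[float, float]:
    """Haseman-Elston heritability estimate and its standard error.

    Regresses the cross-products of standardized phenotypes on the
    off-diagonal GRM entries (with intercept); the slope estimates h2.
    """
    n = len(grm.ids)
    if n < 10:
        raise InvalidConfigError("Haseman-Elston regression needs at least 10 individuals")
    table = phenotypes.set_index("id")["phenotype"]
    missing = [s for s in grm.ids if s not in table.index]
    if missing:
        raise IdMismatchError(f"phenotype missing for ids: {missing[:5]}")
    y = table.loc[grm.ids].to_numpy(dtype=float)
    z = (y - y.mean()) / y.std(ddof=1)
    g = grm.matrix
    diag = np.diag(g)

    def slope(n_pairs, sx, sy, sxx, sxy):
        return (sxy - sx * sy / n_pairs) / (sxx - sx**2 / n_pairs)

    n_pairs = n * (n - 1) / 2
    row_sx = g.sum(axis=1) - diag
    row_sxx = (g**2).sum(axis=1) - diag**2
    row_sy = z * (z.sum() - z)
    row_sxy = z * (g @ z - diag * z)
    sx = row_sx.sum() / 2
    sxx = row_sxx.sum() / 2
    sy = row_sy.sum() / 2
    sxy = row_sxy.sum() / 2
    est = slope(n_pairs, sx, sy, sxx, sxy)
    # leave-one-individual-out jackknife: pairs are dependent, so the naive
    # OLS standard error would understate the sampling variance
    loo = slope(
        n_pairs - (n - 1),
        sx - row_sx,
        sy - row_sy,
        sxx - row_sxx,
        sxy - row_sxy,
    )
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    return float(est), se


def write_grm(grm: GRM, path) -> None:
    """Lower-triangle TSV triplets (id1, id2, value), diagonal included."""
    rows = []
    for i, a in enumerate(grm.ids):
        for j in range(i + 1):
            rows.append((a, grm.ids[j], grm.matrix[i, j]))
    pd.DataFrame(rows, columns=["id1", "id2", "value"]).to_csv(
        path, sep="\t", index=False
    )


def write_pcs(pcs: PCSet, path) -> None:
    cols = {"id": pcs.ids}
    for j in range(pcs.k):
        cols[f"PC{j + 1}"] = pcs.vectors[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
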