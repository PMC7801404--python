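"""Spatial PCA of individual allele frequencies on a connection network.

The analysed matrix is ``C = (1/n) Z' M Z`` where ``Z`` is the
column-centred individual allele-frequency matrix (entries 0 / 0.5 / 1,
missing values mean-imputed per column) and ``M = (W + W') / 2`` the
symmetrised row-normalised spatial weight matrix.  Positive eigenvalues
capture global structure (clines, patches: genetic variance with positive
spatial autocorrelation), negative eigenvalues local structure (strong
differentiation between neighbours).  Monte Carlo tests permute genotype
rows against coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .matrix import GenotypeMatrix


@dataclass
class SpcaResult:
    eigenvalues: np.ndarray        # descending, signed
    scores: np.ndarray             # (n, n_components) individual scores
    edges: list[tuple[int, int]]   # Delaunay (or custom) connection network
    global_p: float | None = None
    local_p: float | None = None
    n_permutations: int = 0


def delaunay_connectivity(coords: np.ndarray, jitter_km: float = 0.1,
                          seed: int = 0) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Row-normalised weight matrix from the Delaunay triangulation.

    Exact duplicate coordinates are jittered by at most ~``jitter_km``
    (default 100 m) with a warning so the triangulation is defined.
    """
    pts = np.asarray(coords, dtype=float).copy()
    n = len(pts)
    if n < 3:
        raise ValueError("Delaunay connectivity needs at least 3 points")
    _, first = np.unique(pts, axis=0, return_index=True)
    dup = np.setdiff1d(np.arange(n), first)
    if dup.size:
        warnings.warn(f"{dup.size} duplicate coordinate(s) jittered by <= {jitter_km} km")
        rng = np.random.default_rng(seed)
        pts[dup] += rng.uniform(-1, 1, (dup.size, 2)) * (jitter_km / 111.2)
    try:
        tri = Delaunay(pts)
    except Exception as e:  # collinear degeneracies
        raise ValueError(f"Delaunay triangulation failed: {e}") from None
    W = np.zeros((n, n))
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
            W[i, j] = W[j, i] = 1.0
    rowsum = W.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return W / rowsum, sorted(edges)


def _centered_freq_matrix(gm: GenotypeMatrix, subset=None) -> np.ndarray:
    X, _ = gm.dosage_matrix(subset)
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    idx = np.nonzero(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    return X - X.mean(axis=0)


def _spca_eig(Z: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = Z.shape[0]
    C = Z.T @ M @ Z / n
    C = (C + C.T) / 2.0
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def spca(gm: GenotypeMatrix, connectivity: np.ndarray, subset=None) -> SpcaResult:
    """Eigenanalysis of genetic variance weighted by spatial autocorrelation."""
    Z = _centered_freq_matrix(gm, subset)
    if not np.any(Z):
        raise ValueError("all-zero variance matrix: no polymorphism in subset")
    W = np.asarray(connectivity, dtype=float)
    if W.shape[0] != Z.shape[0]:
        raise ValueError("connectivity does not cover all genotyped individuals")
    M = (W + W.T) / 2.0
    vals, vecs = _spca_eig(Z, M)
    scores = Z @ vecs
    edges = [(i, j) for i in range(W.shape[0]) for j in range(i + 1, W.shape[0])
             if W[i, j] != 0 or W[j, i] != 0]
    return SpcaResult(vals, scores, edges)


def global_local_tests(gm: GenotypeMatrix, connectivity: np.ndarray,
                       n_perm: int = 10_000, seed: int = 0,
                       subset=None) -> tuple[float, float]:
    """Monte Carlo tests for global and local spatial genetic structure.

    Genotype rows are permuted against coordinates ``n_perm`` times; the
    global statistic is the largest positive eigenvalue, the local one the
    magnitude of the most negative; p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    Z = _centered_freq_matrix(gm, subset)
    W = np.asarray(connectivity, dtype=float)
    M = (W + W.T) / 2.0
    n = Z.shape[0]

    def stats(Zp: np.ndarray) -> tuple[float, float]:
        C = Zp.T @ M @ Zp / n
        vals = np.linalg.eigvalsh((C + C.T) / 2.0)
        return float(vals[-1]), float(-vals[0])

    g_obs, l_obs = stats(Z)
    rng = np.random.default_rng(seed)
    g_hits = l_hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        g, l = stats(Z[perm])
        g_hits += g >= g_obs
        l_hits += l >= l_obs
    global_p = (1 + g_hits) / (n_perm + 1)
    local_p = (1 + l_hits) / (n_perm + 1)
    return float(global_p), float(local_p)
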