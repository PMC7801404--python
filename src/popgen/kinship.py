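"""Pairwise kinship (Loiselle-type) and isolation-by-distance analysis.

The kinship coefficient between individuals i and j is

    F_ij = sum_l sum_a [ (x_ila - p_la)(x_jla - p_la) + p_la(1-p_la)/(n_l-1) ]
           / sum_l sum_a p_la (1 - p_la)

with ``x`` the individual allele frequency (0, 0.5, 1), ``p`` the
reference sample frequency and ``n_l`` the individuals typed at the
locus; loci missing in either member of a pair are dropped from both
sums.  Per-locus components are retained so distance-class means can be
jackknifed over loci.  IBD significance is assessed by permuting spatial
locations among individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import pairwise_distance_km
from .matrix import AlleleFrequencies, GenotypeMatrix, allele_frequencies


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    values: np.ndarray          # (n, n) multilocus kinship, nan where undefined
    num_stack: np.ndarray       # (L, n, n) per-locus numerators (nan = pair untyped)
    den_stack: np.ndarray       # (L, n, n) per-locus denominators (nan = pair untyped)
    locus_ids: list[str]


@dataclass
class IbdResult:
    table: pd.DataFrame         # class_low, class_high, n_pairs, mean_kinship, jackknife_se, p_value
    population_mean: float
    n_permutations: int


def loiselle_kinship(gm: GenotypeMatrix, freqs: AlleleFrequencies | None = None,
                     subset=None) -> KinshipMatrix:
    """All pairwise kinship coefficients relative to sample frequencies."""
    rows = gm.sample_index(subset)
    ids = [gm.sample_ids[i] for i in rows]
    if len(ids) < 2:
        raise ValueError("kinship needs at least 2 individuals")
    if freqs is None:
        freqs = allele_frequencies(gm, ids)
    n = len(ids)
    X, cols = gm.dosage_matrix(ids)
    p_arrays = freqs.as_arrays(gm)

    num_stack = np.zeros((gm.n_loci, n, n))
    den_stack = np.zeros((gm.n_loci, n, n))
    col_locus = np.array([gm.locus_ids.index(lid) for lid, _ in cols])
    for l, lid in enumerate(gm.locus_ids):
        block = X[:, col_locus == l]
        p = p_arrays[l]
        n_l = freqs.n_typed.get(lid, 0)
        if n_l < 2 or (p > 0).sum() < 2:
            num_stack[l] = np.nan
            den_stack[l] = np.nan
            continue
        typed = np.isfinite(block[:, 0])
        centred = np.where(typed[:, None], block - p[None, :], 0.0)
        het_term = float((p * (1 - p)).sum())
        num = centred @ centred.T + het_term / (n_l - 1)
        valid = np.outer(typed, typed)
        num_stack[l] = np.where(valid, num, np.nan)
        den_stack[l] = np.where(valid, het_term, np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.nansum(num_stack, axis=0) / np.nansum(den_stack, axis=0)
    no_shared = np.isnan(den_stack).all(axis=0) | (np.nansum(den_stack, axis=0) == 0)
    values[no_shared] = np.nan
    return KinshipMatrix(ids, values, num_stack, den_stack, list(gm.locus_ids))


def _class_means(kin_pairs: np.ndarray, class_idx: np.ndarray, n_classes: int
                 ) -> np.ndarray:
    means = np.full(n_classes, np.nan)
    for c in range(n_classes):
        sel = class_idx == c
        if sel.any():
            means[c] = np.nanmean(kin_pairs[sel])
    return means


def ibd_analysis(
    kin: KinshipMatrix,
    coords: np.ndarray,
    classes: list[float] | np.ndarray | None = None,
    subset=None,
    n_perm: int = 20_000,
    seed: int = 0,
) -> IbdResult:
    """Distance-class kinship means with permutation p-values and jackknife SE.

    ``classes`` are the upper bounds (km) of the distance classes; the
    last class absorbs everything beyond the final bound.  The null
    permutes spatial locations among the analysed individuals; p-values
    are two-sided around the population mean kinship.  SEs come from a
    delete-one-locus jackknife of the class means.
    """
    ids = kin.sample_ids
    if subset is not None:
        idx = np.array([ids.index(s) for s in subset])
    else:
        idx = np.arange(len(ids))
    if len(idx) < 5:
        warnings.warn("fewer than 5 individuals in IBD subset")
    if classes is None:
        classes = [25, 50, 100, 200, 400, 800]
    bounds = np.asarray(sorted(classes), dtype=float)

    K = kin.values[np.ix_(idx, idx)]
    D = pairwise_distance_km(np.asarray(coords, dtype=float))
    if D.shape != K.shape:
        raise ValueError("coords must align with the analysed subset")
    iu = np.triu_indices(len(idx), k=1)
    kp = K[iu]
    dp = D[iu]
    class_idx = np.digitize(dp, bounds, right=True)   # 0..len(bounds): last open-ended
    n_classes = len(bounds) + 1
    pop_mean = float(np.nanmean(kp))
    obs = _class_means(kp, class_idx, n_classes)

    rng = np.random.default_rng(seed)
    m = len(idx)
    exceed = np.zeros(n_classes)
    n_valid = np.zeros(n_classes)
    obs_dev = np.abs(obs - pop_mean)
    for _ in range(n_perm):
        perm = rng.permutation(m)
        dperm = D[perm[:, None], perm[None, :]][iu]
        cidx = np.digitize(dperm, bounds, right=True)
        means = _class_means(kp, cidx, n_classes)
        dev = np.abs(means - pop_mean)
        ok = np.isfinite(dev) & np.isfinite(obs_dev)
        exceed[ok] += dev[ok] >= obs_dev[ok]
        n_valid[ok] += 1
    with np.errstate(invalid="ignore"):
        pvals = (1 + exceed) / (n_valid + 1)
    pvals[~np.isfinite(obs)] = np.nan

    # delete-one-locus jackknife of class means
    num = kin.num_stack[:, np.ix_(idx, idx)[0], np.ix_(idx, idx)[1]]
    den = kin.den_stack[:, np.ix_(idx, idx)[0], np.ix_(idx, idx)[1]]
    num_tot = np.nansum(num, axis=0)
    den_tot = np.nansum(den, axis=0)
    L = num.shape[0]
    jk = np.full((L, n_classes), np.nan)
    for l in range(L):
        with np.errstate(invalid="ignore", divide="ignore"):
            k_l = (num_tot - np.nan_to_num(num[l])) / (den_tot - np.nan_to_num(den[l]))
        jk[l] = _class_means(k_l[iu], class_idx, n_classes)
    jk_mean = np.nanmean(jk, axis=0)
    with np.errstate(invalid="ignore"):
        se = np.sqrt((L - 1) / L * np.nansum((jk - jk_mean) ** 2, axis=0))
    se[~np.isfinite(obs)] = np.nan

    lows = np.concatenate([[0.0], bounds])
    highs = np.concatenate([bounds, [np.inf]])
    counts = np.bincount(class_idx, minlength=n_classes)
    for c in range(n_classes):
        if counts[c] == 0:
            warnings.warn(f"distance class ({lows[c]:.0f}, {highs[c]:.0f}] km is empty")
    table = pd.DataFrame({
        "class_low_km": lows, "class_high_km": highs, "n_pairs": counts,
        "mean_kinship": obs, "jackknife_se": se, "p_value": pvals,
    })
    return IbdResult(table, pop_mean, n_perm)
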