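"""Linkage-disequilibrium effective population size (bias-corrected r-squared).

For every pair of loci and every retained allele pair, the Burrows
composite disequilibrium is estimated from genotype dosages (no phase
required), corrected for within-locus departure from Hardy–Weinberg
proportions, and normalised to an r-squared:

    Delta_AB = S/(S-1) * [ (1/2S) sum_i xA_i xB_i - 2 pA pB ]
    r2_AB    = Delta_AB^2 / [ (pA qA + DA) (pB qB + DB) ]

with ``x`` the allele dosage (0/1/2), ``D`` the homozygote excess
``P_AA - pA^2`` and ``S`` the individuals typed at both loci.  Rare
alleles (frequency < cutoff in the analysed subset) are excluded.  The
pooled mean r-squared is reduced by its pure-sampling expectation and
transformed to an Ne estimate; all numeric constants follow the standard
LD method for randomly mating populations and are gathered in
:data:`LDNE_CONSTANTS` for auditability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .matrix import MISSING, GenotypeMatrix

#: Constants of the sampling-bias correction and Ne transform, by sample-size
#: regime (weighted harmonic mean S >= 30 or below).
LDNE_CONSTANTS = {
    "large_S": {"er2": (1.0, 3.19), "a": 1.0 / 3.0, "b": 2.76},
    "small_S": {"er2": (0.0018, 0.907, 4.44), "a": 0.308, "b": 2.08},
}


@dataclass
class BurrowsResult:
    pairs: pd.DataFrame            # one row per locus pair
    mean_r2: float                 # df-weighted mean over locus pairs
    n_comparisons: int             # total degrees of freedom
    s_harmonic: float              # harmonic mean S over locus pairs (df-weighted)


@dataclass
class NeEstimate:
    ne: float                      # may be +inf
    ci_low: float
    ci_high: float
    mean_r2: float
    expected_r2: float
    s_harmonic: float
    n_comparisons: int
    freq_cutoff: float


def _locus_blocks(gm: GenotypeMatrix, rows: np.ndarray, cutoff: float):
    """Per locus: (dosage matrix over kept alleles, typed mask) or None."""
    blocks = []
    for l in range(gm.n_loci):
        k = len(gm.alleles[l])
        c = gm.codes[rows, l, :]
        typed = c[:, 0] != MISSING
        if typed.sum() == 0 or k < 2:
            blocks.append(None)
            continue
        dos = np.zeros((len(rows), k))
        for copy in range(2):
            cc = c[typed, copy]
            dos[np.nonzero(typed)[0], cc] += 1.0
        p = dos[typed].sum(axis=0) / (2.0 * typed.sum())
        keep = np.nonzero(p >= cutoff)[0]
        if len(keep) < 2:
            blocks.append(None)  # monomorphic after screening
            continue
        blocks.append((dos[:, keep], typed))
    return blocks


def burrows_r2(gm: GenotypeMatrix, subset=None, freq_cutoff: float = 0.02
               ) -> BurrowsResult:
    """Composite-LD r-squared for all usable locus pairs.

    Returns per-pair mean r-squared over allele-pair comparisons with the
    pair's degrees of freedom ``(k1-1)(k2-1)`` (kept alleles) and joint
    sample size S; pooling weights each locus pair by its df.
    """
    rows = gm.sample_index(subset)
    blocks = _locus_blocks(gm, rows, freq_cutoff)
    usable = [l for l, b in enumerate(blocks) if b is not None]
    if len(usable) < 2:
        raise ValueError("fewer than 2 polymorphic loci after frequency screening")
    records = []
    for ii, l1 in enumerate(usable):
        d1, t1 = blocks[l1]
        for l2 in usable[ii + 1:]:
            d2, t2 = blocks[l2]
            joint = t1 & t2
            S = int(joint.sum())
            if S < 2:
                continue
            Xa = d1[joint]
            Xb = d2[joint]
            pA = Xa.mean(axis=0) / 2.0
            pB = Xb.mean(axis=0) / 2.0
            DA = (Xa == 2).mean(axis=0) - pA ** 2
            DB = (Xb == 2).mean(axis=0) - pB ** 2
            vA = pA * (1 - pA) + DA
            vB = pB * (1 - pB) + DB
            delta = (Xa.T @ Xb) / (2.0 * S) - 2.0 * np.outer(pA, pB)
            delta *= S / (S - 1.0)
            denom = np.outer(vA, vB)
            ok = (np.outer((pA > 0) & (pA < 1), (pB > 0) & (pB < 1))
                  & (denom > 1e-12))
            if not ok.any():
                continue
            r2 = np.where(ok, delta ** 2 / np.where(denom > 1e-12, denom, 1.0), np.nan)
            df = max((Xa.shape[1] - 1) * (Xb.shape[1] - 1), 1)
            records.append({
                "locus1": gm.locus_ids[l1], "locus2": gm.locus_ids[l2],
                "S": S, "df": df, "r2_mean": float(np.nanmean(r2)),
            })
    if not records:
        raise ValueError("no usable locus-pair comparisons")
    pairs = pd.DataFrame.from_records(records)
    w = pairs["df"].to_numpy(dtype=float)
    mean_r2 = float((pairs["r2_mean"] * w).sum() / w.sum())
    s_harm = float(w.sum() / (w / pairs["S"]).sum())
    return BurrowsResult(pairs, mean_r2, int(w.sum()), s_harm)


def _expected_r2(S: float) -> float:
    if S >= 30:
        c1, c2 = LDNE_CONSTANTS["large_S"]["er2"]
        return c1 / S + c2 / S ** 2
    c0, c1, c2 = LDNE_CONSTANTS["small_S"]["er2"]
    return c0 + c1 / S + c2 / S ** 2


def _ne_transform(r2_prime: float, S: float) -> float:
    if not np.isfinite(r2_prime) or r2_prime <= 0:
        return float("inf")
    regime = "large_S" if S >= 30 else "small_S"
    a = LDNE_CONSTANTS[regime]["a"]
    b = LDNE_CONSTANTS[regime]["b"]
    disc = max(a ** 2 - b * r2_prime, 0.0)
    return float((a + np.sqrt(disc)) / (2.0 * r2_prime))


def ld_ne(gm: GenotypeMatrix, subset=None, freq_cutoff: float = 0.02) -> NeEstimate:
    """LD effective population size with a parametric 95% CI.

    The CI treats ``df * mean_r2 / r2_true`` as chi-squared with df equal
    to the number of allele-pair comparisons; each CI bound is pushed
    through the same bias correction and Ne transform as the point
    estimate.  A non-positive drift signal yields an infinite estimate.
    """
    rows = gm.sample_index(subset)
    if len(rows) < 10:
        warnings.warn("fewer than 10 individuals: Ne estimate unreliable")
    b = burrows_r2(gm, subset, freq_cutoff)
    S = b.s_harmonic
    e_r2 = _expected_r2(S)
    r2p = b.mean_r2 - e_r2
    ne = _ne_transform(r2p, S)
    df = b.n_comparisons
    r2_low = df * b.mean_r2 / chi2.ppf(0.975, df)
    r2_high = df * b.mean_r2 / chi2.ppf(0.025, df)
    ci_high = _ne_transform(r2_low - e_r2, S)
    ci_low = _ne_transform(r2_high - e_r2, S)
    return NeEstimate(ne, ci_low, ci_high, b.mean_r2, e_r2, S, df, freq_cutoff)
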