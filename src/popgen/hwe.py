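"""Multi-allelic exact tests of Hardy–Weinberg equilibrium.

The test conditions on the observed allele counts.  Under the null every
genotype table with those margins has the Levene probability

    P(table) = n! * prod_a m_a! * 2^H / ( (2n)! * prod_{i<=j} n_ij! )

where ``n`` is the number of individuals, ``m_a`` the allele counts and
``H`` the number of heterozygotes.  Tables are ordered by the conditional
likelihood-ratio statistic of genotype proportions against the
Hardy–Weinberg expectation; the p-value is the total null probability of
tables at least as extreme as the one observed.  Small margin spaces are
enumerated exhaustively; larger ones fall back to Monte Carlo sampling
(random pairing of the allele vector, which draws exactly from the
conditional null).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log

import numpy as np
from scipy.special import xlogy

from .matrix import MISSING, GenotypeMatrix

_TIE_TOL = 1e-9


class MonomorphicLocusError(ValueError):
    """HWE is undefined for a locus with a single allele."""


@dataclass
class HWETestResult:
    locus: str | None
    p_value: float
    method: str  # "enumeration" | "monte_carlo"
    tables_evaluated: int
    lr_statistic: float  # G^2 = -2 log LR of the observed table


def genotype_counts(gm: GenotypeMatrix, locus_id: str,
                    subset=None) -> np.ndarray:
    """Upper-triangular genotype count matrix (k x k) at one locus."""
    rows = gm.sample_index(subset)
    l = gm.locus_ids.index(locus_id)
    k = len(gm.alleles[l])
    counts = np.zeros((k, k), dtype=int)
    c = gm.codes[rows, l, :]
    c = c[c[:, 0] != MISSING]
    lo = np.minimum(c[:, 0], c[:, 1])
    hi = np.maximum(c[:, 0], c[:, 1])
    np.add.at(counts, (lo, hi), 1)
    return counts


def _margins(counts: np.ndarray) -> np.ndarray:
    k = counts.shape[0]
    m = np.zeros(k, dtype=int)
    for i in range(k):
        for j in range(i, k):
            m[i] += counts[i, j]
            m[j] += counts[i, j]
    return m


def _log_levene_const(n: int, m: np.ndarray) -> float:
    return lgamma(n + 1) + sum(lgamma(x + 1) for x in m) - lgamma(2 * n + 1)


def _table_logp(counts: np.ndarray, log_const: float) -> float:
    k = counts.shape[0]
    H = 0
    s = 0.0
    for i in range(k):
        for j in range(i, k):
            nij = counts[i, j]
            s += lgamma(nij + 1)
            if i != j:
                H += nij
    return log_const + H * log(2.0) - s


def _llr(counts: np.ndarray, log_pi: np.ndarray, n: int) -> float:
    """log LR of the table: HWE likelihood minus its own multinomial MLE."""
    k = counts.shape[0]
    t = 0.0
    for i in range(k):
        for j in range(i, k):
            nij = counts[i, j]
            if nij:
                t += nij * (log_pi[i, j] - log(nij / n))
    return t


def _hwe_log_pi(m: np.ndarray, n: int) -> np.ndarray:
    p = m / (2.0 * n)
    k = len(m)
    log_pi = np.full((k, k), -np.inf)
    for i in range(k):
        for j in range(i, k):
            pi = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            log_pi[i, j] = log(pi) if pi > 0 else -np.inf
    return log_pi


class _TooManyTables(Exception):
    pass


def _enumerate_tables(m: np.ndarray, cap: int):
    """Yield all genotype tables with allele margins ``m`` (abort past cap)."""
    k = len(m)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    table = np.zeros((k, k), dtype=int)
    rem = m.astype(int).copy()
    found = 0
    out: list[np.ndarray] = []

    def rec(idx: int) -> None:
        nonlocal found
        if idx == len(pairs):
            if all(r % 2 == 0 for r in rem):
                for i in range(k):
                    table[i, i] = rem[i] // 2
                out.append(table.copy())
                found += 1
                if found > cap:
                    raise _TooManyTables
            return
        i, j = pairs[idx]
        # last pair mentioning allele i -> its remainder must end up even
        last_for_i = (j == k - 1)
        hi = min(rem[i], rem[j])
        for h in range(hi + 1):
            if last_for_i and (rem[i] - h) % 2:
                continue
            table[i, j] = h
            rem[i] -= h
            rem[j] -= h
            rec(idx + 1)
            rem[i] += h
            rem[j] += h
        table[i, j] = 0

    rec(0)
    return out


def _mc_llr_batch(allele_vec: np.ndarray, k: int, reps: int, n: int,
                  log_pi_flat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = np.argsort(rng.random((reps, allele_vec.size)), axis=1)
    perm = allele_vec[idx]
    a = perm[:, 0::2]
    b = perm[:, 1::2]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    cell = lo * k + hi
    flat = cell + (np.arange(reps)[:, None] * (k * k))
    counts = np.bincount(flat.ravel(), minlength=reps * k * k).reshape(reps, k * k)
    term1 = counts @ np.where(np.isfinite(log_pi_flat), log_pi_flat, 0.0)
    term2 = xlogy(counts, counts).sum(axis=1) - n * log(n)
    return term1 - term2


def hwe_exact_test(
    counts: np.ndarray,
    cutoff_tables: float = 1e9,
    mc_reps: int = 1_000_000,
    seed: int = 0,
    max_enum_tables: int = 200_000,
    locus: str | None = None,
) -> HWETestResult:
    """Exact HWE test for one locus from its genotype count matrix.

    Enumeration is used when the number of tables with the observed
    margins does not exceed ``min(cutoff_tables, max_enum_tables)``;
    otherwise ``mc_reps`` tables are sampled from the conditional null.
    ``max_enum_tables`` bounds the enumeration actually attempted (the
    conditional space can run into the billions of tables, far beyond
    what is worth enumerating when sampling gives the same answer).
    """
    counts = np.asarray(counts, dtype=int)
    m = _margins(counts)
    k = len(m)
    alive = m > 0
    if alive.sum() < 2:
        raise MonomorphicLocusError("HWE undefined for a monomorphic locus")
    n = int(counts.sum())
    log_pi = _hwe_log_pi(m, n)
    llr_obs = _llr(counts, log_pi, n)
    g2 = -2.0 * llr_obs

    cap = int(min(cutoff_tables, max_enum_tables))
    tables = None
    try:
        tables = _enumerate_tables(m, cap)
    except _TooManyTables:
        tables = None

    if tables is not None:
        log_const = _log_levene_const(n, m)
        p = 0.0
        for t in tables:
            if _llr(t, log_pi, n) <= llr_obs + _TIE_TOL:
                p += np.exp(_table_logp(t, log_const))
        return HWETestResult(locus, float(min(p, 1.0)), "enumeration", len(tables), g2)

    # Monte Carlo: random pairing of the allele vector
    rng = np.random.default_rng(seed)
    allele_vec = np.repeat(np.arange(k), m)
    hits = 0
    done = 0
    chunk = 20_000
    log_pi_flat = log_pi.ravel()
    while done < mc_reps:
        r = min(chunk, mc_reps - done)
        llrs = _mc_llr_batch(allele_vec, k, r, n, log_pi_flat, rng)
        hits += int((llrs <= llr_obs + _TIE_TOL).sum())
        done += r
    p = (1 + hits) / (mc_reps + 1)
    return HWETestResult(locus, float(p), "monte_carlo", mc_reps, g2)


def hwe_test_locus(gm: GenotypeMatrix, locus_id: str, subset=None,
                   **kwargs) -> HWETestResult:
    """Convenience wrapper: build genotype counts for a locus and test."""
    c = genotype_counts(gm, locus_id, subset)
    return hwe_exact_test(c, locus=locus_id, **kwargs)
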