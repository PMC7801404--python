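"""Per-locus and per-cluster genetic diversity summaries.

He is Nei's unbiased expected heterozygosity,
``He_l = 2n/(2n-1) * (1 - sum_a p_a^2)`` with ``n`` the individuals typed
at the locus; Ho is the observed heterozygote fraction; A the number of
distinct alleles.  Summaries over loci report mean and SE = sd/sqrt(L).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hwe import MonomorphicLocusError, hwe_test_locus
from .matrix import AlleleFrequencies, GenotypeMatrix, allele_frequencies


@dataclass
class DiversitySummary:
    cluster: str
    n_individuals: int
    he_mean: float
    he_se: float
    ho_mean: float
    ho_se: float
    a_mean: float
    a_se: float
    n_hwe: int | None  # loci with exact-test p < 0.05 (None when skipped)


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    L = len(values)
    if L == 0:
        return float("nan"), float("nan")
    se = float(np.std(values, ddof=1) / np.sqrt(L)) if L > 1 else float("nan")
    return float(values.mean()), se


def expected_het_unbiased(freqs: AlleleFrequencies) -> tuple[pd.Series, float, float]:
    """Nei unbiased He per locus, plus the mean and SE over loci.

    Loci with fewer than two typed individuals are excluded with a warning
    (the unbiased correction 2n/(2n-1) needs n >= 2... at n = 1 the
    statistic is degenerate).
    """
    out = {}
    for lid, f in freqs.freqs.items():
        n = freqs.n_typed.get(lid, 0)
        if n < 2:
            warnings.warn(f"locus {lid!r}: fewer than 2 typed individuals; excluded from He")
            continue
        p = np.array(list(f.values()), dtype=float)
        he = (2 * n / (2 * n - 1)) * (1.0 - float((p ** 2).sum())) if p.size else np.nan
        out[lid] = he
    series = pd.Series(out, name="He")
    mean, se = _mean_se(series.to_numpy())
    return series, mean, se


def observed_het(gm: GenotypeMatrix, subset: Iterable[str] | None = None
                 ) -> tuple[pd.Series, float, float]:
    """Observed heterozygosity per locus (het count / typed count)."""
    rows = gm.sample_index(subset)
    het = gm.het_mask()[rows]
    typed = ~gm.missing_mask()[rows]
    out = {}
    for l, lid in enumerate(gm.locus_ids):
        n = int(typed[:, l].sum())
        if n == 0:
            warnings.warn(f"locus {lid!r}: no typed individuals in subset; excluded from Ho")
            continue
        out[lid] = float(het[:, l].sum() / n)
    series = pd.Series(out, name="Ho")
    mean, se = _mean_se(series.to_numpy())
    return series, mean, se


def mean_alleles(gm: GenotypeMatrix, subset: Iterable[str] | None = None
                 ) -> tuple[pd.Series, float, float]:
    """Number of distinct alleles observed per locus in the subset."""
    counts = gm.n_alleles_per_locus(subset)
    series = pd.Series(counts.astype(float), index=gm.locus_ids, name="A")
    series = series[series > 0]
    mean, se = _mean_se(series.to_numpy())
    return series, mean, se


def count_hwe_departures(
    gm: GenotypeMatrix,
    subset: Sequence[str] | None = None,
    alpha: float = 0.05,
    cutoff_tables: float = 1e9,
    mc_reps: int = 100_000,
    seed: int = 0,
    max_enum_tables: int = 200_000,
) -> tuple[int, pd.Series]:
    """Number of loci departing from HWE at ``alpha`` (per-locus, uncorrected).

    Loci monomorphic within the subset are not testable and do not count.
    Returns the count and the per-locus p-value series.
    """
    pvals = {}
    for j, lid in enumerate(gm.locus_ids):
        try:
            res = hwe_test_locus(gm, lid, subset, cutoff_tables=cutoff_tables,
                                 mc_reps=mc_reps, seed=seed + j,
                                 max_enum_tables=max_enum_tables)
        except MonomorphicLocusError:
            continue
        pvals[lid] = res.p_value
    series = pd.Series(pvals, name="hwe_p")
    return int((series < alpha).sum()), series


def diversity_table(
    gm: GenotypeMatrix,
    cluster_assignments: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    hwe: bool = True,
    cutoff_tables: float = 1e9,
    mc_reps: int = 100_000,
    seed: int = 0,
    max_enum_tables: int = 200_000,
) -> pd.DataFrame:
    """One diversity row per cluster: N, He, Ho, A (mean +/- SE) and N_HWE.

    ``cluster_assignments`` maps a cluster label to its member sample ids;
    clusters with fewer than two members get diversity but no HWE count.
    """
    rows = []
    for label, ids in cluster_assignments.items():
        ids = list(ids)
        if not ids:
            continue
        freqs = allele_frequencies(gm, ids)
        _, he_m, he_se = expected_het_unbiased(freqs)
        _, ho_m, ho_se = observed_het(gm, ids)
        _, a_m, a_se = mean_alleles(gm, ids)
        n_hwe: int | None = None
        if hwe and len(ids) >= 2:
            n_hwe, _ = count_hwe_departures(gm, ids, alpha, cutoff_tables,
                                            mc_reps, seed, max_enum_tables)
        elif hwe:
            warnings.warn(f"cluster {label!r}: fewer than 2 individuals; HWE skipped")
        rows.append(DiversitySummary(label, len(ids), he_m, he_se, ho_m, ho_se,
                                     a_m, a_se, n_hwe))
    return pd.DataFrame([r.__dict__ for r in rows])
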