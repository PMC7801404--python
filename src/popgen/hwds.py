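"""Geographic travelling-window scan of diversity, HWE, membership, F and Ne.

Samples are projected onto a geographic axis, ordered along it, and a
window of fixed size (default 30 geographically consecutive genotypes)
slides one genotype at a time.  For each window the scan reports mean
He/Ho, the number of loci out of Hardy–Weinberg equilibrium, the mean
membership to a designated cluster, an inbreeding summary and the LD
effective population size, giving a spatial profile of how (and where)
the population departs from random mating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import count_hwe_departures, expected_het_unbiased, observed_het
from .geo import project_on_axis
from .inbreeding import estimate_all
from .matrix import AlleleFrequencies, GenotypeMatrix, SampleMetadata, allele_frequencies
from .ne import ld_ne
from .cluster import ClusterModel


@dataclass
class TravellingWindow:
    index: int
    member_ids: list[str]
    axis_km: float                 # median member projection
    he_mean: float
    ho_mean: float
    n_loci_out_of_hwe: int | None
    mean_q: float | None
    f_median: float
    f_iqr: float
    f_mean: float
    ne: float | None
    ne_ci_low: float | None
    ne_ci_high: float | None
    se_unreliable: bool


def travelling_windows(ordered_ids: list[str], size: int = 30, step: int = 1
                       ) -> list[list[str]]:
    """Index sets of consecutive samples: positions 1..(n-size+1) by ``step``."""
    n = len(ordered_ids)
    if n < size:
        raise ValueError(f"{n} samples < window size {size}; reduce the window size")
    return [ordered_ids[s:s + size] for s in range(0, n - size + 1, step)]


def order_along_axis(metadata: SampleMetadata, ids: list[str],
                     axis_start: tuple[float, float],
                     axis_end: tuple[float, float]) -> tuple[list[str], pd.Series]:
    """Samples sorted by axis projection (km); ties broken by sample id."""
    coords = metadata.coords(ids)
    pos = project_on_axis(coords, axis_start, axis_end)
    series = pd.Series(pos, index=ids, name="axis_km")
    ordered = sorted(ids, key=lambda s: (series[s], s))
    return ordered, series


def hwds_profile(
    gm: GenotypeMatrix,
    metadata: SampleMetadata,
    axis_start: tuple[float, float],
    axis_end: tuple[float, float],
    cluster_model: ClusterModel | None = None,
    designated_cluster: int | None = None,
    subset: list[str] | None = None,
    window_size: int = 30,
    step: int = 1,
    inbreeding_freqs: AlleleFrequencies | None = None,
    hwe_alpha: float = 0.05,
    hwe_mc_reps: int = 20_000,
    hwe_max_enum: int = 5_000,
    ne_cutoff: float = 0.02,
    seed: int = 0,
) -> list[TravellingWindow]:
    """Run the travelling-window scan and return one record per window.

    Inbreeding is estimated by the ML estimator against
    ``inbreeding_freqs`` (whole analysed subset by default, so window
    values are comparable along the axis).  ``se_unreliable`` flags
    windows whose Ne point estimate or CI is infinite/undefined.
    """
    ids = subset if subset is not None else list(gm.sample_ids)
    ordered, axis_pos = order_along_axis(metadata, ids, axis_start, axis_end)
    if inbreeding_freqs is None:
        inbreeding_freqs = allele_frequencies(gm, ids)
    f_all = estimate_all(gm.subset_samples(ordered), inbreeding_freqs, "ml")
    q_col = None
    if cluster_model is not None:
        if designated_cluster is None:
            raise ValueError("designated_cluster required when a cluster model is given")
        q_col = pd.Series(cluster_model.q[:, designated_cluster],
                          index=cluster_model.sample_ids)

    windows = travelling_windows(ordered, window_size, step)
    out: list[TravellingWindow] = []
    for w_idx, members in enumerate(windows):
        freqs = allele_frequencies(gm, members)
        _, he_m, _ = expected_het_unbiased(freqs)
        _, ho_m, _ = observed_het(gm, members)
        polymorphic = int((gm.n_alleles_per_locus(members) > 1).sum())
        n_hwe, _ = count_hwe_departures(gm, members, hwe_alpha,
                                        mc_reps=hwe_mc_reps,
                                        max_enum_tables=hwe_max_enum,
                                        seed=seed + 10_000 * w_idx)
        f_vals = f_all.loc[members].to_numpy()
        ne = ne_lo = ne_hi = None
        unreliable = True
        if polymorphic >= 2:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est = ld_ne(gm, members, freq_cutoff=ne_cutoff)
                ne, ne_lo, ne_hi = est.ne, est.ci_low, est.ci_high
                unreliable = not (np.isfinite(est.ne) and np.isfinite(est.ci_high))
            except ValueError:
                warnings.warn(f"window {w_idx}: Ne not computable; skipped")
        else:
            warnings.warn(f"window {w_idx}: fewer than 2 polymorphic loci; Ne skipped")
        out.append(TravellingWindow(
            index=w_idx, member_ids=list(members),
            axis_km=float(np.median(axis_pos.loc[members])),
            he_mean=he_m, ho_mean=ho_m, n_loci_out_of_hwe=n_hwe,
            mean_q=float(q_col.loc[members].mean()) if q_col is not None else None,
            f_median=float(np.median(f_vals)),
            f_iqr=float(np.percentile(f_vals, 75) - np.percentile(f_vals, 25)),
            f_mean=float(f_vals.mean()),
            ne=ne, ne_ci_low=ne_lo, ne_ci_high=ne_hi, se_unreliable=unreliable,
        ))
    return out


def profile_table(windows: list[TravellingWindow]) -> pd.DataFrame:
    """Flatten a list of windows to a plot-ready table (one row per window)."""
    rows = []
    for w in windows:
        d = dict(w.__dict__)
        d["member_ids"] = ";".join(d["member_ids"])
        rows.append(d)
    return pd.DataFrame(rows)
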