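"""Synthetic genotype generators for structured, inbred and drifting populations.

Three generators cover the data shapes the analysis pipeline consumes:

* :func:`simulate_structured_pop` — K geographic clusters along a NW-SE
  axis with Balding–Nichols drift between clusters, per-individual
  inbreeding, and a controllable fraction of migrants.
* :func:`simulate_inbred_cohorts` — cohorts of individuals at fixed true
  inbreeding levels, drawn from given allele frequencies (the harness for
  estimator bias/precision studies).
* :func:`simulate_wright_fisher` — a constant-size discrete-generation
  random-mating population with unlinked loci (the harness for validating
  linkage-disequilibrium effective-size estimation).

All randomness flows through one seeded :class:`numpy.random.Generator`;
identical seeds give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, AlleleFrequencies, GenotypeMatrix, SampleMetadata

#: Default cluster centres (lat, lon): an Ionian colony west of the
#: mainland, then a NW-to-SE transect through the Aegean (northern
#: Sporades -> Dodecanese), mirroring a three-cluster island population.
DEFAULT_CENTERS = [(38.4, 20.6), (39.2, 23.9), (36.4, 27.0)]


@dataclass
class SimulationConfig:
    """Parameters for a structured-population simulation.

    Defaults portray a small, genetically depauperate pinniped
    population: 86 individuals in three uneven clusters (5/34/47), 26
    microsatellite loci with 2–5 alleles each and expected heterozygosity
    around 0.35, moderate cluster differentiation, an inbreeding gradient
    rising toward the south-east, and a small migrant fraction.

    ``fst_target`` controls between-cluster drift under the
    Balding–Nichols model; ``inbreeding_profile`` may be a scalar F for
    all individuals, a per-cluster list, or a full per-individual array.
    ``inbreeding_profile`` of ``None`` applies a west-to-east gradient,
    F rising linearly from 0.03 in the first cluster to 0.11 in the last.
    ``alleles_per_locus`` of ``None`` draws 2–5 alleles per locus;
    ancestral frequencies then come from a sparse Dirichlet
    (concentration ``ancestral_concentration``), which keeps most loci
    dominated by one or two alleles, as in low-diversity marker panels.
    """

    n_clusters: int = 3
    cluster_sizes: list[int] = field(default_factory=lambda: [5, 34, 47])
    n_loci: int = 26
    alleles_per_locus: int | None = None
    ancestral_freqs: AlleleFrequencies | None = None
    ancestral_concentration: float = 0.18
    fst_target: float = 0.15
    inbreeding_profile: float | list[float] | np.ndarray | None = None
    migrant_fraction: float = 0.08
    cluster_centers: list[tuple[float, float]] | None = None
    jitter_km: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("K must be >= 1")
        if not (0.0 <= self.fst_target < 1.0):
            raise ValueError("fst_target must lie in [0, 1)")
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValueError("cluster_sizes length must equal n_clusters")
        if not (0.0 <= self.migrant_fraction < 1.0):
            raise ValueError("migrant_fraction must lie in [0, 1)")


def _ancestral_freqs(cfg: SimulationConfig, rng: np.random.Generator) -> list[np.ndarray]:
    if cfg.ancestral_freqs is not None:
        out = [np.array(list(f.values()), dtype=float)
               for f in cfg.ancestral_freqs.freqs.values() if f]
        if not out:
            raise ValueError("empty ancestral frequency map")
        return out
    out = []
    for _ in range(cfg.n_loci):
        if cfg.alleles_per_locus is None:
            k = int(rng.integers(2, 6))
            p = rng.dirichlet(np.full(k, cfg.ancestral_concentration))
            # avoid effectively monomorphic ancestral loci
            while p.max() > 0.95:
                p = rng.dirichlet(np.full(k, cfg.ancestral_concentration))
        else:
            k = cfg.alleles_per_locus
            p = rng.dirichlet(np.ones(k))
        out.append(p)
    return out


def _cluster_freqs(p_anc: list[np.ndarray], K: int, fst: float,
                   rng: np.random.Generator) -> list[list[np.ndarray]]:
    """Balding–Nichols: cluster freqs ~ Dirichlet(p_anc (1-FST)/FST)."""
    if fst <= 0.0:
        return [[p.copy() for p in p_anc] for _ in range(K)]
    conc = (1.0 - fst) / fst
    out = []
    for _ in range(K):
        drawn = []
        for p in p_anc:
            alpha = np.maximum(p * conc, 1e-6)
            drawn.append(rng.dirichlet(alpha))
        out.append(drawn)
    return out


def _draw_genotype(freq: np.ndarray, F: float, rng: np.random.Generator) -> tuple[int, int]:
    """One diploid call: with prob F the two alleles are identical by descent."""
    if F > 0 and rng.random() < F:
        a = rng.choice(len(freq), p=freq)
        return int(a), int(a)
    a, b = rng.choice(len(freq), size=2, p=freq)
    return int(a), int(b)


def _draw_cohort(freqs: list[np.ndarray], F: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorised genotype draw; ``F`` is per-individual. Returns (n, L, 2)."""
    n = len(F)
    L = len(freqs)
    codes = np.empty((n, L, 2), dtype=np.int32)
    ibd = rng.random((n, L)) < F[:, None]
    for l, p in enumerate(freqs):
        k = len(p)
        cum = np.cumsum(p)
        u = rng.random((n, 2))
        draw = np.searchsorted(cum, u, side="right").clip(0, k - 1)
        draw[ibd[:, l], 1] = draw[ibd[:, l], 0]
        codes[:, l, :] = draw
    return codes


def _offset_latlon(center: tuple[float, float], dx_km: np.ndarray,
                   dy_km: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lat = center[0] + dy_km / 111.2
    lon = center[1] + dx_km / (111.2 * np.cos(np.radians(center[0])))
    return lat, lon


def simulate_structured_pop(cfg: SimulationConfig) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Simulate a K-cluster population; truth columns ride in the metadata.

    The metadata table carries, besides the standard covariates, the truth
    columns ``true_cluster`` (genetic origin), ``true_F`` and ``is_migrant``.
    Migrants draw their genotype from a foreign cluster's frequencies but
    keep home coordinates and region label.
    """
    rng = np.random.default_rng(cfg.seed)
    p_anc = _ancestral_freqs(cfg, rng)
    L = len(p_anc)
    K = cfg.n_clusters
    cluster_p = _cluster_freqs(p_anc, K, cfg.fst_target, rng)
    centers = cfg.cluster_centers or [DEFAULT_CENTERS[k % len(DEFAULT_CENTERS)]
                                      for k in range(K)]
    if K > 3 and cfg.cluster_centers is None:
        # spread extra clusters along the default transect
        lats = np.linspace(DEFAULT_CENTERS[0][0], DEFAULT_CENTERS[-1][0], K)
        lons = np.linspace(DEFAULT_CENTERS[0][1], DEFAULT_CENTERS[-1][1], K)
        centers = list(zip(lats, lons))

    n_total = sum(cfg.cluster_sizes)
    home = np.repeat(np.arange(K), cfg.cluster_sizes)
    profile = cfg.inbreeding_profile
    if profile is None:
        profile = np.linspace(0.03, 0.11, K) if K > 1 else 0.03
    F = np.asarray(profile, dtype=float)
    if F.ndim == 0:
        F = np.full(n_total, float(F))
    elif F.shape == (K,):
        F = F[home]
    elif F.shape != (n_total,):
        raise ValueError("inbreeding_profile must be scalar, per-cluster or per-individual")

    origin = home.copy()
    is_migrant = np.zeros(n_total, dtype=bool)
    if cfg.migrant_fraction > 0 and K > 1:
        mig = rng.random(n_total) < cfg.migrant_fraction
        for i in np.nonzero(mig)[0]:
            others = [k for k in range(K) if k != home[i]]
            origin[i] = rng.choice(others)
        is_migrant = mig

    codes = np.empty((n_total, L, 2), dtype=np.int32)
    for k in range(K):
        rows = np.nonzero(origin == k)[0]
        if rows.size:
            codes[rows] = _draw_cohort(cluster_p[k], F[rows], rng)

    sample_ids = [f"ind{i:03d}" for i in range(n_total)]
    locus_ids = [f"loc{l:02d}" for l in range(L)]
    alleles = [[str(100 + 2 * a) for a in range(len(p))] for p in p_anc]
    gm = GenotypeMatrix(sample_ids, locus_ids, codes, alleles)

    dx = rng.normal(0.0, cfg.jitter_km, n_total)
    dy = rng.normal(0.0, cfg.jitter_km, n_total)
    lat = np.empty(n_total)
    lon = np.empty(n_total)
    for k in range(K):
        rows = home == k
        lat[rows], lon[rows] = _offset_latlon(centers[k], dx[rows], dy[rows])
    sexes = rng.choice(["female", "male"], n_total)
    meta = pd.DataFrame({
        "sex": sexes,
        "age_class": "adult",
        "latitude": np.clip(lat, -90, 90),
        "longitude": np.clip(lon, -180, 180),
        "region": [f"region{k}" for k in home],
        "year": 2000,
        "true_cluster": origin,
        "true_F": F,
        "is_migrant": is_migrant,
    }, index=pd.Index(sample_ids, name="sample_id"))
    return gm, SampleMetadata(meta)


def simulate_inbred_cohorts(
    freqs: AlleleFrequencies,
    levels: np.ndarray | list[float] | None = None,
    n_per_level: int = 100,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.Series]:
    """Cohorts of ``n_per_level`` individuals at each true inbreeding level.

    Defaults reproduce a 20-level design, F = 0.05 ... 1.00 in steps of
    0.05 with 100 individuals per level.  Returns the genotypes and a
    Series of true F indexed by sample id.
    """
    if levels is None:
        levels = np.round(np.arange(0.05, 1.0001, 0.05), 2)
    levels = np.asarray(levels, dtype=float)
    if ((levels < 0) | (levels > 1)).any():
        raise ValueError("inbreeding levels must lie in [0, 1]")
    locus_ids = [l for l in freqs.loci() if freqs.freqs[l]]
    if not locus_ids:
        raise ValueError("empty frequency map")
    rng = np.random.default_rng(seed)
    p_list = [np.array(list(freqs.freqs[l].values()), dtype=float) for l in locus_ids]
    labels = [list(freqs.freqs[l].keys()) for l in locus_ids]

    F = np.repeat(levels, n_per_level)
    codes = _draw_cohort(p_list, F, rng)
    sample_ids = [f"F{lev:.2f}_{j:03d}" for lev in levels for j in range(n_per_level)]
    gm = GenotypeMatrix(sample_ids, locus_ids, codes, labels)
    truth = pd.Series(F, index=pd.Index(sample_ids, name="sample_id"), name="true_F")
    return gm, truth


def simulate_wright_fisher(
    ne_true: int,
    n_generations: int,
    sample_size: int,
    n_loci: int = 40,
    alleles_per_locus: int = 2,
    seed: int = 0,
    init_freqs: list[np.ndarray] | None = None,
) -> GenotypeMatrix:
    """Constant-size random-mating Wright–Fisher population, unlinked loci.

    Each generation every offspring picks two parents uniformly at random
    (monoecious, selfing allowed) and receives one random allele per locus
    from each.  The final generation is sampled for ``sample_size``
    diploids (without replacement when possible).
    """
    if ne_true < 2:
        raise ValueError("ne_true must be >= 2")
    rng = np.random.default_rng(seed)
    N, L = int(ne_true), int(n_loci)
    if init_freqs is None:
        init_freqs = [np.full(alleles_per_locus, 1.0 / alleles_per_locus)] * L
    pop = np.empty((N, L, 2), dtype=np.int32)
    for l, p in enumerate(init_freqs):
        pop[:, l, :] = rng.choice(len(p), size=(N, 2), p=p)

    ar = np.arange(L)
    for _ in range(n_generations):
        new = np.empty_like(pop)
        for copy in range(2):
            parents = rng.integers(N, size=N)
            pick = rng.integers(2, size=(N, L))
            new[:, :, copy] = pop[parents[:, None], ar[None, :], pick]
        pop = new

    S = int(sample_size)
    if S > N:
        warnings.warn("sample_size exceeds ne_true; sampling with replacement")
        rows = rng.integers(N, size=S)
    else:
        rows = rng.choice(N, size=S, replace=False)
    sample = pop[rows]
    sample_ids = [f"wf{i:03d}" for i in range(S)]
    locus_ids = [f"loc{l:02d}" for l in range(L)]
    alleles = [[str(100 + 2 * a) for a in range(len(p))] for p in init_freqs]
    return GenotypeMatrix(sample_ids, locus_ids, sample, alleles)
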