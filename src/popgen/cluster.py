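"""Bayesian admixture clustering by Gibbs sampling, K selection, migrant calls.

The model is the classic admixture mixture: each allele copy of
individual ``i`` originates from cluster ``k`` with probability ``q_ik``
and is then an i.i.d. draw from that cluster's allele frequencies.  The
sampler alternates

1. allele-copy origins  z ~ Categorical(q_ik * p_k,l,a),
2. cluster frequencies  p_k,l ~ Dirichlet(lambda + origin counts),
3. membership rows      q_i ~ Dirichlet(alpha + origin counts),

and records the data log-likelihood each sweep.  Posterior means and 90%
equal-tailed intervals of ``q`` come from post-burn-in samples.  An
optional per-individual Dirichlet prior on ``q`` lets sampling regions
inform membership (a light-weight analogue of location-informed priors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from math import lgamma as _lgamma

from .matrix import MISSING, GenotypeMatrix, SampleMetadata


@dataclass
class ClusterModel:
    K: int
    sample_ids: list[str]
    q: np.ndarray                  # (n, K) posterior mean membership
    q_ci_low: np.ndarray           # (n, K) 5th percentile
    q_ci_high: np.ndarray          # (n, K) 95th percentile
    cluster_freqs: list[np.ndarray]  # per cluster: list over loci of freq vectors
    loglik_trace: np.ndarray
    seed: int
    settings: dict = field(default_factory=dict)

    @property
    def mean_loglik(self) -> float:
        return float(self.loglik_trace.mean())

    @property
    def ln_prob_data(self) -> float:
        """Model-evidence estimate L(K): E[ln L] - Var[ln L] / 2.

        The variance term penalises poorly fitting or overparameterised
        models whose likelihood wanders; this is the quantity replicate
        runs are compared on when choosing K.
        """
        return float(self.loglik_trace.mean() - self.loglik_trace.var() / 2.0)


@dataclass
class MigrantCall:
    sample_id: str
    region: str
    assigned_cluster: int | None   # None = unassigned
    q_assigned: float
    status: str                    # resident | migrant | unassigned


def fit_admixture(
    gm: GenotypeMatrix,
    K: int,
    burn_in: int = 50_000,
    reps: int = 200_000,
    alpha_prior: float | np.ndarray = 1.0,
    seed: int = 0,
    freq_lambda: float = 1.0,
    n_kept_samples: int = 400,
    infer_alpha: bool = True,
) -> ClusterModel:
    """Fit the admixture model with ``K`` clusters by Gibbs sampling.

    ``reps`` counts total sweeps including ``burn_in``; at most
    ``n_kept_samples`` evenly spaced post-burn-in q samples are retained
    for the posterior summaries.  ``alpha_prior`` may be a scalar
    (symmetric Dirichlet on each q row, the starting value when
    ``infer_alpha``) or an ``(n, K)`` array of per-individual prior
    weights (e.g. region-informed priors; disables alpha inference).

    With ``infer_alpha`` (the default, and only for scalar priors) the
    admixture parameter alpha is given a uniform prior on (0, 10] and
    updated each sweep by a lognormal-proposal Metropolis step, so weakly
    admixed data drive alpha small and memberships crisp.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if reps <= burn_in:
        raise ValueError("reps must exceed burn_in")
    rng = np.random.default_rng(seed)
    n, L = gm.n_samples, gm.n_loci
    kmax = max(len(a) for a in gm.alleles)
    X = gm.codes.copy()
    observed = X[:, :, 0] != MISSING
    X[~observed] = 0  # placeholder; masked out of all counts
    obs3 = np.repeat(observed[:, :, None], 2, axis=2)

    valid = np.zeros((L, kmax), dtype=bool)
    for l in range(L):
        valid[l, :len(gm.alleles[l])] = True

    alpha_arr = np.asarray(alpha_prior, dtype=float)
    if alpha_arr.ndim == 0:
        alpha_scalar = float(alpha_arr)
        alpha = np.full((n, K), alpha_scalar)
    elif alpha_arr.shape == (n, K):
        alpha = alpha_arr.copy()
        infer_alpha = False
        alpha_scalar = float("nan")
    else:
        raise ValueError("alpha_prior must be scalar or (n, K)")

    # init
    q = rng.dirichlet(np.ones(K), size=n)
    p = rng.dirichlet(np.ones(kmax), size=(K, L)) * valid[None, :, :]
    p /= p.sum(axis=2, keepdims=True)

    l_idx = np.arange(L)[None, :, None]
    kept_q: list[np.ndarray] = []
    keep_every = max(1, (reps - burn_in) // max(n_kept_samples, 1))
    loglik = np.empty(reps - burn_in)
    p_sum = np.zeros_like(p)
    p_count = 0

    for sweep in range(reps):
        # 1. weights and origins
        pg = p[:, l_idx, X]                       # (K, n, L, 2)
        w = np.moveaxis(pg, 0, -1) * q[:, None, None, :]  # (n, L, 2, K)
        tot = w.sum(axis=-1, keepdims=True)
        tot[tot == 0] = 1.0
        u = rng.random((n, L, 2, 1)) * tot
        z = (w.cumsum(axis=-1) < u).sum(axis=-1)  # (n, L, 2) in 0..K-1

        # 2. cluster frequencies
        flat = (z * (L * kmax) + np.arange(L)[None, :, None] * kmax + X)[obs3]
        counts_p = np.bincount(flat.ravel(), minlength=K * L * kmax).reshape(K, L, kmax)
        g = rng.gamma(freq_lambda + counts_p)
        g *= valid[None, :, :]
        p = g / g.sum(axis=2, keepdims=True)

        # 3. membership rows
        flat_q = (np.arange(n)[:, None, None] * K + z)[obs3]
        counts_q = np.bincount(flat_q.ravel(), minlength=n * K).reshape(n, K)
        gq = rng.gamma(alpha + counts_q)
        q = gq / gq.sum(axis=1, keepdims=True)

        if infer_alpha and K > 1:
            # Metropolis step for the admixture parameter (uniform prior (0, 10])
            sum_logq = float(np.log(np.maximum(q, 1e-300)).sum())
            prop = alpha_scalar * np.exp(rng.normal(0.0, 0.3))
            if 0 < prop <= 10.0:
                def _logdens(a: float) -> float:
                    return n * (_lgamma(K * a) - K * _lgamma(a)) + (a - 1.0) * sum_logq
                log_accept = (_logdens(prop) - _logdens(alpha_scalar)
                              + np.log(prop) - np.log(alpha_scalar))
                if np.log(rng.random()) < log_accept:
                    alpha_scalar = prop
                    alpha[:] = alpha_scalar

        if sweep >= burn_in:
            ll_terms = np.log(np.maximum(tot[..., 0], 1e-300))
            loglik[sweep - burn_in] = float(ll_terms[obs3].sum())
            p_sum += p
            p_count += 1
            if (sweep - burn_in) % keep_every == 0:
                kept_q.append(q.copy())

    qs = np.stack(kept_q)                          # (n_samples, n, K)
    q_mean = qs.mean(axis=0)
    # equal-tailed 90% interval, widened where skew would leave the mean out
    ci_low = np.minimum(np.percentile(qs, 5, axis=0), q_mean)
    ci_high = np.maximum(np.percentile(qs, 95, axis=0), q_mean)
    p_mean = p_sum / p_count
    cluster_freqs = [[p_mean[k, l, :len(gm.alleles[l])] for l in range(L)]
                     for k in range(K)]
    return ClusterModel(
        K=K, sample_ids=list(gm.sample_ids), q=q_mean,
        q_ci_low=ci_low, q_ci_high=ci_high,
        cluster_freqs=cluster_freqs, loglik_trace=loglik, seed=seed,
        settings={"burn_in": burn_in, "reps": reps, "alpha_prior": "array"
                  if np.asarray(alpha_prior).ndim else float(alpha_prior),
                  "freq_lambda": freq_lambda, "alpha_final": alpha_scalar},
    )


def align_clusters(q_ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Greedy label-switching fix: permutation mapping ``q`` columns to ``q_ref``.

    Returns ``perm`` such that ``q[:, perm]`` best matches ``q_ref``.
    """
    K = q_ref.shape[1]
    overlap = q_ref.T @ q                    # (K_ref, K)
    perm = np.full(K, -1)
    used_ref, used = set(), set()
    for _ in range(K):
        best = None
        for i in range(K):
            if i in used_ref:
                continue
            for j in range(K):
                if j in used:
                    continue
                if best is None or overlap[i, j] > overlap[best[0], best[1]]:
                    best = (i, j)
        i, j = best
        perm[i] = j
        used_ref.add(i)
        used.add(j)
    return perm


def fit_admixture_replicated(gm: GenotypeMatrix, K: int, n_replicates: int = 5,
                             seed: int = 0, **kwargs) -> tuple[ClusterModel, list[ClusterModel]]:
    """Run several chains (seed + replicate index), align labels, average q.

    Returns a consensus model (mean of aligned posterior q summaries, with
    the pooled log-likelihood trace) plus the individual replicates.
    """
    models = [fit_admixture(gm, K, seed=seed + r, **kwargs) for r in range(n_replicates)]
    ref = models[0]
    qs, los, his = [ref.q], [ref.q_ci_low], [ref.q_ci_high]
    for m in models[1:]:
        perm = align_clusters(ref.q, m.q)
        qs.append(m.q[:, perm])
        los.append(m.q_ci_low[:, perm])
        his.append(m.q_ci_high[:, perm])
    q_mean = np.mean(qs, axis=0)
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    consensus = ClusterModel(
        K=K, sample_ids=ref.sample_ids, q=q_mean,
        q_ci_low=np.mean(los, axis=0), q_ci_high=np.mean(his, axis=0),
        cluster_freqs=ref.cluster_freqs,
        loglik_trace=np.concatenate([m.loglik_trace for m in models]),
        seed=seed, settings={**ref.settings, "n_replicates": n_replicates},
    )
    return consensus, models


def select_k(gm: GenotypeMatrix, k_range, n_replicates: int = 5, seed: int = 0,
             **kwargs) -> tuple[int, pd.DataFrame]:
    """Choose K by the highest mean replicate L(K).

    Runs ``n_replicates`` chains per K and summarises mean and variance of
    L(K) across replicates.  The returned table allows inspection when the
    highest-likelihood K is not also the lowest-variance one (flagged in
    the ``flag`` column).
    """
    rows = []
    for K in k_range:
        lks = []
        for r in range(n_replicates):
            m = fit_admixture(gm, K, seed=seed + 1000 * K + r, **kwargs)
            lks.append(m.ln_prob_data)
        rows.append({"K": K, "mean_LK": float(np.mean(lks)),
                     "var_LK": float(np.var(lks, ddof=1)) if len(lks) > 1 else 0.0})
    table = pd.DataFrame(rows)
    k_star = int(table.loc[table["mean_LK"].idxmax(), "K"])
    k_lowvar = int(table.loc[table["var_LK"].idxmin(), "K"])
    table["flag"] = ""
    if k_star != k_lowvar:
        table.loc[table["K"] == k_star, "flag"] = "highest likelihood, not lowest variance"
        warnings.warn(f"K selection: highest likelihood K={k_star} but lowest "
                      f"variance at K={k_lowvar}; choosing by likelihood")
    return k_star, table


def modal_clusters_by_region(model: ClusterModel, metadata: SampleMetadata
                             ) -> dict[str, int]:
    """Region -> cluster with the highest mean membership among its samples."""
    regions = metadata.table.loc[model.sample_ids, "region"]
    out: dict[str, int] = {}
    for region, ids in regions.groupby(regions).groups.items():
        rows = [model.sample_ids.index(s) for s in ids]
        means = model.q[rows].mean(axis=0)
        top = np.nonzero(means == means.max())[0]
        if len(top) > 1:
            raise ValueError(f"region {region!r}: tie between clusters {top.tolist()}")
        out[str(region)] = int(top[0])
    return out


def classify_migrants(model: ClusterModel, metadata: SampleMetadata,
                      q_threshold: float = 0.8) -> list[MigrantCall]:
    """Assign individuals to clusters and flag cross-region assignments.

    An individual is *assigned* to cluster k when ``q_ik >= q_threshold``
    and the 90% interval of every other cluster's membership stays below
    the threshold (so no alternative cluster could plausibly dominate).
    Assigned individuals whose cluster differs from their sampling
    region's modal cluster are migrants; unassignable ones are recorded
    as ``unassigned``.
    """
    modal = modal_clusters_by_region(model, metadata)
    calls: list[MigrantCall] = []
    for i, sid in enumerate(model.sample_ids):
        region = str(metadata.table.loc[sid, "region"])
        q_i = model.q[i]
        k = int(np.argmax(q_i))
        others_excluded = all(model.q_ci_high[i, j] < q_threshold
                              for j in range(model.K) if j != k)
        if q_i[k] >= q_threshold and others_excluded:
            status = "resident" if k == modal[region] else "migrant"
            calls.append(MigrantCall(sid, region, k, float(q_i[k]), status))
        else:
            calls.append(MigrantCall(sid, region, None, float(q_i[k]), "unassigned"))
    return calls
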