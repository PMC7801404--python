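"""Admixture clustering: recovery of planted structure, K selection, migrants."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import popgen
from popgen import SimulationConfig, fit_admixture, select_k, simulate_structured_pop
from popgen.cluster import (ClusterModel, align_clusters, classify_migrants,
                            fit_admixture_replicated, modal_clusters_by_region)
from popgen.matrix import SampleMetadata

FAST = dict(burn_in=200, reps=1000)


def _mean_q_to_truth(model, truth):
    i = np.arange(len(truth))
    return max(model.q[i, truth].mean(), model.q[i, 1 - truth].mean())


class TestFitAdmixture:
    def test_k1_is_degenerate(self, tiny_gm):
        m = fit_admixture(tiny_gm, 1, burn_in=10, reps=50, seed=0)
        assert np.allclose(m.q, 1.0)
        assert np.allclose(m.q_ci_low, 1.0)

    def test_recovers_planted_two_clusters(self, structured_pop):
        gm, meta = structured_pop
        m = fit_admixture(gm, 2, burn_in=300, reps=1500, seed=1)
        truth = meta.table["true_cluster"].to_numpy()
        assert _mean_q_to_truth(m, truth) > 0.9

    def test_q_rows_sum_to_one_and_ci_brackets_mean(self, structured_pop):
        gm, _ = structured_pop
        m = fit_admixture(gm, 3, seed=2, **FAST)
        assert np.allclose(m.q.sum(axis=1), 1.0, atol=1e-9)
        assert (m.q_ci_low <= m.q + 1e-9).all()
        assert (m.q_ci_high >= m.q - 1e-9).all()
        assert ((m.q_ci_low >= 0) & (m.q_ci_high <= 1)).all()

    def test_k1_likelihood_matches_pooled_multinomial(self, panmictic_pop):
        # with one cluster the model is a plain multinomial over pooled freqs
        gm, _ = panmictic_pop
        m = fit_admixture(gm, 1, burn_in=100, reps=600, seed=3)
        freqs = popgen.allele_frequencies(gm)
        p_arrays = freqs.as_arrays(gm)
        ll = 0.0
        from popgen.matrix import MISSING
        for i in range(gm.n_samples):
            for l in range(gm.n_loci):
                c = gm.codes[i, l]
                if c[0] == MISSING:
                    continue
                ll += np.log(p_arrays[l][c[0]]) + np.log(p_arrays[l][c[1]])
        assert m.mean_loglik == pytest.approx(ll, rel=0.01)

    def test_mean_assignment_sharpens_with_fst(self):
        maxqs = []
        for fst in (0.05, 0.15, 0.3):
            gm, _ = simulate_structured_pop(SimulationConfig(
                n_clusters=2, cluster_sizes=[50, 50], n_loci=26,
                alleles_per_locus=4, fst_target=fst, inbreeding_profile=0.0,
                migrant_fraction=0.0, seed=21))
            m = fit_admixture(gm, 2, seed=4, **FAST)
            maxqs.append(m.q.max(axis=1).mean())
        assert maxqs[0] < maxqs[1] < maxqs[2]


class TestReplicatesAndK:
    def test_label_alignment_across_replicates(self, structured_pop):
        gm, _ = structured_pop
        consensus, models = fit_admixture_replicated(gm, 2, n_replicates=3,
                                                     seed=5, **FAST)
        ref = models[0]
        for m in models[1:]:
            perm = align_clusters(ref.q, m.q)
            assert np.abs(ref.q - m.q[:, perm]).mean() < 0.05

    def test_selects_planted_k2(self, structured_pop):
        gm, _ = structured_pop
        k_star, table = select_k(gm, range(1, 4), n_replicates=3, seed=6, **FAST)
        assert k_star == 2
        assert set(table["K"]) == {1, 2, 3}

    def test_panmixia_selects_k1(self, panmictic_pop):
        gm, _ = panmictic_pop
        k_star, _ = select_k(gm, range(1, 4), n_replicates=3, seed=7, **FAST)
        assert k_star == 1


def _manual_model(q_rows, ci_high_rows):
    q = np.asarray(q_rows, float)
    n, K = q.shape
    return ClusterModel(K=K, sample_ids=[f"s{i}" for i in range(n)], q=q,
                        q_ci_low=np.clip(q - 0.1, 0, 1),
                        q_ci_high=np.asarray(ci_high_rows, float),
                        cluster_freqs=[], loglik_trace=np.zeros(1), seed=0)


def _meta(regions):
    df = pd.DataFrame({"region": regions,
                       "sex": "female", "age_class": "adult",
                       "latitude": 38.0, "longitude": 24.0, "year": 2000},
                      index=pd.Index([f"s{i}" for i in range(len(regions))],
                                     name="sample_id"))
    return SampleMetadata(df)


class TestMigrantRule:
    def test_resident_migrant_unassigned(self):
        model = _manual_model(
            # residents anchoring each region's modal cluster
            [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0],
             # clear cross-assignment sampled in region B
             [0.85, 0.15, 0.0],
             # high q but alternative interval not excluded
             [0.82, 0.18, 0.0],
             # admixed
             [0.5, 0.5, 0.0]],
            [[1.0, 0.05, 0.05], [0.05, 1.0, 0.05], [0.05, 0.05, 1.0],
             [0.95, 0.3, 0.05],
             [0.95, 0.85, 0.05],
             [0.7, 0.7, 0.05]])
        meta = _meta(["A", "B", "C", "B", "A", "A"])
        calls = {c.sample_id: c.status for c in classify_migrants(model, meta)}
        assert calls["s0"] == "resident"
        assert calls["s3"] == "migrant"
        assert calls["s4"] == "unassigned"
        assert calls["s5"] == "unassigned"

    def test_region_tie_is_an_error(self):
        model = _manual_model([[0.5, 0.5], [0.5, 0.5]],
                              [[0.6, 0.6], [0.6, 0.6]])
        with pytest.raises(ValueError, match="tie"):
            modal_clusters_by_region(model, _meta(["A", "A"]))

    def test_recovers_planted_migrants(self):
        gm, meta = simulate_structured_pop(SimulationConfig(
            n_clusters=3, cluster_sizes=[30, 30, 30], n_loci=26,
            alleles_per_locus=4, fst_target=0.2, inbreeding_profile=0.0,
            migrant_fraction=0.1, seed=7))
        model, _ = fit_admixture_replicated(gm, 3, n_replicates=3, seed=2,
                                            burn_in=400, reps=2000)
        called = {c.sample_id for c in classify_migrants(model, meta)
                  if c.status == "migrant"}
        planted = set(meta.table.index[meta.table["is_migrant"]])
        assert len(planted) >= 5
        assert len(planted & called) / len(planted) >= 0.8
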