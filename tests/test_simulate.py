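"""Synthetic-data generators: planted structure, inbreeding, drift."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import spearmanr

import popgen
from popgen import SimulationConfig, simulate_structured_pop


def weir_cockerham_fst(gm, pops) -> float:
    """Independent multi-allelic Weir–Cockerham FST oracle (per-allele sums)."""
    X, _ = gm.dosage_matrix()
    num = den = 0.0
    col = 0
    for l in range(gm.n_loci):
        k = len(gm.alleles[l])
        for a in range(k):
            x = X[:, col + a] * 2  # dosage 0..2
            ok = np.isfinite(x)
            ns, ps, hs = [], [], []
            for pp in np.unique(pops):
                sel = ok & (pops == pp)
                if sel.sum() < 2:
                    continue
                ns.append(sel.sum())
                ps.append(x[sel].mean() / 2)
                hs.append((x[sel] == 1).mean())
            if len(ns) < 2:
                continue
            ns = np.array(ns, float)
            ps = np.array(ps)
            hs = np.array(hs)
            r = len(ns)
            nbar = ns.mean()
            pbar = (ns * ps).sum() / ns.sum()
            hbar = (ns * hs).sum() / ns.sum()
            nc = (ns.sum() - (ns ** 2).sum() / ns.sum()) / (r - 1)
            s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
            A = pbar * (1 - pbar) - (r - 1) / r * s2
            av = nbar / nc * (s2 - (A - 0.25 * hbar) / (nbar - 1))
            bv = nbar / (nbar - 1) * (A - (2 * nbar - 1) / (4 * nbar) * hbar)
            cv = 0.5 * hbar
            num += av
            den += av + bv + cv
        col += k
    return num / den


class TestStructuredPop:
    def test_fst_matches_target(self):
        gm, meta = simulate_structured_pop(SimulationConfig(
            n_clusters=2, cluster_sizes=[200, 200], n_loci=26,
            alleles_per_locus=4, fst_target=0.2, inbreeding_profile=0.0,
            migrant_fraction=0.0, seed=11))
        fst = weir_cockerham_fst(gm, meta.table["true_cluster"].to_numpy())
        assert fst == pytest.approx(0.2, abs=0.05)

    def test_no_structure_limit(self):
        gm, meta = simulate_structured_pop(SimulationConfig(
            n_clusters=2, cluster_sizes=[150, 150], n_loci=26,
            alleles_per_locus=4, fst_target=0.0, inbreeding_profile=0.0,
            migrant_fraction=0.0, seed=12))
        fst = weir_cockerham_fst(gm, meta.table["true_cluster"].to_numpy())
        assert abs(fst) < 0.02

    def test_same_seed_is_bit_identical(self):
        a, ma = simulate_structured_pop(SimulationConfig(seed=5))
        b, mb = simulate_structured_pop(SimulationConfig(seed=5))
        assert np.array_equal(a.codes, b.codes)
        assert ma.table.equals(mb.table)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(fst_target=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_clusters=0, cluster_sizes=[])

    def test_default_emulates_low_diversity_panel(self):
        gm, meta = simulate_structured_pop(SimulationConfig(seed=1))
        assert gm.n_samples == 86 and gm.n_loci == 26
        ks = gm.n_alleles_per_locus()
        assert ks.max() <= 5
        _, he, _ = popgen.expected_het_unbiased(popgen.allele_frequencies(gm))
        assert 0.25 < he < 0.45  # genetically depauperate regime


class TestInbredCohorts:
    def test_default_design_is_20x100(self, panmictic_pop):
        gm, _ = panmictic_pop
        freqs = popgen.allele_frequencies(gm)
        cohort, truth = popgen.simulate_inbred_cohorts(freqs, seed=1)
        assert cohort.n_samples == 2000
        assert sorted(truth.unique()) == pytest.approx(
            list(np.round(np.arange(0.05, 1.0001, 0.05), 2)))
        assert (truth.value_counts() == 100).all()

    def test_f1_forces_homozygosity(self, panmictic_pop):
        gm, _ = panmictic_pop
        freqs = popgen.allele_frequencies(gm)
        cohort, _ = popgen.simulate_inbred_cohorts(freqs, levels=[1.0],
                                                   n_per_level=50, seed=2)
        assert not cohort.het_mask().any()

    def test_het_fraction_at_half_f(self, panmictic_pop):
        gm, _ = panmictic_pop
        freqs = popgen.allele_frequencies(gm)
        cohort, _ = popgen.simulate_inbred_cohorts(freqs, levels=[0.5],
                                                   n_per_level=200, seed=3)
        p_arrays = freqs.as_arrays(cohort)
        exp_het_per_locus = np.array([(1 - (p ** 2).sum()) for p in p_arrays])
        expected = 0.5 * exp_het_per_locus.mean()
        observed = cohort.het_mask().mean()
        n_calls = cohort.n_samples * cohort.n_loci
        se = np.sqrt(expected * (1 - expected) / n_calls)
        assert abs(observed - expected) < 3 * se + 1e-3

    def test_heterozygosity_monotone_in_f(self, panmictic_pop):
        gm, _ = panmictic_pop
        freqs = popgen.allele_frequencies(gm)
        cohort, truth = popgen.simulate_inbred_cohorts(freqs, n_per_level=100, seed=4)
        het_per_ind = cohort.het_mask().mean(axis=1)
        level_means = [het_per_ind[(truth == lev).to_numpy()].mean()
                       for lev in sorted(truth.unique())]
        rho, _ = spearmanr(sorted(truth.unique()), level_means)
        assert rho < -0.9

    def test_empty_frequency_map_rejected(self):
        from popgen.matrix import AlleleFrequencies
        with pytest.raises(ValueError, match="empty"):
            popgen.simulate_inbred_cohorts(AlleleFrequencies({}, {}), seed=0)


class TestWrightFisher:
    def test_heterozygosity_decay_rate(self):
        hets = []
        gens = [0, 20, 40, 60, 80, 100]
        for g in gens:
            gm = popgen.simulate_wright_fisher(50, g, 50, n_loci=300, seed=5)
            hets.append(gm.het_mask().mean())
        slope = np.polyfit(gens, np.log(hets), 1)[0]
        expected = np.log(1 - 1 / 100)  # (1 - 1/2Ne) per generation
        assert slope == pytest.approx(expected, rel=0.10)

    def test_no_drift_limit_gives_no_ld_signal(self):
        from popgen.ne import burrows_r2, _expected_r2
        deltas = []
        for rep in range(30):
            gm = popgen.simulate_wright_fisher(20_000, 2, 50, n_loci=20,
                                               seed=100 + rep)
            b = burrows_r2(gm, freq_cutoff=0.02)
            deltas.append(b.mean_r2 - _expected_r2(b.s_harmonic))
        assert abs(np.mean(deltas)) < 1.5e-3

    def test_determinism_and_oversampling_warning(self):
        a = popgen.simulate_wright_fisher(30, 5, 20, n_loci=10, seed=7)
        b = popgen.simulate_wright_fisher(30, 5, 20, n_loci=10, seed=7)
        assert np.array_equal(a.codes, b.codes)
        with pytest.warns(UserWarning, match="replacement"):
            popgen.simulate_wright_fisher(10, 2, 20, n_loci=5, seed=8)
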