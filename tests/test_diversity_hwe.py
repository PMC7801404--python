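"""Diversity statistics and the exact Hardy–Weinberg test."""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import factorial, log

import numpy as np
import pytest

import popgen
from popgen import GenotypeMatrix, allele_frequencies
from popgen.diversity import diversity_table, expected_het_unbiased, mean_alleles, observed_het
from popgen.hwe import MonomorphicLocusError, genotype_counts, hwe_exact_test


# ---------------------------------------------------------------------------
# diversity statistics

def _gm_one_locus(genos: list[tuple[str, str] | None]) -> GenotypeMatrix:
    return GenotypeMatrix.from_calls([f"s{i}" for i in range(len(genos))],
                                     ["loc"], [[g] for g in genos])


class TestHeterozygosity:
    def test_monomorphic_he_is_zero(self):
        gm = _gm_one_locus([("1", "1")] * 4)
        he, mean, _ = expected_het_unbiased(allele_frequencies(gm))
        assert mean == 0.0

    def test_unbiased_he_hand_value(self):
        # 5 individuals, p = (0.6, 0.4): He = (10/9) * 0.48 = 0.5333
        gm = _gm_one_locus([("a", "a"), ("a", "a"), ("a", "b"),
                            ("b", "b"), ("a", "b")])
        _, mean, _ = expected_het_unbiased(allele_frequencies(gm))
        assert mean == pytest.approx((10 / 9) * 0.48, abs=1e-9)

    def test_observed_het_fraction(self):
        gm = _gm_one_locus([("a", "b"), ("a", "b"), ("a", "b"),
                            ("a", "a"), ("b", "b")])
        _, mean, _ = observed_het(gm)
        assert mean == pytest.approx(0.6)
        gm_all_het = _gm_one_locus([("a", "b")] * 4)
        assert observed_het(gm_all_het)[1] == 1.0

    def test_he_unbiasedness_over_many_loci(self):
        # the 2n/(2n-1) factor makes E[He-hat] equal the generating 1 - sum p^2
        rng = np.random.default_rng(0)
        n, L = 50, 1000
        p = 0.3
        g = rng.random((n, L, 2)) < p
        hes = np.empty(L)
        for l in range(L):
            phat = g[:, l, :].mean()
            hes[l] = (2 * n / (2 * n - 1)) * (1 - phat ** 2 - (1 - phat) ** 2)
        target = 1 - p ** 2 - (1 - p) ** 2
        assert hes.mean() == pytest.approx(target, rel=0.005)

    def test_se_is_sd_over_sqrt_nloci(self, structured_pop):
        gm, _ = structured_pop
        series, mean, se = expected_het_unbiased(allele_frequencies(gm))
        assert se == pytest.approx(series.std(ddof=1) / np.sqrt(len(series)))


class TestMeanAlleles:
    def test_biallelic_everywhere(self):
        gm = GenotypeMatrix.from_calls(
            ["a", "b"], ["l1", "l2"],
            [[("1", "2"), ("3", "4")], [("1", "1"), ("3", "4")]])
        _, mean, _ = mean_alleles(gm)
        assert mean == 2.0

    def test_diploid_upper_bound(self, structured_pop):
        gm, _ = structured_pop
        subset = gm.sample_ids[:4]
        series, _, _ = mean_alleles(gm, subset)
        assert (series <= 2 * len(subset)).all()


# ---------------------------------------------------------------------------
# exact HWE test oracles

def _levene_p_fraction(counts: np.ndarray) -> float:
    """Exact p by independent rational-arithmetic enumeration (biallelic)."""
    n = int(counts.sum())
    m1 = 2 * counts[0, 0] + counts[0, 1]
    m2 = 2 * counts[1, 1] + counts[0, 1]

    def prob(naa: int, nab: int, nbb: int) -> Fraction:
        return (Fraction(factorial(n) * factorial(m1) * factorial(m2) * 2 ** nab,
                         factorial(2 * n) * factorial(naa) * factorial(nab) * factorial(nbb)))

    def llr(naa: int, nab: int, nbb: int) -> float:
        p1 = m1 / (2 * n)
        t = 0.0
        for cnt, pi in ((naa, p1 ** 2), (nab, 2 * p1 * (1 - p1)), ((nbb), (1 - p1) ** 2)):
            if cnt:
                t += cnt * (log(pi) - log(cnt / n))
        return t

    tables = []
    for nab in range(min(m1, m2), -1, -2):
        naa = (m1 - nab) // 2
        nbb = (m2 - nab) // 2
        if naa >= 0 and nbb >= 0:
            tables.append((naa, nab, nbb))
    obs = llr(counts[0, 0], counts[0, 1], counts[1, 1])
    p = sum(prob(*t) for t in tables if llr(*t) <= obs + 1e-9)
    return float(p)


def _pairing_oracle_p(counts: np.ndarray) -> float:
    """Exact p by brute force over all ordered pairings of the allele vector."""
    from popgen.hwe import _hwe_log_pi, _llr
    m = counts.sum(axis=0) + counts.sum(axis=1)
    n = int(counts.sum())
    k = len(m)
    vec = [a for a in range(k) for _ in range(int(m[a]))]
    log_pi = _hwe_log_pi(np.asarray(m), n)
    obs = _llr(counts, log_pi, n)
    hits = total = 0
    for perm in itertools.permutations(vec):
        t = np.zeros((k, k), dtype=int)
        for i in range(0, len(perm), 2):
            a, b = sorted(perm[i:i + 2])
            t[a, b] += 1
        total += 1
        if _llr(t, log_pi, n) <= obs + 1e-9:
            hits += 1
    return hits / total


class TestHweExactTest:
    def test_single_heterozygote_p_is_one(self):
        counts = np.array([[0, 1], [0, 0]])
        res = hwe_exact_test(counts)
        assert res.p_value == 1.0
        assert res.method == "enumeration"
        assert res.tables_evaluated == 1

    def test_all_heterozygotes_matches_rational_oracle(self):
        counts = np.array([[0, 5], [0, 0]])  # margins (5, 5)
        res = hwe_exact_test(counts)
        assert res.method == "enumeration"
        assert res.p_value == pytest.approx(_levene_p_fraction(counts), abs=1e-12)

    @pytest.mark.parametrize("counts", [
        np.array([[1, 2], [0, 1]]),
        np.array([[0, 2, 1], [0, 0, 1], [0, 0, 0]]),
        np.array([[1, 0, 1], [0, 1, 0], [0, 0, 1]]),
    ])
    def test_enumeration_matches_pairing_oracle(self, counts):
        res = hwe_exact_test(counts)
        assert res.method == "enumeration"
        assert res.p_value == pytest.approx(_pairing_oracle_p(counts), abs=1e-12)

    def test_monte_carlo_agrees_with_enumeration(self):
        rng = np.random.default_rng(3)
        g = rng.choice(3, size=(40, 2), p=[0.5, 0.3, 0.2])
        counts = np.zeros((3, 3), dtype=int)
        lo = np.minimum(g[:, 0], g[:, 1])
        hi = np.maximum(g[:, 0], g[:, 1])
        np.add.at(counts, (lo, hi), 1)
        exact = hwe_exact_test(counts, max_enum_tables=500_000)
        assert exact.method == "enumeration"
        reps = 100_000
        mc = hwe_exact_test(counts, max_enum_tables=1, mc_reps=reps, seed=5)
        assert mc.method == "monte_carlo"
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / reps)
        assert abs(mc.p_value - exact.p_value) <= 3 * se + 2 / reps

    def test_monomorphic_is_undefined(self):
        with pytest.raises(MonomorphicLocusError):
            hwe_exact_test(np.array([[4, 0], [0, 0]]))

    def test_genotype_counts_extraction(self, tiny_gm):
        counts = genotype_counts(tiny_gm, "locA")
        assert counts.sum() == 5
        assert counts[0, 1] == 3  # three 150/152 heterozygotes


class TestDiversityTable:
    def test_empty_assignment_gives_empty_table(self, tiny_gm):
        assert diversity_table(tiny_gm, {}).empty

    def test_row_contents_and_hwe_skip(self, structured_pop):
        gm, meta = structured_pop
        ids = gm.sample_ids[:30]
        table = diversity_table(gm, {"grp": ids, "solo": gm.sample_ids[:1]},
                                mc_reps=2000, max_enum_tables=2000, seed=0)
        row = table.set_index("cluster").loc["grp"]
        assert row["n_individuals"] == 30
        _, he, _ = expected_het_unbiased(allele_frequencies(gm, ids))
        assert row["he_mean"] == pytest.approx(he)
        assert 0 <= row["n_hwe"] <= gm.n_loci
        assert table.set_index("cluster").loc["solo", "n_hwe"] is None or \
            np.isnan(table.set_index("cluster").loc["solo", "n_hwe"])

    def test_type_i_error_rate_under_hwe(self, panmictic_pop):
        # panmictic, F=0: expect ~5% of loci significant at alpha=0.05
        gm, _ = panmictic_pop
        hits = []
        for seed in range(4):
            g, _ = popgen.simulate_structured_pop(popgen.SimulationConfig(
                n_clusters=1, cluster_sizes=[50], n_loci=50, alleles_per_locus=4,
                fst_target=0.0, inbreeding_profile=0.0, migrant_fraction=0.0,
                seed=200 + seed))
            from popgen.diversity import count_hwe_departures
            n_hwe, _ = count_hwe_departures(g, mc_reps=2000, max_enum_tables=2000,
                                            seed=seed)
            hits.append(n_hwe)
        rate = np.sum(hits) / (4 * 50)
        # binomial 99% band around 0.05 for 200 tests
        assert 0.01 < rate < 0.10
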