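# popgen-seal

A conservation-genetics toolkit for multilocus microsatellite genotypes,
built around the analysis workflow used to assess small, fragmented
marine-mammal populations: Bayesian admixture clustering with migrant
classification, spatial PCA, exact Hardy–Weinberg testing, Loiselle
kinship with isolation-by-distance permutation tests, individual
inbreeding estimation with a simulation-based estimator comparison,
linkage-disequilibrium effective population size, and a geographic
travelling-window scan that profiles all of these statistics along a
spatial axis. A synthetic-data module generates populations with the
same statistical structure (low diversity, few clusters, migrants, an
inbreeding gradient), so the entire pipeline can be exercised and
validated without field data.

It is aimed at conservation geneticists working with codominant marker
panels of modest size — tens of individuals, tens of loci — where every
statistic needs an exact or permutation-based test rather than an
asymptotic one.

## The statistics at the core

* **Diversity.** Nei's unbiased expected heterozygosity per locus,
  `He = 2n/(2n−1) · (1 − Σₐ p̂ₐ²)`, observed heterozygosity `Ho`, and
  allele counts `A`, summarised as mean ± SE over loci.
* **Exact HWE test.** Conditional on allele counts *m₁…m_k*, each
  genotype table has Levene probability
  `P = n!·Πₐ mₐ!·2^H / ((2n)!·Π n_ij!)`; tables are ordered by the
  likelihood-ratio statistic of genotype proportions against
  Hardy–Weinberg expectations, with exhaustive enumeration for small
  margin spaces and conditional Monte Carlo (random pairing of the
  allele vector) otherwise.
* **Admixture clustering.** The classic mixture model — allele copies
  originate from cluster *k* with probability `q_ik` — fitted by a Gibbs
  sampler with a Metropolis update of the admixture parameter α; K is
  chosen over replicate runs by the model-evidence estimate
  `L(K) = E[ln L] − Var[ln L]/2`. Individuals are assigned to a cluster
  when `q ≥ 0.8` and the 90% posterior intervals exclude the
  alternatives; assigned individuals sampled outside their cluster's
  home region are classified as migrants.
* **Spatial PCA.** Eigenanalysis of `(1/n)·Zᵀ((W+Wᵀ)/2)Z`, where `Z`
  holds centred individual allele frequencies and `W` the row-normalised
  Delaunay adjacency; positive eigenvalues capture global (cline/patch)
  structure, negative ones local structure, both tested by permuting
  genotypes against coordinates.
* **Kinship and IBD.** Loiselle-type kinship
  `F_ij = Σ_l Σ_a [(x_ila−p_la)(x_jla−p_la) + p_la(1−p_la)/(n_l−1)] / Σ_l Σ_a p_la(1−p_la)`,
  averaged in distance classes, with location-permutation p-values and
  delete-one-locus jackknife standard errors.
* **Inbreeding.** Per-individual maximum-likelihood F
  (`P(hom) = p² + F·p(1−p)`, `P(het) = 2p_a p_b(1−F)`, maximised on
  [0, 1]) plus unbounded Ritland-type moment estimators; estimators are
  ranked by bias and precision on cohorts simulated at known F
  (0.05…1.00 in steps of 0.05, 100 individuals per level).
* **Effective population size.** Burrows composite disequilibrium
  `Δ̂ = S/(S−1)·[(1/2S)Σ x_A x_B − 2p_A p_B]` normalised with
  HW-departure-corrected denominators, averaged over allele-pair
  comparisons (rare alleles below a 0.02 frequency cutoff excluded),
  reduced by the sampling expectation `E[r²] ≈ 1/S + 3.19/S²` and
  transformed to `N̂e = (1/3 + √(1/9 − 2.76·r̂²'))/(2·r̂²')`, with a
  chi-square CI; a non-positive drift signal reports `Ne = ∞`.
* **Travelling-window scan.** Samples are projected onto a geographic
  axis and a window of 30 geographically consecutive genotypes slides
  along it, reporting He/Ho, loci out of HWE, mean cluster membership,
  the inbreeding summary and LD-Ne per window — a spatial profile of
  departure from random mating.

## Worked example

```python
import popgen

gm, meta = popgen.simulate_structured_pop(popgen.SimulationConfig(seed=1))
gm = popgen.filter_monomorphic(gm)

freqs = popgen.allele_frequencies(gm)
_, he, he_se = popgen.expected_het_unbiased(freqs)
_, ho, ho_se = popgen.observed_het(gm)
print(f"He = {he:.3f} +/- {he_se:.3f}")     # He = 0.430 +/- 0.033
print(f"Ho = {ho:.3f} +/- {ho_se:.3f}")     # Ho = 0.357 +/- 0.028

est = popgen.ld_ne(gm, freq_cutoff=0.02)
print(f"Ne = {est.ne:.1f} ({est.ci_low:.1f}-{est.ci_high:.1f})")
# Ne = 22.9 (18.3-28.7)

k_star, table = popgen.select_k(gm, range(1, 4), n_replicates=3,
                                burn_in=300, reps=1500, seed=1)
print("K* =", k_star)                        # K* = 3
```

The simulated population holds 86 individuals at 26 low-diversity loci
in three clusters with a planted inbreeding gradient and ~8% migrants.
He exceeds Ho (Wahlund effect plus inbreeding), the pooled LD-Ne is
small — pooling differentiated clusters creates mixture LD, mimicking a
genuinely small admixing population — and K-selection recovers the
three planted clusters.

The same analyses run from the shell:

```bash
popgen run --config configs/demo.yaml --out demo_out
```

writes a diversity table, q-matrix and migrant list, sPCA eigenvalues
and test p-values, sex-stratified IBD tables, per-individual inbreeding,
per-cluster Ne and the travelling-window profile, plus a manifest with
all seeds. Identical seeds reproduce every numeric output byte for
byte.

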