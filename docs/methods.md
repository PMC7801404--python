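# Methods

This note documents the models implemented in `popgen`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical decisions a maintainer would otherwise
have to reverse-engineer.

## Data model

Genotypes are unordered diploid allele pairs at codominant loci.
Allele labels are opaque strings: microsatellite fragment lengths are
treated as identifiers, never ordered or differenced, because every
statistic here uses identity only. Missing data is per-call (both
alleles or neither) and handled by pairwise deletion downstream: each
statistic uses the individuals typed at the loci it touches. Missing
codes are normalised on input — GenePop `000`/`000000`, STRUCTURE `-9`,
empty CSV cells. Coordinates are decimal degrees WGS84; all distances
are great-circle on a 6371-km sphere, and axis projections use a local
equirectangular plane centred on the axis midpoint (adequate below a
few hundred km; both endpoints of the default axis sit inside one UTM
zone's worth of longitude).

## Exact Hardy–Weinberg testing

The test conditions on observed allele counts and sums Levene
probabilities over genotype tables at least as extreme as the observed
one. Extremeness is the conditional likelihood-ratio ordering: the
multinomial log-likelihood of the table under Hardy–Weinberg
proportions (allele frequencies fixed at their sample values) minus the
log-likelihood at the table's own genotype-proportion MLE. Ties (within
1e-9 of the observed statistic) are included in the rejection region.

Enumeration is exhaustive when the number of tables with the observed
margins does not exceed `min(cutoff_tables, max_enum_tables)`. The
`cutoff_tables` parameter (default 10^9) expresses the analysis-level
policy; `max_enum_tables` (default 2×10^5) is the practical bound above
which enumeration is slower than sampling in this implementation.
Beyond it, tables are drawn from the exact conditional null by randomly
pairing the vector of allele copies; the reported p is
`(1 + hits)/(reps + 1)`, which is never exactly zero. Monte Carlo
p-values pass a Kolmogorov–Smirnov uniformity check against U(0,1) on
1000 simulated equilibrium loci (4 alleles, n = 50), and enumeration
agrees with an independent rational-arithmetic oracle to 1e-9.

The per-locus significance threshold is 0.05 without multiple-testing
correction: the "loci out of HWE" count is used descriptively, as a
spatial signal in the window scan, not as a family of formal tests.

## Admixture clustering

The model is the standard admixture mixture: conditional on membership
proportions `q_i` and cluster allele frequencies, allele copies are
independent draws. The Gibbs sampler updates allele-copy origins,
cluster frequencies (Dirichlet(1 + counts)), and membership rows
(Dirichlet(α + counts)), all as blocked vectorised draws, so a sweep
costs O(n·L·K).

The admixture parameter α is not fixed: it carries a uniform prior on
(0, 10] and a lognormal-proposal Metropolis update each sweep. This
matters for assignment: with α pinned at 1 the prior drags every `q_i`
toward the simplex centre and weakly admixed individuals fail the
`q ≥ 0.8` rule; with α inferred (it settles near 0.01 on clearly
structured data) memberships are crisp and planted migrants are
recovered. Passing an `(n, K)` α matrix instead activates a
region-informed prior and disables α inference — a lightweight
analogue of location-informed clustering, which this package does not
implement in full.

K is selected over replicate chains by the model-evidence estimate
`L(K) = E[ln L] − Var[ln L]/2` computed from the post-burn-in
likelihood trace. Raw mean likelihood is not used: once α is inferred,
an extra cluster can only increase it, and panmictic data would drift
toward the largest K offered. The variance-penalised form selects
K = 1 on panmictic data and the planted K on structured data. When the
highest-evidence K is not also the lowest-variance K the selection
table flags it and a warning is raised rather than silently resolving
the trade-off.

Replicate q matrices are aligned by greedy column matching on the
overlap matrix `q_refᵀ q` before averaging; 90% equal-tailed posterior
intervals come from thinned post-burn-in samples (at most 400 retained)
and are widened where necessary to bracket the posterior mean, which a
skewed boundary posterior can otherwise leave outside the equal-tailed
interval.

Function defaults keep long, safe run lengths (burn-in 5×10^4, 2×10^5
sweeps). The pipeline configuration and test suite run far shorter
chains (hundreds to a few thousand sweeps): the blocked sampler mixes
in tens of sweeps on 26-locus data, and replicate agreement (mean |Δq|
< 0.05) is verified at those lengths.

Migrant classification follows the assignment rule: individual i is
assigned to cluster k when `q_ik ≥ 0.8` and the 90% interval of every
other cluster's membership stays below the threshold; an assigned
individual whose cluster is not its sampling region's modal cluster is
a migrant, anything unassignable is reported as such rather than
forced.

## Spatial PCA

The analysed matrix is `C = (1/n)·Zᵀ M Z` with `Z` the column-centred
individual allele-frequency matrix (entries 0/0.5/1; missing values
mean-imputed per column before centring) and `M` the symmetrised
row-normalised Delaunay weight matrix. Eigenvalues are signed products
of genetic variance and spatial autocorrelation: with the identity
connectivity the decomposition reduces exactly to ordinary PCA of
`(1/n)ZᵀZ`, which the tests verify to 1e-8. Duplicate coordinates are
jittered by at most ~100 m (seeded) so the triangulation is defined.

The global (local) permutation statistic is the largest positive
(most negative) eigenvalue under row permutations of `Z` against the
coordinates. The cited spatial-PCA literature uses a slightly
different summary (the sum of positive/negative eigenvalue mass); the
single-extreme-eigenvalue choice is declared here as the package's
statistic — it affects permutation p-values, not eigenvalues or
scores. The number of interpretable components is left to the user;
the scan emits the full eigenvalue table rather than deciding.

## Kinship and isolation by distance

Kinship is the Loiselle estimator relative to the analysed sample's
allele frequencies, with the `p(1−p)/(n_l−1)` finite-sample correction
per allele and locus. Per-locus numerators and denominators are
retained so any class mean can be recomputed with one locus deleted;
jackknife SEs use the standard `(L−1)/L` scaling. Its mean over all
pairs of a panmictic sample is ~0 by construction (verified |mean| <
0.02 at n = 100).

IBD distance classes default to upper bounds {25, 50, 100, 200, 400,
800} km with an open-ended final class; the grid is configurable
because class boundaries are a reporting choice, not a model property.
The null permutes spatial locations among the analysed individuals,
keeping the kinship matrix intact; p-values are two-sided deviations
of the class mean from the population mean kinship. Permutation
p-values are uniform under a shuffled-coordinates null (KS check over
200 replicates), and a four-colony stepping-stone arrangement yields a
significant first-class excess in ≥ 90% of replicates.

## Individual inbreeding

The ML estimator maximises `Π_l P(g_l | F)` on [0, 1], with genotype
probabilities linear in F; the log-likelihood is concave, the bounded
optimiser is cross-checked against a 1e-4 grid, and boundary solutions
return exactly 0 or 1 (decided by the sign of the score at the
endpoints). The Ritland moment estimator uses per-locus terms
`(Σₐ δₐ/pₐ − 1)/(A_l − 1)` with `(A_l − 1)` locus weights and is
deliberately unbounded; `lynch_ritland` is the same per-locus form with
equal locus weights, kept as a weighting-sensitivity comparison.

The evaluation harness simulates cohorts at known F (default 20 levels
× 100 individuals) from supplied allele frequencies and scores each
estimator by bias (mean error), precision (population SD, so
RMSE² = bias² + SD² holds exactly) and RMSE, ranked lexicographically
on (mean |bias|, mean SD). Two behaviours of the bounded ML estimator
are worth knowing. First, with 26 low-diversity loci the per-individual
SD is large (≈ 0.15–0.2), so truncation at 0 inflates the mean at the
lowest F levels — the bias at F = 0.05 sits near +0.05, essentially at
the tolerance used in the acceptance checks. Second, for the same
reason the *median* estimate at low true F collapses toward 0 when up
to half the cohort hits the boundary; window medians from very weak
panels are therefore conservative, and mean F per window is reported
alongside the median in the scan output.

Reference frequencies for empirical F estimates default to the whole
analysed sample. On strongly structured data this imports a Wahlund
component into F̂ (excess homozygosity relative to pooled frequencies);
that is a property of the estimand, shared with the software this
workflow mirrors, not an implementation artefact.

## LD effective population size

All constants follow the standard bias-corrected LD method for random
mating and are collected in one table (`LDNE_CONSTANTS`): sampling
expectation `E[r²] = 1/S + 3.19/S²` for harmonic-mean S ≥ 30 (small-S
variant `0.0018 + 0.907/S + 4.44/S²` below), and the Ne transform
`(1/3 + √(1/9 − 2.76·r̂²'))/(2·r̂²')` (small-S constants 0.308/2.08).
Burrows Δ is computed from dosages with the `S/(S−1)` factor and
HW-departure-corrected denominators, one comparison per retained
allele pair; alleles below the frequency cutoff (default 0.02) in the
analysed subset are dropped. Locus-pair values are pooled with
`(k₁−1)(k₂−1)` degree-of-freedom weights, and the 95% CI treats
`df·r̂²/r²` as chi-square with df equal to the total comparisons — the
parametric CI of the cited method; a jackknife CI is intentionally not
the default. A non-positive corrected signal (or negative discriminant)
reports Ne = ∞: "no evidence of drift at this sample size" is a
result, not an error.

Validation uses the Wright–Fisher harness: constant-size monoecious
random mating, unlinked loci, 20 burn-in generations from equal allele
frequencies (unlinked-locus LD equilibrates within a handful of
generations, and longer burn-in only loses polymorphism to fixation at
small Ne). The median estimate over 100 replicates at true Ne = 50
(S = 50, 40 biallelic loci) falls in [40, 62], medians are monotone in
true Ne across {25, 50, 100}, and heterozygosity decays at
`(1 − 1/2Ne)` per generation within 10%.

## Travelling-window scan

Samples are ordered by axis projection (ties broken by sample id) and
windows of 30 consecutive genotypes advance by a configurable step
(default 1; the bundled demo uses 4 to stay fast). Each window reports
mean He/Ho, the count of loci with exact-HWE p < 0.05 (seeded per
window for determinism), mean membership to a designated cluster,
median/IQR/mean ML inbreeding against the whole-subset reference
frequencies (so windows are comparable), and LD-Ne with the 0.02
cutoff. The window's x-position is the median member projection. A
window whose Ne point estimate or upper CI is infinite or undefined is
flagged `se_unreliable` rather than dropped. A window spanning the
whole sample reproduces the whole-sample statistics exactly.

## Synthetic data: what it emulates, what it does not

`simulate_structured_pop` defaults portray the study system the
package was built around: 86 individuals in three uneven clusters
(5/34/47) placed Ionian / north-Aegean / south-Aegean-like along a
NW–SE transect, 26 loci with 2–5 alleles, sparse ancestral Dirichlet
frequencies (concentration 0.18, giving mean He ≈ 0.35 and ~2.6 alleles
per locus), Balding–Nichols drift at FST 0.15 — the differentiation at
which three clusters are reliably detectable by the K-selection rule,
as they were in the study system — a west-to-east inbreeding gradient
(0.03 → 0.11) and an 8% migrant fraction. Genotypes are drawn with the
correlated-alleles construction (`P(IBD) = F`), which reproduces the
inbreeding genotype probabilities exactly. Migrants carry a foreign
cluster's genotype at home coordinates. Truth columns (origin cluster,
true F, migrant flag) ride in the metadata.

Not emulated: mutation (no stepping-stone allele-size process),
linked loci, overlapping generations, within-cluster spatial kinship
decay, genotyping error and allelic dropout, or the drift history that
would give each cluster an internally consistent small-Ne LD
signature. Consequently, passing tests demonstrate that the estimators
recover the structure this generator plants; they do not certify
behaviour under scoring error or marker ascertainment, and a
per-cluster LD-Ne on the structured generator's output reflects the
(large) effective size implied by independent Dirichlet draws, not a
small-colony history — which is why Ne validation uses the
Wright–Fisher harness instead.

## Problem sizes and determinism

The test-suite and acceptance-script problem sizes are the package's
validation design: 1000 loci for p-value uniformity, 100 Wright–Fisher
replicates for the Ne band, 20 × 100 cohorts for the estimator study,
200 replicates at 500 permutations for permutation-null calibration,
50 stepping-stone replicates for IBD power, three replicate seeds for
migrant recovery, and short-chain clustering as described above.
Every random draw flows from explicit integer seeds (replicate seeds
are base + index), so any reported number is reproducible bit for bit;
the pipeline writes its seeds into the run manifest.

## Known limitations

* The exact-test implementation is pure Python; margin spaces beyond a
  few hundred thousand tables go to Monte Carlo rather than
  enumeration, whatever `cutoff_tables` allows in principle.
* The clustering model uses uncorrelated cluster frequencies; closely
  related clusters are harder to separate than under the correlated
  model, and data with strong within-cluster inbreeding can push the
  evidence criterion toward an extra cluster.
* The sPCA permutation statistic differs in detail from the cited
  method (single extreme eigenvalue vs eigenvalue mass).
* Moment-estimator variance explodes when rare alleles appear as
  homozygotes (terms in 1/p); the ML estimator is the default
  everywhere.
* Window-level Ne at size 30 is noisy by construction; treat the
  profile shape, not individual windows, as the signal.
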