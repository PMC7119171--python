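# Methods

## Informativeness from allele frequencies

The core measure is the Lancaster Estimator of Independence (LEI), a
mean-square-contingency–type statistic on the 3 × k table of genotype
(mm, mM, MM) against population membership. The table is not observed:
it is reconstructed from per-population reference-allele frequencies
f_j and sample counts c_j under Hardy–Weinberg equilibrium,
n̂_1j = c_j (1−f_j)², n̂_2j = 2 c_j f_j (1−f_j), n̂_3j = c_j f_j². With
p̂_ij = n̂_ij / n this gives

    θ̂² = Σ_ij p̂_ij² / (p̂_i+ p̂_+j) − 1,

algebraically identical to Pearson's φ² = Σ (p̂_ij − p̂_i+ p̂_+j)²/(p̂_i+ p̂_+j)
because the cells sum to one; the test suite verifies the identity against
an independently coded φ² (and scipy's chi-square on the count table) to
1e−10. The estimator is 0 iff every population has the same frequency and
is bounded by min(3, k) − 1. Three numerical conventions:

* terms with a zero genotype marginal contribute 0 (their cells are exactly
  zero, avoiding 0/0);
* tiny negative round-off is clamped to 0;
* markers with any missing frequency get a missing (NaN) score with a
  logged warning — never imputed, and always excluded from panels.

HWE expansion makes θ̂² invariant to which allele is labelled "reference"
(rows 1 and 3 swap), to permuting populations, and to rescaling all counts
by a common factor. These invariances are property-tested. The weighting
c_j defaults to equal weights (c_j = 1) when a frequency file carries no
sample sizes; users can pass real panel sizes (`--counts`), which matters
only when counts are unequal. Whether θ̂² can actually attain 2 for a
biallelic marker under HWE with k ≥ 3 is left open; the acceptance script
reports the maximum over the dense grid {0, 0.01, …, 1}³ (≈ 1.2 with equal
weights) and asserts only the bound.

## Genotype-based rankings

With individual genotypes (0/1/2 counts of the reference allele), LEI is
computed from per-population estimated frequencies
f̂ = (allele sum over non-missing samples) / (2 × non-missing samples),
carrying the per-marker non-missing counts as c_j, so the genotype path
agrees bit-for-bit with the two-step path on fully observed data.

The alternative rankings are standard embedded feature-selection scores.
There is no single canonical way to turn PCA, an SVM or a random forest
into per-marker values, so the definitions below are this package's
choices, selected to be deterministic (or seedable) and testable:

* **PCA** — score_j = Σ_c evr_c · loading²_cj over the top `n_components`
  (default 2, matching the usual two-PC structure plots) of the
  column-standardised matrix; squared loadings make the score invariant to
  component sign.
* **SVM** — maximum absolute coefficient of marker j across linear
  one-vs-rest support-vector classifiers (hinge loss, C = 1 by default,
  configurable) on standardised genotypes.
* **RF** — mean impurity-decrease importance of a random-forest classifier
  (default 500 trees, seed 1); importances are non-negative and sum to 1.

Standardisation (zero mean, unit variance per marker) keeps scores
comparable across allele frequencies; zero-variance markers are dropped
from the model and scored 0. Missing genotypes are mean-imputed per marker
for PCA/SVM/RF only — the LEI path always uses complete-case allele counts.
On data where informativeness is controlled by the frequency gap between
populations, the four rankings are strongly rank-concordant (Spearman
ρ > 0.7 in the seeded concordance test).

## Panel construction

`threshold_filter` keeps markers with score ≥ threshold (inclusive
comparison). `spacing_filter` thins by physical distance as a proxy for
removing linkage-disequilibrium redundancy: per chromosome, markers are
visited in descending score (ties broken by ascending position, then
lexicographic id) and kept iff they lie at least `spacing_kb` kilobases
from every already-kept marker. The greedy score-first rule was chosen
because it retains the most informative marker of every local cluster in a
single deterministic pass; positions are 1-based point coordinates and
markers on different chromosomes never conflict. `build_panel` chains
threshold → spacing → optional top-k cap and returns rows sorted by
descending score. The pipeline is idempotent, and tightening either knob
never grows the panel (both property-tested).

## Synthetic data

The simulator exists so every stage is testable without reference
downloads. Ancestral allele frequencies follow the Balding–Nichols model:
a base frequency p ~ Uniform(0.05, 0.95) per marker, then per population
f_j ~ Beta(p(1−F)/F, (1−p)(1−F)/F), with F acting as FST. Defaults — k = 3
populations, F = 0.15, 100 samples per population, 200 admixed samples with
Dirichlet(1, 1, 1) ancestry proportions — represent a diverse
continental-scale scenario (an F near 0.15 is typical of
African/European/East-Asian panels); F = 1e−6 serves as the near-identical
contrast in tests. Population cohorts draw genotypes Binomial(2, f_j)
(HWE, unlinked markers). Admixed individuals draw q ~ Dirichlet(α) once and
each genotype Binomial(2, Σ_j q_j f_j): admixture acts at the frequency
level, which is exact for unlinked markers but does not produce LD or
local-ancestry tracts — so passing tests say nothing about haplotype-scale
structure, recombination or linked selection in real cohorts, only about
frequency-level informativeness. Markers sit on one synthetic chromosome at
10 kb intervals so spacing filters are exercised. A single seed feeds all
stages through fixed-label `SeedSequence` children, so each stage is
independently reproducible.

## Ancestry-proportion estimation and panel validation

The proportion estimator is supervised maximum likelihood on the simplex —
the standard choice when parental frequencies are known, and the matched
inverse of the admixture simulator. Each of a sample's two allele copies at
marker m is reference with probability π_m = Σ_j q_j f_mj; genotypes are
Binomial(2, π_m). From the uniform start the multiplicative EM update

    q_j ← q_j · [Σ_m (g_m f_mj / π_m + (2−g_m)(1−f_mj)/(1−π_m))] / (2M)

stays on the simplex and increases the likelihood; iteration stops at
max |Δq| < 1e−6 or 500 rounds. Parental frequencies are clipped to
[1e−6, 1−1e−6] so fixed alleles keep the likelihood finite. Identical
parental frequencies leave the update at the uniform point — the correct
answer for a non-identifiable model. Missing genotypes simply drop out of
the per-sample sums.

Panel quality is reported as the entries-wise RMSE over all n × k cells of
(Q_true − Q_est) — entries-wise rather than per-ancestry-averaged, a
deliberate definition since either reading is defensible — and as PCA
separation: explained-variance ratios of the top two components of the
standardised panel genotypes plus the mean silhouette of the true labels in
that plane. Silhouette is the quantitative stand-in for "the populations
form distinct clusters": > 0.6 for diverse panels, < 0.2 for near-identical
ones in the seeded tests.

## Problem sizes

The acceptance pipeline ranks 50,000 simulated markers from 100-sample
ancestral cohorts, keeps the top 1,000, and estimates proportions for 200
admixed samples; it completes in well under a minute on one CPU. Unit and
property tests use 100–3,000 markers and 30–100 samples per population,
sizes at which every asserted effect (recovery within ±0.02–0.05,
silhouette contrasts, rank concordance) is comfortably resolved.

## Known limitations

* LEI assumes HWE within each population; inbreeding or genotyping error
  that distorts heterozygosity will bias the reconstructed table.
* No LD-aware informativeness: spacing is a distance heuristic, not an
  r²/D′ computation, and jointly redundant markers further apart than the
  spacing are all retained.
* The proportion estimator treats parental frequencies as known constants;
  uncertainty from finite reference panels is not propagated.
* PCA/SVM/RF scores depend on documented hyperparameters (components,
  regularisation, trees); alternative settings reorder weakly informative
  markers.
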