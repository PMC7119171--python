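# aimpanel

Selection and validation of ancestry-informative markers (AIMs) for studies
of admixed populations.

Admixture mapping and ancestry inference need small panels of SNPs whose
allele frequencies differ strongly between ancestral populations. `aimpanel`
scores biallelic markers for ancestry informativeness across *k* ≥ 2
populations using **allele-frequency data alone**, via the Lancaster
Estimator of Independence (LEI); it also ranks markers from individual-level
genotypes (LEI, PCA, SVM, random forest), builds panels by score
thresholding and physical-distance thinning, and validates panels on
simulated admixed cohorts by ancestry-proportion recovery and
principal-component separation.

## The statistic

For a marker with reference-allele frequency *f<sub>j</sub>* and sample
count *c<sub>j</sub>* in population *j*, Hardy–Weinberg equilibrium gives
expected genotype counts

n̂<sub>1j</sub> = c<sub>j</sub>(1−f<sub>j</sub>)², n̂<sub>2j</sub> = 2c<sub>j</sub>f<sub>j</sub>(1−f<sub>j</sub>), n̂<sub>3j</sub> = c<sub>j</sub>f<sub>j</sub>²

for genotypes (mm, mM, MM). With *n* = Σ c<sub>j</sub>, the joint
distribution p̂<sub>ij</sub> = n̂<sub>ij</sub>/n of genotype × population
yields

θ̂² = Σ<sub>ij</sub> p̂<sub>ij</sub>² / (p̂<sub>i+</sub> p̂<sub>+j</sub>) − 1

which equals Pearson's mean-square contingency φ² of the table: 0 when all
populations share one frequency, and bounded by min(3, k) − 1 — so at most
1 for two populations and at most 2 for three or more. Larger values mean a
more ancestry-informative marker.

## Worked example

A two-marker frequency file (`demo_freqs.tsv`, tab- or comma-delimited):

```
SNPID	Chromosome	Ref_Allele	Alt_Allele	CEU_Freq	CHB_Freq	YRI_Freq
rs7289657	22	C	T	0.4	0.4	0.4
rs2294368	22	T	C	0.79	0.17	0.99
```

```
$ aimpanel score demo_freqs.tsv --method LEI -o demo_scores.tsv
INFO aimpanel: input=demo_freqs.tsv digest=5c3af4b7ae9f k=3 markers=2 method=LEI seed=1
wrote 2 scored markers to demo_scores.tsv
$ cat demo_scores.tsv
SNPID	Chromosome	Ref_Allele	CEU_Freq	CHB_Freq	YRI_Freq	Score
rs2294368	22	T	0.79	0.17	0.99	0.7772058245350817
rs7289657	22	C	0.4	0.4	0.4	0.0
```

`rs2294368` scores θ̂² ≈ 0.78: its reference allele is nearly fixed in one
population (0.99), rare in another (0.17) and intermediate in the third
(0.79), so genotype strongly predicts ancestry. `rs7289657` has identical
frequencies everywhere and is non-informative (θ̂² = 0). The same number
comes from the library:

```python
>>> import numpy as np
>>> from aimpanel import PopulationPanel, joint_distribution, lei
>>> panel = PopulationPanel(("CEU", "CHB", "YRI"))
>>> lei(joint_distribution(np.array([0.79, 0.17, 0.99]), panel))
0.7772058245350817
```

Other subcommands: `aimpanel panel` (adds `--threshold`, `--spacing-kb`,
`--top-k`), `aimpanel simulate` (synthetic ancestral/admixed cohorts),
`aimpanel evaluate` (ancestry-proportion RMSE and PCA separation of a
panel), `aimpanel convert` (VCF + sample-population map → frequency table).

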