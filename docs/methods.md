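# Methods

`sorlscan` implements the statistical stages of a gene-centric rare-variant
study — the kind run on a candidate neurodegeneration gene such as *SORL1*
across multiple case-control biobank strata and a sequenced family cohort.
Real biobank genotypes are access-controlled, so the package ships a
synthetic-cohort generator whose outputs have the statistical structure
every stage assumes; all tests and the acceptance script run on generated
data.  This note records the models, the defaults and why they were chosen,
the numerical choices, and what the synthetic validation does and does not
establish.

## Allele statistics and the prioritization cascades

Within a stratum (ancestry x disease group), per-variant statistics are
computed over non-missing genotypes only: MAC (alternate-allele count),
MAF = MAC / (2 x N non-missing), and het/hom carrier counts.  Missing
genotypes are dropped from denominators, never imputed (the single
exception is the SKAT kernel, below).

Two cascades operate on these statistics plus the consumed annotation
(CADD, consequence class, reference allele frequencies — the package never
computes annotations):

* **Case-control track** — keep variants with zero control alternate
  alleles, case MAC >= 2, CADD strictly > 20, and a protein-altering
  (missense, stopgain, stoploss, frameshift, in-frame indel) or splicing
  consequence.  The MAC floor is counted in cases within the stratum;
  controls contribute nothing under the case-only rule.  CADD is compared
  strictly (> 20), MAC non-strictly (>= 2).
* **Family track** — keep loss-of-function alleles (stopgain, frameshift,
  splicing) regardless of CADD, plus missense with CADD > 20, restricted to
  an ancestry-specific reference allele frequency < 1%.  A variant absent
  from the reference panel is treated as frequency 0: absence of a rare
  allele from a finite panel is expected and must not exclude it.
  Candidates are restricted to the gene under analysis; pathogenic variants
  in other known disease genes are carried along as co-occurrence evidence,
  not as candidates.

A variant present in the genotype data but missing from the annotation
table is listed in a skipped-variant report rather than silently dropped.
Adding a criterion can only shrink the surviving set (tested as a
property).

## Single-variant association

Per variant, an additive-dosage logistic regression of case status on
dosage + sex + age + PC1..10, complete-case rows only, maximum likelihood
with Wald 95% intervals and p-values.  Monomorphic variants are skipped
with a reason.  Separation and non-convergence are *flagged*
(`converged=False`, crude allelic odds ratio as fallback) rather than
Firth-corrected: for ultra-rare variants the extreme Wald interval is
itself informative, and penalized fits are left as an option rather than a
default.  The per-stratum multiple-testing threshold is alpha = 0.05 / m
over the m variants actually tested there.

Carrier enrichment between two groups uses the one-sided Fisher exact test
(alternative: more carriers in cases) on the carrier/non-carrier x
case/control table, with the conditional-MLE odds ratio.  Carrier
demographics report family-history percentages over all carriers and
onset percentages over carriers with age-at-onset available; late onset
means AAO >= 50 years for Parkinson's disease and >= 65 for Alzheimer's
disease and Lewy body dementia.

## SKAT, burden, and SKAT-O

For binary phenotype y with covariates X, the null model is the logistic
fit of y on X; r = y - mu are the residuals and v = mu(1 - mu) the variance
weights.  With weighted genotypes Z = G diag(w), the score-statistic family

    Q_rho = (1 - rho) Q_SKAT + rho Q_burden,  rho in [0, 1]

interpolates between the variance-component SKAT statistic (rho = 0) and
the squared weighted-count burden score (rho = 1).  Under the null each
Q_rho is distributed as a weighted sum of chi-square(1) variables with
weights the eigenvalues of R_rho^{1/2} Z*'Z* R_rho^{1/2}, where Z* is the
variance-scaled, covariate-projected weighted genotype matrix.  The
omnibus p combines the grid through the minimum per-rho p-value using the
standard one-factor decomposition Q_rho ~ (1 - rho) eta + tau(rho) chi1:
per-rho quantiles at the minimum p come from moment-matched (Liu)
inversion, the survival probability of eta is integrated over the shared
chi-square(1) factor with a 128-node Gauss-Legendre rule (substituting
x = t^2 to remove the density singularity), and the result is capped by
the Bonferroni bound over the grid and floored at the unadjusted minimum.

Defaults: rho grid {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1} and
Beta(1, 25)-density weights at the pooled MAF — the conventional
rare-variant choices; both configurable.  The variant set for gene-level
testing is exonic + splicing with MAC >= 2, synonymous retained.  Missing
dosages are mean-imputed within variant for the kernel only, the one
documented departure from complete-case handling (a kernel needs a
rectangular matrix).

**Chi-square-mixture tails.**  P(sum lambda_i chi2_1 > q) is computed by
Imhof's exact inversion integral, evaluated with vectorized composite
Gauss-Legendre panels no wider than a quarter period of the fastest
oscillation and truncated where an integration-by-parts tail bound falls
below 1e-8.  Eigenvalues are normalized to mean 1 first (the tail is
scale-invariant) to keep the truncation search conditioned.  A single
eigenvalue uses the closed-form chi-square tail.  Where the truncation
point would exceed the panel budget — which happens only for thresholds in
the left/central region, where p is large — the Liu moment-matching
approximation takes over; its absolute error is smallest exactly there, so
right-tail accuracy (the regime p-values are used in) is preserved.  A
batch evaluator shares the panel grid across many thresholds with a common
spectrum; the permutation oracle uses it to convert 20,000 permuted
statistics per rho through a monotone interpolated map.

**Validation and its limits.**  The per-rho tails agree with 10^6-draw
Monte-Carlo within 3 MC standard errors; the omnibus combination agrees
with an exact-asymptotic oracle (scores drawn from their limiting
multivariate normal) to ~1e-3 absolute for homogeneous weights; empirical
type-I error at alpha = 0.05 over 1,000 null replicates (n = 1,000, 20
variants) falls within [0.035, 0.065].  At very small samples (tens of
individuals) the exact permutation null of Q is discrete and bounded away
from zero, so no chi-square mixture matches it to Monte-Carlo precision in
the central region; small-sample moment adjustments are deliberately out
of scope, and the permutation comparison at n = 60 should be read with
that in mind (absolute agreement is within ~0.005; a strict +/-3 MC SE
check fails on a minority of instances).

## Kinship-graph families and segregation

Individuals not in curated core pedigrees form a graph with edges where
pairwise kinship exceeds 0.0884 (the conventional second-degree cutoff;
strictly greater, the complement of the removal rule used for unrelated
strata).  Connected components with >= 2 members become families; since
kinship magnitude alone cannot orient relationships, all inferred members
are founders.  Core and inferred families merge into a unified set
(disjointness enforced; id collisions namespaced).  Informative families
have >= 1 PD case and >= 2 members.

A candidate variant is prioritized when, in at least one family, every
*genotyped* PD member carries >= 1 alternate allele and no genotyped
family control carries it.  A missing genotype neither vetoes nor
supports: the member simply leaves the genotyped denominator.  Het and hom
carriers both count as carriers (zygosity is reported separately).
Co-carried pathogenic variants in user-listed known-PD genes are attached
to each family summary.  Ancestry strata are treated as disjoint: a family
never spans two ancestry files.

## Fine-mapping

Single-trait, single-causal-variant fine-mapping from summary statistics.
Per variant the Wakefield approximate Bayes factor

    log ABF = 0.5 log(V / (V + W^2)) + 0.5 z^2 W^2 / (V + W^2)

with V = se^2, z = beta/se, and effect prior sd W = 0.2 (the conventional
case-control value; configurable).  With per-variant prior probability
p1 = 1e-4 against the null, posterior mass is proportional to p1 ABF_k per
variant and 1 for the no-association model, normalized in log space
(`logsumexp`) and renormalized so the total is 1 to 1e-9.  Because the
single-PP threshold of 0.6 can in principle refer to either hypothesis,
both sides are compared against it and a three-way decision is reported:
`causal-candidate` (some variant's PP > 0.6), `null-favored`
(PP of the null model > 0.6), else `inconclusive`.  Multi-signal
(conditional/stepwise) fine-mapping is out of scope; the single-PP
reporting convention assumes one signal.

## The synthetic-cohort generator

The generator emulates, per ancestry stratum: Hardy-Weinberg background
genotypes at phenotype-independent frequencies (uniform MAF 0.01-0.30,
benign annotations: CADD < 15, missense/synonymous), planted case-only
damaging variants with an exact heterozygote count in cases and zero
alternate alleles in controls, planted association variants, families with
within-family kinship 0.25 and one rare damaging candidate variant each,
and a summary-statistic region (non-causal beta ~ N(0, se),
se = 1/sqrt(2 n maf (1-maf)), causal beta ~ N(causal_beta, se)).

Planted association variants follow the additive logistic model exactly by
exponential tilting: if population genotypes are Binomial(2, p), the
case-genotype distribution under a per-allele odds ratio OR is again
Hardy-Weinberg at p' = p OR / (1 - p + p OR), so cases draw Binomial(2, p')
and controls Binomial(2, p) (the rare-disease retrospective sampling
identity).  Covariates are sex ~ Bernoulli(0.5) (PLINK 1/2 codes), age ~
Normal(65, 10) truncated at 18, PCs ~ Normal(0, 1), all independent of
phenotype — plain documented defaults, since covariate distributions are
not part of the study conditions being emulated.  Default stratum sizes
mirror a large sequencing case-control stratum (5,812 cases, 4,411
controls, EUR) and the default planted case-only variant carries 3
heterozygotes at CADD 27.3; the default family set contains an affected
sib pair co-carrying a pathogenic known-PD-gene variant, a second affected
pair, and three affected siblings — the three segregation patterns of
interest.  Genotypes are independent across variants by default; an
optional Gaussian-copula AR(1) switch (`ld_rho`) exists for burden-test
stress tests.  Everything derives from `numpy` Generator streams keyed on
(seed, stage), so outputs are bit-identical under a fixed seed and
independent of call order.

What passing on synthetic data does **not** show: robustness to linkage
disequilibrium (no realistic haplotype structure), imputation error
(dosages are hard calls; R2 fields are carried, not modeled), population
stratification beyond the null-effect PCs, genotyping batch effects, or
pedigree structures richer than founder sets.

## Problem sizes in tests and acceptance

The published-scale arithmetic (carrier fractions at n = 1,793/6,781/
1,340/6,782; MAF at 5,812 cases) is computed at full size — these are
O(n) counts.  Simulation-based checks use sizes chosen for tight oracles
at desk-scale runtime: odds-ratio recovery over 200 replicates at
5,000/5,000; null-p uniformity over 500 variants at 800/800; SKAT-O
type-I error over 1,000 replicates at n = 1,000 x 20 variants; permutation
comparison at 60 x 5 with 20,000 permutations; family recovery over 50
pedigrees; fine-mapping over 200-SNP regions at GWAS-scale n = 440,683.

## Known limitations

* Asymptotic p-values throughout; no exact or saddlepoint small-sample
  versions.
* Fisher enrichment treats carriers as independent — it is applied to the
  *unrelated* stratum by design, never within families.
* The ABF fine-map ignores LD between variants (single-causal assumption).
* Logistic separation reporting (crude OR, `converged=False`) leaves the
  interpretation to the analyst.
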