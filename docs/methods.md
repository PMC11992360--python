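# Methods

This note documents the statistical models, default parameters, and
design choices behind `microkin`, and what the bundled synthetic data
does and does not establish about real data.

## Pair-genotype probabilities (kinship core)

Relationships are parameterized by Cotterman IBD coefficients
κ = (κ0, κ1, κ2). At a locus with allele frequencies p the true-pair
probability is

P(T1, T2 | κ) = κ0 P(T1) P(T2) + κ1 P(T1) Trans(T2 | T1) + κ2 P(T1) 1[T2 = T1],

where P(·) are Hardy–Weinberg genotype proportions and Trans draws the
shared allele uniformly from T1's two alleles and the other allele from
p. Genotyping error uses the *true-genotype-independent* channel: with
probability ε the observed genotype is an independent Hardy–Weinberg
redraw, applied to each member of a pair independently,

P(O | T) = (1 − ε) 1[O = T] + ε P_HWE(O).

Defaults: ε = 0.005; natural-log LLRs (the natural-log scale reproduces
per-pair Λ magnitudes of order tens for a 170-locus panel, matching
how such panels are usually reported; log10 is available via
`LLRConfig(log_base="10")`). Loci where either member is missing are
skipped and the loci-used count reported; a pair with no shared called
locus has an undefined Λ and raises/labels UNEVALUABLE. Likelihood
allele frequencies should come from a designated reference cohort
(e.g. a geographically broad harvest sample), not the pairs under
test; `AlleleFrequencySet.from_genotype_matrix` adds a 0.5 pseudocount
per allele so unobserved catalog alleles keep positive frequency.

Numerical notes: with ε = 0 some pairs are impossible under some
hypotheses; per-locus log-ratio tables then contain ±inf, and 0/0
cells (impossible under both hypotheses) are set to 0 since they occur
with probability zero under either model. With ε > 0 every pair has
positive probability and all tables are finite. Correctness is pinned
by two independent test oracles: exhaustive enumeration over founder
gametes, IBD states, and error channels (agreement to 1e-12), and
normalization of every observed-pair matrix to total mass 1.

## Threshold calibration and importance sampling (power)

For each comparison num/den (SELF/U, PO/U, FS/U, FS/HS, PO/FS),
10,000 pairs of the numerator relationship are simulated directly from
the per-locus observed-pair distribution — equivalent to pedigree
simulation under locus independence and much faster (the equivalence
is asserted against the pedigree simulator in tests). The threshold η
is the empirical FNR-quantile with an explicit convention: the largest
sample value v with (#samples strictly below v)/n ≤ FNR; pairs are
declared positive when Λ > η. Default FNR 0.01. PO/FS instead uses the
conventional fixed cutoff η = 3, overridable.

False-positive rates are importance-sampled with the numerator
relationship as the importance distribution: since exp(−Λ) is exactly
the den/num likelihood ratio of a sampled pair,
P(Λ > η | den) = E_num[exp(−Λ) 1{Λ > η}]. The estimate is reported
with its draw-level Monte-Carlo standard error; when no draw exceeds η
the result is flagged `no_exceedances` rather than silently zero.
Default 100,000 importance draws, which keeps the SE well below 10% of
the estimate at the magnitudes a 170-locus panel produces. Validity is
tested against exact enumeration (2-locus panels) and 10^6-draw direct
Monte Carlo (10-locus panels); test thresholds are placed off the
atoms of the discrete Λ distribution, where a strict tail probability
is numerically ill-posed.

## Microhaplotype calling (caller)

Reads aligned to amplicon references are filtered at MAPQ ≥ 30,
unmapped reads dropped, and only reads covering every SNP offset of a
locus (CIGAR-aware) contribute. Per read and haplotype allele the
likelihood multiplies (1 − e_i) for matching bases and e_i/3 for
mismatches, with e_i the phred-implied error; N bases are
uninformative. A genotype {a, b} scores (P(r|a) + P(r|b))/2 per read
and the call is the maximum-posterior genotype under a uniform prior.

Calls become missing when: depth < 21 reads ("greater than 20");
posterior < 0.99 (the upstream caller's acceptance level is not
published, so 0.99 is this package's default, configurable); or a
heterozygote's minor/major assigned-depth ratio is < 0.4. The ratio
rule admits two readings — void the genotype, or drop the minor
haplotype and keep the major homozygote — both are implemented
(`ratio_filter="genotype"` default, `"haplotype"` optional). Reads
whose haplotype is absent from the catalog still contribute to
likelihoods via their best-matching catalog allele and are counted in
a per-locus novel-haplotype tally.

QC order is loci first, then samples: loci missing everywhere are
dropped; loci out of Hardy–Weinberg equilibrium (Monte-Carlo exact
test, Guo–Thompson allele permutation; p < 1e-4) in *every* sample
collection are dropped; then samples with more than 20% missing
genotypes are removed. Note the Monte-Carlo p-value floor is
1/(n_perm + 1), so clearing α = 1e-4 requires the default 10,000
permutations.

## Panel design

SNP predicates: global MAF > 0.35, every collection's MAF > 0.25, call
rate ≥ 0.95, and distance from the source-read ends > 10 bp. The
within-read position is parsed from Stacks-style VCF ID fields
(`locus:column`); SNPs without a parseable offset pass the end filter
and are flagged in the report, since the margin cannot be evaluated.
The 10 bp margin itself is a package default (the rule's upstream
description does not quantify "ends"), configurable. Surviving SNPs
within 20 bp on a scaffold merge into one candidate microhaplotype;
conflicting loci closer than 30 kb are resolved greedily by highest
minimum per-collection MAF, leftmost on ties (the resolution rule is a
package choice; sources do not state one). Because dropping a winning
locus can free its spacing window for a neighbour, the final selection
is not globally monotone in the thresholds; the monotone property (and
the tested invariant) is the retained-SNP set. Consensus amplicons
span [min SNP − 50, max SNP + 50] with major alleles substituted,
truncated (and flagged) at scaffold edges; coordinates are 1-based
inclusive externally and 0-based within amplicons.

The contamination screen computes per-sample multilocus
heterozygosity H_I = het calls / called loci and flags samples more
than 2 population SDs above the cohort mean (one-sided by default,
matching the inflation signature of cross-contamination; two-sided
available).

## Synthetic data

The generator emulates a GT-seq kinship panel study:

- **Allele frequencies.** 170 loci; allele counts uniform on 2–8 (the
  empirical allele-count histogram for such panels is not published,
  so uniform is an explicit assumption); symmetric Dirichlet
  frequencies with a single concentration scalar bisected until the
  realized mean expected heterozygosity is 0.46 ± 0.02. The bisection
  uses inverse-CDF gammas on fixed uniforms (via Gamma(a) =
  Gamma(a+1)·U^(1/a) in log space) so realized He is a smooth
  increasing function of the concentration; infeasible targets raise
  an error naming the achievable range.
- **Pedigrees.** Founders drawn from Hardy–Weinberg, offspring by
  uniform gamete choice per parent per locus; gamete tags make IBD
  sharing exactly observable for tests. Truth labels: SELF, PO, FS,
  HS (exactly one shared parent), OTHER (any other ancestor overlap,
  e.g. grandparent or avuncular), U.
- **Error and reads.** The ε-channel genotyping-error layer and
  phred-rate base substitution errors are separate layers; tests use
  one at a time. Read depth is negative binomial (default mean 200×,
  dispersion 8 — overdispersion typical of amplicon data; the study
  scale of ~4300× is configurable but not the desk default).
  Heterozygote reads pick either haplotype with probability ½. Output
  is minimal standard-compliant SAM: unpaired, forward strand,
  full-match CIGAR, MAPQ 60.
- **Sex locus.** Males receive reads on a single-allele SRY amplicon
  at ~5×10⁻⁴ of their total reads (the empirical male read-fraction
  distribution is not published; this sits comfortably above the 10⁻⁴
  calling threshold at default depths), females none.
- **Validation scenario.** 36 individuals (24 F / 12 M) sampled 82
  times with recapture counts 2–7 for 15 of them: a matriarch with
  three litters by different sires (litter sizes 3/2/2, typical of
  black bears), a daughter's litter of 2, an unrelated family of 3
  cubs, and 17 unrelated harvest-like singletons. This yields 24 PO
  and 9 FS pairs plus HS/OTHER structure and a large unrelated block.

What the synthetic data does *not* emulate: real amplification-bias
and allele-dropout structure, index hopping, primer failure, linked
loci, population structure in the reference frequencies, or DNA
degradation. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under their stated model, not field
performance on degraded samples.

## Classification

Hierarchy: duplicates first (≤ 10 genotype mismatches joins samples;
connected components are individuals; per-locus majority consensus
with ties set missing — the consensus rule is a package choice), then
for each individual pair the relatedness gate Λ_PO/U > η_PO/U OR
Λ_FS/U > η_FS/U (the combination rule is stated as OR here; sources
use both ratios without stating a combination), then PO iff
Λ_PO/FS > 3, else FS iff Λ_FS/HS > η_FS/HS, else
AMBIGUOUS_SECOND_ORDER — pairs are not forced into a first-order
category. A pair sharing fewer than 50% of loci is never auto-joined
as a duplicate (guard against high-missingness merges). Sex: male iff
SRY-aligned reads are strictly more than 0.01% of total reads; zero
total reads gives UNKNOWN. PO edges are undirected — parent vs
offspring cannot be distinguished without ages.

## Problem sizes and tolerances in the test suite

Oracle-equivalence runs 1000 random loci with ≤ 4 alleles at |Δ| <
1e-12; normalization 200 random loci at 1e-10; threshold calibration
and the fresh-sample FNR check use 10,000 pairs (3 binomial SEs);
importance-sampling checks use 2×10⁵ IS draws against exact
enumeration and 10⁶ direct draws; the end-to-end scenario runs at
200× simulated depth with 2000 HWE permutations in QC and judges
relationship recovery over all first-order pairs plus 10⁵ simulated
unrelated pairs. These sizes keep the full suite within a desktop-
scale run while leaving Monte-Carlo error well inside the asserted
bands.

## Known limitations

- Locus independence is assumed throughout (panel spacing is the
  mitigation); linked-marker kinship models are out of scope.
- Inbreeding-adjusted genotype frequencies are not implemented.
- The ε error channel is a single-parameter approximation; real
  per-locus error heterogeneity (e.g. depth-dependent dropout) is not
  modeled.
- PO/FS discrimination is intrinsically weak at ~170 loci; the fixed
  PO/FS > 3 rule leaves a percent-scale exchange rate between PO and
  FS labels, which the threshold table quantifies per panel.
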