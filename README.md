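# microkin

Microhaplotype panel design, amplicon genotype calling, and close-kin
log-likelihood-ratio inference for GT-seq data.

`microkin` is aimed at wildlife and conservation geneticists who build
genotyping-in-thousands (GT-seq) panels for individual identification
and pairwise kinship — for example, resolving parent–offspring and
sibling structure in a bear population from biopsy darts and
hunter-harvest tissue. It covers the full workflow:

1. **Panel design** — select clusters of high-MAF SNPs from a
   population VCF (global MAF, per-collection MAF, call rate, read-end
   avoidance, 20 bp clustering into microhaplotypes, 30 kb spacing) and
   extract consensus amplicons from the reference, plus a multilocus-
   heterozygosity contamination screen.
2. **Genotype calling** — multiallelic microhaplotype calls from
   aligned amplicon reads (SAM), with depth, posterior, and allelic-
   ratio filters, a Monte-Carlo exact test of Hardy–Weinberg
   proportions, and locus/sample QC.
3. **Kinship inference** — exact genotype-pair probabilities under
   Cotterman IBD models with a genotyping-error channel, multilocus
   log-likelihood ratios, simulation-calibrated thresholds, and
   importance-sampled false-positive rates for the deep tail.
4. **Classification** — duplicate-sample matching, hierarchical
   relationship labels (PO / FS / ambiguous second-order / unrelated),
   SRY-based sex calling, and family networks.
5. **Synthetic data** — a generator for calibrated allele-frequency
   panels, pedigrees with Mendelian transmission, genotyping error,
   and simulated amplicon reads, so the whole pipeline is testable
   without any external download.

## The model

A pairwise relationship is summarized by its Cotterman coefficients
κ = (κ0, κ1, κ2), the probabilities of sharing 0, 1, or 2 alleles
identical by descent at a locus (SELF = (0,0,1), PO = (0,1,0),
FS = (¼,½,¼), HS = (½,½,0), U = (1,0,0)). The probability of a pair of
true genotypes at one locus is

```
P(T1, T2 | κ) = κ0·P(T1)P(T2) + κ1·P(T1)·Trans(T2|T1) + κ2·P(T1)·1[T2 = T1]
```

with Hardy–Weinberg genotype frequencies P(·) and the shared-gamete
transmission kernel Trans. Observed genotypes pass through a
true-genotype-independent error channel, `P(O|T) = (1−ε)·1[O=T] +
ε·P_HWE(O)`, with ε = 0.005 by default. The pairwise statistic is the
multilocus log-likelihood ratio, e.g.

```
Λ_PO/U = Σ_loci log [ P(pair | PO) / P(pair | U) ]
```

Decision thresholds η are the empirical quantiles of simulated
true-relationship Λ distributions at a target false-negative rate
(default 0.01), and false-positive rates are estimated by importance
sampling from the numerator relationship,
`P(Λ > η | U) = E_PO[ exp(−Λ)·1{Λ > η} ]`, which reaches tail
probabilities far below direct Monte-Carlo resolution.

## Worked example

```python
import numpy as np
from microkin import PanelSpec, simulate_allele_frequencies, build_threshold_table
from microkin.kinship import PO, U, LLRConfig
from microkin.power import simulate_llr_distribution

freqs = simulate_allele_frequencies(PanelSpec(seed=1))   # 170 loci, 2-8 alleles
print(f"mean He = {freqs.mean_expected_heterozygosity():.4f}")

table = build_threshold_table(freqs, seed=11)
print(table.to_frame()[["comparison", "eta", "fpr", "fpr_se"]].to_string(index=False))

po = simulate_llr_distribution(freqs, PO, LLRConfig(PO, U), n_pairs=10000, seed=3)
print(f"PO Lambda range: {po.samples.min():.1f} .. {po.samples.max():.1f}")
```

prints

```
mean He = 0.4624
comparison        eta          fpr       fpr_se
    SELF/U 200.726490 1.287539e-90 6.219359e-92
      PO/U  32.160772 4.707939e-17 1.497180e-18
      FS/U  22.467760 6.167463e-13 2.156178e-14
     FS/HS   1.062547 2.740424e-03 5.996492e-05
     PO/FS   3.000000 7.337021e-04 1.143802e-05
PO Lambda range: 18.8 .. 85.1
```

The mean expected heterozygosity is calibrated to 0.46; each row gives
the Λ cutoff at a 1% false-negative rate for that comparison and the
importance-sampled probability that a pair simulated under the
*denominator* relationship still exceeds it (with its Monte-Carlo
standard error). SELF/U is astronomically safe — the basis for genetic
mark–recapture — and PO/FS uses the conventional fixed cutoff of 3.

The full synthetic study (82 samples from 36 individuals with known
pedigree, reads included) is one call:

```bash
microkin simulate --seed 1 --outdir study/
microkin genotype --sam-dir study/sam --catalog study/catalog.tsv --out-genotypes study/geno.tsv
microkin sex --read-counts study/read_counts.tsv --out study/sex.tsv
```

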