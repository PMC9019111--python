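# kdrhap

Haplotype analysis of target-site insecticide resistance in malaria
vectors, built as a reusable, fully tested pipeline.

Pyrethroid insecticides target the voltage-gated sodium channel (VGSC);
amino-acid substitutions in the *Vgsc* gene — classically L995F and L995S
(*kdr*, "knock-down resistance") — reduce knock-down and sweep through
mosquito populations under the selection pressure of treated bed-nets.
Surveillance programmes genotype codon 995, but phased whole-genome data
can do much more: identify which *genetic background* a resistance allele
rides on, track those backgrounds between countries, and nominate small
SNP panels that a field assay can genotype instead of a whole genome.
`kdrhap` implements that analysis stack for anyone with a phased VCF, a
gene model, a reference sequence and a sample table — and ships a seeded
synthetic-cohort generator that plants sweep haplotype groups with full
ground truth, so every stage is testable without controlled-access data.

## What it computes

| Stage | Statistic |
|---|---|
| `genemodel` / `alignment` | codon effects of SNPs in any transcript (strand-aware, multi-allelic); cross-species codon-number maps via global protein alignment |
| `popgen` | per-population allele frequencies and the max-frequency filter; Lewontin's D′ per allele pair; nucleotide diversity π; π<sub>N</sub>/π<sub>S</sub> with Nei–Gojobori site opportunities; Dirichlet Monte-Carlo heterozygote-excess test |
| `groups` | pairwise Hamming distances, hierarchical clusters, median-joining networks (Bandelt) with edge pruning, non-synonymous edge labels, group concordance |
| `selection` | core haplotypes, EHH decay (excluding non-synonymous and singleton SNPs), moving-window haplotype homozygosity, fixed-difference divergence tracts, shared-haplotype lengths in cM with bootstrap CIs, first-detection-year correlation |
| `assay` | information-gain ranking of SNPs, ID3/CART decision trees over binary SNP features, stratified k-fold CV, surveillance panel tables |
| `simulate` | seeded synthetic cohort: reference FASTA, GFF3, phased VCF, metadata, truth table |

Key statistics, in the field's notation: D′ = D/D<sub>max</sub> with
D = p<sub>ab</sub> − p<sub>a</sub>p<sub>b</sub>; EHH at position *x* =
Σ<sub>i</sub> C(c<sub>i</sub>,2)/C(n,2) over classes of carriers
identical from the core out to *x*; haplotype homozygosity
H = Σ c<sub>i</sub>(c<sub>i</sub>−1)/(n(n−1)); the heterozygote-excess
test draws allele frequencies from Dirichlet(counts + 1), forms
Hardy–Weinberg genotype proportions, simulates genotype counts for *n*
diploids and reports the fraction of replicates whose compound
heterozygote count strictly exceeds the observed one.

## Worked example

Generate the default synthetic cohort (16 populations, 384 phased
haplotypes, twelve planted sweep groups), recover the groups by
clustering, and run the heterozygote-excess test on a published-style
input:

```python
import collections
from kdrhap import (default_config, generate_cohort, pairwise_hamming,
                    hierarchical_groups, het_excess_test)

cohort = generate_cohort(default_config(seed=1))
h = cohort.haplotypes
print("haplotypes:", h.n_haplotypes, "| variant sites:", h.n_sites)

fc = cohort.focal_carriage()
dist = pairwise_hamming(h, window=cohort.config.gene_interval)
labels = hierarchical_groups(dist, fc, cut_height=5.0, min_group_size=3)
print(dict(sorted(collections.Counter(labels).items())))

res = het_excess_test(c_f=312, c_s=93, c_wt=189, n=297,
                      observed_het=50, reps=1_000_000, seed=1)
print("p =", res.p_value)
```

prints

```
haplotypes: 384 | variant sites: 3654
{'F1': 56, 'F2': 16, 'F3': 14, 'F4': 12, 'F5': 10, 'L1': 10, 'L2': 8,
 'S1': 32, 'S2': 16, 'S3': 14, 'S4': 12, 'S5': 12, 'wt': 172}
p = 0.410488
```

The recovered group sizes match the planted truth exactly (F1…F5 carry
the L995F-analogue allele, S1…S5 the L995S analogue, L1/L2 the two minor
alleles, `wt` is wild type).  The p-value says that in 41% of a million
Hardy–Weinberg simulations the compound-heterozygote count exceeded the
observed 50 of 297 — no evidence of excess in that cohort.

The whole pipeline, with a manifest of outputs, runs from the shell:

```sh
kdrhap run-all --out out/ --seed 1          # synthetic cohort end to end
kdrhap simulate --seed 1 --out data/        # just the generator
kdrhap hetexcess --c-f 45 --c-s 93 --c-wt 0 --n 69 --observed-het 41 --seed 1
```

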