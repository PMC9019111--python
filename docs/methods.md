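# Methods

This note documents the models and procedures implemented in `kdrhap`,
the defaults they use, and the design choices made where more than one
reasonable construction exists.

## Coordinates and data model

All genomic coordinates are 1-based; intervals are end-exclusive
(`(start, end)` has length `end − start`), matching how a VCF position
and a window tiling compose.  CDS exons follow the GFF convention
(1-based, inclusive); functions doing half-open arithmetic internally
say so in their docstrings.  The central container is the
`HaplotypeMatrix`: a (sites × haplotypes) matrix of allele codes
(0 = reference), two haplotype columns per diploid sample, with
per-haplotype population/species/year metadata.  Phasing is a hard
requirement — an unphased genotype in the input VCF is an error.

## Codon-effect annotation

A variant is annotated by splicing the CDS from the reference
(reverse-complemented for minus-strand transcripts), substituting the
alternate base in transcript orientation, and translating the affected
codon with the standard genetic code.  Effects are `synonymous`,
`missense`, or `nonsense` — nonsense changes are a separate class and
never folded into missense.  Multi-allelic sites are decomposed into
`(site, alt_index)` allele records; every downstream allele-level
statistic addresses alleles, not sites.  Cross-transcript annotation
flags variants whose effect class differs between transcripts
(counting "non-coding" as a class), which is how alternative splicing
can hide a protein-changing variant from a single canonical transcript.

## Cross-species codon maps

Resistance alleles are named in two numbering frames (the vector's own
transcript and the housefly frame in which *Vgsc* alleles were first
described).  The map between frames comes from an end-to-end
Needleman–Wunsch alignment of the two protein sequences using the Gotoh
three-state affine-gap recursion, BLOSUM62 scoring, gap open 10 and
extension 1 (a gap of length k costs `open + (k−1)·extend`).  The
dynamic program is written out in-package so the traceback tie-break is
deterministic: at equal score, match/mismatch is preferred over a gap in
the second sequence, which is preferred over a gap in the first.  Tests
cross-check the optimal score against Biopython's pairwise aligner under
the same scoring.

## Population-genetic statistics

**Allele frequencies** are exact haplotype-count ratios per population;
the retention filter keeps alleles whose *maximum* per-population
frequency is at or above the threshold (default 5%, inclusive).

**Lewontin's D′** is computed from haplotype frequencies with each
allele binarised to carrier/non-carrier, so multi-allelic sites
contribute one result per allele pair.  `D = p_ab − p_a p_b`;
`Dmax = min(p_a(1−p_b), (1−p_a)p_b)` for positive D, else
`min(p_a p_b, (1−p_a)(1−p_b))`.  Monomorphic alleles yield an
undefined-flagged result rather than NaN.  D′ is antisymmetric under
relabelling which allele at a site is "alt": the magnitude is invariant,
the sign flips.

**Nucleotide diversity** uses the unbiased unordered-pair estimator:
mean pairwise Hamming differences over C(n,2) pairs divided by interval
length.  π<sub>N</sub>/π<sub>S</sub> normalises the missense and
synonymous pairwise-difference sums by Nei–Gojobori site opportunities —
per codon, each of the 9 possible single-base changes is classified by
translation and the codon contributes (changes/3) sites to each class;
changes creating a stop count as non-synonymous.  The unnormalised
variant-site ratio is available behind `normalize=False`.  A subset with
no synonymous diversity gives an undefined-flagged ratio.

**Heterozygote-excess test.** Given allele counts (c_F, c_S, c_wt) from
2n haplotypes and an observed count of F/S compound heterozygotes among
n diploids, each of the (default 1,000,000) replicates draws allele
frequencies from Dirichlet(c_F+1, c_S+1, c_wt+1) — a flat prior over the
frequency simplex — forms Hardy–Weinberg genotype proportions, and draws
genotype counts for n diploids from the implied multinomial.  Only the
F/S-heterozygote coordinate matters, and its multinomial marginal is
exactly Binomial(n, 2 p_F p_S), which is what is sampled (vectorised;
one million replicates take about a second).  The p-value is the
fraction of replicates *strictly* exceeding the observed count, so ties
do not count toward significance.  Two calibration facts are worth
knowing.  Under the test's own generative model (fixed counts, Dirichlet
frequencies, binomial draw) the p-values are essentially uniform: the
measured type-I error at nominal 0.05 is ≈0.057.  Under an external null
— genotypes drawn from true Hardy–Weinberg frequencies, with allele
counts then recomputed from those same genotypes — the test is
conservative (type-I ≈0.01–0.02 at any n), because the allele counts
include the observed heterozygotes and the posterior-predictive
distribution therefore tracks the observation.  This conservativeness is
inherent to the construction, not an implementation artefact.

## Haplotype grouping

Distances are exact integer Hamming counts over biallelic sites in a
fixed window (by default, the gene span).  Hierarchical grouping uses
average-linkage agglomerative clustering cut at a height expressed in
SNP differences (default 5); linkage and cut height are configurable.
Clusters smaller than `min_group_size` (default 3) dissolve into
`OR`/`wt` by focal-allele carriage.

The median-joining network follows Bandelt's construction: iterate —
build the ε-relaxed minimum spanning network over the current node set
(ε defaults to 0); for every mutually connected node triple, form the
per-site majority-consensus median and add it as an inferred node when
the three-edge star through it is shorter than connecting the triple
directly; repeat to fixation.  Median candidates are generated only from
connected triples in deterministic lexicographic order, so output is
reproducible and invariant to input haplotype order.  Unused (degree ≤ 1)
median nodes are removed; edges longer than `max_edge_dist` (default 2
SNPs) are pruned *after* construction, and connected components are
recorded afterwards — small components may be hidden in display exports
but are never dropped from the data structure.  A note on a tempting
invariant: the *total* edge length of a minimum spanning network can
exceed the MST length when homoplasy creates tied cycles (a 4-cycle of
unit edges has MSN length 4 versus MST 3, and no admissible median
helps); what is true, and tested, is that a spanning tree over the node
set including medians is never longer than one over the observed
haplotypes alone.

Group labels follow field convention: clusters/components whose members
carry a focal resistance allele are named by that allele's base letter
and ranked by decreasing size (F1 = largest group on the L995F-analogue
allele); single-group alleles keep their own name (L1, L2); carriers
outside any labelled group are `OR` (other resistant); the rest are
`wt`.  A haplotype only ever receives an F/S label if it itself carries
the focal allele.  Concordance between two assignments is the fraction
of haplotypes co-assigned under the best one-to-one label matching
(maximum-agreement bipartite assignment), so pure relabellings score 1.

## Selection scans

**Core haplotypes** are the distinct allele strings over a short core
interval; cores at a cohort frequency not strictly above the threshold
(default 1%; "above" is a strict comparison) are dropped, and retained
cores are labelled by their focal-allele content.

**EHH** for a core's carriers partitions them, site by site moving away
from the core, by their haplotype string from the core edge to the
current site; EHH = Σ C(c_i,2)/C(n,2).  Missense/nonsense sites and
cohort-wide singletons are excluded from the partitioning — the former
so the decay reflects the genetic background rather than the resistance
alleles themselves, the latter as phasing/sequencing noise; the
exclusion is cohort-wide, not per population.  EHH is 1 at the core by
construction, non-increasing outward, is a step function indexed at site
positions (no interpolation), and stops at the region edge.

**Windowed haplotype homozygosity** uses the same unbiased estimator
H = Σ c_i(c_i−1)/(n(n−1)) per window; a window with no variant sites has
H = 1.  The **divergence scan** counts sites fixed for different alleles
in two groups, per window, and merges contiguous non-zero windows into
reported tracts — the tool that localises a gene-conversion segment
separating two otherwise identical sweep groups.

**Shared haplotype lengths**: for each unordered carrier pair, both
flanks extend independently from the core edges to the first mismatch at
an included site; the shared interval's length is measured on a genetic
map (piecewise-constant cM/Mb; default a single constant 1 cM/Mb, since
no specific map is assumed).  Pairs identical out to a region edge are
censored at the edge and flagged.  The summary is the median with a
seeded percentile-bootstrap CI (default 2,000 replicates).  The
first-detection-year analysis is a Pearson correlation of each group's
earliest collection year against its median shared length, with the
two-sided p from the t transform; zero variance in either variable flags
the result undefined.

## Panel design

Haplotypes are labelled by group (everything non-resistant merged to a
single `wt` class) and featurised as binary carrier indicators over
biallelic SNPs in the gene ± flank (default 10 kb for the frequency
table, 20 kb for trees).  SNPs are ranked by information gain in bits.
Trees are greedy and top-down with either information-gain (ID3-style)
or Gini (CART-style) splits; ties break to the lowest SNP index (or a
seeded random order when stochastic tie-breaking is enabled), leaves
predict the majority class with ties to the lexicographically lowest
label, and growth stops on purity, maximum depth, or no positive gain —
with one exception: a zero-gain split is still taken when a one-step
lookahead finds a positive-gain split in a child, so parity patterns
(XOR-style allele combinations) remain learnable.  Accuracy is assessed
by stratified k-fold cross-validation (default 5 folds, configurable to
10), repeated with derived seeds; classes rarer than the fold count are
merged into `wt` with a notation in the results rather than erroring.
Each result row records the number of distinct SNPs the trained tree
actually used — the quantity that matters for assay multiplexing.

## The synthetic cohort generator

The generator emulates the structure of a multi-country phased cohort
around a single insecticide-target gene.  It is not a coalescent
simulator; each ingredient is the simplest mechanism that produces the
feature the pipeline must detect.

* **Wild-type variation.** Segregating sites are dropped at density θ
  (default 7×10⁻³/bp) with allele counts realised over a pool of K = 24
  founder haplotypes from a 1/i-weighted frequency spectrum; each
  wild-type haplotype is a founder mosaic with Poisson switch points
  (default rate 2×10⁻⁴/bp), which creates background LD and finite
  haplotype-block structure.  Under the defaults wild-type π over the
  gene is ≈1.5–2×10⁻³/bp, the order observed in high-diversity vector
  populations.
* **Sweep groups.** Each group copies one founder haplotype, receives
  its focal missense allele (the generator searches the CDS near a
  configured anchor for a substitution that translates to a missense
  change) plus a few non-coding group-diagnostic SNPs inside the core
  interval, so each group has a unique core string.  Recombination
  erodes each carrier independently: per flank, the distance from the
  *gene edge* to the nearest breakpoint is exponential with rate `g_r`
  (expected breakpoints per bp — sweep age × per-generation
  recombination rate; defaults 0.5–1.5×10⁻⁵/bp across groups); beyond
  the breakpoint the carrier continues as a freshly drawn wild-type
  haplotype.  Measuring from the gene edge rather than the core keeps
  the gene body near-identical within a group — the empirical signature
  these sweeps show — while still producing EHH decay and
  shared-length variation on the flanks; the within-group diversity a
  mid-gene breakpoint would create belongs to much older sweeps than
  the ones modelled here.
* **Secondary mutations** radiate on one group (default F1) as planted
  missense alleles on small *disjoint* carrier subsets placed in the
  gene but outside the core — the star-shaped radiation a
  median-joining network should display, without splitting the group's
  core string.  Private singleton mutations (Poisson per carrier,
  default mean 0.5) land anywhere in the region.
* **Gene conversion.** One group shares its founder with a twin group
  and carries a planted run of fixed differences (default 6) inside a
  tract upstream of the focal codon; at least two tract sites are
  anchored inside the core so the twins' cores differ.  The twins carry
  no other diagnostics, so the tract is exactly their divergence — and
  the divergence scan must recover exactly the planted count.
* **Assembly.** Haplotypes are paired into diploids within populations
  and written as a phased VCF alongside the reference FASTA, GFF3 gene
  model, metadata TSV and a truth table.  All randomness flows from one
  mandatory seed; two runs with the same config are byte-identical.

Default scale: a 500-kb region, an 18-kb three-exon gene, a ~6-kb core,
16 populations × 12 diploid samples = 384 haplotypes, twelve sweep
groups totalling just under half the cohort.  At this scale the full
pipeline runs in well under a minute, which is the intended size for
validation work.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: coalescent genealogies and realistic allele
frequency spectra under drift; population structure beyond discrete
labels; overlapping or soft sweeps; genotyping and phasing error; gaps
and inaccessible regions in the reference.  Recovery results on the
synthetic cohort demonstrate that the statistics detect the features
they target at realistic magnitudes — not that real cohorts are as
cleanly separable.

## Numerical and procedural choices

* Threshold comparisons follow their verbal definitions exactly:
  allele retention is inclusive ("at or above 5%"), core retention is
  strict ("above 1%"), heterozygote-excess exceedance is strict.
* The EHH wild-type reference used in validation is the carrier-weighted
  mean EHH over wild-type cores: individual wild-type cores at this
  cohort size can hold 4–9 carriers, where single-core EHH is dominated
  by sampling noise.
* Bootstrap CIs use the percentile method with a seeded generator.
* Degenerate inputs error early and specifically: diversity on fewer
  than two haplotypes, EHH with fewer than two carriers, non-biallelic
  sites in a network window, inconsistent allele counts in the
  heterozygote-excess test, invalid simulation configs (which list every
  violation at once).
* Determinism: every stochastic routine takes an explicit seed; the
  pipeline manifest records parameters, seeds and SHA-256 checksums of
  all outputs, and reruns are byte-identical.

## Known limitations

* The medians of shared-haplotype lengths depend on the genetic map;
  with the default constant 1 cM/Mb map they are comparable between
  groups but not calibrated to any particular chromosome.
* The median-joining implementation targets the gene-scale windows used
  here (hundreds of distinct haplotypes); it is quadratic in node count
  and not meant for genome-scale inputs.
* ID3/CART trees are single trees by design — the question is how few
  SNPs suffice, not maximal classifier performance.
* The heterozygote-excess test inherits the conservativeness described
  above whenever its allele counts are computed from the same genotypes
  that provide the observed heterozygote count.
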