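"""Allele frequencies, linkage disequilibrium, diversity and the
heterozygote-excess Monte-Carlo test.

All statistics are haplotype-based: frequencies are counted over phased
haplotype columns, and Lewontin's D' is computed from haplotype (gamete)
frequencies directly rather than inferred from genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .genemodel import CodonEffect
from .hapmatrix import HaplotypeMatrix

__all__ = [
    "allele_frequencies",
    "filter_by_max_frequency",
    "lewontin_dprime",
    "LDResult",
    "nucleotide_diversity",
    "pin_pis_ratio",
    "DiversityResult",
    "het_excess_test",
    "HetExcessResult",
    "synonymous_opportunities",
]

Allele = tuple[int, int]  # (site_index, alt_index)


# ----------------------------------------------------------- frequencies


def allele_frequencies(
    haps: HaplotypeMatrix,
    grouping: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-population allele frequencies for every alternate allele.

    Parameters
    ----------
    haps : HaplotypeMatrix
    grouping : optional mapping population -> haplotype column indices;
        defaults to grouping by the metadata ``population`` column.

    Returns
    -------
    DataFrame with one row per (site, alt allele): columns chrom, pos,
    ref, alt, alt_index, then one frequency column per population.
    Frequencies are exact count ratios; an empty population yields NaN.
    """
    if grouping is None:
        grouping = {p: haps.population_haplotypes(p) for p in haps.populations()}
    rows = []
    for i, site in enumerate(haps.sites):
        for alt_index, alt in enumerate(site.alts):
            row: dict = dict(
                chrom=site.chrom, pos=site.pos, ref=site.ref, alt=alt, alt_index=alt_index
            )
            for pop, idx in grouping.items():
                n = len(idx)
                row[pop] = np.nan if n == 0 else float(
                    np.count_nonzero(haps.codes[i, idx] == alt_index + 1) / n
                )
            rows.append(row)
    return pd.DataFrame(rows)


def filter_by_max_frequency(
    table: pd.DataFrame, threshold: float = 0.05
) -> pd.DataFrame:
    """Keep alleles whose maximum per-population frequency is >= threshold.

    The comparison is inclusive ("at or above"), so an allele at exactly
    the threshold in a single population is retained.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    id_cols = ["chrom", "pos", "ref", "alt", "alt_index"]
    pop_cols = [c for c in table.columns if c not in id_cols]
    max_freq = table[pop_cols].max(axis=1)
    return table[max_freq >= threshold].reset_index(drop=True)


# -------------------------------------------------------------------- LD


@dataclass(frozen=True)
class LDResult:
    """Lewontin's D' for one pair of alleles (carrier/non-carrier coding)."""

    allele_a: Allele
    allele_b: Allele
    D: float
    Dmax: float
    Dprime: float
    defined: bool

    def __post_init__(self) -> None:
        if self.defined and not (-1 - 1e-9 <= self.Dprime <= 1 + 1e-9):
            raise ValueError(f"|D'| > 1: {self.Dprime}")


def lewontin_dprime(
    haps: HaplotypeMatrix,
    allele_a: Allele,
    allele_b: Allele,
    hap_subset: np.ndarray | None = None,
) -> LDResult:
    """Normalised linkage coefficient D' between two alleles.

    Each allele is binarised to carrier/non-carrier over the haplotype
    set, so multi-allelic sites contribute one result per allele pair.
    D = p_ab - p_a p_b; Dmax = min(p_a(1-p_b), (1-p_a)p_b) when D > 0,
    else min(p_a p_b, (1-p_a)(1-p_b)); D' = D / Dmax.  D' = +1 means one
    allele is only found with the other; -1 means they never co-occur.
    A monomorphic allele gives an undefined-flagged result (no NaNs leak).
    """
    cols = slice(None) if hap_subset is None else np.asarray(hap_subset)
    a = haps.codes[allele_a[0], cols] == allele_a[1] + 1
    b = haps.codes[allele_b[0], cols] == allele_b[1] + 1
    n = a.size
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LDResult(allele_a, allele_b, 0.0, 0.0, 0.0, defined=False)
    p_ab = np.count_nonzero(a & b) / n
    D = p_ab - p_a * p_b
    if D > 0:
        Dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        Dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    Dprime = 0.0 if Dmax == 0 else D / Dmax
    return LDResult(allele_a, allele_b, float(D), float(Dmax), float(Dprime), defined=True)


def dprime_matrix(
    haps: HaplotypeMatrix, alleles: list[Allele]
) -> pd.DataFrame:
    """Symmetric D' matrix over a list of alleles (NaN where undefined)."""
    k = len(alleles)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    for i, j in combinations(range(k), 2):
        res = lewontin_dprime(haps, alleles[i], alleles[j])
        if res.defined:
            mat[i, j] = mat[j, i] = res.Dprime
    labels = [f"{haps.sites[s].pos}:{haps.sites[s].alts[a]}" for s, a in alleles]
    return pd.DataFrame(mat, index=labels, columns=labels)


# --------------------------------------------------------------- diversity


@dataclass
class DiversityResult:
    """Per-bp nucleotide diversity for a haplotype subset, optionally split
    into non-synonymous and synonymous components."""

    label: str
    interval: tuple[int, int]
    pi_per_bp: float
    n_haplotypes: int
    pi_n: float | None = None
    pi_s: float | None = None
    ratio: float | None = None
    ratio_defined: bool = True


def _mean_pairwise_differences(sub: np.ndarray) -> float:
    """Mean Hamming distance over all unordered column pairs.

    Computed per site from allele counts: a site with counts c_k over n
    haplotypes contributes (n^2 - sum c_k^2) / 2 mismatching pairs.
    """
    n = sub.shape[1]
    if n < 2:
        raise ValueError("need at least two haplotypes")
    total = 0.0
    for row in sub:
        counts = np.bincount(row)
        total += (n * n - np.sum(counts.astype(np.int64) ** 2)) / 2
    return total / (n * (n - 1) / 2)


def nucleotide_diversity(
    haps: HaplotypeMatrix,
    subset: np.ndarray,
    interval: tuple[int, int],
    label: str = "",
) -> DiversityResult:
    """Per-bp pi: mean pairwise differences / interval length.

    ``interval`` is (start, end), 1-based, end-exclusive; the unordered
    n-choose-2 pair denominator gives the unbiased estimator.
    """
    subset = np.asarray(subset)
    if subset.size < 2:
        raise ValueError("subset must contain at least two haplotypes")
    start, end = interval
    length = end - start
    if length <= 0:
        raise ValueError("empty interval")
    rows = haps.site_index_in(start, end)
    sub = haps.codes[np.ix_(rows, subset)]
    mpd = _mean_pairwise_differences(sub) if len(rows) else 0.0
    return DiversityResult(
        label=label,
        interval=interval,
        pi_per_bp=mpd / length,
        n_haplotypes=int(subset.size),
    )


def synonymous_opportunities(coding_sequence: str) -> tuple[float, float]:
    """Counts of non-synonymous and synonymous site-opportunities in a CDS.

    Per codon, each of the 9 possible single-base changes is classified by
    translation; the codon contributes (changes/3) sites to each class
    (Nei-Gojobori counting).  Changes creating a stop count as
    non-synonymous.  Returns (n_nonsyn_sites, n_syn_sites).
    """
    from Bio.Seq import Seq

    if len(coding_sequence) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    nucs = "ACGT"
    n_nonsyn = n_syn = 0.0
    for i in range(0, len(coding_sequence), 3):
        codon = coding_sequence[i : i + 3].upper()
        aa = str(Seq(codon).translate())
        syn = 0
        for j in range(3):
            for nt in nucs:
                if nt == codon[j]:
                    continue
                mut = codon[:j] + nt + codon[j + 1 :]
                if str(Seq(mut).translate()) == aa:
                    syn += 1
        n_syn += syn / 3
        n_nonsyn += (9 - syn) / 3
    return n_nonsyn, n_syn


def pin_pis_ratio(
    haps: HaplotypeMatrix,
    subset: np.ndarray,
    effects: dict[int, CodonEffect | str],
    coding_sequence: str,
    label: str = "",
    normalize: bool = True,
) -> DiversityResult:
    """Ratio of non-synonymous to synonymous nucleotide diversity.

    pi_N is the mean pairwise difference count restricted to missense (and
    nonsense) sites, divided by the CDS's non-synonymous site-opportunity
    count; pi_S likewise for synonymous sites.  ``effects`` maps matrix
    site index -> CodonEffect (sites without a coding effect are ignored).
    With ``normalize=False`` the raw per-variant-site sums are used
    instead of opportunity counts (the unnormalised variant-site ratio).
    """
    subset = np.asarray(subset)
    if subset.size < 2:
        raise ValueError("subset must contain at least two haplotypes")
    nonsyn_rows = [
        i for i, e in effects.items()
        if not isinstance(e, str) and e.effect_class in ("missense", "nonsense")
    ]
    syn_rows = [
        i for i, e in effects.items()
        if not isinstance(e, str) and e.effect_class == "synonymous"
    ]

    def diff_sum(rows: list[int]) -> float:
        if not rows:
            return 0.0
        return _mean_pairwise_differences(haps.codes[np.ix_(np.array(rows), subset)])

    d_n = diff_sum(nonsyn_rows)
    d_s = diff_sum(syn_rows)
    if normalize:
        opp_n, opp_s = synonymous_opportunities(coding_sequence)
    else:
        opp_n, opp_s = max(len(nonsyn_rows), 1), max(len(syn_rows), 1)
    pi_n = d_n / opp_n if opp_n > 0 else 0.0
    pi_s = d_s / opp_s if opp_s > 0 else 0.0
    defined = pi_s > 0
    return DiversityResult(
        label=label,
        interval=(0, 0),
        pi_per_bp=float("nan"),
        n_haplotypes=int(subset.size),
        pi_n=pi_n,
        pi_s=pi_s,
        ratio=(pi_n / pi_s) if defined else None,
        ratio_defined=defined,
    )


# ----------------------------------------------- heterozygote-excess test


@dataclass
class HetExcessResult:
    """Monte-Carlo test for an excess of F/S compound heterozygotes."""

    c_f: int
    c_s: int
    c_wt: int
    n_individuals: int
    observed_het: int
    reps: int
    seed: int
    p_value: float
    mean_simulated: float = field(default=float("nan"))


def het_excess_test(
    c_f: int,
    c_s: int,
    c_wt: int,
    n: int,
    observed_het: int,
    reps: int = 1_000_000,
    seed: int = 0,
) -> HetExcessResult:
    """Empirical p-value for the observed count of F/S heterozygotes.

    Each replicate draws allele frequencies (p_F, p_S, p_wt) from
    Dirichlet(c_F+1, c_S+1, c_wt+1) (flat prior over the simplex), forms
    Hardy-Weinberg genotype proportions, and draws genotype counts for n
    diploid individuals from the implied multinomial.  Only the F/S
    heterozygote coordinate is recorded; its multinomial marginal is
    exactly Binomial(n, 2 p_F p_S), which is what is sampled.  The
    p-value is the fraction of replicates whose simulated heterozygote
    count strictly exceeds the observed count ("found higher
    proportions"), so ties do not count toward significance.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if c_f + c_s + c_wt != 2 * n:
        raise ValueError(f"allele counts {c_f}+{c_s}+{c_wt} != 2n = {2 * n}")
    if observed_het > n:
        raise ValueError("observed heterozygote count exceeds sample size")
    rng = np.random.default_rng(seed)
    freqs = rng.dirichlet(np.array([c_f, c_s, c_wt]) + 1.0, size=reps)
    p_het = 2.0 * freqs[:, 0] * freqs[:, 1]
    sim = rng.binomial(n, p_het)
    p_value = float(np.count_nonzero(sim > observed_het) / reps)
    return HetExcessResult(
        c_f=c_f,
        c_s=c_s,
        c_wt=c_wt,
        n_individuals=n,
        observed_het=observed_het,
        reps=reps,
        seed=seed,
        p_value=p_value,
        mean_simulated=float(sim.mean()),
    )
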