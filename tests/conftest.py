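"""Shared fixtures: toy gene models and synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from kdrhap.genemodel import GeneModel, VariantSite
from kdrhap.hapmatrix import HaplotypeMatrix
from kdrhap.simulate import (
    PopulationConfig,
    SweepGroupConfig,
    SweepSimConfig,
    default_config,
    generate_cohort,
)


def make_haps(codes, positions=None, alleles=None, populations=None, years=None):
    """Build a HaplotypeMatrix from a plain (sites x haplotypes) array.

    All sites default to biallelic A->T on chromosome "chr1" at 1-based
    positions 1, 2, ...; populations default to a single "pop1".
    """
    codes = np.asarray(codes, dtype=np.int16)
    n_sites, n_haps = codes.shape
    if positions is None:
        positions = list(range(1, n_sites + 1))
    sites = []
    for i, pos in enumerate(positions):
        if alleles is not None:
            ref, alts = alleles[i]
        else:
            n_alleles = max(int(codes[i].max()) + 1, 2)
            ref, alts = "A", tuple("TCG"[:n_alleles - 1])
        sites.append(VariantSite(chrom="chr1", pos=pos, ref=ref, alts=tuple(alts)))
    if populations is None:
        populations = ["pop1"] * n_haps
    if years is None:
        years = [2010] * n_haps
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{h // 2}" for h in range(n_haps)],
            "population": populations,
            "species": ["gambiae"] * n_haps,
            "year": years,
        }
    )
    return HaplotypeMatrix(codes=codes, sites=sites, meta=meta)


@pytest.fixture
def plus_strand_model():
    """Single-exon CDS at 101-109 with sequence ATGCTTTAA."""
    reference = "N" * 100 + "ATGCTTTAA" + "N" * 100
    # reference indexing is 0-based; replace Ns with real bases for safety
    reference = "A" * 100 + "ATGCTTTAA" + "A" * 100
    model = GeneModel(
        transcript_id="tx_plus", chrom="chr1", strand="+", cds_exons=[(101, 109)]
    )
    return model, reference


@pytest.fixture
def minus_strand_model():
    """CDS at 201-209 on the minus strand; plus-strand sequence TTACATCAT,
    so the CDS reads ATGATGTAA."""
    reference = "A" * 200 + "TTACATCAT" + "A" * 100
    model = GeneModel(
        transcript_id="tx_minus", chrom="chr1", strand="-", cds_exons=[(201, 209)]
    )
    return model, reference


def small_sim_config(seed: int) -> SweepSimConfig:
    """A fast, reduced cohort for unit tests (64 haplotypes, 120 kb)."""
    pops = [
        PopulationConfig("A", "gambiae", 8, 2009),
        PopulationConfig("B", "gambiae", 8, 2011),
        PopulationConfig("C", "coluzzii", 8, 2010),
        PopulationConfig("D", "coluzzii", 8, 2012),
    ]
    groups = [
        SweepGroupConfig("F1", "F", {"A": 8}, g_r=1e-5, secondary_carriers=[2]),
        SweepGroupConfig("S1", "S", {"B": 8}, g_r=1e-5),
        SweepGroupConfig("L1", "L1", {"C": 6}, g_r=1.5e-5),
    ]
    return SweepSimConfig(
        seed=seed,
        region_length=120_000,
        gene_interval=(50_001, 62_001),
        cds_exons=[(50_001, 53_000), (55_001, 58_000), (59_001, 62_000)],
        core_interval=(53_500, 57_000),
        focal_codons={"F": 56_000, "S": 56_100, "L1": 60_500, "L2": 51_000},
        populations=pops,
        n_founders=12,
        mosaic_switch_rate=2e-4,
        theta=4e-3,
        sweep_groups=groups,
        gene_conversion=None,
        n_diagnostic_per_group=3,
    )


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_sim_config(11))


@pytest.fixture(scope="session")
def default_cohort():
    """The package's reference study conditions at a fixed seed."""
    return generate_cohort(default_config(42))
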