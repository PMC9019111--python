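"""Seeded synthetic-cohort generator with planted sweep haplotype groups.

The generator emulates the structure of a multi-country phased cohort
around a single insecticide-target gene: deep wild-type diversity with
background linkage, a set of near-identical sweep haplotype groups each
carrying a planted resistance allele, secondary protein-changing
mutations radiating on one sweep background, EHH decay produced by
recombination onto wild-type backgrounds, and an optional gene-conversion
tract distinguishing two otherwise identical groups.  Every feature has a
ground-truth record, so each pipeline stage can be validated end to end
without external data.

Model sketch (all rates per bp, all randomness from one seed):

* Wild-type variation: segregating sites are dropped at density ``theta``
  with allele frequencies from a 1/i-weighted spectrum realised over a
  pool of founder haplotypes; each wild-type haplotype is a founder
  mosaic with Poisson switch points, which creates background LD.
* Sweep groups: each group copies a single founder haplotype, receives
  its focal resistance allele plus a few group-diagnostic SNPs inside the
  core region, and erodes by recombination — per carrier and per flank
  the distance from the gene edge to the nearest breakpoint is
  exponential with rate ``g_r`` (expected breakpoints per bp, i.e. sweep
  age x recombination rate); beyond the breakpoint the carrier continues
  as a freshly drawn wild-type haplotype.  Recombination starts at the
  gene edges so the gene body itself stays near-identical within a group,
  mirroring the within-sweep diversity contrast the scans look for.
* Private mutations: each carrier adds Poisson-distributed singleton
  mutations anywhere in the region.
* Secondary missense mutations are planted on disjoint carrier subsets
  of one group, producing the star-shaped radiation in the network.
* Gene conversion: one group shares its founder with a twin group and
  additionally carries a planted run of fixed differences inside a tract
  upstream of the focal codon.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genemodel import GeneModel, VariantSite, annotate_codon_effect
from .hapmatrix import HaplotypeMatrix
from . import io as kio

__all__ = [
    "PopulationConfig",
    "SweepGroupConfig",
    "GeneConversionConfig",
    "SweepSimConfig",
    "SimulatedCohort",
    "generate_cohort",
    "regenerate_check",
    "default_config",
]


# ------------------------------------------------------------- config


@dataclass
class PopulationConfig:
    name: str
    species: str
    n_samples: int
    year: int


@dataclass
class SweepGroupConfig:
    """One planted sweep group.

    ``focal`` names the resistance allele the group carries (a key of
    ``SweepSimConfig.focal_codons``); ``carriers`` maps population name to
    haplotype count; ``g_r`` is the expected recombination breakpoints per
    bp per flank (sweep age x per-generation rate) controlling EHH decay;
    ``new_mutation_rate`` is the expected number of private singleton
    mutations per carrier; ``secondary_carriers`` lists carrier counts for
    planted secondary missense mutations (disjoint subsets);
    ``founder_twin`` names another group to share a founder with.
    """

    name: str
    focal: str
    carriers: dict[str, int]
    g_r: float = 2e-5
    new_mutation_rate: float = 0.5
    secondary_carriers: list[int] = field(default_factory=list)
    founder_twin: str | None = None


@dataclass
class GeneConversionConfig:
    """Planted conversion tract: ``n_fixed`` fixed differences between
    ``recipient`` and its founder twin inside (start, end)."""

    recipient: str
    start: int
    end: int
    n_fixed: int = 6


@dataclass
class SweepSimConfig:
    seed: int
    chrom: str = "sim2L"
    region_length: int = 500_000
    # gene and core intervals: 1-based, end-exclusive
    gene_interval: tuple[int, int] = (240_001, 258_000)
    cds_exons: list[tuple[int, int]] = field(
        default_factory=lambda: [(240_001, 244_998), (248_001, 252_998), (255_001, 258_000)]
    )
    strand: str = "+"
    transcript_id: str = "SIM_TX1"
    core_interval: tuple[int, int] = (247_461, 253_539)
    # codon-position anchors for the plantable resistance alleles
    focal_codons: dict[str, int] = field(
        default_factory=lambda: {"F": 250_500, "S": 250_501, "L1": 256_200, "L2": 241_500}
    )
    populations: list[PopulationConfig] = field(default_factory=list)
    n_founders: int = 24
    mosaic_switch_rate: float = 2e-4
    theta: float = 7e-3  # segregating-site density per bp
    sweep_groups: list[SweepGroupConfig] = field(default_factory=list)
    gene_conversion: GeneConversionConfig | None = None
    n_diagnostic_per_group: int = 3

    # ------------------------------------------------------------------
    def validate(self) -> None:
        errors = []
        if self.seed is None:
            errors.append("seed is mandatory")
        pop_caps = {p.name: 2 * p.n_samples for p in self.populations}
        demand: dict[str, int] = {}
        for g in self.sweep_groups:
            if g.focal not in self.focal_codons:
                errors.append(f"group {g.name}: unknown focal allele {g.focal!r}")
            for pop, count in g.carriers.items():
                if pop not in pop_caps:
                    errors.append(f"group {g.name}: unknown population {pop!r}")
                else:
                    demand[pop] = demand.get(pop, 0) + count
            if sum(g.carriers.values()) < sum(g.secondary_carriers):
                errors.append(f"group {g.name}: secondary subsets exceed carriers")
        for pop, total in demand.items():
            if total > pop_caps.get(pop, 0):
                errors.append(
                    f"population {pop}: {total} carrier haplotypes requested, "
                    f"only {pop_caps.get(pop, 0)} available"
                )
        for pos in self.focal_codons.values():
            if not 1 <= pos <= self.region_length:
                errors.append(f"focal position {pos} outside region")
        twin_names = {g.name for g in self.sweep_groups if g.founder_twin}
        if twin_names and (
            self.gene_conversion is None
            or self.gene_conversion.recipient not in twin_names
        ):
            errors.append(
                "founder-twin groups need a gene-conversion tract to stay distinguishable"
            )
        gc = self.gene_conversion
        if gc is not None:
            names = {g.name for g in self.sweep_groups}
            if gc.recipient not in names:
                errors.append(f"gene conversion recipient {gc.recipient!r} unknown")
            if not (1 <= gc.start < gc.end <= self.region_length):
                errors.append("gene conversion tract outside region")
        if errors:
            raise ValueError("invalid simulation config:\n" + "\n".join(errors))

    # JSON round-trip -------------------------------------------------
    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SweepSimConfig":
        raw = json.loads(text)
        raw["populations"] = [PopulationConfig(**p) for p in raw.get("populations", [])]
        raw["sweep_groups"] = [SweepGroupConfig(**g) for g in raw.get("sweep_groups", [])]
        if raw.get("gene_conversion"):
            raw["gene_conversion"] = GeneConversionConfig(**raw["gene_conversion"])
        raw["gene_interval"] = tuple(raw["gene_interval"])
        raw["core_interval"] = tuple(raw["core_interval"])
        raw["cds_exons"] = [tuple(e) for e in raw["cds_exons"]]
        return cls(**raw)


def default_config(seed: int) -> SweepSimConfig:
    """The package's reference study conditions.

    Sixteen population cohorts of two species (384 haplotypes), twelve
    planted sweep groups — five on each of the two main resistance
    alleles, plus one for each of the two minor alleles — with the
    largest group spread over four populations and both species, one
    group pair sharing a founder and separated only by a gene-conversion
    tract, and secondary missense mutations radiating on the largest
    group.
    """
    pops = []
    species = ["gambiae", "coluzzii"]
    years = [2009, 2010, 2011, 2012, 2000, 2009, 2011, 2010,
             2012, 2009, 2010, 2011, 2009, 2012, 2010, 2011]
    for i in range(16):
        pops.append(
            PopulationConfig(
                name=f"P{i + 1:02d}",
                species=species[i % 2],
                n_samples=12,
                year=years[i],
            )
        )
    groups = [
        # F1: the large multi-country, two-species group with a radiation
        # of small secondary-mutation subclades; P04 carries both main
        # alleles so the heterozygote-excess stage has a target cohort.
        SweepGroupConfig("F1", "F", {"P01": 16, "P02": 16, "P03": 16, "P04": 8},
                         g_r=0.5e-5, secondary_carriers=[4, 3, 2, 2]),
        SweepGroupConfig("F2", "F", {"P05": 16}, g_r=0.8e-5),
        SweepGroupConfig("F3", "F", {"P06": 12}, g_r=1.0e-5),
        SweepGroupConfig("F4", "F", {"P07": 8, "P08": 6}, g_r=1.2e-5),
        SweepGroupConfig("F5", "F", {"P09": 10}, g_r=1.5e-5),
        SweepGroupConfig("S1", "S", {"P04": 8, "P10": 14, "P11": 10}, g_r=0.6e-5),
        SweepGroupConfig("S2", "S", {"P12": 16}, g_r=0.9e-5),
        SweepGroupConfig("S3", "S", {"P13": 8, "P14": 6}, g_r=1.1e-5),
        SweepGroupConfig("S4", "S", {"P15": 12}, g_r=1.3e-5),
        SweepGroupConfig("S5", "S", {"P15": 6, "P16": 6}, g_r=1.5e-5,
                         founder_twin="S4"),
        SweepGroupConfig("L1", "L1", {"P06": 10}, g_r=1.0e-5),
        SweepGroupConfig("L2", "L2", {"P16": 8}, g_r=1.2e-5),
    ]
    return SweepSimConfig(
        seed=seed,
        populations=pops,
        sweep_groups=groups,
        gene_conversion=GeneConversionConfig(
            recipient="S5", start=242_001, end=249_001, n_fixed=6
        ),
    )


# ------------------------------------------------------------ generator


@dataclass
class TruthTable:
    """Ground truth for one generated cohort."""

    group_labels: list[str]  # per haplotype column
    secondary_carriers: dict[str, list[int]]  # mutation label -> haplotype columns
    diagnostic_sites: dict[str, list[int]]  # group -> genomic positions
    focal_sites: dict[str, int]  # focal base -> genomic position
    conversion_tract: dict | None  # start, end, n_fixed, recipient, twin
    group_g_r: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype": np.arange(len(self.group_labels)),
                "group": self.group_labels,
            }
        )


@dataclass
class SimulatedCohort:
    config: SweepSimConfig
    reference: str
    gene_model: GeneModel
    haplotypes: HaplotypeMatrix
    sample_meta: pd.DataFrame
    truth: TruthTable

    def focal_carriage(self) -> dict[str, np.ndarray]:
        """Boolean carrier vector per focal allele base, from the matrix.

        Focal alleles with no planted carriers are absent from the VCF and
        are skipped here.
        """
        lookup = self.haplotypes.site_lookup()
        out = {}
        for base, pos in self.truth.focal_sites.items():
            if pos in lookup:
                out[base] = self.haplotypes.codes[lookup[pos]] > 0
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA / GFF3 / phased VCF / metadata / truth TSV files."""
        outdir = kio.ensure_dir(outdir)
        paths = {
            "fasta": outdir / "reference.fasta",
            "gff3": outdir / "genes.gff3",
            "vcf": outdir / "cohort.vcf",
            "metadata": outdir / "samples.tsv",
            "truth": outdir / "truth.tsv",
            "config": outdir / "sim_config.json",
        }
        kio.write_fasta(paths["fasta"], {self.config.chrom: self.reference})
        kio.write_gff3(paths["gff3"], [self.gene_model])
        kio.write_phased_vcf(
            paths["vcf"],
            self.haplotypes,
            contig_lengths={self.config.chrom: self.config.region_length},
        )
        kio.write_metadata(paths["metadata"], self.sample_meta)
        self.truth.as_frame().to_csv(paths["truth"], sep="\t", index=False)
        paths["config"].write_text(self.config.to_json())
        return paths


def _find_missense(
    reference: str,
    model: GeneModel,
    near_pos: int,
    rng: np.random.Generator,
    taken: set[int] | None = None,
) -> tuple[int, str, str]:
    """A (pos, ref, alt) giving a missense change, at or near ``near_pos``."""
    for delta in range(0, 5000):
        for sign in (1, -1) if delta else (1,):
            pos = near_pos + sign * delta
            if pos < 1 or pos > len(reference):
                continue
            if taken is not None and pos in taken:
                continue
            if model.cds_offset(pos) is None:
                continue
            ref = reference[pos - 1]
            alts = [str(a) for a in rng.permutation([n for n in "ACGT" if n != ref])]
            for alt in alts:
                eff = annotate_codon_effect(
                    VariantSite(model.chrom, pos, ref, (alt,)), 0, model, reference
                )
                if not isinstance(eff, str) and eff.effect_class == "missense":
                    return pos, ref, alt
    raise RuntimeError("no missense site found near requested position")


def _noncoding_positions(
    interval: tuple[int, int], model: GeneModel, n: int, rng: np.random.Generator,
    taken: set[int],
) -> list[int]:
    """n distinct non-coding positions inside [start, end)."""
    start, end = interval
    candidates = [
        p for p in range(start, end)
        if model.cds_offset(p) is None and p not in taken
    ]
    if len(candidates) < n:
        raise RuntimeError("interval too small for requested planted sites")
    return sorted(rng.choice(np.array(candidates), size=n, replace=False).tolist())


def generate_cohort(config: SweepSimConfig) -> SimulatedCohort:
    """Generate the full synthetic cohort; byte-reproducible given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.region_length

    reference = "".join(rng.choice(list("ACGT"), size=L))
    model = GeneModel(
        transcript_id=config.transcript_id,
        chrom=config.chrom,
        strand=config.strand,
        cds_exons=list(config.cds_exons),
    )

    # ---- haplotype slots and metadata
    hap_pop, hap_species, hap_year, hap_sample = [], [], [], []
    sample_rows = []
    for pop in config.populations:
        for s in range(pop.n_samples):
            sid = f"{pop.name}_s{s:03d}"
            sample_rows.append(
                dict(sample_id=sid, population=pop.name, species=pop.species, year=pop.year)
            )
            for _ in range(2):
                hap_sample.append(sid)
                hap_pop.append(pop.name)
                hap_species.append(pop.species)
                hap_year.append(pop.year)
    n_haps = len(hap_pop)
    sample_meta = pd.DataFrame(sample_rows)

    # assign carriers to slots, population by population
    group_labels = ["wt"] * n_haps
    free: dict[str, list[int]] = {}
    for h, p in enumerate(hap_pop):
        free.setdefault(p, []).append(h)
    carriers_of_group: dict[str, list[int]] = {}
    for g in config.sweep_groups:
        slots: list[int] = []
        for pop, count in sorted(g.carriers.items()):
            pool = free[pop]
            pick = rng.choice(len(pool), size=count, replace=False)
            chosen = [pool[i] for i in sorted(pick)]
            for c in chosen:
                pool.remove(c)
            slots.extend(chosen)
        for h in slots:
            group_labels[h] = g.name
        carriers_of_group[g.name] = slots

    # ---- background variation
    n_bg = rng.poisson(config.theta * L)
    taken: set[int] = set()
    bg_positions = []
    while len(bg_positions) < n_bg:
        p = int(rng.integers(1, L + 1))
        if p not in taken:
            taken.add(p)
            bg_positions.append(p)
    bg_positions = np.array(sorted(bg_positions))
    K = config.n_founders
    # allele counts from the 1/i neutral spectrum, realised over founders
    weights = 1.0 / np.arange(1, K)
    weights /= weights.sum()
    founder_mat = np.zeros((n_bg, K), dtype=np.int8)
    for j in range(n_bg):
        count = int(rng.choice(np.arange(1, K), p=weights))
        founders = rng.choice(K, size=count, replace=False)
        founder_mat[j, founders] = 1

    def sample_wt(rng_: np.random.Generator) -> np.ndarray:
        """One wild-type haplotype: founder mosaic over background sites."""
        n_switch = rng_.poisson(config.mosaic_switch_rate * L)
        breaks = np.sort(rng_.integers(1, L + 1, size=n_switch))
        seg_founders = rng_.integers(0, K, size=n_switch + 1)
        seg_of_site = np.searchsorted(breaks, bg_positions, side="right")
        return founder_mat[np.arange(n_bg), seg_founders[seg_of_site]]

    bg_codes = np.zeros((n_bg, n_haps), dtype=np.int8)
    for h in range(n_haps):
        if group_labels[h] == "wt":
            bg_codes[:, h] = sample_wt(rng)

    # ---- sweep founders and carriers
    founder_of_group: dict[str, np.ndarray] = {}
    for g in config.sweep_groups:
        if g.founder_twin and g.founder_twin in founder_of_group:
            founder_of_group[g.name] = founder_of_group[g.founder_twin]
        else:
            founder_of_group[g.name] = sample_wt(rng)

    gene_start, gene_end = config.gene_interval
    for g in config.sweep_groups:
        founder = founder_of_group[g.name]
        for h in carriers_of_group[g.name]:
            hap = founder.copy()
            # recombination erodes each flank from the gene edge outward
            d_up = rng.exponential(1.0 / g.g_r) if g.g_r > 0 else np.inf
            d_down = rng.exponential(1.0 / g.g_r) if g.g_r > 0 else np.inf
            bp_up = gene_start - d_up
            bp_down = (gene_end - 1) + d_down
            donor = None
            mask = (bg_positions < bp_up) | (bg_positions > bp_down)
            if mask.any():
                donor = sample_wt(rng)
                hap[mask] = donor[mask]
            bg_codes[:, h] = hap

    # ---- planted sites --------------------------------------------------
    planted: list[tuple[int, str, str, np.ndarray]] = []  # pos, ref, alt, carrier cols

    focal_sites: dict[str, int] = {}
    taken_planted: set[int] = set(bg_positions.tolist())
    for base, near in sorted(config.focal_codons.items()):
        pos, ref, alt = _find_missense(reference, model, near, rng, taken_planted)
        taken_planted.add(pos)
        focal_sites[base] = pos
        cols = []
        for g in config.sweep_groups:
            if g.focal == base:
                cols.extend(carriers_of_group[g.name])
        planted.append((pos, ref, alt, np.array(sorted(cols), dtype=int)))

    # groups separated only by the gene-conversion tract carry no
    # standalone diagnostics: the tract is their distinguishing feature
    twin_groups: set[str] = set()
    for g in config.sweep_groups:
        if g.founder_twin:
            twin_groups |= {g.name, g.founder_twin}

    diagnostic_sites: dict[str, list[int]] = {}
    for g in config.sweep_groups:
        if g.name in twin_groups:
            diagnostic_sites[g.name] = []
            continue
        positions = _noncoding_positions(
            config.core_interval, model, config.n_diagnostic_per_group, rng, taken_planted
        )
        taken_planted.update(positions)
        diagnostic_sites[g.name] = positions
        cols = np.array(sorted(carriers_of_group[g.name]), dtype=int)
        for pos in positions:
            ref = reference[pos - 1]
            alt = rng.choice([n for n in "ACGT" if n != ref])
            planted.append((pos, ref, str(alt), cols))

    secondary_carriers: dict[str, list[int]] = {}
    for g in config.sweep_groups:
        if not g.secondary_carriers:
            continue
        pool = list(carriers_of_group[g.name])
        rng.shuffle(pool)
        cursor = 0
        for k, count in enumerate(g.secondary_carriers):
            subset = sorted(pool[cursor : cursor + count])
            cursor += count
            # secondary mutations radiate over the gene but outside the
            # core interval, which must keep one string per group
            core_lo, core_hi = config.core_interval
            avoid = taken_planted | set(range(core_lo, core_hi))
            side = rng.random() < 0.5
            near = int(
                rng.integers(gene_start, core_lo) if side else rng.integers(core_hi, gene_end)
            )
            pos, ref, alt = _find_missense(reference, model, near, rng, avoid)
            taken_planted.add(pos)
            eff = annotate_codon_effect(
                VariantSite(config.chrom, pos, ref, (alt,)), 0, model, reference
            )
            secondary_carriers[f"{g.name}:{eff.label}"] = subset
            planted.append((pos, ref, alt, np.array(subset, dtype=int)))

    conversion_tract = None
    gc = config.gene_conversion
    if gc is not None:
        recipient = next(g for g in config.sweep_groups if g.name == gc.recipient)
        twin = recipient.founder_twin
        # anchor at least two tract sites inside the core so the twin
        # pair's core haplotypes stay distinguishable
        core_overlap = (
            max(gc.start, config.core_interval[0]),
            min(gc.end, config.core_interval[1]),
        )
        positions: list[int] = []
        if core_overlap[0] < core_overlap[1] and gc.n_fixed >= 2:
            positions = _noncoding_positions(
                core_overlap, model, 2, rng, taken_planted
            )
            taken_planted.update(positions)
        positions = sorted(
            positions
            + _noncoding_positions(
                (gc.start, gc.end), model, gc.n_fixed - len(positions), rng, taken_planted
            )
        )
        taken_planted.update(positions)
        cols = np.array(sorted(carriers_of_group[gc.recipient]), dtype=int)
        for pos in positions:
            ref = reference[pos - 1]
            alt = rng.choice([n for n in "ACGT" if n != ref])
            planted.append((pos, ref, str(alt), cols))
        diagnostic_sites[gc.recipient] = positions  # tract sites are S5-private
        conversion_tract = dict(
            start=gc.start, end=gc.end, n_fixed=gc.n_fixed,
            recipient=gc.recipient, twin=twin, positions=positions,
        )

    # private singleton mutations
    for g in config.sweep_groups:
        if g.new_mutation_rate <= 0:
            continue
        for h in carriers_of_group[g.name]:
            for _ in range(rng.poisson(g.new_mutation_rate)):
                pos = int(rng.integers(1, L + 1))
                if pos in taken_planted:
                    continue
                taken_planted.add(pos)
                ref = reference[pos - 1]
                alt = str(rng.choice([n for n in "ACGT" if n != ref]))
                planted.append((pos, ref, alt, np.array([h], dtype=int)))

    # ---- assemble matrix -------------------------------------------------
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    bg_iter = [
        (int(p), reference[int(p) - 1], None, j) for j, p in enumerate(bg_positions)
    ]
    planted_iter = [(p[0], p[1], p[2], p[3]) for p in planted]
    merged = sorted(
        [(pos, "bg", refb, payload) for pos, refb, _alt, payload in bg_iter]
        + [(pos, "planted", refb, (alt, cols)) for pos, refb, alt, cols in planted_iter]
    )
    alt_cache: dict[int, str] = {}
    for pos, kind, refb, payload in merged:
        if kind == "bg":
            j = payload
            row = bg_codes[j].copy()
            if pos not in alt_cache:
                alt_cache[pos] = str(rng.choice([n for n in "ACGT" if n != refb]))
            sites.append(
                VariantSite(chrom=config.chrom, pos=pos, ref=refb, alts=(alt_cache[pos],))
            )
            rows.append(row)
        else:
            alt, cols = payload
            row = np.zeros(n_haps, dtype=np.int8)
            row[cols] = 1
            sites.append(VariantSite(chrom=config.chrom, pos=pos, ref=refb, alts=(alt,)))
            rows.append(row)

    # drop sites that ended monomorphic (all-ref or fixed) in the cohort
    keep = [i for i, r in enumerate(rows) if 0 < int(r.sum()) < n_haps]
    sites = [sites[i] for i in keep]
    codes = (
        np.vstack([rows[i] for i in keep])
        if keep
        else np.empty((0, n_haps), dtype=np.int8)
    )

    hap_meta = pd.DataFrame(
        {
            "sample_id": hap_sample,
            "population": hap_pop,
            "species": hap_species,
            "year": hap_year,
        }
    )
    haps = HaplotypeMatrix(codes=codes, sites=sites, meta=hap_meta)

    truth = TruthTable(
        group_labels=group_labels,
        secondary_carriers=secondary_carriers,
        diagnostic_sites=diagnostic_sites,
        focal_sites=focal_sites,
        conversion_tract=conversion_tract,
        group_g_r={g.name: g.g_r for g in config.sweep_groups},
    )
    return SimulatedCohort(
        config=config,
        reference=reference,
        gene_model=model,
        haplotypes=haps,
        sample_meta=sample_meta,
        truth=truth,
    )


def regenerate_check(config: SweepSimConfig, outdir_a: str | Path, outdir_b: str | Path) -> bool:
    """True when two runs with the same config produce byte-identical files."""
    pa = generate_cohort(config).write(outdir_a)
    pb = generate_cohort(config).write(outdir_b)
    return all(pa[k].read_bytes() == pb[k].read_bytes() for k in pa)
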