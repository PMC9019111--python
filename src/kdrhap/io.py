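"""Readers and writers for the standard formats the pipeline consumes.

Inputs are a reference FASTA, a GFF3 gene model (CDS features grouped by
transcript), a phased VCF and a sample metadata TSV.  Phasing is a hard
requirement: every statistic in the package operates on haplotypes, so an
unphased genotype separator in the VCF is an error, not a warning.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .genemodel import CodonEffect, GeneModel, VariantSite
from .hapmatrix import META_COLUMNS, HaplotypeMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3_models",
    "write_gff3",
    "read_metadata",
    "write_metadata",
    "read_phased_vcf",
    "write_phased_vcf",
    "write_annotation_table",
]


class UnphasedGenotypeError(ValueError):
    """A VCF record carries an unphased genotype."""


# ----------------------------------------------------------------- FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Sequences keyed by record id, uppercased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------------------------ GFF3


def read_gff3_models(path: str | os.PathLike) -> list[GeneModel]:
    """Build one GeneModel per transcript from the CDS features of a GFF3.

    CDS features are grouped by their ``Parent`` attribute (falling back to
    ``ID``); strand must be consistent within a transcript.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    grouped: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID") or ["?"]
        grouped.setdefault(parents[0], []).append(feat)
    models = []
    for tid, feats in grouped.items():
        strands = {f.strand for f in feats}
        if len(strands) != 1:
            raise ValueError(f"transcript {tid} mixes strands {strands}")
        chroms = {f.seqid for f in feats}
        if len(chroms) != 1:
            raise ValueError(f"transcript {tid} spans chromosomes {chroms}")
        models.append(
            GeneModel(
                transcript_id=tid,
                chrom=feats[0].seqid,
                strand=feats[0].strand,
                cds_exons=[(f.start, f.end) for f in feats],
            )
        )
    models.sort(key=lambda m: m.transcript_id)
    return models


def write_gff3(path: str | os.PathLike, models: list[GeneModel], source: str = "kdrhap") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            fh.write(
                f"{m.chrom}\t{source}\tmRNA\t{span[0]}\t{span[1]}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id}\n"
            )
            for i, (s, e) in enumerate(m.cds_exons, 1):
                fh.write(
                    f"{m.chrom}\t{source}\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID={m.transcript_id}.cds{i};Parent={m.transcript_id}\n"
                )


# ------------------------------------------------------------- metadata


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Sample table with columns sample_id, population, species, year."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing columns {missing}")
    return df


def write_metadata(path: str | os.PathLike, meta: pd.DataFrame) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- VCF


def read_phased_vcf(
    vcf_path: str | os.PathLike,
    metadata: pd.DataFrame,
) -> HaplotypeMatrix:
    """Load a phased diploid VCF into a HaplotypeMatrix.

    Sample order follows the VCF header; each sample contributes two
    haplotype columns in order.  Any unphased genotype raises
    :class:`UnphasedGenotypeError`.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    meta_by_sample = metadata.set_index("sample_id")
    missing = [s for s in samples if s not in meta_by_sample.index]
    if missing:
        raise ValueError(f"samples absent from metadata: {missing[:5]}")

    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        gts = rec.genotypes  # list of [a0, a1, phased]
        row = np.empty(2 * len(samples), dtype=np.int16)
        for j, g in enumerate(gts):
            if len(g) != 3:
                raise ValueError(f"non-diploid genotype at {rec.CHROM}:{rec.POS}")
            if not g[2]:
                raise UnphasedGenotypeError(
                    f"unphased genotype for sample {samples[j]} at {rec.CHROM}:{rec.POS}"
                )
            row[2 * j] = g[0]
            row[2 * j + 1] = g[1]
        sites.append(
            VariantSite(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alts=tuple(rec.ALT))
        )
        rows.append(row)

    hap_meta = pd.DataFrame(
        {
            "sample_id": np.repeat(samples, 2),
            "population": np.repeat(meta_by_sample.loc[samples, "population"].to_numpy(), 2),
            "species": np.repeat(meta_by_sample.loc[samples, "species"].to_numpy(), 2),
            "year": np.repeat(meta_by_sample.loc[samples, "year"].to_numpy(), 2),
        }
    )
    codes = np.vstack(rows) if rows else np.empty((0, 2 * len(samples)), dtype=np.int16)
    return HaplotypeMatrix(codes=codes, sites=sites, meta=hap_meta)


def write_phased_vcf(
    path: str | os.PathLike,
    haps: HaplotypeMatrix,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write the matrix back out as a minimal phased VCF (text, uncompressed)."""
    sample_ids = list(dict.fromkeys(haps.meta["sample_id"]))
    if 2 * len(sample_ids) != haps.n_haplotypes:
        raise ValueError("haplotype columns do not pair into diploid samples")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=kdrhap\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for i, site in enumerate(haps.sites):
            row = haps.codes[i]
            gts = "\t".join(
                f"{row[2 * j]}|{row[2 * j + 1]}" for j in range(len(sample_ids))
            )
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{','.join(site.alts)}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ------------------------------------------------------------ annotation


def write_annotation_table(
    path: str | os.PathLike,
    records: list[tuple[VariantSite, int, CodonEffect | str]],
) -> pd.DataFrame:
    """Annotation TSV: chrom, pos, ref, alt, transcript, codon, aa_change, effect_class.

    Non-coding calls get empty codon/aa_change fields.  Returns the frame
    that was written.
    """
    rows = []
    for site, alt_index, effect in records:
        if isinstance(effect, str):
            rows.append(
                dict(
                    chrom=site.chrom,
                    pos=site.pos,
                    ref=site.ref,
                    alt=site.alts[alt_index],
                    transcript="",
                    codon="",
                    aa_change="",
                    effect_class=effect,
                )
            )
        else:
            rows.append(
                dict(
                    chrom=site.chrom,
                    pos=site.pos,
                    ref=site.ref,
                    alt=site.alts[alt_index],
                    transcript=effect.transcript_id,
                    codon=effect.codon_number,
                    aa_change=effect.label,
                    effect_class=effect.effect_class,
                )
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
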