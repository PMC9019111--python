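"""Gene models and codon-effect annotation of SNPs.

A :class:`GeneModel` holds the CDS structure of one transcript in genomic
coordinates (1-based inclusive, the VCF/GFF convention).  Annotation maps a
single-nucleotide substitution onto the transcript reading frame, honouring
strand, and classifies the resulting amino-acid change.  This is the
internal replacement for an external effect predictor: supply the transcript
models you trust and every variant is translated against them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "VariantSite",
    "CodonEffect",
    "NON_CODING",
    "annotate_codon_effect",
    "effects_across_transcripts",
]

#: Sentinel returned for substitutions outside the CDS of a transcript.
NON_CODING = "non-coding"

_NUCS = frozenset("ACGT")


class ReferenceMismatchError(ValueError):
    """Reference base in the sequence disagrees with the variant record."""


class GeneModelError(ValueError):
    """The transcript model is internally inconsistent (e.g. frame broken)."""


@dataclass(frozen=True)
class VariantSite:
    """A single variant position with one or more alternate alleles.

    Multi-allelic sites are allowed; downstream allele-level statistics
    address a specific allele as ``(site, alt_index)``.
    """

    chrom: str
    pos: int  # 1-based genomic position
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.ref in self.alts:
            raise ValueError(f"ref allele {self.ref!r} repeated in alts")
        if len(set(self.alts)) != len(self.alts):
            raise ValueError("duplicate alt alleles")

    @property
    def alleles(self) -> tuple[str, ...]:
        """All alleles, ref first; index i here is the matrix allele code."""
        return (self.ref,) + self.alts


@dataclass(frozen=True)
class CodonEffect:
    """Predicted amino-acid consequence of a substitution in one transcript."""

    transcript_id: str
    codon_number: int
    ref_aa: str
    alt_aa: str
    effect_class: str  # synonymous | missense | nonsense

    @property
    def label(self) -> str:
        """Compact field notation, e.g. ``L995F``."""
        return f"{self.ref_aa}{self.codon_number}{self.alt_aa}"


@dataclass
class GeneModel:
    """CDS structure of one transcript.

    Parameters
    ----------
    transcript_id : str
    chrom : str
    strand : {"+", "-"}
    cds_exons : list of (start, end)
        1-based inclusive genomic intervals, non-overlapping.  They are
        sorted by start on construction; total CDS length must be a
        multiple of three.
    """

    transcript_id: str
    chrom: str
    strand: str
    cds_exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise GeneModelError(f"overlapping CDS exons ({s1},{e1}) and ({s2},{e2})")
        for s, e in exons:
            if e < s:
                raise GeneModelError(f"exon end {e} before start {s}")
        self.cds_exons = exons
        if self.cds_length % 3 != 0:
            raise GeneModelError(
                f"CDS length {self.cds_length} of {self.transcript_id} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exons)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) of the whole CDS, 1-based inclusive."""
        return self.cds_exons[0][0], self.cds_exons[-1][1]

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of genomic ``pos`` within the spliced CDS.

        Offsets run 5'→3' in the *transcript* frame: for a minus-strand
        transcript, offset 0 is the highest genomic coordinate of the last
        exon.  Returns None when ``pos`` is not inside any CDS exon.
        """
        plus_off = 0
        found = None
        for s, e in self.cds_exons:
            if s <= pos <= e:
                found = plus_off + (pos - s)
                break
            plus_off += e - s + 1
        if found is None:
            return None
        if self.strand == "+":
            return found
        return self.cds_length - 1 - found

    def coding_sequence(self, reference: "ReferenceLookup") -> str:
        """Spliced CDS in the transcript frame (reverse-complemented on '-')."""
        seq = "".join(reference[s - 1 : e] for s, e in self.cds_exons)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


# A ReferenceLookup is anything sliceable with 0-based half-open indices
# returning uppercase nucleotide strings (a plain str works).
ReferenceLookup = str


def _classify(ref_aa: str, alt_aa: str) -> str:
    if alt_aa == "*" and ref_aa != "*":
        return "nonsense"
    if ref_aa == alt_aa:
        return "synonymous"
    return "missense"


def annotate_codon_effect(
    variant: VariantSite,
    alt_index: int,
    model: GeneModel,
    reference: str,
) -> CodonEffect | str:
    """Translate one substitution in the frame of one transcript.

    Parameters
    ----------
    variant : VariantSite
    alt_index : int
        Which alternate allele of the site to annotate (0-based into
        ``variant.alts``).
    model : GeneModel
    reference : str
        Genome (plus-strand) sequence covering the CDS; indexed 0-based,
        i.e. ``reference[pos - 1]`` is the base at genomic position ``pos``.

    Returns
    -------
    CodonEffect, or the string ``"non-coding"`` when the position falls
    outside the CDS of this transcript.
    """
    ref = variant.ref.upper()
    alt = variant.alts[alt_index].upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in _NUCS or alt not in _NUCS:
        raise ValueError("only single-nucleotide substitutions can be annotated")
    ref_base = reference[variant.pos - 1].upper()
    if ref_base != ref:
        raise ReferenceMismatchError(
            f"reference has {ref_base} at {variant.chrom}:{variant.pos}, variant says {ref}"
        )
    offset = model.cds_offset(variant.pos)
    if offset is None:
        return NON_CODING

    cds = model.coding_sequence(reference)
    codon_idx = offset // 3
    within = offset % 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    if model.strand == "+":
        alt_base = alt
    else:
        alt_base = str(Seq(alt).complement())
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    return CodonEffect(
        transcript_id=model.transcript_id,
        codon_number=codon_idx + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect_class=_classify(ref_aa, alt_aa),
    )


@dataclass(frozen=True)
class TranscriptEffects:
    """Per-transcript effects of one allele plus a discordance summary."""

    variant: VariantSite
    alt_index: int
    effects: dict[str, CodonEffect | str]
    discordant: bool


def effects_across_transcripts(
    variant: VariantSite,
    alt_index: int,
    models: list[GeneModel],
    reference: str,
) -> TranscriptEffects:
    """Annotate one allele against several transcript models.

    The discordance flag is set when the effect class differs between any
    two transcripts (counting "non-coding" as its own class), which is how
    alternative splicing can hide a protein-changing variant from a single
    canonical transcript.
    """
    if not models:
        raise ValueError("at least one gene model required")
    effects: dict[str, CodonEffect | str] = {}
    classes = set()
    for model in models:
        eff = annotate_codon_effect(variant, alt_index, model, reference)
        effects[model.transcript_id] = eff
        classes.add(eff if isinstance(eff, str) else eff.effect_class)
    return TranscriptEffects(
        variant=variant,
        alt_index=alt_index,
        effects=effects,
        discordant=len(classes) > 1,
    )
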