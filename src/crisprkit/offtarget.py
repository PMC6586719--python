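"""Genome-wide off-target screening of resequenced edited lines.

The screen asks whether a mutant genome carries any *effective mutation*
beyond the intended edit: a homozygous call differing from the wild-type
sequence, supported by more than 3 mutated reads, with mapping quality
>= 50 and an effective matched degree (matched alignment length over
whole read length) >= 0.90. Passing variants are annotated by genomic
region (exon > UTR > intron > intergenic precedence) and, for exonic
SNVs, as synonymous or missense.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .popgen import STANDARD_CODE


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"


@dataclass
class FilterThresholds:
    """The effective-mutation filter thresholds.

    ``min_alt_reads`` is a strict bound (reads must *exceed* it); the
    other two are inclusive.
    """

    min_alt_reads: int = 3
    min_mapping_quality: float = 50.0
    min_effective_matched_degree: float = 0.90


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    alt_read_count: int
    mapping_quality: float
    effective_matched_degree: float
    genotype: Genotype
    sample: str = ""

    def __post_init__(self) -> None:
        if self.alt_read_count < 0:
            raise ValueError("alt_read_count must be >= 0")
        if not (0.0 <= self.effective_matched_degree <= 1.0):
            raise ValueError("effective_matched_degree must lie in [0, 1]")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def effective_matched_degree(matched_length: int, read_length: int) -> float:
    """Ratio of matched alignment length to whole read length."""
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if not (0 <= matched_length <= read_length):
        raise ValueError("matched_length must lie in [0, read_length]")
    return matched_length / read_length


def emd_from_cigartuples(cigartuples: list[tuple[int, int]]) -> float:
    """Effective matched degree from CIGAR operations.

    Aligned bases (M/=/X) form the numerator; the denominator is the
    whole read length including soft clips and insertions.
    """
    matched = sum(n for op, n in cigartuples if op in (0, 7, 8))
    read_len = sum(n for op, n in cigartuples if op in (0, 1, 4, 7, 8))
    return effective_matched_degree(matched, read_len)


def genotype_from_alt_fraction(alt_fraction: float, hom_threshold: float = 0.9) -> Genotype:
    """Fallback genotyping when no GT field is available."""
    if alt_fraction >= hom_threshold:
        return Genotype.HOM_ALT
    if alt_fraction > 0.1:
        return Genotype.HET
    return Genotype.HOM_REF


def effective_mutation_filter(
    variants: list[VariantRecord],
    wildtype_calls: dict[tuple[str, int], str],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Apply the effective-mutation filter.

    A variant passes when it is homozygous-alt, its alt allele differs
    from the wild-type call at that site (wild-type ref allele when the
    site is absent from the wild-type table counts as the reference
    base), its mutated read count strictly exceeds ``min_alt_reads``, and
    mapping quality / effective matched degree meet their thresholds.

    ``wildtype_calls`` maps (chrom, pos) to the wild-type allele observed
    at that site. Variants at sites with no wild-type information at all
    (signalled by a missing entry when ``wildtype_calls`` carries the
    sentinel key ``("__strict__", 0)``) are excluded as unresolved.

    Returns (passing, unresolved).
    """
    thresholds = thresholds or FilterThresholds()
    strict = ("__strict__", 0) in wildtype_calls
    passing: list[VariantRecord] = []
    unresolved: list[VariantRecord] = []
    for v in variants:
        wt = wildtype_calls.get(v.key)
        if wt is None:
            if strict:
                warnings.warn(
                    f"no wild-type call at {v.chrom}:{v.pos}; variant excluded",
                    stacklevel=2,
                )
                unresolved.append(v)
                continue
            wt = v.ref_allele  # site invariant in wild type
        if v.genotype is not Genotype.HOM_ALT:
            continue
        if v.alt_allele.upper() == wt.upper():
            continue  # same as the wild-type sequence: not a mutation
        if v.alt_read_count <= thresholds.min_alt_reads:
            continue
        if v.mapping_quality < thresholds.min_mapping_quality:
            continue
        if v.effective_matched_degree < thresholds.min_effective_matched_degree:
            continue
        passing.append(v)
    return passing, unresolved


# ---------------------------------------------------------------------------
# region annotation

REGION_PRECEDENCE = ("exon", "UTR", "intron", "intergenic")


@dataclass
class RegionAnnotation:
    """Typed genomic intervals with exon > UTR > intron precedence.

    ``intervals`` maps region type to per-chromosome lists of 0-based
    half-open intervals. Positions matching nothing are intergenic.
    ``cds_frames`` optionally maps (chrom, cds_start0, cds_end0, strand)
    CDS segments used for codon lookup of exonic SNVs.
    """

    intervals: dict[str, dict[str, list[tuple[int, int]]]] = field(default_factory=dict)
    cds_segments: dict[str, list[tuple[int, int, str, int]]] = field(default_factory=dict)
    # cds_segments[chrom] = [(start0, end0, strand, phase_offset_in_cds)]

    def add(self, region_type: str, chrom: str, start0: int, end0: int) -> None:
        if region_type not in REGION_PRECEDENCE[:3]:
            raise ValueError(f"unknown region type {region_type!r}")
        self.intervals.setdefault(region_type, {}).setdefault(chrom, []).append(
            (start0, end0)
        )

    def classify(self, chrom: str, pos: int) -> str:
        """Region class of a 1-based position, by precedence."""
        p0 = pos - 1
        for rtype in REGION_PRECEDENCE[:3]:
            for s, e in self.intervals.get(rtype, {}).get(chrom, []):
                if s <= p0 < e:
                    return rtype
        return "intergenic"

    @classmethod
    def from_gene_models(cls, models: list) -> "RegionAnnotation":
        """Build exon/UTR/intron intervals from GeneModel objects.

        Coding exon parts are typed ``exon``; exonic parts outside the
        CDS are ``UTR``; gaps between exons are ``intron``.
        """
        ann = cls()
        for m in models:
            for iso in m.isoforms:
                cds_pos = 0
                for s, e in iso.exons:
                    lo, hi = max(s, iso.cds_start), min(e, iso.cds_end)
                    if lo < hi:
                        ann.add("exon", m.chrom, lo, hi)
                        ann.cds_segments.setdefault(m.chrom, []).append(
                            (lo, hi, m.strand, cds_pos)
                        )
                        cds_pos += hi - lo
                    if s < min(e, iso.cds_start):
                        ann.add("UTR", m.chrom, s, min(e, iso.cds_start))
                    if max(s, iso.cds_end) < e:
                        ann.add("UTR", m.chrom, max(s, iso.cds_end), e)
                for istart, iend in iso.introns():
                    ann.add("intron", m.chrom, istart, iend)
        return ann


@dataclass
class VariantAnnotation:
    region: str
    coding_effect: str | None = None  # synonymous / missense / None


def annotate_variant(
    v: VariantRecord,
    ann: RegionAnnotation,
    genome_seq: str | None = None,
) -> VariantAnnotation:
    """Region class of a variant plus, for exonic SNVs with genomic
    sequence available, its synonymous/missense status."""
    if genome_seq is not None and v.pos > len(genome_seq):
        raise ValueError(f"position {v.pos} beyond chromosome end {len(genome_seq)}")
    region = ann.classify(v.chrom, v.pos)
    effect = None
    if region == "exon" and v.is_snv and genome_seq is not None:
        effect = _coding_effect(v, ann, genome_seq)
    return VariantAnnotation(region=region, coding_effect=effect)


def _coding_effect(
    v: VariantRecord, ann: RegionAnnotation, genome_seq: str
) -> str | None:
    from Bio.Seq import Seq

    p0 = v.pos - 1
    for s, e, strand, cds_off in ann.cds_segments.get(v.chrom, []):
        if not (s <= p0 < e):
            continue
        if strand == "-":
            # position within CDS counted from the segment's 3' genomic end
            cds_index = cds_off + (e - 1 - p0)
        else:
            cds_index = cds_off + (p0 - s)
        frame = cds_index % 3
        # rebuild the codon from the genome around this position
        if strand == "-":
            idxs = [p0 + frame, p0 + frame - 1, p0 + frame - 2]
            codon = "".join(
                str(Seq(genome_seq[i]).reverse_complement()) for i in idxs
            )
            alt_base = str(Seq(v.alt_allele).reverse_complement())
            codon_pos = frame  # position of p0 within the codon
            mut_codon = codon[:frame] + alt_base + codon[frame + 1 :]
        else:
            start = p0 - frame
            codon = genome_seq[start : start + 3].upper()
            mut_codon = codon[:frame] + v.alt_allele.upper() + codon[frame + 1 :]
        if len(codon) != 3 or set(codon) - set("ACGT") or set(mut_codon) - set("ACGT"):
            return None
        return (
            "synonymous"
            if STANDARD_CODE[codon] == STANDARD_CODE[mut_codon]
            else "missense"
        )
    return None


def summarize_by_region(
    variants: list[VariantRecord],
    ann: RegionAnnotation,
    genome_seq: str | None = None,
) -> pd.DataFrame:
    """Counts per region class x variant class (SNP / INDEL).

    The counts partition the input: every variant lands in exactly one
    (region, class) cell.
    """
    regions = []
    classes = []
    for v in variants:
        regions.append(annotate_variant(v, ann, genome_seq).region)
        classes.append("SNP" if v.is_snv else "INDEL")
    idx = pd.CategoricalIndex(
        regions, categories=list(REGION_PRECEDENCE), name="region"
    )
    cols = pd.Categorical(classes, categories=["SNP", "INDEL"])
    table = pd.crosstab(idx, cols, dropna=False)
    table.columns.name = "class"
    return table


def screen_gene_list(
    variants: list[VariantRecord],
    gene_intervals: dict[str, tuple[str, int, int]],
    wildtype_calls: dict[tuple[str, int], str],
    thresholds: FilterThresholds | None = None,
) -> dict[str, list[VariantRecord]]:
    """Per-gene verdicts for a user-supplied gene list.

    Runs the effective-mutation filter restricted to each gene's interval
    (1-based inclusive); an empty list for a gene means no effective
    mutation was found there.
    """
    passing, _ = effective_mutation_filter(variants, wildtype_calls, thresholds)
    out: dict[str, list[VariantRecord]] = {}
    for gene, (chrom, start, end) in gene_intervals.items():
        out[gene] = [
            v for v in passing if v.chrom == chrom and start <= v.pos <= end
        ]
    return out
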