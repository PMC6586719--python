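"""Splice-junction quantification, frame-restoration ("rescue")
enumeration, mosaic transcript construction, and 2^-ddCt expression.

A frameshift insertion in an exon can be circumvented when the
spliceosome adopts an alternative 5' donor a few bases upstream of the
annotated one: if the extra exonic bases removed (the donor *shift*)
cancel the edit's length change modulo 3, the downstream reading frame is
restored and a near-full-length protein can still be made. This module
extracts junctions from spliced alignments, compares their usage between
genotypes, and enumerates which donor shifts restore the frame.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .edits import EditEvent, GeneModel, translate_cds


@dataclass
class SpliceJunction:
    """An intron interval with per-sample supporting read counts.

    ``intron_start``/``intron_end`` are the first and last intronic bases,
    1-based inclusive (the style junction coordinates are reported in,
    e.g. chr06:23502684-23502763).
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = "?"
    counts: dict[str, int] = field(default_factory=dict)
    status: str = "novel"

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError("intron_start must be <= intron_end")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)

    def total_count(self, sample: str | None = None) -> int:
        if sample is None:
            return sum(self.counts.values())
        return self.counts.get(sample, 0)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return (
            self.chrom == chrom
            and self.intron_start <= end
            and self.intron_end >= start
        )


# ---------------------------------------------------------------------------
# junction extraction

BAM_CREF_SKIP = 3  # CIGAR 'N'


def extract_junctions(
    sam_path: str | Path,
    sample: str,
    existing: list[SpliceJunction] | None = None,
    annotated: set[tuple[str, int, int]] | None = None,
) -> list[SpliceJunction]:
    """Extract splice junctions from a SAM file of spliced alignments.

    One junction is produced per distinct N-skip interval, with read
    counts aggregated under ``sample``. Passing ``existing`` merges counts
    into a prior junction list (so several samples/files accumulate into
    one table); the result is order-invariant. ``annotated`` marks
    junction keys whose status should be ``"annotated"``.
    """
    table: dict[tuple[str, int, int], SpliceJunction] = {
        j.key: j for j in (existing or [])
    }
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for read in fh:
            if read.is_unmapped or read.cigartuples is None:
                continue
            ref = read.reference_start  # 0-based
            chrom = read.reference_name
            for op, length in read.cigartuples:
                if op == BAM_CREF_SKIP:
                    start1 = ref + 1  # first skipped base, 1-based
                    end1 = ref + length
                    key = (chrom, start1, end1)
                    j = table.get(key)
                    if j is None:
                        j = SpliceJunction(chrom=chrom, intron_start=start1,
                                           intron_end=end1)
                        table[key] = j
                    j.counts[sample] = j.counts.get(sample, 0) + 1
                    ref += length
                elif op in (0, 2, 7, 8):  # M, D, =, X consume reference
                    ref += length
    out = [table[k] for k in sorted(table)]
    if annotated:
        for j in out:
            if j.key in annotated:
                j.status = "annotated"
    return out


def junction_proportion(
    junctions: list[SpliceJunction],
    locus: tuple[str, int, int],
    target: tuple[str, int, int],
    sample: str,
    min_support: int = 1,
) -> float:
    """Fraction of junction-supporting reads at ``locus`` that support the
    ``target`` junction, for one sample.

    The denominator is the summed count of all junctions overlapping the
    locus interval (1-based inclusive). Returns NaN when the denominator
    is zero.
    """
    chrom, start, end = locus
    pool = [
        j for j in junctions
        if j.overlaps(chrom, start, end) and j.total_count(sample) >= min_support
    ]
    denom = sum(j.total_count(sample) for j in pool)
    if denom == 0:
        return math.nan
    num = sum(j.total_count(sample) for j in pool if j.key == target)
    return num / denom


def proportion_fold_change(p_case: float, p_control: float) -> float:
    """Fold change of a junction proportion between genotypes."""
    if p_control == 0:
        return math.inf
    return p_case / p_control


# ---------------------------------------------------------------------------
# frame-restoration enumeration

@dataclass
class RescueCandidate:
    """An alternative donor shifted ``shift`` bases into the exon.

    ``net_frame`` is ``(insertion_length - shift) mod 3``; the candidate
    restores the frame when it is 0 and, if genomic sequence was
    available, the shifted intron keeps a GT..AG signal and the resulting
    CDS reaches the annotated stop without a premature one.
    """

    shift: int
    insertion_length: int
    net_frame: int
    restores_frame: bool
    splice_signal_ok: bool | None = None  # None = unverified (no genome)
    predicted_protein: str | None = None


def enumerate_rescue_junctions(
    model: GeneModel,
    edit: EditEvent,
    max_shift: int,
    genome_seq: str | None = None,
    shifts: list[int] | None = None,
    isoform_id: str | None = None,
) -> list[RescueCandidate]:
    """Enumerate donor shifts that could restore the reading frame.

    The edit must lie in a coding exon that is followed by an intron; for
    each shift ``s`` in 1..``max_shift`` (or an explicit ``shifts`` list)
    the annotated donor moves ``s`` bases upstream, removing ``s`` exonic
    bases. Frame restoration is the residue-class condition
    ``(length_change - s) % 3 == 0``; when ``genome_seq`` is given the
    shifted intron must additionally begin GT and end AG and the spliced,
    edited CDS must be free of premature stops, and the predicted protein
    is attached. Without genomic sequence candidates are arithmetic-only
    and carry ``splice_signal_ok=None``.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    iso = model.get_isoform(isoform_id) if isoform_id else model.primary()
    pos0 = edit.position - 1
    host = None
    intron = None
    for idx, (s, e) in enumerate(iso.exons[:-1]):
        if s <= pos0 < e:
            host = (s, e)
            intron = iso.introns()[idx]
            break
    if host is None or intron is None:
        return []  # edit not in an exon followed by an intron

    length_change = edit.length_change
    donor0 = intron[0]  # 0-based first intronic base
    acceptor_end = intron[1]  # half-open end; last intronic base = end-1
    shift_list = sorted(shifts) if shifts is not None else list(range(1, max_shift + 1))

    out: list[RescueCandidate] = []
    for s in shift_list:
        if s < 1 or s > max_shift or donor0 - s < host[0]:
            continue
        net = (length_change - s) % 3
        frame_ok = net == 0
        signal_ok: bool | None = None
        protein: str | None = None
        restores = frame_ok
        if genome_seq is not None:
            signal_ok = (
                genome_seq[donor0 - s : donor0 - s + 2].upper() == "GT"
                and genome_seq[acceptor_end - 2 : acceptor_end].upper() == "AG"
            )
            restores = frame_ok and signal_ok
            if restores:
                protein = _spliced_protein_with_shift(
                    iso, model, genome_seq, edit, donor0, s
                )
                if protein is None:
                    restores = False
        out.append(
            RescueCandidate(
                shift=s, insertion_length=length_change, net_frame=net,
                restores_frame=restores, splice_signal_ok=signal_ok,
                predicted_protein=protein,
            )
        )
    out.sort(key=lambda c: abs(c.shift))
    return out


def _spliced_protein_with_shift(
    iso, model: GeneModel, genome_seq: str, edit: EditEvent,
    donor0: int, shift: int,
) -> str | None:
    """Splice with a shifted donor, apply the edit, translate.

    Returns None when the resulting CDS terminates before its annotated
    stop (a premature stop defeats the rescue).
    """
    from .edits import Isoform, apply_edit

    new_exons = [
        (s, e - shift if e == donor0 else e) for s, e in iso.exons
    ]
    shifted = Isoform(
        isoform_id=iso.isoform_id + f"_shift{shift}",
        exons=new_exons,
        cds_start=iso.cds_start,
        cds_end=iso.cds_end,
    )
    shifted_model = GeneModel(
        gene_id=model.gene_id, chrom=model.chrom, strand=model.strand,
        isoforms=[shifted], protein_domains=list(model.protein_domains),
    )
    applied = apply_edit(shifted_model, genome_seq, edit)
    cds = applied.mut_cds
    usable = len(cds) - len(cds) % 3
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prot = translate_cds(cds)
    if (len(prot) + 1) * 3 < usable:
        return None  # premature stop
    return prot


# ---------------------------------------------------------------------------
# mosaic transcripts

def build_mosaic_transcript(
    model: GeneModel,
    isoform_a: str,
    isoform_b: str,
    breakpoint: int,
    genome_seq: str,
) -> tuple[str, str]:
    """Join the exonic CDS of isoform A 5' of a genomic breakpoint to the
    exonic CDS of isoform B 3' of it; returns (transcript, protein).

    ``breakpoint`` is a 1-based genomic coordinate that must fall within
    both isoforms' genomic spans. Emulates a chimeric mRNA that reads the
    first exons of one annotated isoform and continues in the exon
    structure of the other.
    """
    iso_a = model.get_isoform(isoform_a)
    iso_b = model.get_isoform(isoform_b)
    bp0 = breakpoint - 1
    for iso in (iso_a, iso_b):
        span = (iso.exons[0][0], iso.exons[-1][1])
        if not (span[0] <= bp0 <= span[1]):
            raise ValueError(
                f"breakpoint {breakpoint} outside isoform {iso.isoform_id!r} span"
            )
    parts = []
    for s, e in iso_a.exons:
        lo, hi = max(s, iso_a.cds_start), min(e, min(iso_a.cds_end, bp0))
        if lo < hi:
            parts.append(genome_seq[lo:hi])
    for s, e in iso_b.exons:
        lo, hi = max(max(s, bp0), iso_b.cds_start), min(e, iso_b.cds_end)
        if lo < hi:
            parts.append(genome_seq[lo:hi])
    transcript = "".join(parts)
    if model.strand == "-":
        from Bio.Seq import Seq

        transcript = str(Seq(transcript).reverse_complement())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        protein = translate_cds(transcript) if len(transcript) >= 3 else ""
    return transcript, protein


# ---------------------------------------------------------------------------
# relative expression

@dataclass
class CtTable:
    """qPCR Ct values: rows of (sample, gene, replicate, ct)."""

    data: pd.DataFrame
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self) -> None:
        required = {"sample", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        for s in self.data["sample"].unique():
            genes = set(self.data.loc[self.data["sample"] == s, "gene"])
            if self.reference_gene not in genes:
                raise ValueError(
                    f"reference gene {self.reference_gene!r} absent for sample {s!r}"
                )

    def mean_ct(self, sample: str, gene: str) -> float:
        sel = self.data[(self.data["sample"] == sample) & (self.data["gene"] == gene)]
        if sel.empty:
            raise KeyError(f"no Ct rows for sample={sample!r}, gene={gene!r}")
        return float(sel["ct"].mean())


def delta_delta_ct(table: CtTable, target_gene: str, sample: str) -> float:
    """Relative expression by the 2^-ddCt method.

    Replicate Ct values are averaged (arithmetic mean); dCt is
    Ct(target) - Ct(reference) within each sample; ddCt subtracts the
    calibrator sample's dCt; the result is 2^-ddCt.
    """
    d_sample = table.mean_ct(sample, target_gene) - table.mean_ct(
        sample, table.reference_gene
    )
    d_cal = table.mean_ct(table.calibrator_sample, target_gene) - table.mean_ct(
        table.calibrator_sample, table.reference_gene
    )
    return 2.0 ** (-(d_sample - d_cal))
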