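"""CRISPR edit inference, application to gene models, and protein
consequence classification.

The workflow mirrors how editing outcomes are read off Sanger traces of a
target region: the printed wild-type and mutant sequences are compared to
infer a normalized edit, the edit is applied to a gene model, both CDSs
are translated, and the protein-level consequence (in-frame indel,
frameshift, missense, ...) is classified together with the conserved
domains lost.

Indels are leftmost-normalized (VCF convention). The protein diff is an
anchored longest-common-prefix/suffix diff with the prefix claimed first
on ambiguity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import edlib
from Bio.Seq import Seq

DOMAIN_LOST_SURVIVAL = 0.5  # a domain is "lost" if < 50% of its residues survive


class EditKind(str, Enum):
    INSERTION = "insertion"
    DELETION = "deletion"
    SUBSTITUTION = "substitution"
    COMPLEX = "complex"


class ConsequenceKind(str, Enum):
    IN_FRAME_DELETION = "in_frame_deletion"
    IN_FRAME_INSERTION = "in_frame_insertion"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NO_CDS_OVERLAP = "no_cds_overlap"
    START_LOST = "start_lost"


@dataclass
class EditEvent:
    """A normalized edit at a genomic (or region-local) coordinate.

    ``position`` is 1-based: for deletions/substitutions the first changed
    base; for pure insertions the base *before which* ``alt_allele`` is
    inserted. ``ref_allele``/``alt_allele`` may be empty (pure
    insertion/deletion) but not both.
    """

    chrom: str
    position: int
    ref_allele: str
    alt_allele: str
    blocks: list["EditEvent"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ref_allele and not self.alt_allele:
            raise ValueError("ref and alt alleles cannot both be empty")

    @property
    def kind(self) -> EditKind:
        if self.blocks:
            return EditKind.COMPLEX
        if not self.ref_allele:
            return EditKind.INSERTION
        if not self.alt_allele:
            return EditKind.DELETION
        if len(self.ref_allele) == len(self.alt_allele):
            return EditKind.SUBSTITUTION
        return EditKind.COMPLEX

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass
class Isoform:
    isoform_id: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, non-overlapping
    cds_start: int  # 0-based
    cds_end: int  # half-open

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError("exons overlap")
        span = [(s, e) for s, e in self.exons]
        if not any(s <= self.cds_start < e for s, e in span):
            raise ValueError("CDS start outside exons")
        if not any(s < self.cds_end <= e for s, e in span):
            raise ValueError("CDS end outside exons")

    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def spliced_cds(self, genome_seq: str) -> str:
        parts = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo < hi:
                parts.append(genome_seq[lo:hi])
        return "".join(parts)


@dataclass
class GeneModel:
    """A gene with one or more isoforms; coordinates 0-based half-open
    internally, 1-based inclusive at I/O boundaries."""

    gene_id: str
    chrom: str
    strand: str
    isoforms: list[Isoform]
    protein_domains: list[tuple[str, int, int]] = field(default_factory=list)

    def primary(self) -> Isoform:
        return self.isoforms[0]

    def spliced_cds(self, genome_seq: str, isoform_id: str | None = None) -> str:
        iso = self.get_isoform(isoform_id) if isoform_id else self.primary()
        cds = iso.spliced_cds(genome_seq)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds

    def get_isoform(self, isoform_id: str) -> Isoform:
        for iso in self.isoforms:
            if iso.isoform_id == isoform_id:
                return iso
        raise KeyError(f"no isoform {isoform_id!r} in gene {self.gene_id!r}")


# ---------------------------------------------------------------------------
# edit inference

def infer_edit(
    wt_region: str, mut_region: str, chrom: str = "region", offset: int = 0
) -> EditEvent:
    """Infer the leftmost-normalized edit transforming ``wt_region`` into
    ``mut_region``.

    Gap characters are stripped before comparison. A single contiguous
    difference block yields an insertion/deletion/substitution; sequences
    needing more than one block yield a complex event with the block list.
    ``offset`` shifts reported positions into genomic coordinates.
    """
    wt = wt_region.replace("-", "").upper()
    mut = mut_region.replace("-", "").upper()
    if not wt or not mut:
        raise ValueError("both sequences must be non-empty")
    if wt == mut:
        raise ValueError("sequences are identical: no edit to infer")

    # Leftmost normalization: claim the maximal common suffix first, then
    # the maximal common prefix, which pushes the difference block as far
    # left as it will go.
    max_suffix = min(len(wt), len(mut))
    ls = 0
    while ls < max_suffix and wt[len(wt) - 1 - ls] == mut[len(mut) - 1 - ls]:
        ls += 1
    lp = 0
    lp_max = min(len(wt), len(mut)) - ls
    while lp < lp_max and wt[lp] == mut[lp]:
        lp += 1
    ref = wt[lp : len(wt) - ls]
    alt = mut[lp : len(mut) - ls]

    event = EditEvent(chrom=chrom, position=offset + lp + 1, ref_allele=ref,
                      alt_allele=alt)
    needs_blocks = event.kind is EditKind.COMPLEX or (
        event.kind is EditKind.SUBSTITUTION
        and any(a == b for a, b in zip(ref, alt))
    )
    if needs_blocks:
        blocks = _complex_blocks(wt, mut, chrom, offset)
        if len(blocks) > 1:
            event.blocks = blocks
        elif blocks:
            event = blocks[0]  # a single contiguous difference after all
    return event


def _complex_blocks(
    wt: str, mut: str, chrom: str, offset: int
) -> list[EditEvent]:
    """Decompose a multi-block difference via an edlib alignment path."""
    res = edlib.align(mut, wt, task="path")
    blocks: list[EditEvent] = []
    wpos = mpos = 0
    cur_ref: list[str] = []
    cur_alt: list[str] = []
    cur_start = 0

    def flush() -> None:
        nonlocal cur_ref, cur_alt
        if cur_ref or cur_alt:
            blocks.append(
                EditEvent(chrom=chrom, position=offset + cur_start + 1,
                          ref_allele="".join(cur_ref), alt_allele="".join(cur_alt))
            )
            cur_ref, cur_alt = [], []

    import re

    for count, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        count = int(count)
        if op == "=":
            flush()
            wpos += count
            mpos += count
        else:
            if not (cur_ref or cur_alt):
                cur_start = wpos
            if op in ("X", "M"):
                cur_ref.append(wt[wpos : wpos + count])
                cur_alt.append(mut[mpos : mpos + count])
                wpos += count
                mpos += count
            elif op == "D":  # in edlib's query-vs-target: deletion from query
                cur_ref.append(wt[wpos : wpos + count])
                wpos += count
            elif op == "I":
                cur_alt.append(mut[mpos : mpos + count])
                mpos += count
    flush()
    return blocks


# ---------------------------------------------------------------------------
# edit application

@dataclass
class AppliedEdit:
    """Result of applying an edit to a gene model over a genome sequence."""

    wt_cds: str
    mut_cds: str
    edited_model: GeneModel
    edited_genome: str
    overlaps_cds: bool
    boundary_warning: bool


def apply_edit(
    model: GeneModel, genome_seq: str, edit: EditEvent,
    isoform_id: str | None = None,
) -> AppliedEdit:
    """Apply an edit to the genome and rebuild the spliced CDS.

    Exon coordinates downstream of the edit shift by the edit's length
    change; splice sites outside the edited interval are untouched. An
    edit spanning an exon/intron boundary is applied but flagged.
    """
    iso = model.get_isoform(isoform_id) if isoform_id else model.primary()
    pos0 = edit.position - 1
    ref_end = pos0 + len(edit.ref_allele)
    if edit.ref_allele and genome_seq[pos0:ref_end].upper() != edit.ref_allele.upper():
        raise ValueError(
            f"reference allele mismatch at {edit.chrom}:{edit.position}: "
            f"genome has {genome_seq[pos0:ref_end]!r}"
        )
    shift = edit.length_change
    edited_genome = genome_seq[:pos0] + edit.alt_allele + genome_seq[ref_end:]

    boundary = False
    for s, e in iso.exons:
        if (pos0 < s < ref_end) or (pos0 < e < ref_end):
            boundary = True

    def remap(x: int) -> int:
        if x <= pos0:
            return x
        if x >= ref_end:
            return x + shift
        return pos0 + min(x - pos0, len(edit.alt_allele))

    new_isoforms = []
    for item in model.isoforms:
        new_isoforms.append(
            Isoform(
                isoform_id=item.isoform_id,
                exons=[(remap(s), remap(e)) for s, e in item.exons],
                cds_start=remap(item.cds_start),
                cds_end=remap(item.cds_end),
            )
        )
    edited_model = GeneModel(
        gene_id=model.gene_id, chrom=model.chrom, strand=model.strand,
        isoforms=new_isoforms, protein_domains=list(model.protein_domains),
    )
    wt_cds = model.spliced_cds(genome_seq, isoform_id)
    mut_cds = edited_model.spliced_cds(edited_genome, isoform_id)
    cds_exonic = any(
        max(s, iso.cds_start) < min(e, iso.cds_end)
        and pos0 < min(e, iso.cds_end)
        and max(ref_end, pos0 + 1) > max(s, iso.cds_start)
        for s, e in iso.exons
    )
    return AppliedEdit(
        wt_cds=wt_cds, mut_cds=mut_cds, edited_model=edited_model,
        edited_genome=edited_genome, overlaps_cds=cds_exonic,
        boundary_warning=boundary,
    )


# ---------------------------------------------------------------------------
# translation and consequence

def translate_cds(cds: str) -> str:
    """Translate a CDS, stopping at the first stop codon.

    A trailing partial codon is ignored with a warning; codons containing
    N translate to X.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    if len(cds) % 3:
        warnings.warn(
            f"CDS length {len(cds)} is not a multiple of 3; trailing "
            "partial codon ignored", stacklevel=2,
        )
        cds = cds[: len(cds) - len(cds) % 3]
    return str(Seq(cds).translate(to_stop=True))


@dataclass
class ConsequenceReport:
    kind: ConsequenceKind
    aa_removed: int = 0
    aa_inserted: int = 0
    premature_stop_at: int | None = None  # 1-based codon index in the mutant
    domains_lost: list[str] = field(default_factory=list)


def _anchored_diff(wt: str, mut: str) -> tuple[int, int]:
    """(prefix_len, suffix_len) of an anchored diff, prefix claimed first."""
    lp = 0
    lim = min(len(wt), len(mut))
    while lp < lim and wt[lp] == mut[lp]:
        lp += 1
    ls = 0
    while ls < lim - lp and wt[len(wt) - 1 - ls] == mut[len(mut) - 1 - ls]:
        ls += 1
    return lp, ls


def classify_consequence(
    wt_cds: str,
    mut_cds: str,
    domains: list[tuple[str, int, int]] | None = None,
) -> ConsequenceReport:
    """Classify the protein-level consequence of an edited CDS.

    ``domains`` are protein-coordinate intervals (name, start, end),
    1-based inclusive; a domain is reported lost when fewer than half of
    its residues survive in the mutant protein (survival judged by the
    anchored diff).
    """
    domains = domains or []
    wt_prot = translate_cds(wt_cds)
    if not mut_cds.upper().startswith("ATG"):
        return ConsequenceReport(
            kind=ConsequenceKind.START_LOST,
            aa_removed=len(wt_prot),
            domains_lost=[d[0] for d in domains],
        )
    with warnings.catch_warnings():
        # frameshifted CDSs legitimately end mid-codon
        warnings.simplefilter("ignore")
        mut_prot = translate_cds(mut_cds)
    frameshift = (len(mut_cds) - len(wt_cds)) % 3 != 0

    lp, ls = _anchored_diff(wt_prot, mut_prot)
    removed = len(wt_prot) - lp - ls
    inserted = len(mut_prot) - lp - ls

    # A stop is premature when translation terminated before the end of the
    # (frame-trimmed) mutant CDS rather than at its terminal codon.
    premature = None
    if (len(mut_prot) + 1) * 3 < len(mut_cds) - len(mut_cds) % 3:
        premature = len(mut_prot) + 1

    lost = []
    for name, start, end in domains:
        size = end - start + 1
        surviving = sum(
            1 for i in range(start, end + 1)
            if i <= lp or i > len(wt_prot) - ls
        )
        if size > 0 and surviving / size < DOMAIN_LOST_SURVIVAL:
            lost.append(name)

    if frameshift:
        kind = ConsequenceKind.FRAMESHIFT
    elif removed == 0 and inserted == 0:
        kind = ConsequenceKind.SYNONYMOUS
    elif len(mut_cds) == len(wt_cds) and removed == inserted:
        kind = ConsequenceKind.MISSENSE
    elif len(mut_cds) < len(wt_cds):
        kind = ConsequenceKind.IN_FRAME_DELETION
    else:
        kind = ConsequenceKind.IN_FRAME_INSERTION

    return ConsequenceReport(
        kind=kind, aa_removed=removed, aa_inserted=inserted,
        premature_stop_at=premature, domains_lost=lost,
    )


def editing_rate(n_mutants: int, n_identified: int) -> float:
    """Editing rate in percent: 100 x mutants / PCR-identified plants."""
    if n_identified <= 0:
        raise ValueError("number of identified plants must be positive")
    return 100.0 * n_mutants / n_identified
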