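"""Synthetic data generators for every pipeline stage.

Everything the analyses consume can be generated here with the
statistical structure the methods assume: neutral coalescent CDS
alignments with optional regional selection (for the diversity
statistics), a spliced gene with junction-spanning reads drawn from a
configurable junction mixture (for junction quantification), and variant
tables with planted true edits plus threshold-violating noise (for the
effective-mutation filter). The printed wild-type/mutant target-region
alleles of the editing experiment ship as an in-code fixture together
with a synthetic gene model that embeds them in frame.

All generators are seed-deterministic: the same configuration yields
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .edits import EditEvent, GeneModel, Isoform
from .popgen import CodingAlignment

BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Shared knobs for the synthetic generators.

    theta is the population mutation parameter per region (4*N*mu summed
    over sites); ``domain_layout`` entries are (name, start, end,
    rate_multiplier) with 1-based inclusive coordinates; proportions in
    ``junction_mixture`` must sum to <= 1 (any remainder is unspliced
    coverage and contributes no junction).
    """

    seed: int = 0
    n_samples: int = 20
    sequence_length: int = 900
    theta: float = 5.0
    domain_layout: list[tuple[str, int, int, float]] = field(default_factory=list)
    junction_mixture: dict[str, float] = field(
        default_factory=lambda: {"annotated": 0.99, "shift11": 0.004, "shift13": 0.006}
    )
    read_depth: int = 10000
    noise_margin: float = 0.05

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if sum(self.junction_mixture.values()) > 1 + 1e-9:
            raise ValueError("junction mixture proportions must sum to <= 1")


# ---------------------------------------------------------------------------
# Hudson coalescent with infinite sites

def _coalescent_tree(n: int, rng: np.random.Generator):
    """Hudson coalescent genealogy: returns (parent, branch_len, children).

    Nodes 0..n-1 are leaves; the root is node 2n-2. Times are in units of
    2N generations: while k lineages remain, the waiting time is
    exponential with rate k(k-1)/2 and a uniformly chosen pair merges.
    """
    parent = np.full(2 * n - 1, -1, dtype=int)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    branch = np.zeros(2 * n - 2)
    for v in range(2 * n - 2):
        branch[v] = time[parent[v]] - time[v]
    return parent, branch


def _leaves_under(node: int, parent: np.ndarray, n: int) -> list[int]:
    children: dict[int, list[int]] = {}
    for v, p in enumerate(parent):
        if p >= 0:
            children.setdefault(p, []).append(v)
    stack, out = [node], []
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
        else:
            stack.extend(children.get(v, []))
    return out


def simulate_coalescent_alignment(cfg: SimulationConfig) -> CodingAlignment:
    """Neutral coalescent alignment under the infinite-sites model.

    Mutation count is Poisson(theta * T_total / 2) where T_total is the
    total branch length; each mutation picks a branch proportional to its
    length and a distinct site, weighted by the per-domain rate
    multipliers of ``domain_layout``. Leaves under the branch carry a
    derived base at that site.
    """
    if cfg.n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n_samples, cfg.sequence_length
    parent, branch = _coalescent_tree(n, rng)

    site_weight = np.ones(L)
    for _, start, end, mult in cfg.domain_layout:
        site_weight[start - 1 : end] = mult
    site_weight = site_weight / site_weight.sum()

    ancestral = rng.choice(list(BASES), size=L)
    seqs = np.tile(ancestral, (n, 1))

    total_len = branch.sum()
    n_mut = rng.poisson(cfg.theta * total_len / 2.0)
    n_mut = min(n_mut, L)  # infinite sites: one mutation per site
    sites = rng.choice(L, size=n_mut, replace=False, p=site_weight)
    branch_p = branch / total_len if total_len > 0 else None
    for site in sites:
        b = rng.choice(len(branch), p=branch_p)
        anc = ancestral[site]
        derived = rng.choice([c for c in BASES if c != anc])
        for leaf in _leaves_under(b, parent, n):
            seqs[leaf, site] = derived

    domains = [(name, s, e) for name, s, e, _ in cfg.domain_layout]
    return CodingAlignment(
        sample_ids=[f"s{i:03d}" for i in range(n)],
        sequences=["".join(row) for row in seqs],
        domains=domains,
    )


# ---------------------------------------------------------------------------
# spliced gene + junction-spanning reads

@dataclass
class SimulatedGene:
    model: GeneModel
    genome_seq: str
    junction_keys: dict[str, tuple[str, int, int]]  # mixture label -> key


def make_spliced_gene(
    exon_seqs: list[str],
    intron_seqs: list[str],
    chrom: str = "synth1",
    gene_id: str = "geneA",
    utr5: str = "",
    utr3: str = "",
    pad: str = "CCTCAC",
    protein_domains: list[tuple[str, int, int]] | None = None,
) -> SimulatedGene:
    """Assemble a plus-strand gene from exonic CDS pieces and introns.

    ``exon_seqs`` are coding sequences; ``utr5``/``utr3`` extend the first
    and last exon. Introns are written as given (callers supply GT..AG
    signals). Junction keys named ``intron1``, ``intron2``, ... are
    recorded for read simulation.
    """
    if len(intron_seqs) != len(exon_seqs) - 1:
        raise ValueError("need exactly one fewer intron than exons")
    genome = [pad]
    cursor = len(pad)
    exons: list[tuple[int, int]] = []
    junctions: dict[str, tuple[str, int, int]] = {}
    for i, exon in enumerate(exon_seqs):
        piece = exon
        if i == 0:
            piece = utr5 + piece
        if i == len(exon_seqs) - 1:
            piece = piece + utr3
        exons.append((cursor, cursor + len(piece)))
        genome.append(piece)
        cursor += len(piece)
        if i < len(intron_seqs):
            junctions[f"intron{i + 1}"] = (chrom, cursor + 1, cursor + len(intron_seqs[i]))
            genome.append(intron_seqs[i])
            cursor += len(intron_seqs[i])
    genome.append(pad)
    cds_start = exons[0][0] + len(utr5)
    cds_end = exons[-1][1] - len(utr3)
    iso = Isoform(isoform_id=f"{gene_id}-01", exons=exons,
                  cds_start=cds_start, cds_end=cds_end)
    model = GeneModel(
        gene_id=gene_id, chrom=chrom, strand="+", isoforms=[iso],
        protein_domains=protein_domains or [],
    )
    return SimulatedGene(model=model, genome_seq="".join(genome),
                         junction_keys=junctions)


def simulate_junction_reads(
    gene: SimulatedGene,
    cfg: SimulationConfig,
    sam_path: str | Path,
    sample: str = "sim",
    focal_intron: str = "intron2",
    shift_labels: dict[str, int] | None = None,
    flank: int = 10,
) -> dict[str, int]:
    """Write junction-spanning SAM reads drawn from the junction mixture.

    The mixture's ``annotated`` label maps to ``focal_intron``'s
    annotated donor; labels like ``shift13`` (or an explicit
    ``shift_labels`` map) move the donor that many bases upstream. Read
    counts per label are multinomial at ``cfg.read_depth``. Returns the
    drawn truth counts per label.
    """
    import pysam

    chrom, istart, iend = gene.junction_keys[focal_intron]
    labels = list(cfg.junction_mixture)
    probs = np.array([cfg.junction_mixture[k] for k in labels], dtype=float)
    rest = 1.0 - probs.sum()
    if rest > 1e-12:
        labels.append("__unspliced__")
        probs = np.append(probs, rest)
    rng = np.random.default_rng(cfg.seed + 1)
    counts = rng.multinomial(cfg.read_depth, probs / probs.sum())
    truth = dict(zip(labels, (int(c) for c in counts)))

    shift_labels = shift_labels or {}

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": len(gene.genome_seq) + 1000}],
    }
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        idx = 0
        for label, cnt in truth.items():
            if label == "__unspliced__":
                continue
            if label == "annotated":
                shift = 0
            elif label in shift_labels:
                shift = shift_labels[label]
            elif label.startswith("shift"):
                shift = int(label[5:])
            else:
                raise ValueError(f"cannot interpret junction label {label!r}")
            donor0 = istart - 1 - shift  # 0-based first intronic base
            intron_len = (iend - donor0) if shift else (iend - istart + 1)
            start0 = donor0 - flank
            seq_left = gene.genome_seq[start0:donor0]
            acc_end0 = iend  # half-open end of the intron
            seq_right = gene.genome_seq[acc_end0 : acc_end0 + flank]
            for _ in range(cnt):
                a = pysam.AlignedSegment()
                a.query_name = f"{sample}_{label}_{idx}"
                idx += 1
                a.query_sequence = seq_left + seq_right
                a.reference_id = 0
                a.reference_start = start0
                a.mapping_quality = 60
                a.cigartuples = [(0, flank), (3, intron_len), (0, flank)]
                a.flag = 0
                out.write(a)
    return truth


# ---------------------------------------------------------------------------
# variant tables with planted edits + noise

def simulate_variant_table(
    cfg: SimulationConfig,
    planted_edits: list[EditEvent],
    out_dir: str | Path,
    contigs: dict[str, int] | None = None,
    n_noise: int = 50,
    sample: str = "mutant",
) -> dict[str, Path]:
    """Write a mutant VCF, a wild-type VCF and a truth sidecar TSV.

    Planted edits are emitted homozygous-alt with alt reads >= 5, mapping
    quality >= 55 and EMD >= 0.95, comfortably inside the filter. Each
    noise variant violates exactly one named threshold by at least the
    configured margin (low reads, low MQ, low EMD, heterozygous, or
    matching the wild-type call). The sidecar records which.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 2)
    contigs = contigs or {"chr06": 31_000_000}

    rows = []  # (chrom,pos,ref,alt,reads,mq,emd,gt,label,violation)
    used = {(e.chrom, e.position) for e in planted_edits}
    for e in planted_edits:
        ref = e.ref_allele or "N"
        alt = e.alt_allele or "N"
        if not e.ref_allele:  # VCF needs an anchor base for pure indels
            ref, alt = "A", "A" + e.alt_allele
        elif not e.alt_allele:
            ref, alt = "A" + e.ref_allele, "A"
        rows.append(
            (e.chrom, e.position, ref, alt,
             int(rng.integers(5, 20)), float(rng.uniform(55, 60)),
             float(rng.uniform(0.95, 1.0)), "1/1", "planted", "none")
        )

    violations = ["low_reads", "low_mq", "low_emd", "het", "matches_wildtype"]
    chroms = list(contigs)
    for i in range(n_noise):
        viol = violations[i % len(violations)]
        chrom = chroms[int(rng.integers(len(chroms)))]
        while True:
            pos = int(rng.integers(1000, contigs[chrom] - 1000))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        reads = int(rng.integers(5, 20))
        mq = float(rng.uniform(55, 60))
        emd = float(rng.uniform(0.95, 1.0))
        gt = "1/1"
        if viol == "low_reads":
            reads = int(rng.integers(0, 4))  # <= 3: fails the strict bound
        elif viol == "low_mq":
            mq = float(rng.uniform(20, 50 - cfg.noise_margin))
        elif viol == "low_emd":
            emd = float(rng.uniform(0.5, 0.90 - cfg.noise_margin))
        elif viol == "het":
            gt = "0/1"
        rows.append((chrom, pos, str(ref), str(alt), reads, mq, emd, gt, "noise", viol))

    rows.sort(key=lambda r: (r[0], r[1]))

    mut_vcf = out_dir / "mutant.vcf"
    wt_vcf = out_dir / "wildtype.vcf"
    truth_tsv = out_dir / "truth.tsv"

    _write_vcf(mut_vcf, rows, contigs, sample)
    wt_rows = [
        (c, p, ref, alt, 10, 60.0, 1.0, "1/1", "wt", "none")
        for (c, p, ref, alt, *_rest, label, viol) in rows
        if viol == "matches_wildtype"
    ]
    _write_vcf(wt_vcf, wt_rows, contigs, "wildtype")

    with open(truth_tsv, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tlabel\tviolation\n")
        for c, p, ref, alt, _r, _m, _e, _g, label, viol in rows:
            fh.write(f"{c}\t{p}\t{ref}\t{alt}\t{label}\t{viol}\n")

    return {"mutant": mut_vcf, "wildtype": wt_vcf, "truth": truth_tsv}


def _write_vcf(path: Path, rows, contigs: dict[str, int], sample: str) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AOC,Number=1,Type=Integer,Description="Alt-supporting read count">')
    header.add_line('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">')
    header.add_line('##INFO=<ID=EMD,Number=1,Type=Float,Description="Effective matched degree">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom, pos, ref, alt, reads, mq, emd, gt, _label, _viol in rows:
            rec = out.new_record(
                contig=chrom, start=pos - 1, stop=pos - 1 + len(ref),
                alleles=(ref, alt),
            )
            rec.info["AOC"] = reads
            rec.info["MQ"] = round(mq, 2)
            rec.info["EMD"] = round(emd, 4)
            rec.samples[sample]["GT"] = (1, 1) if gt == "1/1" else (0, 1)
            out.write(rec)


# ---------------------------------------------------------------------------
# the printed target-region fixture

WT_TARGET_47 = "GGGCGTACAGGCGGAACGCGCTGCGGGAGGACGCCGCGAGGGCGAAG"

MUTANT_ALLELES = {
    # printed with alignment gaps; infer_edit strips them
    "3bp_deletion": "GG-TACAGGCGGAACGCGCTGCGGGAGGACGCCGCGAGGGCGAAG",
    "39bp_deletion": "GG-GCGAAG",
    "G_insertion": "GGGCGGTACAGGCGGAACGCGCTGCGGGAGGACGCCGCGAGGGCGAAG",
    "T_insertion": "GGGCGTTACAGGCGGAACGCGCTGCGGGAGGACGCCGCGAGGGCGAAG",
}

# Editing outcome counts of the T0 screen: variety -> (PCR-identified, mutants)
T0_EDITING_COUNTS = {"Kasalath": (6, 2), "Wuyunjing24": (5, 5)}

# CDS prefix of the fixture gene: 21 codons + 1 base, so the 47-mer lands
# with its GCG triplet (positions 3-5) on a codon boundary and the printed
# 3-bp deletion removes one complete alanine codon. Encodes the Domain II
# degron core GWPPV upstream of the target.
_FIXTURE_PREFIX = (
    "ATGTCCGAGCTCGGCTTCGACCTGAAGGAGACCGAGCTCGGATGGCCTCCTGTTGCCAAGGAGC"
)
# Exon-2 tail: carries GT dinucleotides at donor shifts 13 and 11, the two
# alternative 5' splice sites observed for the second intron.
_FIXTURE_TAIL = "GTGTACCTGCAGG"
# Exon-3 CDS: completes the split codon, then codon pairs (GTA ACC and
# GAT AAG) that read as stops in either +1-shifted frame, then Domains III
# and IV and the stop.
_FIXTURE_EXON3_CDS = (
    "AG"
    "AAGGTAACCGATAAGGTGGACTGGATGCTCAAGGTCGACTACGTGCCCGAGTCCAAGCGCCTG"
    "GACTTCGTGAAGACCGAGCTGCGCGAGAAGTAA"
)
_FIXTURE_INTRON1 = "GTAAGTCTCCTTACGATCGGAACTTCCAGGATCCGTTACGGCTTAAACCGGTTCCATTGATTGCACAG"
_FIXTURE_INTRON2 = "GTACGTACCGGAACTTACCGGCTTCAAGGCCTTACGGATCCGGAACTTCCGGCTCCATTCGCAG"

# Protein-coordinate domains of the fixture protein (73 aa).
FIXTURE_DOMAINS = [("I", 3, 8), ("II", 14, 37), ("III", 48, 59), ("IV", 62, 73)]


@dataclass
class Table2Fixture:
    wt_target: str
    alleles: dict[str, str]
    gene: SimulatedGene
    target_offset: int  # 0-based genomic offset of the 47-mer
    editing_counts: dict[str, tuple[int, int]]


def table2_fixture() -> Table2Fixture:
    """The printed wild-type target region, the four mutant alleles, and a
    synthetic three-exon gene embedding the 47-mer in frame.

    The gene is built so the printed alleles reproduce their reported
    protein consequences: the 3-bp deletion removes one alanine, the
    39-bp deletion removes 13 residues, and either single-base insertion
    frameshifts with a premature stop ahead of Domains III and IV. The
    second intron's donor has alternative GT signals 11 and 13 bases
    upstream, so a 13-base donor shift restores the frame after a 1-bp
    insertion.
    """
    exon1_cds = _FIXTURE_PREFIX[:34]
    exon2 = _FIXTURE_PREFIX[34:] + WT_TARGET_47 + _FIXTURE_TAIL
    gene = make_spliced_gene(
        exon_seqs=[exon1_cds, exon2, _FIXTURE_EXON3_CDS],
        intron_seqs=[_FIXTURE_INTRON1, _FIXTURE_INTRON2],
        chrom="synth1",
        gene_id="OsIAA23_like",
        utr5="CTCACA",
        utr3="TGCCATCA",
        protein_domains=list(FIXTURE_DOMAINS),
    )
    exon2_start = gene.model.primary().exons[1][0]
    target_offset = exon2_start + len(_FIXTURE_PREFIX) - 34
    return Table2Fixture(
        wt_target=WT_TARGET_47,
        alleles=dict(MUTANT_ALLELES),
        gene=gene,
        target_offset=target_offset,
        editing_counts=dict(T0_EDITING_COUNTS),
    )
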