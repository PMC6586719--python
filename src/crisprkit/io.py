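"""Shared format readers and writers.

All on-disk coordinates are 1-based inclusive (FASTA/GFF3/VCF/BED
conventions); everything in memory is 0-based half-open. Conversion
happens only here.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .edits import EditEvent, GeneModel, Isoform
from .offtarget import Genotype, VariantRecord
from .popgen import CodingAlignment, PopGenSummary
from .transcripts import SpliceJunction


# ---------------------------------------------------------------------------
# FASTA

def read_alignment_fasta(
    path: str | Path, domains_path: str | Path | None = None
) -> CodingAlignment:
    """Read an aligned FASTA (gaps as ``-``) plus an optional 3-column
    domain sidecar (name, start, end; 1-based inclusive, tab-separated)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    domains: list[tuple[str, int, int]] = []
    if domains_path is not None:
        domains = read_domains_tsv(domains_path)
    return CodingAlignment(
        sample_ids=[r.id for r in records],
        sequences=[str(r.seq).upper() for r in records],
        domains=domains,
    )


def write_alignment_fasta(aln: CodingAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_domains_tsv(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
        out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def read_fasta_seq(path: str | Path, name: str | None = None) -> str:
    """First (or named) sequence of a FASTA file as a plain string."""
    for rec in SeqIO.parse(str(path), "fasta"):
        if name is None or rec.id == name:
            return str(rec.seq).upper()
    raise KeyError(f"sequence {name!r} not found in {path}")


def write_fasta_seq(seq: str, name: str, path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene -> mRNA -> exon/CDS) from GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        isoforms = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [
                (f.start - 1, f.end)  # 1-based inclusive -> 0-based half-open
                for f in db.children(mrna, featuretype="exon")
            ]
            cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
            if not exons and cds:
                exons = cds
            if not exons:
                continue
            exons.sort()
            cds_start = min(s for s, _ in cds) if cds else exons[0][0]
            cds_end = max(e for _, e in cds) if cds else exons[-1][1]
            isoforms.append(
                Isoform(
                    isoform_id=mrna.id, exons=exons,
                    cds_start=cds_start, cds_end=cds_end,
                )
            )
        if isoforms:
            models.append(
                GeneModel(
                    gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                    isoforms=isoforms,
                )
            )
    return models


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = (
                min(i.exons[0][0] for i in m.isoforms) + 1,
                max(i.exons[-1][1] for i in m.isoforms),
            )
            fh.write(
                f"{m.chrom}\tcrisprkit\tgene\t{span[0]}\t{span[1]}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            for iso in m.isoforms:
                fh.write(
                    f"{m.chrom}\tcrisprkit\tmRNA\t{iso.exons[0][0] + 1}\t"
                    f"{iso.exons[-1][1]}\t.\t{m.strand}\t.\t"
                    f"ID={iso.isoform_id};Parent={m.gene_id}\n"
                )
                for s, e in iso.exons:
                    fh.write(
                        f"{m.chrom}\tcrisprkit\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                        f"Parent={iso.isoform_id}\n"
                    )
                for s, e in iso.exons:
                    lo, hi = max(s, iso.cds_start), min(e, iso.cds_end)
                    if lo < hi:
                        fh.write(
                            f"{m.chrom}\tcrisprkit\tCDS\t{lo + 1}\t{hi}\t.\t"
                            f"{m.strand}\t0\tParent={iso.isoform_id}\n"
                        )


# ---------------------------------------------------------------------------
# VCF

def read_variants_vcf(path: str | Path, sample: str | None = None) -> list[VariantRecord]:
    """Read variants with AOC/MQ/EMD INFO keys into VariantRecords.

    Multi-allelic records are split into one record per alt allele.
    """
    import pysam

    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        use_sample = sample or (sample_names[0] if sample_names else "")
        for rec in vcf:
            gt_field = None
            if use_sample and use_sample in rec.samples:
                gt_field = rec.samples[use_sample].get("GT")
            for alt_idx, alt in enumerate(rec.alts or (), start=1):
                if gt_field and None not in gt_field:
                    alleles = set(gt_field)
                    if alleles == {alt_idx}:
                        gt = Genotype.HOM_ALT
                    elif alt_idx in alleles:
                        gt = Genotype.HET
                    else:
                        gt = Genotype.HOM_REF
                else:
                    gt = Genotype.HOM_ALT
                out.append(
                    VariantRecord(
                        chrom=rec.chrom, pos=rec.pos, ref_allele=rec.ref,
                        alt_allele=alt,
                        alt_read_count=int(rec.info.get("AOC", 0)),
                        mapping_quality=float(rec.info.get("MQ", 0.0)),
                        effective_matched_degree=float(rec.info.get("EMD", 0.0)),
                        genotype=gt, sample=use_sample,
                    )
                )
    return out


def wildtype_calls_from_vcf(path: str | Path) -> dict[tuple[str, int], str]:
    """Alt alleles called in the wild-type sample, keyed by site."""
    import pysam

    calls: dict[tuple[str, int], str] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts:
                calls[(rec.chrom, rec.pos)] = rec.alts[0]
    return calls


def write_edit_vcf(
    edits: list[EditEvent], path: str | Path, contigs: dict[str, int]
) -> None:
    """Write inferred edits as VCF records (anchor-base convention)."""
    import pysam

    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for e in edits:
            if e.ref_allele and e.alt_allele:
                pos0, ref, alt = e.position - 1, e.ref_allele, e.alt_allele
            else:
                # pad pure indels with the preceding base
                pos0 = e.position - 2
                ref = "N" + e.ref_allele
                alt = "N" + e.alt_allele
            rec = out.new_record(
                contig=e.chrom, start=pos0, stop=pos0 + len(ref), alleles=(ref, alt)
            )
            out.write(rec)


# ---------------------------------------------------------------------------
# junction BED and tables

def read_junction_bed(path: str | Path, sample: str) -> list[SpliceJunction]:
    """6-column junction BED: chrom, start (0-based), end, name, count,
    strand. The interval is the intron, half-open."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
        chrom, start, end, _name, count, strand = parts[:6]
        out.append(
            SpliceJunction(
                chrom=chrom, intron_start=int(start) + 1, intron_end=int(end),
                strand=strand, counts={sample: int(count)},
            )
        )
    return out


def write_junction_table(junctions: list[SpliceJunction], path: str | Path) -> None:
    samples = sorted({s for j in junctions for s in j.counts})
    rows = []
    for j in junctions:
        row = {
            "chrom": j.chrom, "intron_start": j.intron_start,
            "intron_end": j.intron_end, "strand": j.strand, "status": j.status,
        }
        for s in samples:
            row[f"count_{s}"] = j.counts.get(s, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary_tsv(
    rows: list[PopGenSummary], path: str | Path, permille: bool = False
) -> None:
    """Write PopGenSummary rows as TSV; ``permille`` scales pi by 1000
    (the display convention for per-mil diversity)."""
    recs = []
    for r in rows:
        d = {f: getattr(r, f) for f in PopGenSummary.FIELDS}
        if permille:
            for key in ("pi_raw", "pi_jc"):
                if not math.isnan(d[key]):
                    d[key] = d[key] * 1000.0
        recs.append(d)
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct TSV with columns sample, gene, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    return df
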