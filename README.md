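# crisprkit

A Python toolkit for the computational side of a CRISPR/Cas9 knockout
study in a plant gene family — written around the analysis of rice
Aux/IAA genes, where a guide RNA targeting the degron region (Domain II)
of an *OsIAA23*-like gene produces small indels whose protein-level and
transcript-level consequences must be worked out from sequence alone.

It is aimed at researchers who have the *outputs* of the wet lab and the
standard mapping pipelines — target-region Sanger sequences, coding
alignments of a gene family, spliced RNA-seq alignments, variant calls
from resequencing, qPCR Ct tables — and need the downstream analyses:

* **Population genetics of the gene family** (`crisprkit.popgen`):
  nucleotide diversity π with Jukes–Cantor correction
  (d = −¾ ln(1 − 4p/3)), Watterson's θ̂ = S/a₁, Tajima's D with the
  standard normalising constants (a₁…e₂), Nei–Gojobori Ka/Ks with
  pathway averaging over substitution orderings, Kimura 2-parameter
  distances (K = −½ ln(1−2P−Q) − ¼ ln(1−2Q)) and a deterministic
  neighbor-joining tree — per gene and per protein domain.
* **Edit inference and consequence calling** (`crisprkit.edits`): infer a
  leftmost-normalized indel from a wild-type/mutant sequence pair, apply
  it to a gene model, translate, and classify the outcome (in-frame
  deletion/insertion, frameshift with premature stop, missense,
  synonymous), including which conserved domains are lost.
* **Splice-junction analysis and frame rescue** (`crisprkit.transcripts`):
  extract junctions from spliced alignments (CIGAR `N` operations),
  compare novel-junction proportions between genotypes, and enumerate
  alternative 5′ donors that restore the reading frame after a frameshift
  edit — a donor shifted s bases into the exon rescues an insertion of
  length ℓ exactly when (ℓ − s) ≡ 0 (mod 3), the new intron still reads
  GT…AG, and no premature stop appears. Also: mosaic (isoform-chimeric)
  transcript construction and 2^−ΔΔCt relative expression.
* **Off-target screening** (`crisprkit.offtarget`): the *effective
  mutation* filter over called variants — homozygous, differing from the
  wild type, mutated reads > 3, mapping quality ≥ 50, effective matched
  degree (matched length / read length) ≥ 0.90 — with region annotation
  (exon > UTR > intron > intergenic) and per-class summaries.
* **Synthetic data** (`crisprkit.simulate`): seed-deterministic
  generators for every input — Hudson-coalescent coding alignments with
  per-domain mutation-rate multipliers, junction-spanning reads drawn
  from a configurable junction mixture, and variant tables with planted
  true edits plus threshold-violating noise — plus the printed
  target-region alleles as an in-code fixture.

## Worked example

The printed wild-type target region (47 nt spanning the end of Domain II)
and its four mutant alleles ship as a fixture, embedded in frame in a
synthetic three-exon gene:

```python
from crisprkit import apply_edit, classify_consequence, infer_edit
from crisprkit.simulate import table2_fixture

fx = table2_fixture()
for name, allele in fx.alleles.items():
    edit = infer_edit(fx.wt_target, allele,
                      chrom=fx.gene.model.chrom, offset=fx.target_offset)
    applied = apply_edit(fx.gene.model, fx.gene.genome_seq, edit)
    rep = classify_consequence(applied.wt_cds, applied.mut_cds,
                               fx.gene.model.protein_domains)
    print(name, edit.kind.value, rep.kind.value, rep.aa_removed,
          rep.premature_stop_at, rep.domains_lost)
```

prints

```
3bp_deletion deletion in_frame_deletion 1 None []
39bp_deletion deletion in_frame_deletion 13 None ['II']
G_insertion insertion frameshift 50 47 ['II', 'III', 'IV']
T_insertion insertion frameshift 50 47 ['II', 'III', 'IV']
```

i.e. the 3-bp deletion removes a single residue (an alanine), the 39-bp
deletion removes 13 residues, and either single-base insertion shifts the
frame, truncating the protein at codon 47 and losing the two
protein-interaction domains (III and IV). The same chain is available
from the shell:

```bash
crispr-kit consequence --gff gene.gff3 --fasta genome.fa \
    --wt GGGCGTACAGGCGGAACGCGCTGCGGGAGGACGCCGCGAGGGCGAAG \
    --mut GG-GCGAAG
crispr-kit rescue --gff gene.gff3 --fasta genome.fa --wt ... --mut ... --max-shift 30
crispr-kit popgen --alignment family.fasta --domains domains.tsv --out summary.tsv
crispr-kit offtarget --mutant mut.vcf --wildtype wt.vcf --gff ann.gff3
crispr-kit ddct --table ct.tsv --ref G3PDH --calibrator WT --target OsIAA23
```

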