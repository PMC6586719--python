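# Methods

This note documents the models, conventions and design choices behind
each analysis stage, the parameters that matter, and what the synthetic
data does and does not emulate.

## Diversity statistics (`popgen`)

**Missing data.** Gaps (`-`) and `N` are treated as missing, never as a
fifth character state. π and K2P use *pairwise deletion* (a site is
dropped only for pairs in which either member is missing); the
segregating-site count S, and therefore Tajima's D and Watterson's θ̂,
use *complete deletion* (columns with any missing character are dropped
for all samples). Pairwise deletion keeps the most information for
pairwise statistics; complete deletion keeps S and the pairwise-count
k̂ on the same set of columns, which Tajima's variance formula assumes.

**π.** The mean over all unordered sample pairs of the per-site
difference proportion. With `corrected=True` each pairwise proportion is
Jukes–Cantor corrected *before* averaging (so reported π is a mean of
corrected distances, not a corrected mean). Correction saturates at
p ≥ 3/4 and raises a `SaturationError` rather than silently truncating.
Reported per site; a per-mil display (×1000) is a formatting option of
the summary writer only.

**Tajima's D.** Computed from (n, S, k̂) with the standard constants
a₁ = Σ 1/i, a₂ = Σ 1/i², b₁ = (n+1)/(3(n−1)),
b₂ = 2(n²+n+3)/(9n(n−1)), c₁ = b₁ − 1/a₁,
c₂ = b₂ − (n+2)/(a₁n) + a₂/a₁², e₁ = c₁/a₁, e₂ = c₂/(a₁²+a₂);
D = (k̂ − S/a₁)/√(e₁S + e₂S(S−1)). k̂ is the *uncorrected* mean pairwise
difference count — no multiple-hit correction enters D; JC correction is
applied only to reported π. S = 0 yields NaN (undefined), never 0.

**Nei–Gojobori Ka/Ks.** Potential synonymous sites per codon are the
summed synonymous fractions of the three positions, averaged between the
two sequences; N + S = 3 per codon exactly, with changes *to* stop codons
counted nonsynonymous in site counting. Observed differences in codons
differing at >1 position are averaged over all substitution orderings;
orderings passing through a stop codon are excluded (if every ordering is
blocked, all are used so the difference count is preserved — a degenerate
case that cannot arise between stop-free codon pairs differing at one
position). pN and pS are JC-corrected; Ka/Ks is NaN when Ks = 0. Codons
containing a gap or N in either sequence are skipped (codon-level
pairwise deletion). Per-region Ka/Ks for an alignment is the mean
pairwise Ka over the mean pairwise Ks (a mean-pairwise convention, made
explicit because a reference-versus-sample convention is equally
defensible; the functions accept any pair directly if the latter is
wanted).

**Neighbor joining.** Classic Saitou–Nei agglomeration on the Q matrix.
Two determinism/robustness choices: ties in the Q minimum are broken by
joining the lexicographically smallest label pair, and negative branch
lengths are clamped to zero with the deficit shifted onto the sister
branch (total path lengths preserved). Verified against scikit-bio's NJ
and against exact recovery of random additive trees.

**Domain scans.** Domain intervals are declared in alignment coordinates
(1-based inclusive) and snapped *outward* to codon boundaries before
Ka/Ks so codon statistics stay well defined; π/S/D use the snapped slice
too, keeping all statistics of a row on one region. The whole-CDS row is
always first. Overlapping domains are allowed; each row is computed
independently.

## Edit inference and consequences (`edits`)

**Normalization.** The inferred edit is the single contiguous difference
block obtained by claiming the maximal common *suffix* first and then the
maximal common prefix — this places indels at their leftmost equivalent
position (the VCF convention; printed mutant alleles mark a deletion at
one of several equivalent positions, so a convention is required).
Sequences whose difference cannot be one block become a `complex` event
carrying an explicit block list derived from an edlib alignment path.

**Protein diff.** Anchored longest-common-prefix/suffix diff on the
translated proteins, prefix claimed first on ambiguity. For a clean
codon-aligned deletion of 3k nt this reports exactly k residues removed;
non-codon-aligned in-frame deletions may additionally convert one
junction residue, which appears as one removed + one inserted.

**Premature stops.** A mutant stop is premature when translation
terminates before the terminal codon of the (frame-trimmed) mutant CDS.
`premature_stop_at` is the 1-based codon index of that stop in the
mutant.

**Domain loss.** A protein-coordinate domain is "lost" when fewer than
50% of its residues survive, where a residue survives iff it lies in the
anchored prefix or suffix. The 50% threshold is a package choice — a
frameshift destroys everything downstream of its anchor, so any
mid-range threshold gives the same verdict for downstream domains; 50%
also behaves sensibly for partial in-frame deletions.

**Strand.** Minus-strand models are reverse-complemented at CDS assembly;
all coordinates reported remain genomic.

## Splice junctions and frame rescue (`transcripts`)

**Coordinates.** A junction is reported as the first and last intronic
bases, 1-based inclusive (the `chr06:23502684-23502763` style); the
internal representation is 0-based half-open. Extraction reads CIGAR
`N` operations from SAM; counts aggregate per sample and are invariant
to read order and file splitting.

**Proportions.** The denominator is the summed count of all junctions
overlapping the annotated intron's interval for that sample. This is a
documented choice (a per-gene denominator is also defensible); the locus
argument makes it explicit and configurable. The default minimum
junction support is 1 read.

**Rescue enumeration.** For an edit of net length change ℓ in an exon
followed by an intron, a donor shifted s bases upstream restores the
frame iff (ℓ − s) ≡ 0 (mod 3). With genomic sequence available two
further conditions are enforced: the shifted intron must begin GT and
end AG, and the spliced, edited CDS must reach its annotated stop with
no premature stop (checked by splicing and translating); the predicted
protein is attached to restoring candidates. Without genomic sequence
the candidates are arithmetic-only and flagged as carrying an unverified
splice signal. Note the donor-shift magnitude, not any absolute genomic
coordinate, is what the analysis treats as authoritative for the two
observed novel junctions (11 and 13 bases): with a 1-bp insertion only
the 13-base shift satisfies the residue-class condition.

**Mosaic transcripts.** The exonic CDS of isoform A 5′ of a genomic
breakpoint concatenated with that of isoform B 3′ of it, then translated.
Degenerate cases (equal isoforms; breakpoint at an isoform start) reduce
to ordinary translation of one isoform.

**2^−ΔΔCt.** Replicate Ct values are combined by arithmetic mean (a
choice; geometric aggregation operates on efficiencies, not Ct).
ΔCt = Ct(target) − Ct(reference) per sample, ΔΔCt subtracts the
calibrator's ΔCt, relative expression is 2^−ΔΔCt. Exactly halves per +1
of ΔΔCt.

## Off-target screening (`offtarget`)

The effective-mutation filter keeps a variant iff it is homozygous-alt,
its alt allele differs from the wild-type call at that site, its mutated
read count strictly exceeds 3 (">" is deliberate: 4 reads pass, 3 fail),
mapping quality ≥ 50, and effective matched degree ≥ 0.90. Mapping
quality is interpreted as the variant-site aggregate from the VCF record;
EMD, when computed from alignments, is (M/=/X bases)/(read length
including soft clips and insertions). Sites absent from the wild-type
table are treated as reference-identical in the wild type by default; a
strict mode instead excludes them as unresolved, with a warning.
Homozygosity comes from the GT field when present, else from an
alt-fraction ≥ 0.9 fallback. Multi-allelic records are split per allele
before filtering. Region classes follow exon > UTR > intron > intergenic
precedence, and region counts always partition the passing set. A
gene-list screen applies the same filter restricted to supplied gene
intervals and reports per-gene verdicts (the algorithmic counterpart of
manually inspecting a gene family in a browser).

## Synthetic data (`simulate`)

**Coalescent alignments.** Hudson's algorithm (exponential waiting times
with rate k(k−1)/2, uniform pair merges), infinite-sites mutations:
Poisson(θ·T/2) mutations placed on branches proportionally to length, at
distinct sites, optionally weighted by per-domain rate multipliers.
No recombination or demography — the target scale is a single gene's CDS.
Defaults (n = 20, L = 900, θ = 5) give E[S] = θ·a₁ ≈ 17.7 and E[D] ≈ 0,
which the test suite verifies over 300 seeded replicates (mean D within
±0.3, mean S within 15%).

**Junction reads.** Error-free junction-spanning reads drawn
multinomially from a junction mixture at a configurable depth (default
10,000, matching deep targeted RNA-seq). The default mixture keeps the
annotated junction at 99% with the two shifted donors sharing the
remainder, mirroring the observation that annotated junctions dominate
even in mutants. GT-AG dinucleotides are written at all simulated
introns. Reads are error-free because read mapping and variant calling
are out of scope; an EMD-exercising mismatch path exists in the variant
generator instead.

**Variant tables.** Planted edits are emitted homozygous with alt reads
≥ 5, MQ ≥ 55 and EMD ≥ 0.95 — comfortably inside every threshold — while
each noise variant violates exactly one named threshold with a margin
(reads ≤ 3, MQ < 49.95, EMD < 0.85, heterozygous, or present identically
in the wild type). A truth sidecar records each variant's label and
violated threshold; downstream tests read truth only from the sidecar.
By construction the filter must recover exactly the planted set; this
verifies the filter's boundary logic, not its behaviour on marginal
real-world calls.

**The printed-allele fixture.** The 47-nt wild-type target and the four
printed mutant alleles are package constants. The synthetic host gene
places the 47-mer at CDS offset 64 (≡ 1 mod 3) so the printed 3-bp
deletion removes one complete GCG (alanine) codon and the 39-bp deletion
removes 13 codons; the exon-2 tail carries GT dinucleotides at donor
shifts 11 and 13; and exon 3 contains codon pairs that read as stops in
either +1-shifted frame, so frameshift alleles terminate prematurely
regardless of where the anchored diff places the shift. The real locus
coordinates are not printed in full, so the fixture is explicitly
synthetic; all conclusions drawn from it concern sequence arithmetic,
not the real chromosome.

**What passing tests do not show.** The generators emulate idealized
versions of the real inputs: no sequencing error in reads, no alignment
ambiguity, noise variants with clean one-threshold violations, a
recombination-free coalescent. Tests passing on them demonstrate the
correctness of the statistics and the filter logic, not robustness to
the full error structure of real resequencing data.

## Numerical and interface conventions

1-based inclusive coordinates at every file boundary, 0-based half-open
internally, converted only in `io`. All randomness flows through
`numpy.random.default_rng(seed)`; identical configuration gives
byte-identical outputs. Saturated distances raise typed errors rather
than returning clipped values; undefined statistics (D at S = 0, Ka/Ks at
Ks = 0, proportions with empty denominators) return NaN. Problem sizes
used in the test suite (300 coalescent replicates at n = 20, depth
10,000 for junction recovery, 50-noise variant tables, 5-leaf tree
recovery over 20 seeds) were chosen as the smallest scales at which the
statistical assertions are stable.

## Known limitations

Minus-strand genes are supported in CDS assembly and consequence calling
but junction extraction reports strand as given by the input records
rather than inferring it; BAM/CRAM are not read (text SAM only); the
Ka/Ks machinery assumes in-frame, stop-free codon alignments and refuses
internal stops rather than masking them; bootstrap support and
substitution-model selection for trees are out of scope.
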