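# Methods

## Transcript model and splice events

A gene is one transcript: ordered exons (1-based inclusive genomic
intervals, transcription order; reverse-strand models are supported and
reverse-complement their spliced sequence) with CDS boundaries in transcript
coordinates and an optional locus sequence.  Splice events operate on the
exon structure:

| kind                | parameters                  | length delta |
|---------------------|-----------------------------|--------------|
| `exon_skip`         | exon indices                | −Σ skipped   |
| `alt_acceptor`      | exon, signed offset (bp)    | −offset      |
| `alt_donor`         | exon, signed offset (bp)    | +offset      |
| `alt_exon_inclusion`| genomic interval            | +length      |
| `intron_retention`  | intron index                | +intron      |

The modified transcript keeps its CDS start anchored to the genomic base of
the original start codon; events deleting that base are rejected.

Protein consequences are annotated by translating both transcripts from the
anchored CDS start to the first in-frame stop (standard codon table only;
non-ATG starts are an error) and comparing left-aligned.  The emitted HGVS-p
is a deliberate subset ("HGVS-p-lite"): `p.(XaaN_YaaMdel)`, `p.(XaaN*)`,
`p.(XaaNYyyfs*K)` with K counting codons from the first altered residue to
the new stop inclusive.  No 3'-rule repositioning is applied, so deletions
within repeated residues are reported left-aligned; in-frame net changes are
carried under the single `inframe_deletion` category (the analyses here
involve only deletions), and a delta-zero junction substitution — not
producible by a single catalogued event — falls back to `no_change`.

## Synthetic data: what it emulates and what it does not

The simulator emits full-length primer-to-primer amplicon reads: every read
is a complete isoform sequence with allele-tag SNV bases substituted, which
matches the RT-PCR design (one molecule, one read).  It does **not** model
fragmentation or truncation, homopolymer-specific nanopore error,
PCR chimeras, or quality–error coupling (qualities are constant at
`quality_mean`).  The error model applies independent per-base substitution
(0.03), insertion (0.01) and deletion (0.02) probabilities — a
nanopore-flavoured but uncalibrated default.  Consequently, passing tests
show that the classifier and quantifier are correct under independent
per-base noise at realistic magnitudes; they do not certify performance
under structured nanopore error.

Mixture fractions are converted to read counts by largest-remainder
rounding in `exact` mode (ties broken by lexical event id), so published
percentages like 90.25% of 400 reads are representable without rounding
slack; a seeded multinomial mode is available for stochastic studies.
Control cohorts draw their basal inclusion fraction uniformly from a band
(default 6.5–10.14%, the basal alternate-exon inclusion range seen in
control RNA); control depth defaults to 2000 reads, a configurable invented
value.  A tag SNV falling in a region absent from a requested isoform makes
that isoform untaggable and is rejected rather than silently mislabelled.

Family genotypes are simulated as phased single-carrier VCFs around a
target variant: one global marker panel (default spacing 15 kb, ±250 kb
window, boundary markers always present), rare MAFs uniform on
[0.005, 0.09] with 30% common markers mixed in.  Carrier haplotypes are
identical by descent across families inside the shared interval and draw
independently outside; the nearest rare marker beyond each boundary is
placed on exactly one family's carrier haplotype so that the truth segment
ends exactly at the interval boundaries — emulating the situation where
different families extend the shared core in different directions.

## Alignment and classification

The built-in aligner is Biopython's affine-gap pairwise aligner
(match +1, mismatch −2, gap open −6, gap extend −0.05, reference overhangs
free).  Two numerical choices matter:

* an affine (not flat) gap cost — pure edit distance fragments a long
  splice deletion via coincidental single-base matches inside the gap;
* a near-flat extension cost — at 0.5/bp a 200-bp intron costs more than
  mismatching the read tail against intronic sequence, and the optimal
  path stops spanning real introns.

minimap2 can be substituted as a subprocess for real FASTQ data; a
pre-aligned SAM/BAM path exists so no aligner is required downstream.

Junction chains take every D/N run ≥ `min_gap` (default 20 bp) as a gap;
gaps separated by an aligned bridge shorter than `min_gap` are merged, the
symmetric treatment of noise inside long gaps.  Classification requires the
same gap count and every boundary within ±`tol` (default 5 bp); minimum
total deviation wins, ties keep catalogue order.  Both defaults absorb
junction wobble without conflating the catalogued events, which differ by
≥ 83 bp in the bundled replicas; the decision flips exactly at `tol`
(verified by a boundary-perturbation sweep).  Secondary and supplementary
alignments are ignored: one vote per molecule.

Under default noise the transcript-frame classifier keeps ≥ 97% per-read
event accuracy; genome-frame chains through ten short introns are
substantially noisier (each junction contributes wobble), so the
genome-frame inclusion analysis is defined at zero error and real multi-
intron data should prefer the transcript frame or a spliced aligner.
Allele calls walk the CIGAR to the reference position (insertions do not
shift the call; deletion, clipping or base quality < `min_baseq` = 7 gives
`missing`); non-ref non-alt bases are tracked as `other` and excluded from
allele denominators, so the per-allele read counts need not sum to the
total — deliberate bookkeeping for the unassigned remainder seen in real
allele splits.  The cis/trans verdict requires a 4:1 concordant:discordant
odds ratio and ≥ 20 doubly-informative reads; per-read haplotype labels
leave contradictory double calls unlabelled, since those are exactly the
suspected miscalls.

## Quantification

Two routes: per-read fractions over classified reads (unclassified events
and missing/other alleles excluded from denominators and tallied), and
mean-depth inclusion = mean per-base depth over the alternate-exon region
divided by the canonical anchor exon's ("anchor" convention, the default;
a "competing" alt/(alt+anchor) convention is available).  For full-length
reads and whole-exon regions the two routes agree exactly, which the tests
assert.  Text output prints percentages to 2 dp; machine output keeps full
precision.

## Exact 2×2 association

Conditional on all margins, the first cell follows the noncentral (Fisher)
hypergeometric law with odds ratio ψ.  The two-sided p sums point
probabilities ≤ the observed table's (with the customary 1+1e−7 relative
guard); the reported OR is the conditional MLE, the root of
E<sub>ψ</sub>[K] = k<sub>obs</sub> bracketed on log ψ ∈ [−80, 80] and solved
to ~1e−12; CI bounds invert P<sub>ψ</sub>(K ≥ k) = α/2 and
P<sub>ψ</sub>(K ≤ k) = α/2.  These are the conventions of the standard R
implementation, solved tightly — implementations using loose root
tolerances can differ in the last printed digits for extreme tables.
Degenerate margins give p = 1 with an undefined OR; the sample
cross-product OR is also reported for transparency.  Correctness is pinned
two ways: exact-rational enumeration over all tables with margins ≤ 6, and
an independent library implementation on published-style tables.  The
single-test setting needs no multiplicity correction.

## Prioritization

The frequency gate uses the population-maximum frequency when
population-resolved counts exist (populations under 2000 genotyped alleles
are ignored) and the overall MAF otherwise; absence from the reference
table sorts as rarest.  Intronic splice-region variants are kept to ±25 bp
from an exon boundary — covering the acceptor-region variants this analysis
targets — and deeper ones require an external splice-predictor flag, which
is consumed as an opaque annotation, never computed.  The recurrence
whitelist exempts named (gene, HGVS-c) alleles from the gate and tags them
`frequency-exceptional`: recurrent hypomorphic alleles slightly above a
hard 0.001 cutoff would otherwise be lost despite case-level evidence.
Compound-het phase is resolved against parental genotypes when a trio
exists; two variants from one parent demote the pair (a recessive candidate
requires trans); Mendelian inconsistencies annotate rather than drop a
candidate.  ACMG-style labels are carried as free text only.

## Haplotype sharing

Identity-by-state of rare alleles, not probabilistic IBD: markers are
compared by (position, allele); rsids are display metadata.  The shared
segment is the longest run of consecutive candidate markers (position-
ordered union of the families' cis sets) carried by every family, reported
by its outermost markers; the span is the distance between those boundary
marker positions — the convention that turns printed boundary coordinates
into the quoted span (26,933,928 − 26,535,625 = 398,303 ≈ 398 kb).  Adding
a family can only shrink or preserve the segment.  Pairwise segments are
reported alongside the global one and not adjudicated further: IBS sharing
is consistent with, but does not prove, common ancestry.

## Problem sizes and determinism

The bundled replicas run at the depths the analysis quotes: 400 + 1619
reads for the two-allele inclusion experiment, 100 reads per allele for the
skip-fraction experiment, 6 controls, 3 simulated families (~67 markers).
All randomness flows from explicit integer seeds (NumPy PCG64); zero-error
exact-mode outputs are fully deterministic, and fixed-seed FASTQ output is
byte-identical across runs.

## Known limitations

* No de-novo isoform discovery: reads matching no catalogued chain are
  `unclassified`, never invented.
* HGVS-p-lite only; no full HGVS normalization, no NMD prediction.
* Genome-frame classification through many short introns degrades under
  noise (see above).
* The error model is uncalibrated to any specific basecaller; accuracy
  bands quoted here are under independent per-base noise.
* Structural variants pass the VCF parser (symbolic alleles) but receive no
  SV-specific logic.
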