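# amplisplice

Allele-resolved quantification of cryptic splicing from long-read RT-PCR
amplicon sequencing, with the companion analyses of a rare-disease splicing
study: rare biallelic variant prioritization over the coenzyme-Q10
biosynthesis gene panel, cross-family shared-haplotype detection, and an
exact 2×2 association test.

## The problem

Intronic variants outside canonical splice sites (e.g. `c.682-7T>G`,
`c.468-25A>G`) can activate cryptic acceptors, noncanonical exons or exon
skipping.  Single-molecule sequencing of an RT-PCR amplicon gives one read
per transcript molecule, so mis-splicing can be *quantified per allele*: a
heterozygous exonic SNV tags each read with its haplotype of origin, and the
fraction of mis-spliced reads can be compared between the variant-bearing
allele and the trans allele (and against control samples' basal
mis-splicing).  This package implements that analysis for aligned long
reads, plus a simulator that generates the amplicon read sets, control
cohorts and phased family genotypes needed to exercise it (the motivating
patient data cannot be redistributed).

## What it computes

* **Junction chains** — each read's alignment gaps (D/N runs ≥ `min_gap`,
  default 20 bp) form its splicing fingerprint; reads are classified against
  an event catalogue (exon skip, alternate acceptor/donor, alternate-exon
  inclusion, intron retention) gap-for-gap within a boundary tolerance
  (default ±5 bp).
* **Allele calls and read-backed phasing** — the base aligned to a phasing
  SNV assigns each read to an allele; co-occurrence of calls at two linked
  SNVs yields a cis/trans verdict (default 4:1 concordant:discordant odds).
* **Quantification** — per-allele event fractions over classified reads,
  and a mean-depth inclusion metric: depth over the alternate-exon region
  divided by depth over a canonical anchor exon.
* **Exact association** — Fisher's exact test under the noncentral
  hypergeometric model with the conditional-MLE odds ratio
  (ψ solving E<sub>ψ</sub>[K] = k<sub>obs</sub>) and the exact CI from
  inverting one-sided conditional tail tests at (1−γ)/2 per side.
* **Prioritization** — panel restriction (13 CoQ10-pathway genes),
  popmax-aware MAF < 0.001 gate with a recurrence whitelist, consequence
  class filter, and pedigree-aware biallelic genotype detection
  (compound-het pairs demoted when both variants are on one parental
  haplotype).
* **Haplotype sharing** — rare (MAF < 0.1) SNVs in cis with a target
  variant within ±250 kb per family, intersected across families by
  identity-by-state; the shared segment is reported by its outermost
  markers and span.

## Worked example

```python
>>> from amplisplice.workflows import coq5_skip_analysis, case_population_association
>>> r = coq5_skip_analysis(seed=1)          # 100 reads/allele, zero error
>>> print(r.quant.to_text())
allele_id	event_id	read_count	fraction_pct
trans	canonical	96	96.00
trans	exon5_skip	4	4.00
variant	canonical	41	41.00
variant	exon45_skip	3	3.00
variant	exon5_skip	56	56.00
>>> r.verdict
'cis'
>>> f = case_population_association()        # [[3, 19], [411, 282353]]
>>> round(f.or_cmle, 2), round(f.ci_low, 2), round(f.ci_high, 2)
(108.44, 20.47, 370.45)
>>> f.p_two_sided
4.698998111554789e-06
```

The per-allele table shows exon-5 skipping on 56% of variant-allele reads
against 4% on the trans allele (basal mis-splicing), with exon-4–5 skipping
in a low fraction (3%); the two tag SNVs phase as cis.  The exact test says
the case-enriched allele is associated with disease at OR ≈ 108 with a wide
but clearly positive exact CI.

A command-line interface mirrors the library (`amplisplice simulate`,
`classify`, `quantify`, `fisher`, `coq10-flag`, `prioritize`, `haplotype`);
run `amplisplice --help`.

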