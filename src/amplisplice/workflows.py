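"""End-to-end analysis workflows over the synthetic study replicas.

Each workflow runs the full pipeline — simulate reads, align, extract
junction chains, classify against the event catalogue, call the phasing
SNV, quantify per allele — and returns the quantities a practitioner would
report.  They are the single source for the worked examples in the README,
the integration tests and the reproduction script.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import replicas
from .classify import (
    SNVSite,
    align_sim_reads,
    build_catalogue,
    call_alleles,
    classify_reads,
    phase_by_linked_snv,
)
from .gene_models import build_transcript
from .haplotype import (
    cis_set_from_phased_vcf,
    informative_snvs,
    shared_segment,
    window_around,
)
from .quantify import (
    FisherResult,
    InclusionResult,
    QuantTable,
    depth_inclusion,
    fisher_exact_2x2,
    per_allele_fractions,
)
from .simulate import ErrorModel, simulate_family_genotypes, simulate_reads


@dataclass
class InclusionAnalysis:
    inclusion: dict[str, InclusionResult]
    quant: QuantTable
    event_calls: pd.DataFrame
    allele_calls: pd.DataFrame
    truth: pd.DataFrame


def pdss1_inclusion_analysis(
    seed: int = 0,
    err: ErrorModel | None = None,
    a_reads: int = 400,
    g_reads: int = 1619,
) -> InclusionAnalysis:
    """Allele-resolved alternate-exon inclusion on the 11-exon replica.

    Simulates both alleles of the amplicon at their isoform mixtures, aligns
    every read to the unspliced locus (genome frame), classifies junction
    chains, calls the allele at the exonic tag SNV, and computes the
    mean-depth inclusion of the alternate-exon region against the canonical
    exon-6 anchor for each allele group.
    """
    model, events = replicas.pdss1_like_model()
    alleles, n_total = replicas.pdss1_allele_specs(a_reads, g_reads)
    err = err or ErrorModel.perfect(seed)
    reads, truth = simulate_reads(model, events, alleles, n_total, err)
    aligned = align_sim_reads(reads, model.sequence, model.chrom, ref_start=model.seq_offset)
    catalogue = build_catalogue(model, events, frame="genome")
    event_calls = classify_reads(aligned, catalogue)
    tx = build_transcript(model)
    tag_g = tx.to_genomic(replicas.PDSS1_TAG_POS)
    site = SNVSite(tag_g, "A", "G", name="c.589A>G-like")
    allele_calls = call_alleles(aligned, site)
    by_allele = {"A": [], "G": []}
    status_by_read = dict(zip(allele_calls.read_id, allele_calls.status))
    for read in aligned:
        status = status_by_read.get(read.read_id)
        if status == "ref":
            by_allele["A"].append(read)
        elif status == "alt":
            by_allele["G"].append(read)
    alt_region, anchor_region = replicas.pdss1_regions(model)
    inclusion = {
        r.allele_id: r
        for r in depth_inclusion(by_allele, alt_region, anchor_region)
    }
    quant = per_allele_fractions(
        event_calls, allele_calls, allele_names={"ref": "A", "alt": "G"}
    )
    return InclusionAnalysis(inclusion, quant, event_calls, allele_calls, truth)


@dataclass
class PhasedSkipAnalysis:
    quant: QuantTable
    verdict: str
    event_calls: pd.DataFrame
    allele_calls_a: pd.DataFrame
    allele_calls_b: pd.DataFrame
    truth: pd.DataFrame

    def skip_fraction(self, allele: str, event: str = "exon5_skip") -> float:
        return self.quant.fraction(allele, event)


def coq5_skip_analysis(
    seed: int = 0,
    err: ErrorModel | None = None,
    reads_per_allele: int = 100,
) -> PhasedSkipAnalysis:
    """Per-allele exon-skip fractions and cis/trans phasing on the 7-exon replica.

    Reads are aligned in transcript frame (reference = canonical spliced
    sequence), so exon skips appear as 89 / 196 bp deletion gaps.  Reads are
    phased to alleles at tag SNV A; the verdict comes from co-occurrence of
    calls at the two linked tag SNVs.
    """
    model, events = replicas.coq5_like_model()
    alleles, n_total = replicas.coq5_allele_specs(reads_per_allele)
    err = err or ErrorModel.perfect(seed)
    reads, truth = simulate_reads(model, events, alleles, n_total, err)
    tx = build_transcript(model)
    aligned = align_sim_reads(reads, tx.sequence, model.gene_id)
    catalogue = build_catalogue(model, events, frame="transcript")
    event_calls = classify_reads(aligned, catalogue)
    a_pos, a_ref, a_alt = replicas.COQ5_SITE_A
    b_pos, b_ref, b_alt = replicas.COQ5_SITE_B
    calls_a = call_alleles(aligned, SNVSite(a_pos, a_ref, a_alt, "siteA"))
    calls_b = call_alleles(aligned, SNVSite(b_pos, b_ref, b_alt, "siteB"))
    phase = phase_by_linked_snv(calls_a, calls_b)
    quant = per_allele_fractions(
        event_calls, calls_a, allele_names={"alt": "variant", "ref": "trans"}
    )
    return PhasedSkipAnalysis(
        quant, phase.verdict, event_calls, calls_a, calls_b, truth
    )


def case_population_association(conf: float = 0.95) -> FisherResult:
    """Exact association test on the reconstructed case/population table."""
    return fisher_exact_2x2(replicas.CASE_POPULATION_TABLE, conf=conf)


@dataclass
class HaplotypeAnalysis:
    segment: object  # HaplotypeSegment | None
    pairwise: pd.DataFrame
    truth_interval: tuple[int, int]


def shared_haplotype_analysis(
    seed: int = 0,
    n_families: int = 3,
    target: tuple = replicas.HAPLOTYPE_TARGET,
    shared_interval: tuple[int, int] = replicas.SHARED_INTERVAL,
) -> HaplotypeAnalysis:
    """Simulate carrier families and recover their shared haplotype segment."""
    families, markers = simulate_family_genotypes(
        n_families, target, shared_interval, seed=seed
    )
    window = window_around(target[1])
    informative = informative_snvs(markers, window)
    cis_sets = []
    with tempfile.TemporaryDirectory() as tmp:
        for fam in families:
            path = Path(tmp) / f"{fam.family_id}.vcf"
            fam.write_vcf(path)
            cis_sets.append(
                cis_set_from_phased_vcf(path, fam.family_id, target, informative)
            )
    segment, pairwise = shared_segment(cis_sets)
    return HaplotypeAnalysis(segment, pairwise, shared_interval)
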