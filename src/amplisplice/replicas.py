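"""Synthetic study-replica fixtures: toy loci, mixtures and a cohort table.

Everything in this module is synthetic.  The gene models are small invented
forward-strand loci whose *structure* mirrors the two amplicon experiments
the pipeline is built for — an 11-exon, 941-bp PDSS1-style amplicon with an
83-bp alternate noncanonical exon adjacent to a 142-bp canonical exon, and a
7-exon COQ5-style amplicon whose exon 4 (107 bp) and exon 5 (89 bp) can be
skipped singly or together (89 / 196 bp deletions) — while their sequences
are pseudorandom with fixed seeds.  The allele mixtures encode the published
per-allele isoform proportions (90.25% alternate-exon inclusion on 400
variant-allele reads; 56% / 4% / 3% skip fractions at 100 reads per allele),
and the cohort table re-enters the study's twelve-family genotype spectrum
with its printed population frequencies as a synthetic prioritization
fixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_models import GeneModel, SpliceEventSpec, build_transcript
from .prioritize import VariantRecord
from .simulate import AlleleSpec, TagSNV

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_NONSTOP_CODONS, size=n_codons))


def _random_bases(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _assemble_locus(
    exon_lengths: list[int],
    intron_lengths: list[int],
    transcript_seq: str,
    locus_start: int,
    rng: np.random.Generator,
    chrom: str,
    gene_id: str,
    cds_start: int,
    cds_end: int,
) -> GeneModel:
    exons = []
    pos = locus_start
    t_off = 0
    genome = []
    for i, length in enumerate(exon_lengths):
        exons.append((pos, pos + length - 1))
        genome.append(transcript_seq[t_off : t_off + length])
        t_off += length
        pos += length
        if i < len(intron_lengths):
            genome.append(_random_bases(intron_lengths[i], rng))
            pos += intron_lengths[i]
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand="+",
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        sequence="".join(genome),
        seq_offset=locus_start,
    )


# ---------------------------------------------------------------------------
# PDSS1-style replica: 941-bp 11-exon amplicon, 83-bp alternate exon,
# exonic tag SNV at transcript position 589 (ref A / alt G)

PDSS1_EXON_LENGTHS = [100, 90, 80, 100, 85, 142, 66, 70, 90, 60, 58]  # sum 941
PDSS1_TAG_POS = 589
PDSS1_ALT_EXON_LEN = 83
_PDSS1_SEED = 20220531


def pdss1_like_model() -> tuple[GeneModel, dict[str, SpliceEventSpec]]:
    """Toy 11-exon amplicon locus with an alternate exon adjacent to exon 6.

    The alternate noncanonical exon (83 bp) occupies the 3' end of intron 5,
    immediately upstream of canonical exon 6 (142 bp) — mirroring the
    adjacency of the alternate/canonical exon regions in the modelled
    experiment.  The phasing SNV site sits at transcript position 589
    (inside exon 6), exonic in both isoforms.
    """
    rng = np.random.default_rng(_PDSS1_SEED)
    cds_start, cds_end = 30, 929  # 900-base CDS
    t = list(_random_bases(941, rng))
    t[cds_start - 1 : cds_end] = list(_random_cds((cds_end - cds_start + 1) // 3, rng))
    t[cds_start - 1 : cds_start + 2] = list("ATG")
    t[cds_end - 3 : cds_end] = list("TAA")
    # codon covering the tag position gets a fixed non-stop codon with the
    # reference 'A' at transcript position 589
    codon_start = cds_start - 1 + 3 * ((PDSS1_TAG_POS - cds_start) // 3)
    t[codon_start : codon_start + 3] = list("CAT")
    assert t[PDSS1_TAG_POS - 1] == "A"
    transcript_seq = "".join(t)
    introns = [200, 200, 200, 200, 200 + PDSS1_ALT_EXON_LEN, 200, 200, 200, 200, 200]
    model = _assemble_locus(
        PDSS1_EXON_LENGTHS, introns, transcript_seq,
        locus_start=1000, rng=rng, chrom="toyA", gene_id="PDSS1_like",
        cds_start=cds_start, cds_end=cds_end,
    )
    # alternate exon: last 83 bases of intron 5, adjacent to exon 6
    exon6_start = model.exons[5][0]
    alt_interval = (exon6_start - PDSS1_ALT_EXON_LEN, exon6_start - 1)
    events = {
        "canonical": SpliceEventSpec("canonical", "canonical"),
        "alt_exon": SpliceEventSpec(
            "alt_exon", "alt_exon_inclusion", interval=alt_interval
        ),
    }
    return model, events


def pdss1_regions(model: GeneModel) -> tuple[tuple[int, int], tuple[int, int]]:
    """(alternate-exon region, canonical-exon-6 anchor region), genomic."""
    exon6 = model.exons[5]
    alt = (exon6[0] - PDSS1_ALT_EXON_LEN, exon6[0] - 1)
    return alt, exon6


def pdss1_allele_specs(
    a_reads: int = 400, g_reads: int = 1619
) -> tuple[list[AlleleSpec], int]:
    """Allele specs realizing the published per-allele inclusion proportions.

    The splice-variant allele carries the reference 'A' at the tag site and
    includes the alternate exon in 361/400 of its reads; the other allele
    carries 'G' with basal inclusion 159/1619.
    """
    total = a_reads + g_reads
    tag = (PDSS1_TAG_POS, "A", "G")
    a_spec = AlleleSpec(
        "A",
        [TagSNV(*tag, carried="ref")],
        {"alt_exon": 0.9025, "canonical": 1 - 0.9025},
        copy_fraction=a_reads / total,
    )
    g_spec = AlleleSpec(
        "G",
        [TagSNV(*tag, carried="alt")],
        {"alt_exon": 159 / 1619, "canonical": 1 - 159 / 1619},
        copy_fraction=g_reads / total,
    )
    return [a_spec, g_spec], total


# ---------------------------------------------------------------------------
# COQ5-style replica: 7-exon amplicon; exon 5 (89 bp) and exons 4–5 (196 bp)
# skipping; two linked tag SNVs in cis on the splice-variant allele

COQ5_EXON_LENGTHS = [120, 110, 100, 107, 89, 120, 100]  # sum 746
COQ5_SITE_A = (150, "C", "T")  # exon 2
COQ5_SITE_B = (700, "G", "A")  # exon 7
_COQ5_SEED = 20220532


def coq5_like_model() -> tuple[GeneModel, dict[str, SpliceEventSpec]]:
    """Toy 7-exon amplicon whose exon 4 (107 bp) / exon 5 (89 bp) can skip."""
    rng = np.random.default_rng(_COQ5_SEED)
    cds_start, cds_end = 10, 735
    t = list(_random_bases(746, rng))
    t[cds_start - 1 : cds_end] = list(_random_cds((cds_end - cds_start + 1) // 3, rng))
    t[cds_start - 1 : cds_start + 2] = list("ATG")
    t[cds_end - 3 : cds_end] = list("TAA")
    for pos, ref, _alt in (COQ5_SITE_A, COQ5_SITE_B):
        t[pos - 1] = ref
    transcript_seq = "".join(t)
    model = _assemble_locus(
        COQ5_EXON_LENGTHS, [150] * 6, transcript_seq,
        locus_start=500, rng=rng, chrom="toyB", gene_id="COQ5_like",
        cds_start=cds_start, cds_end=cds_end,
    )
    events = {
        "canonical": SpliceEventSpec("canonical", "canonical"),
        "exon5_skip": SpliceEventSpec("exon5_skip", "exon_skip", exons=(5,)),
        "exon45_skip": SpliceEventSpec("exon45_skip", "exon_skip", exons=(4, 5)),
    }
    return model, events


def coq5_allele_specs(reads_per_allele: int = 100) -> tuple[list[AlleleSpec], int]:
    """Variant-allele and trans-allele mixtures at the published proportions.

    Variant allele: 56% exon-5 skip, 3% exon-4–5 skip, remainder canonical;
    trans allele: 4% exon-5 skip.  Both tag SNVs ride the variant allele
    (they are in cis).
    """
    a_pos, a_ref, a_alt = COQ5_SITE_A
    b_pos, b_ref, b_alt = COQ5_SITE_B
    variant = AlleleSpec(
        "variant",
        [TagSNV(a_pos, a_ref, a_alt, "alt"), TagSNV(b_pos, b_ref, b_alt, "alt")],
        {"exon5_skip": 0.56, "exon45_skip": 0.03, "canonical": 0.41},
        copy_fraction=0.5,
    )
    trans = AlleleSpec(
        "trans",
        [TagSNV(a_pos, a_ref, a_alt, "ref"), TagSNV(b_pos, b_ref, b_alt, "ref")],
        {"exon5_skip": 0.04, "canonical": 0.96},
        copy_fraction=0.5,
    )
    return [variant, trans], 2 * reads_per_allele


# ---------------------------------------------------------------------------
# exact-test fixture

#: Synthetic reconstruction of the case/population allele-count table behind
#: the reported association of the recurrent missense allele with disease:
#: 3 variant vs 19 reference case alleles (11 genotyped individuals) against
#: 411 variant vs 282353 reference population alleles.  Back-calculated so
#: that the exact test reproduces the published OR/CI/p; not printed in the
#: study's main text.
CASE_POPULATION_TABLE = [[3, 19], [411, 282353]]


# ---------------------------------------------------------------------------
# haplotype-analysis defaults

HAPLOTYPE_TARGET = ("Chr10", 26_744_000, "A", "G")
SHARED_INTERVAL = (26_535_625, 26_933_928)
PAIRWISE_53_INTERVAL = (26_720_339, 26_933_928)


# ---------------------------------------------------------------------------
# twelve-family cohort fixture (synthetic): the study's genotype spectrum with
# its printed population-maximum frequencies, plus decoy variants that the
# cascade must remove

_AN = 1_000_000  # synthetic popmax denominators; only the ratio matters


def _pop(maf: float | None) -> dict[str, tuple[int, int]]:
    if maf is None:
        return {}
    return {"popmax": (round(maf * _AN), _AN)}


@dataclass
class CohortFixture:
    variants: list[VariantRecord]
    genotypes: dict[str, dict[tuple, str]]
    pedigree: pd.DataFrame
    whitelist: list[tuple[str, str]]


def cohort_fixture() -> CohortFixture:
    """Synthetic twelve-family cohort replaying the study genotype spectrum.

    Positions are invented; gene symbols, HGVS-c labels, consequence classes
    and population-maximum frequencies follow the published genotype table.
    Families 1, 3, 4 and 7 have genotyped parents (trio phase available);
    the rest are singletons.  Decoys: an off-panel gene pair, a rare
    synonymous variant, a too-common missense variant and a deep-intronic
    variant without a splice-predictor flag.
    """
    V = VariantRecord
    mk = {}

    def add(name, gene, pos, ref, alt, csq, maf, hgvs, **kw):
        mk[name] = V(
            chrom="toyChr", pos=pos, ref=ref, alt=alt, gene_id=gene,
            consequence=csq, pop_counts=_pop(maf), hgvs_c=hgvs, **kw
        )

    add("p368", "PDSS1", 101_000, "A", "G", "missense", None, "c.368A>G")
    add("p18", "PDSS1", 100_020, "G", "A", "lof", None, "c.18G>A")
    add("p232", "PDSS1", 100_900, "C", "A", "missense", None, "c.232C>A")
    add("p886", "PDSS1", 102_000, "G", "A", "missense", 0.00009239, "c.886G>A")
    add("p722", "PDSS1", 101_800, "A", "G", "splice_canonical", 0.000008799,
        "c.722-2A>G", intron_offset=-2)
    add("p589", "PDSS1", 101_500, "A", "G", "missense", 0.003499, "c.589A>G")
    add("p1118", "PDSS1", 102_500, "T", "TCTG", "inframe_indel", None,
        "c.1118_1120dup")
    add("p468", "PDSS1", 101_200, "A", "G", "splice_region_intronic", 0.00002641,
        "c.468-25A>G", intron_offset=-25)
    add("p893", "PDSS1", 102_100, "A", "AT", "lof", None, "c.893dup")
    add("q735", "COQ2", 201_000, "C", "G", "lof", None, "c.735C>G")
    add("q683", "COQ2", 200_900, "A", "G", "missense", 0.0002813, "c.683A>G")
    add("q338", "COQ2", 200_500, "GTAC", "G", "inframe_indel", None,
        "c.338_341delinsG")
    add("r692", "COQ4", 301_000, "G", "A", "missense", 0.0001148, "c.692G>A")
    add("r376", "COQ4", 300_500, "G", "A", "missense", 0.0003508, "c.376G>A")
    add("s933", "COQ5", 401_200, "TC", "T", "lof", 0.0000176, "c.933delC")
    add("s682", "COQ5", 400_900, "T", "G", "splice_region_intronic", 0.001434,
        "c.682-7T>G", intron_offset=-7)
    add("s367", "COQ5", 400_500, "C", "T", "missense", 0.00003266, "c.367C>T")
    # decoys
    add("ush", "USH2A", 900_000, "T", "C", "missense", None, "c.8555T>C")
    add("syn", "PDSS1", 101_050, "C", "T", "synonymous", None, "c.400C>T")
    add("common", "PDSS1", 101_060, "G", "T", "missense", 0.012, "c.410G>T")
    add("deep", "COQ2", 200_400, "G", "C", "splice_region_intronic", None,
        "c.300-80G>C", intron_offset=-80)

    variants = list(mk.values())
    fam_geno = {
        "F1": [("p368", "het"), ("p18", "het"), ("ush", "het")],
        "F2": [("p232", "het"), ("p886", "het"), ("syn", "het")],
        "F3": [("p722", "het"), ("p589", "het")],
        "F4": [("p1118", "hom_alt")],
        "F5": [("p468", "het"), ("p589", "het"), ("common", "het")],
        "F6": [("p893", "het"), ("p589", "het")],
        "F7": [("q735", "het"), ("q683", "het"), ("deep", "het")],
        "F8": [("q683", "het"), ("q338", "het")],
        "F9": [("q683", "hom_alt")],
        "F10": [("r692", "het"), ("r376", "het")],
        "F11": [("s933", "het"), ("s682", "het")],
        "F12": [("s367", "het"), ("s682", "het")],
    }
    genotypes: dict[str, dict[tuple, str]] = {}
    ped_rows = []
    trio_fams = {"F1": ("p368", "p18"), "F3": ("p589", "p722"),
                 "F4": ("p1118", "p1118"), "F7": ("q683", "q735")}
    for fam, items in fam_geno.items():
        proband = f"{fam}.P"
        genotypes[proband] = {mk[n].key: gt for n, gt in items}
        father, mother = "0", "0"
        if fam in trio_fams:
            father, mother = f"{fam}.F", f"{fam}.M"
            pat, mat = trio_fams[fam]
            genotypes[father] = {mk[pat].key: "het"}
            genotypes[mother] = {mk[mat].key: "het"}
            ped_rows.append((fam, father, "0", "0", "1", "1"))
            ped_rows.append((fam, mother, "0", "0", "2", "1"))
        ped_rows.append((fam, proband, father, mother, "0", "2"))
    pedigree = pd.DataFrame(
        ped_rows, columns=["family", "sample", "father", "mother", "sex", "phenotype"]
    )
    whitelist = [("PDSS1", "c.589A>G"), ("COQ5", "c.682-7T>G")]
    return CohortFixture(variants, genotypes, pedigree, whitelist)
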