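"""Rare biallelic candidate-genotype prioritization over a CoQ10 gene panel.

The cascade mirrors standard rare-disease practice for a recessive
hypothesis: restrict variants to the ubiquinone-biosynthesis gene panel,
annotate population frequency (overall and population-maximum), keep rare
protein-altering / splice-affecting variants, and call biallelic candidate
genotypes — homozygous rare variants, or two heterozygous variants in one
gene whose phase is resolved against parental genotypes where a pedigree
allows it (two variants on the same parental haplotype are demoted: a
recessive candidate requires *trans*).

A small recurrence whitelist lets specific variants bypass the frequency
gate: recurrent hypomorphic alleles (the situation of PDSS1 c.589A>G and
COQ5 c.682-7T>G, both slightly above a 0.001 MAF gate) would otherwise be
discarded despite strong case-level evidence.  Whitelisted survivors are
tagged ``frequency-exceptional``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

COQ10_PANEL = (
    "PDSS1", "PDSS2", "COQ2", "COQ3", "COQ4", "COQ5", "COQ6", "COQ7",
    "COQ8A", "COQ8B", "COQ9", "COQ10A", "COQ10B",
)

CONSEQUENCE_CLASSES = (
    "lof", "missense", "inframe_indel", "splice_canonical",
    "splice_region_intronic", "synonymous", "other",
)

DEFAULT_KEEP_CLASSES = frozenset(
    ("lof", "missense", "inframe_indel", "splice_canonical", "splice_region_intronic")
)


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    consequence: str
    allele_count: Optional[int] = None
    allele_number: Optional[int] = None
    pop_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    hgvs_c: str = ""
    intron_offset: Optional[int] = None  # HGVS-style signed offset for intronic variants
    splice_predictor_flag: bool = False  # external predictor annotation (opaque)
    annotations: dict[str, str] = field(default_factory=dict)
    tags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.consequence!r}")
        if (
            self.allele_count is not None
            and self.allele_number is not None
            and self.allele_count > self.allele_number
        ):
            raise ValueError("allele_count exceeds allele_number")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class FrequencyAnnotation:
    maf: Optional[float]  # overall; None when absent from the reference table
    popmax: Optional[float]
    popmax_population: Optional[str]

    @property
    def gate_frequency(self) -> Optional[float]:
        """Frequency used by the rarity gate: popmax when available, else overall."""
        return self.popmax if self.popmax is not None else self.maf

    def display_maf(self, sig: int = 4) -> str:
        if self.maf is None:
            return "-"
        return f"{self.maf:.{sig}g}"


def panel_restrict(
    variants: Sequence[VariantRecord], panel: Sequence[str] = COQ10_PANEL
) -> list[VariantRecord]:
    """Keep variants in panel genes, preserving input order."""
    panel_set = set(panel)
    return [v for v in variants if v.gene_id in panel_set]


def annotate_frequency(
    variant: VariantRecord, min_pop_an: int = 2000
) -> FrequencyAnnotation:
    """Overall MAF and popmax from the variant's allele-count annotations.

    Populations with fewer than ``min_pop_an`` genotyped alleles are excluded
    from popmax (tiny denominators make frequencies meaningless).  A variant
    with no nonzero allele number anywhere is treated as absent from the
    reference — i.e. as rare as possible.
    """
    maf = None
    if variant.allele_number:
        maf = variant.allele_count / variant.allele_number
    popmax = popmax_pop = None
    for pop, (ac, an) in sorted(variant.pop_counts.items()):
        if an >= min_pop_an and an > 0:
            f = ac / an
            if popmax is None or f > popmax:
                popmax, popmax_pop = f, pop
    return FrequencyAnnotation(maf, popmax, popmax_pop)


def filter_rare(
    variants: Sequence[VariantRecord],
    maf_threshold: float = 0.001,
    keep_classes: frozenset = DEFAULT_KEEP_CLASSES,
    recurrence_whitelist: Sequence[tuple[str, str]] = (),
    intron_window: int = 25,
    min_pop_an: int = 2000,
) -> list[VariantRecord]:
    """Rarity and consequence-class filter.

    A variant survives iff its consequence class is kept AND its gate
    frequency (popmax when population counts exist, overall otherwise) is
    absent or below ``maf_threshold`` — unless it is on the recurrence
    whitelist (matched as ``(gene_id, hgvs_c)``), in which case it bypasses
    the frequency gate and is tagged ``frequency-exceptional``.  Intronic
    splice-region variants deeper than ``intron_window`` bp from an exon
    boundary additionally require an external splice-predictor flag.
    """
    whitelist = set(recurrence_whitelist)
    out = []
    for v in variants:
        if v.consequence not in keep_classes:
            continue
        if v.consequence == "splice_region_intronic":
            deep = v.intron_offset is not None and abs(v.intron_offset) > intron_window
            if deep and not v.splice_predictor_flag:
                continue
        freq = annotate_frequency(v, min_pop_an=min_pop_an)
        gate = freq.gate_frequency
        if gate is None or gate < maf_threshold:
            out.append(v)
        elif (v.gene_id, v.hgvs_c) in whitelist:
            if "frequency-exceptional" not in v.tags:
                v.tags.append("frequency-exceptional")
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# biallelic genotype detection


@dataclass
class CandidateGenotype:
    sample: str
    gene_id: str
    variants: tuple[tuple[str, int, str, str], ...]  # 1 (hom) or 2 (compound het)
    zygosity: str  # hom | compound_het
    phase: str  # trans | cis | unknown
    notes: list[str] = field(default_factory=list)

    @property
    def is_candidate(self) -> bool:
        """Cis pairs are demoted: a recessive genotype requires trans."""
        return not (self.zygosity == "compound_het" and self.phase == "cis")


def read_ped(path) -> pd.DataFrame:
    """Read a PED-like table (family, sample, father, mother, sex, phenotype)."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["family", "sample", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    return df


def _parental_phase(
    v1_key, v2_key, sample: str, genotypes: Mapping[str, Mapping[tuple, str]],
    pedigree: Optional[pd.DataFrame],
) -> tuple[str, list[str]]:
    """Resolve compound-het phase from parental genotypes, if a trio exists."""
    notes: list[str] = []
    if pedigree is None:
        return "unknown", notes
    row = pedigree[pedigree["sample"] == sample]
    if row.empty:
        return "unknown", notes
    father, mother = row.iloc[0]["father"], row.iloc[0]["mother"]
    carriers = {}
    for key in (v1_key, v2_key):
        has = set()
        for parent in (father, mother):
            if parent in (None, "0", "", "nan") or parent not in genotypes:
                continue
            if genotypes[parent].get(key, "hom_ref") in ("het", "hom_alt"):
                has.add(parent)
        carriers[key] = has
        if not has and father in genotypes and mother in genotypes:
            notes.append(f"variant {key} carried by neither genotyped parent")
    c1, c2 = carriers[v1_key], carriers[v2_key]
    if not (c1 and c2):
        return "unknown", notes
    if c1 == c2 and len(c1) == 1:
        return "cis", notes
    if c1.isdisjoint(c2):
        return "trans", notes
    return "unknown", notes


def detect_biallelic(
    variants: Sequence[VariantRecord],
    genotypes: Mapping[str, Mapping[tuple, str]],
    pedigree: Optional[pd.DataFrame] = None,
    samples: Optional[Sequence[str]] = None,
) -> list[CandidateGenotype]:
    """Detect biallelic candidate genotypes per sample.

    ``genotypes`` maps sample -> {variant key -> genotype} with genotypes in
    {hom_ref, het, hom_alt, missing}.  A homozygous surviving variant is a
    ``hom`` candidate; two or more heterozygous surviving variants in one
    gene form ``compound_het`` candidates whose phase is resolved against
    parental genotypes when the pedigree allows (both variants from one
    parent -> cis, demoted).  Mendelian inconsistencies are annotated, not
    fatal.
    """
    by_key = {v.key: v for v in variants}
    out: list[CandidateGenotype] = []
    for sample in samples or sorted(genotypes):
        gts = genotypes.get(sample, {})
        by_gene: dict[str, list] = {}
        for key, gt in gts.items():
            v = by_key.get(key)
            if v is None or gt in ("hom_ref", "missing"):
                continue
            by_gene.setdefault(v.gene_id, []).append((key, gt))
        for gene, items in sorted(by_gene.items()):
            homs = [k for k, gt in items if gt == "hom_alt"]
            hets = [k for k, gt in items if gt == "het"]
            for k in homs:
                notes = []
                v = by_key[k]
                if "frequency-exceptional" in v.tags:
                    notes.append("frequency-exceptional allele")
                out.append(
                    CandidateGenotype(sample, gene, (k,), "hom", "trans", notes)
                )
            if len(hets) >= 2:
                # pair het variants; in practice a gene carries at most a few
                for i in range(len(hets)):
                    for j in range(i + 1, len(hets)):
                        k1, k2 = hets[i], hets[j]
                        phase, notes = _parental_phase(
                            k1, k2, sample, genotypes, pedigree
                        )
                        for k in (k1, k2):
                            if by_key[k].consequence == "lof":
                                notes.append(f"counter-allele or allele {k} is LOF")
                                break
                        out.append(
                            CandidateGenotype(
                                sample, gene, (k1, k2), "compound_het", phase, notes
                            )
                        )
    return out


def candidates_to_frame(candidates: Sequence[CandidateGenotype]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "sample": c.sample,
                "gene_id": c.gene_id,
                "zygosity": c.zygosity,
                "phase": c.phase,
                "candidate": c.is_candidate,
                "variants": ";".join(
                    f"{ch}:{p}:{r}>{a}" for ch, p, r, a in c.variants
                ),
                "notes": "|".join(c.notes),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF intake


GT_CODES = {(0, 0): "hom_ref", (0, 1): "het", (1, 0): "het", (1, 1): "hom_alt"}


def read_vcf(path) -> tuple[list[VariantRecord], dict[str, dict[tuple, str]]]:
    """Read a multi-sample VCF with GENE/CSQ/AC/AN INFO annotations.

    Expected INFO keys: ``GENE``, ``CSQ`` (one of the consequence classes),
    optional ``AC``/``AN`` (overall), ``POP_AC``/``POP_AN`` as
    comma-joined ``pop:count`` pairs, optional ``HGVSC``, ``INTRON_OFFSET``
    and ``SPLICE_PRED`` flags.  Symbolic (structural) alternate alleles pass
    the parser with consequence class ``other``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    genotypes: dict[str, dict[tuple, str]] = {s: {} for s in samples}
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        info = dict(rec.INFO)
        pop_counts = {}
        if info.get("POP_AC") and info.get("POP_AN"):
            acs = dict(p.split(":") for p in str(info["POP_AC"]).split(","))
            ans = dict(p.split(":") for p in str(info["POP_AN"]).split(","))
            pop_counts = {
                pop: (int(acs[pop]), int(ans[pop])) for pop in acs if pop in ans
            }
        csq = str(info.get("CSQ", "other"))
        if alt.startswith("<"):
            csq = "other"
        v = VariantRecord(
            chrom=rec.CHROM,
            pos=rec.POS,
            ref=rec.REF,
            alt=alt,
            gene_id=str(info.get("GENE", "")),
            consequence=csq,
            allele_count=int(info["AC"]) if "AC" in info else None,
            allele_number=int(info["AN"]) if "AN" in info else None,
            pop_counts=pop_counts,
            hgvs_c=str(info.get("HGVSC", "")),
            intron_offset=int(info["INTRON_OFFSET"]) if "INTRON_OFFSET" in info else None,
            splice_predictor_flag=bool(info.get("SPLICE_PRED", False)),
        )
        variants.append(v)
        for s, gt in zip(samples, rec.genotypes):
            alleles = tuple(x for x in gt[:-1])
            if -1 in alleles:
                genotypes[s][v.key] = "missing"
            else:
                genotypes[s][v.key] = GT_CODES.get(tuple(alleles), "het")
    return variants, genotypes
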