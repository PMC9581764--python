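"""Synthetic amplicon read sets and phased family genotypes with truth tables.

Every downstream stage of the pipeline (alignment, junction-chain
classification, allele calling, quantification, haplotype analysis) is
exercised against data produced here, because the study system — RT-PCR
amplicons of a blood transcript, sequenced on a nanopore device, from
patients whose sequencing data cannot be shared — has no public read sets.

The generator emits full-length primer-to-primer amplicon reads: each read is
the complete modified-transcript sequence of one splice isoform, with
allele-tagging SNV bases substituted, and (optionally) nanopore-like
substitution/insertion/deletion noise applied.  A truth table records the
(allele, isoform) label of every read.  ``realize_counts`` converts mixture
fractions to integer read counts either exactly (largest-remainder rounding,
so that printed study percentages like 90.25% of 400 reads are representable
without rounding slack) or multinomially.

``simulate_family_genotypes`` builds phased single-carrier VCFs for several
families whose carrier haplotypes are identical by descent across a chosen
genomic interval: inside the interval all carrier haplotypes carry the same
rare-marker alleles; outside, rare alleles are drawn independently per
family.  This is the truth model for the shared ancestral-haplotype search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .gene_models import (
    EventSpecError,
    GeneModel,
    SpliceEventSpec,
    TranscriptModel,
    apply_splice_event,
    build_transcript,
)


class UntaggableIsoformError(EventSpecError):
    """A tag SNV position is not exonic in an isoform that must carry it."""


@dataclass(frozen=True)
class TagSNV:
    """An allele-tagging SNV at a canonical-transcript position.

    ``carried`` says which base this allele writes into its reads: ``"ref"``
    or ``"alt"``.
    """

    t_pos: int
    ref: str
    alt: str
    carried: str = "alt"

    @property
    def base(self) -> str:
        return self.alt if self.carried == "alt" else self.ref


@dataclass
class AlleleSpec:
    allele_id: str
    tag_snvs: list[TagSNV]
    isoform_mixture: dict[str, float]
    copy_fraction: float = 1.0

    def __post_init__(self):
        total = sum(self.isoform_mixture.values())
        if any(f < 0 for f in self.isoform_mixture.values()):
            raise ValueError("mixture fractions must be nonnegative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {total}, expected 1")


@dataclass
class ErrorModel:
    substitution_rate: float = 0.03
    insertion_rate: float = 0.01
    deletion_rate: float = 0.02
    quality_mean: int = 20
    seed: int = 0

    def __post_init__(self):
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0 <= r <= 0.2:
                raise ValueError("error rates must lie in [0, 0.2]")

    @classmethod
    def perfect(cls, seed: int = 0) -> "ErrorModel":
        return cls(0.0, 0.0, 0.0, quality_mean=40, seed=seed)


@dataclass
class SimRead:
    read_id: str
    allele_id: str
    event_id: str
    sequence: str
    quality: int


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def largest_remainder(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Apportion ``n`` into integer counts by largest-remainder rounding.

    Ties in the fractional remainders are broken by lexical key order, so the
    result is fully deterministic.
    """
    keys = sorted(fractions)
    raw = {k: n * fractions[k] for k in keys}
    counts = {k: math.floor(raw[k]) for k in keys}
    short = n - sum(counts.values())
    by_rem = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def realize_counts(
    n_reads: int,
    alleles: Sequence[AlleleSpec],
    mode: str = "exact",
    seed: int = 0,
) -> dict[tuple[str, str], int]:
    """Per-(allele, event) integer read counts for a requested mixture."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if mode not in ("exact", "multinomial"):
        raise ValueError(f"unknown mode {mode!r}")
    copy_total = sum(a.copy_fraction for a in alleles)
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], int] = {}
    if mode == "exact":
        per_allele = largest_remainder(
            n_reads, {a.allele_id: a.copy_fraction / copy_total for a in alleles}
        )
        for a in alleles:
            sub = largest_remainder(per_allele[a.allele_id], a.isoform_mixture)
            for ev, c in sub.items():
                out[(a.allele_id, ev)] = c
    else:
        cells = [
            (a.allele_id, ev, a.copy_fraction / copy_total * f)
            for a in alleles
            for ev, f in sorted(a.isoform_mixture.items())
        ]
        draws = rng.multinomial(n_reads, [p for _, _, p in cells])
        for (aid, ev, _), c in zip(cells, draws):
            out[(aid, ev)] = int(c)
    return out


def _isoform_templates(
    model: GeneModel,
    events: Mapping[str, SpliceEventSpec],
    alleles: Sequence[AlleleSpec],
) -> dict[tuple[str, str], str]:
    """Template sequence per (allele, event), with tag bases substituted.

    A tag SNV whose canonical-transcript position is not exonic in a
    requested isoform makes that (allele, isoform) pair untaggable and is
    rejected, since reads from it could not be assigned to the allele.
    """
    canonical = build_transcript(model)
    templates: dict[tuple[str, str], str] = {}
    for allele in alleles:
        for event_id in allele.isoform_mixture:
            if event_id not in events:
                raise EventSpecError(f"event {event_id!r} missing from catalogue")
            iso, _ = apply_splice_event(canonical, events[event_id])
            seq = list(iso.sequence)
            for tag in allele.tag_snvs:
                g = canonical.to_genomic(tag.t_pos)
                cmap = iso.to_transcript(g)
                if cmap.kind != "exonic":
                    raise UntaggableIsoformError(
                        f"tag SNV at canonical position {tag.t_pos} is not exonic "
                        f"in isoform {event_id!r} required by allele "
                        f"{allele.allele_id!r}"
                    )
                if seq[cmap.t_pos - 1].upper() != tag.ref.upper():
                    raise EventSpecError(
                        f"reference base at transcript position {tag.t_pos} is "
                        f"{seq[cmap.t_pos - 1]!r}, tag declares {tag.ref!r}"
                    )
                seq[cmap.t_pos - 1] = tag.base
            templates[(allele.allele_id, event_id)] = "".join(seq)
    return templates


def _apply_errors(template: str, err: ErrorModel, rng: np.random.Generator) -> str:
    if err.substitution_rate == err.insertion_rate == err.deletion_rate == 0:
        return template
    arr = np.frombuffer(template.encode(), dtype="S1")
    n = len(arr)
    u = rng.random(n)
    keep = u >= err.deletion_rate
    sub = (u >= err.deletion_rate) & (u < err.deletion_rate + err.substitution_rate)
    out = arr.copy()
    if sub.any():
        # substitute with a uniformly random *different* base
        shifts = rng.integers(1, 4, size=int(sub.sum()))
        idx_map = {b: i for i, b in enumerate(_BASES)}
        orig_idx = np.array([idx_map.get(b, 0) for b in arr[sub]])
        out[sub] = _BASES[(orig_idx + shifts) % 4]
    ins_mask = rng.random(n) < err.insertion_rate
    if ins_mask.any() or not keep.all():
        pieces = []
        ins_bases = _BASES[rng.integers(0, 4, size=int(ins_mask.sum()))]
        ins_iter = iter(ins_bases)
        for i in range(n):
            if keep[i]:
                pieces.append(out[i])
            if ins_mask[i]:
                pieces.append(next(ins_iter))
        return b"".join(pieces).decode()
    return out.tobytes().decode()


def simulate_reads(
    model: GeneModel,
    events: Mapping[str, SpliceEventSpec],
    alleles: Sequence[AlleleSpec],
    n_reads: int,
    err: Optional[ErrorModel] = None,
    mode: str = "exact",
    read_prefix: str = "read",
) -> tuple[list[SimRead], pd.DataFrame]:
    """Emit amplicon reads plus a complete per-read truth table.

    Deterministic for a fixed ``err.seed``; with all error rates zero every
    read equals its isoform template (with allele tag bases substituted).
    """
    err = err or ErrorModel.perfect()
    templates = _isoform_templates(model, events, alleles)
    counts = realize_counts(n_reads, alleles, mode=mode, seed=err.seed)
    rng = np.random.default_rng(err.seed)
    reads: list[SimRead] = []
    rows = []
    i = 0
    for (allele_id, event_id) in sorted(counts):
        template = templates[(allele_id, event_id)]
        for _ in range(counts[(allele_id, event_id)]):
            seq = _apply_errors(template, err, rng)
            rid = f"{read_prefix}{i:06d}"
            reads.append(SimRead(rid, allele_id, event_id, seq, err.quality_mean))
            rows.append((rid, allele_id, event_id, "+"))
            i += 1
    truth = pd.DataFrame(rows, columns=["read_id", "allele_id", "event_id", "strand"])
    return reads, truth


def write_fastq(reads: Iterable[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            q = chr(33 + r.quality) * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{q}\n")


def simulate_control_cohort(
    model: GeneModel,
    events: Mapping[str, SpliceEventSpec],
    inclusion_event: str,
    k_samples: int = 6,
    n_reads: int = 2000,
    band: tuple[float, float] = (0.065, 0.1014),
    err: Optional[ErrorModel] = None,
    mode: str = "exact",
) -> list[dict]:
    """Simulate control samples with basal mis-splicing.

    Each control draws its inclusion fraction uniformly from ``band`` (the
    default band matches the 6.5–10.14% basal inclusion seen in control RNA)
    and emits an untagged single-allele read set at that mixture.
    """
    if k_samples <= 0:
        raise ValueError("k_samples must be positive")
    lo, hi = band
    if not (0 <= lo <= hi <= 1):
        raise ValueError(f"invalid inclusion band {band}")
    err = err or ErrorModel.perfect()
    rng = np.random.default_rng(err.seed)
    out = []
    for k in range(k_samples):
        f = float(rng.uniform(lo, hi)) if hi > lo else lo
        mixture = {inclusion_event: f, "canonical": 1 - f} if f > 0 else {"canonical": 1.0}
        spec = AlleleSpec(f"control{k + 1}", [], mixture)
        sample_err = ErrorModel(
            err.substitution_rate, err.insertion_rate, err.deletion_rate,
            err.quality_mean, seed=err.seed + 1000 + k,
        )
        reads, truth = simulate_reads(
            model, events, [spec], n_reads, sample_err, mode=mode,
            read_prefix=f"c{k + 1}_",
        )
        out.append(
            {"sample": f"control{k + 1}", "inclusion_fraction": f,
             "reads": reads, "truth": truth}
        )
    return out


# ---------------------------------------------------------------------------
# phased family genotypes around a target variant


@dataclass(frozen=True)
class Marker:
    chrom: str
    pos: int
    rsid: str
    ref: str
    alt: str
    maf: float


@dataclass
class FamilySim:
    family_id: str
    target: tuple[str, int, str, str]  # chrom, pos, ref, alt
    markers: list[Marker]
    # per marker: (carrier_hap_has_alt, other_hap_has_alt)
    haplotypes: dict[int, tuple[bool, bool]]
    truth_cis: set[int]  # positions carrying the rare allele on the carrier hap

    def vcf_text(self, sample: Optional[str] = None) -> str:
        """Render the family's carrier as a phased single-sample VCF 4.2."""
        sample = sample or f"{self.family_id}_proband"
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            f"##contig=<ID={self.target[0]}>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
        ]
        chrom, tpos, tref, talt = self.target
        records = []
        for m in self.markers:
            a, b = self.haplotypes[m.pos]
            gt = f"{int(a)}|{int(b)}"
            records.append((m.pos, m.rsid, m.ref, m.alt, gt))
        records.append((tpos, "target", tref, talt, "1|0"))
        for pos, rsid, ref, alt, gt in sorted(records):
            lines.append(
                f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}"
            )
        return "\n".join(lines) + "\n"

    def write_vcf(self, path, sample: Optional[str] = None) -> None:
        Path(path).write_text(self.vcf_text(sample))


def frequency_table(markers: Sequence[Marker]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.chrom, m.pos, m.rsid, m.ref, m.alt, m.maf) for m in markers],
        columns=["chrom", "pos", "rsid", "ref", "alt", "maf"],
    )


def simulate_family_genotypes(
    n_families: int,
    target: tuple[str, int, str, str],
    shared_interval: tuple[int, int],
    snv_density: float = 1 / 15000,
    window: int = 250_000,
    maf_rare: tuple[float, float] = (0.005, 0.09),
    common_fraction: float = 0.3,
    seed: int = 0,
    boundary_rsids: tuple[str, str] = ("rs187101868", "rs111256658"),
) -> tuple[list[FamilySim], list[Marker]]:
    """Simulate phased carrier genotypes for families sharing a haplotype.

    One global marker panel is laid down across ``target pos +/- window``
    with average spacing ``1/snv_density``; markers at exactly the two ends
    of ``shared_interval`` are always present.  Rare-marker alleles
    (MAF < 0.1) inside ``shared_interval`` are carried identically on every
    family's carrier haplotype (identity by descent); outside the interval
    each family's haplotypes draw alleles independently at the marker's
    population frequency.  The first rare marker beyond each boundary is
    forced onto exactly one family's carrier haplotype so that, in truth,
    the cross-family shared segment ends exactly at the interval boundaries.
    """
    if snv_density <= 0:
        raise ValueError("snv_density must be positive")
    lo, hi = shared_interval
    if lo >= hi:
        raise ValueError("shared interval is empty")
    chrom, tpos, tref, talt = target
    rng = np.random.default_rng(seed)
    span_lo, span_hi = tpos - window, tpos + window
    spacing = int(round(1 / snv_density))
    positions = set(range(span_lo, span_hi + 1, spacing))
    positions.update((lo, hi))
    positions.discard(tpos)
    positions = sorted(positions)
    markers = []
    for i, pos in enumerate(positions):
        if pos == lo:
            rsid, maf = boundary_rsids[0], float(rng.uniform(*maf_rare))
        elif pos == hi:
            rsid, maf = boundary_rsids[1], float(rng.uniform(*maf_rare))
        else:
            rsid = f"sim{i:04d}"
            if rng.random() < common_fraction:
                maf = float(rng.uniform(0.15, 0.45))
            else:
                maf = float(rng.uniform(*maf_rare))
        ref, alt = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")][i % 4]
        markers.append(Marker(chrom, pos, rsid, ref, alt, maf))
    rare_inside = [m for m in markers if m.maf < 0.1 and lo <= m.pos <= hi]
    rare_outside = [m for m in markers if m.maf < 0.1 and not lo <= m.pos <= hi]
    below = max((m for m in rare_outside if m.pos < lo), key=lambda m: m.pos, default=None)
    above = min((m for m in rare_outside if m.pos > hi), key=lambda m: m.pos, default=None)
    families = []
    for f in range(n_families):
        fam = f"family{f + 1}"
        haplotypes: dict[int, tuple[bool, bool]] = {}
        truth_cis: set[int] = set()
        for m in markers:
            if m in rare_inside:
                carrier = True  # identical by descent across families
            elif below is not None and m.pos == below.pos:
                carrier = f == 0
            elif above is not None and m.pos == above.pos:
                carrier = f == min(1, n_families - 1)
            else:
                carrier = bool(rng.random() < m.maf)
            other = bool(rng.random() < m.maf)
            haplotypes[m.pos] = (carrier, other)
            if carrier and m.maf < 0.1:
                truth_cis.add(m.pos)
        families.append(
            FamilySim(fam, target, markers, haplotypes, truth_cis)
        )
    return families, markers
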