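"""Cross-family shared ancestral-haplotype detection by identity-by-state.

For each family carrying a recurrent variant, the set of rare SNVs phased
*in cis* with the target allele within a flanking window is extracted from
the family's phased genotypes; the cross-family intersection of those sets,
taken over the ordered candidate-marker panel, is the shared haplotype
segment, reported by its outermost shared markers and their spanned
distance.  The comparison is identity-by-state of rare alleles (matched on
position and allele; rsids are display metadata only) — no probabilistic
IBD model is involved, so a reported segment is *consistent with* but does
not prove shared ancestry.

Rare markers (MAF below 0.1 by default) are the informative ones: a common
allele shared across families carries little evidence of co-ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .simulate import Marker


@dataclass
class CisSet:
    family_id: str
    target: tuple[str, int, str, str]
    markers: dict[int, str]  # position -> cis (rare) allele
    rsids: dict[int, str] = field(default_factory=dict)

    def __contains__(self, item: tuple[int, str]) -> bool:
        pos, allele = item
        return self.markers.get(pos) == allele


@dataclass
class HaplotypeSegment:
    chrom: str
    start: tuple[int, str]  # (position, rsid)
    end: tuple[int, str]
    n_markers: int
    families: tuple[str, ...]

    @property
    def span_bp(self) -> int:
        return self.end[0] - self.start[0]

    @property
    def span_kb(self) -> int:
        return round(self.span_bp / 1000)


def informative_snvs(
    markers: Sequence[Marker],
    window: tuple[int, int],
    maf_max: float = 0.1,
) -> list[Marker]:
    """Markers rare enough to be informative for phasing, within the window."""
    lo, hi = window
    return [m for m in markers if m.maf < maf_max and lo <= m.pos <= hi]


def window_around(center: int, window_kb: float = 250.0) -> tuple[int, int]:
    half = int(round(window_kb * 1000))
    return center - half, center + half


def cis_set_from_phased_vcf(
    vcf_path,
    family_id: str,
    target: tuple[str, int, str, str],
    markers: Sequence[Marker],
) -> CisSet:
    """Markers whose rare (alt) allele lies on the target's haplotype.

    The target variant must be heterozygous and phased in the carrier; the
    cis set collects every informative marker whose alt allele sits on the
    same phased haplotype as the target's alt allele.
    """
    from cyvcf2 import VCF

    chrom, tpos, tref, talt = target
    marker_by_pos = {m.pos: m for m in markers}
    vcf = VCF(str(vcf_path))
    if len(vcf.samples) != 1:
        raise ValueError("cis-set extraction expects a single-carrier VCF")
    target_hap = None
    records = []
    for rec in vcf:
        if rec.CHROM != chrom:
            continue
        gt = rec.genotypes[0]
        alleles, phased = tuple(gt[:-1]), bool(gt[-1])
        if rec.POS == tpos and rec.REF == tref and (rec.ALT or [None])[0] == talt:
            if sorted(alleles) != [0, 1]:
                raise ValueError("target variant is not heterozygous in the carrier")
            if not phased:
                raise ValueError(
                    "target variant is unphased; run trio phasing or read-backed "
                    "phasing first"
                )
            target_hap = alleles.index(1)
        elif rec.POS in marker_by_pos:
            records.append((rec.POS, alleles, phased, (rec.ALT or ["."])[0]))
    if target_hap is None:
        raise ValueError(f"target variant {target} absent from {vcf_path}")
    cis: dict[int, str] = {}
    rsids: dict[int, str] = {}
    for pos, alleles, phased, alt in records:
        if not phased or 1 not in alleles:
            continue
        if alleles[target_hap] == 1:
            m = marker_by_pos[pos]
            cis[pos] = alt
            rsids[pos] = m.rsid
    return CisSet(family_id, target, cis, rsids)


def _run_segments(
    cis_sets: Sequence[CisSet], panel: Sequence[tuple[int, str]]
) -> list[list[tuple[int, str]]]:
    """Maximal runs of consecutive panel markers present in every cis set."""
    runs, cur = [], []
    for pos, allele in panel:
        if all((pos, allele) in cs for cs in cis_sets):
            cur.append((pos, allele))
        else:
            if cur:
                runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return runs


def shared_segment(
    cis_sets: Sequence[CisSet],
) -> tuple[Optional[HaplotypeSegment], pd.DataFrame]:
    """Shared segment across all families, plus the pairwise sharing table.

    The candidate-marker panel is the position-ordered union of all cis
    sets; the global segment is the longest run of consecutive panel
    markers carried (same allele) by every family, reported by its
    outermost markers.  ``span_bp`` is the distance between the boundary
    marker positions.  An empty intersection yields ``None`` with the
    pairwise report still emitted.  A single cis set passes through as its
    own span (with a note column in the report).
    """
    if not cis_sets:
        raise ValueError("at least one cis set is required")
    chrom = cis_sets[0].target[0]
    union: dict[int, str] = {}
    rsids: dict[int, str] = {}
    for cs in cis_sets:
        union.update(cs.markers)
        rsids.update(cs.rsids)
    panel = sorted(union.items())

    def best_run(sets) -> Optional[HaplotypeSegment]:
        runs = _run_segments(sets, panel)
        if not runs:
            return None
        run = max(runs, key=lambda r: (len(r), r[-1][0] - r[0][0]))
        (s_pos, _), (e_pos, _) = run[0], run[-1]
        return HaplotypeSegment(
            chrom,
            (s_pos, rsids.get(s_pos, "")),
            (e_pos, rsids.get(e_pos, "")),
            len(run),
            tuple(cs.family_id for cs in sets),
        )

    global_seg = best_run(cis_sets)
    rows = []
    for a, b in combinations(cis_sets, 2):
        seg = best_run([a, b])
        rows.append(
            {
                "family_a": a.family_id,
                "family_b": b.family_id,
                "start": seg.start[0] if seg else None,
                "end": seg.end[0] if seg else None,
                "span_bp": seg.span_bp if seg else 0,
                "n_markers": seg.n_markers if seg else 0,
            }
        )
    if len(cis_sets) == 1:
        rows.append(
            {
                "family_a": cis_sets[0].family_id,
                "family_b": cis_sets[0].family_id,
                "start": global_seg.start[0] if global_seg else None,
                "end": global_seg.end[0] if global_seg else None,
                "span_bp": global_seg.span_bp if global_seg else 0,
                "n_markers": global_seg.n_markers if global_seg else 0,
            }
        )
    pairwise = pd.DataFrame(rows)
    return global_seg, pairwise
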