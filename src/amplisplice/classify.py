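"""Junction-chain extraction, splice-isoform classification and read-backed phasing.

Each aligned long read implies a *junction chain*: the ordered set of
reference-coordinate gaps (deletion or intron ``N`` operations of at least
``min_gap`` bases) in its alignment — the read's splicing fingerprint.
Classification matches a read's chain gap-for-gap against the expected chain
of each catalogued isoform within a per-boundary tolerance; the per-read base
at a phasing SNV assigns the read to an allele; and co-occurrence of calls at
two linked SNVs yields a cis/trans verdict with per-read haplotype labels.

Two alignment frames are supported and the classifier is agnostic to which
one produced the chains:

* *transcript* frame — reads aligned to a spliced isoform sequence; splice
  differences appear as ``D`` runs.
* *genome* frame — reads aligned to the unspliced locus; introns and skipped
  exons appear as large gaps (``N`` in spliced aligners, ``D`` from the
  built-in aligner; both are treated identically).

The built-in aligner is an affine-gap pairwise aligner (Biopython's C
implementation): the gap-open penalty is what keeps an 89-bp splice
deletion as one gap instead of the fragmented runs a pure edit-distance
alignment produces through coincidental matches inside the gap.  It is
exact and deterministic for full-length amplicons; minimap2 can be invoked
as a subprocess instead when available.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .gene_models import GeneModel, SpliceEventSpec, TranscriptModel, apply_splice_event, build_transcript
from .simulate import SimRead

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
REF_CONSUMING = set("MDN=X")
QUERY_CONSUMING = set("MIS=X")


@dataclass
class AlignedRead:
    """A minimal SAM-like alignment record (1-based alignment start)."""

    read_id: str
    reference_name: str
    start: int
    cigar: list[tuple[str, int]]
    sequence: str
    qualities: Optional[list[int]] = None
    mapped: bool = True
    secondary: bool = False
    supplementary: bool = False

    def query_length_from_cigar(self) -> int:
        return sum(n for op, n in self.cigar if op in QUERY_CONSUMING)

    def reference_end(self) -> int:
        """1-based inclusive end of the aligned reference span."""
        return self.start + sum(n for op, n in self.cigar if op in REF_CONSUMING) - 1

    def reference_blocks(self) -> list[tuple[int, int]]:
        """Aligned (match) reference intervals, 1-based inclusive; gaps excluded."""
        blocks = []
        ref = self.start
        cur_start = None
        for op, n in self.cigar:
            if op in "M=X":
                if cur_start is None:
                    cur_start = ref
                ref += n
            elif op in "DN":
                if cur_start is not None:
                    blocks.append((cur_start, ref - 1))
                    cur_start = None
                ref += n
            # I/S/H/P consume no reference
        if cur_start is not None:
            blocks.append((cur_start, ref - 1))
        return blocks


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]


@dataclass
class JunctionChain:
    gaps: list[tuple[int, int]]  # (first skipped ref base, first ref base after)

    @property
    def gapped_length(self) -> int:
        return sum(e - s for s, e in self.gaps)

    def __len__(self) -> int:
        return len(self.gaps)


def extract_junction_chain(read: AlignedRead, min_gap: int = 20) -> Optional[JunctionChain]:
    """Turn D/N cigar runs of at least ``min_gap`` bases into reference gaps.

    Smaller deletions are treated as alignment noise; symmetrically, two
    gaps separated by an aligned bridge shorter than ``min_gap`` are merged
    into one (base errors inside a long splice gap routinely produce such
    coincidental micro-bridges).  Unmapped reads yield ``None`` (a skip
    signal, not an exception).
    """
    if not read.mapped:
        return None
    gaps: list[tuple[int, int]] = []
    ref = read.start
    for op, n in read.cigar:
        if op in "DN":
            if n >= min_gap:
                if gaps and ref - gaps[-1][1] < min_gap:
                    gaps[-1] = (gaps[-1][0], ref + n)
                else:
                    gaps.append((ref, ref + n))
            ref += n
        elif op in REF_CONSUMING:
            ref += n
    return JunctionChain(gaps)


@dataclass
class EventCall:
    read_id: str
    event: str  # event_id | "canonical" | "unclassified"
    deviation: Optional[int]  # total boundary deviation in bp, None if unclassified


def classify_chain(
    chain: JunctionChain,
    catalogue: Mapping[str, list[tuple[int, int]]],
    tol: int = 5,
) -> tuple[str, Optional[int]]:
    """Match a junction chain against the catalogue of expected chains.

    An event matches when it has the same number of gaps and every boundary
    agrees within ``tol`` bp.  Among matches the smallest total boundary
    deviation wins; exact ties keep catalogue order.  No match returns
    ``("unclassified", None)``.
    """
    if not catalogue:
        raise ValueError("empty event catalogue")
    best: tuple[int, int, str] = None  # (deviation, order, event_id)
    for order, (event_id, expected) in enumerate(catalogue.items()):
        if len(expected) != len(chain.gaps):
            continue
        dev = 0
        ok = True
        for (s, e), (xs, xe) in zip(chain.gaps, expected):
            if abs(s - xs) > tol or abs(e - xe) > tol:
                ok = False
                break
            dev += abs(s - xs) + abs(e - xe)
        if ok and (best is None or (dev, order) < best[:2]):
            best = (dev, order, event_id)
    if best is None:
        return "unclassified", None
    return best[2], best[0]


def classify_reads(
    reads: Iterable[AlignedRead],
    catalogue: Mapping[str, list[tuple[int, int]]],
    min_gap: int = 20,
    tol: int = 5,
) -> pd.DataFrame:
    """Per-read event calls for all primary mapped reads."""
    rows = []
    for read in reads:
        if not read.mapped or read.secondary or read.supplementary:
            continue
        chain = extract_junction_chain(read, min_gap=min_gap)
        event, dev = classify_chain(chain, catalogue, tol=tol)
        rows.append((read.read_id, event, dev))
    return pd.DataFrame(rows, columns=["read_id", "event", "deviation"])


def build_catalogue(
    model: GeneModel,
    events: Mapping[str, SpliceEventSpec],
    frame: str = "transcript",
    reference_event: Optional[str] = None,
) -> dict[str, list[tuple[int, int]]]:
    """Expected junction chain per event, in the chosen alignment frame.

    ``transcript`` frame: chains are expressed in coordinates of the
    reference isoform (default the canonical transcript; pass
    ``reference_event`` to use another isoform, e.g. one containing an
    alternate exon so that every catalogued isoform is a subsequence of the
    reference).  ``genome`` frame: chains are the intron/skip gaps on the
    unspliced locus.
    """
    canonical = build_transcript(model)
    isoforms = {eid: apply_splice_event(canonical, ev)[0] for eid, ev in events.items()}
    if frame == "genome":
        out = {}
        for eid, iso in isoforms.items():
            # merge adjacent/overlapping segments: an alternate exon abutting
            # a canonical exon forms one contiguous aligned block
            merged: list[list[int]] = []
            for s, e in sorted(iso.exons):
                if merged and s <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[eid] = [
                (e1 + 1, s2) for (_, e1), (s2, _) in zip(merged, merged[1:])
            ]
        return out
    if frame != "transcript":
        raise ValueError(f"unknown frame {frame!r}")
    ref_iso = isoforms[reference_event] if reference_event else canonical
    ref_positions: list[int] = []
    for s, e in sorted(ref_iso.exons, reverse=ref_iso.strand == "-"):
        rng = range(s, e + 1) if ref_iso.strand == "+" else range(e, s - 1, -1)
        ref_positions.extend(rng)
    out = {}
    for eid, iso in isoforms.items():
        present = set()
        for s, e in iso.exons:
            present.update(range(s, e + 1))
        extra = present.difference(ref_positions)
        if extra:
            raise ValueError(
                f"isoform {eid!r} contains segments absent from the transcript-frame "
                "reference; choose a reference isoform that contains every catalogued "
                "segment or use the genome frame"
            )
        gaps = []
        run_start = None
        for i, g in enumerate(ref_positions, 1):
            if g not in present:
                if run_start is None:
                    run_start = i
            elif run_start is not None:
                gaps.append((run_start, i))
                run_start = None
        if run_start is not None:
            gaps.append((run_start, len(ref_positions) + 1))
        out[eid] = gaps
    return out


# ---------------------------------------------------------------------------
# alignment


def _make_affine_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    # near-flat gap extension: a splice-length gap (tens to hundreds of bp)
    # must cost little more than opening it, or the optimal path trades real
    # introns for mismatch-ridden alignment of the read tail
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -0.05
    # the reference may extend beyond the amplicon span: its overhangs are free
    try:
        aligner.end_deletion_score = 0
    except AttributeError:  # Biopython < 1.85 name
        aligner.query_end_gap_score = 0
    return aligner


def align_read_affine(
    read_id: str,
    sequence: str,
    reference: str,
    reference_name: str = "ref",
    quality: Optional[int] = None,
    aligner=None,
    ref_start: int = 1,
) -> AlignedRead:
    """Align one read against a reference with affine gap penalties.

    Returns a SAM-style alignment record; splice-length deletions come out
    as single ``D`` runs.  ``ref_start`` is the coordinate of the first
    reference base (use the locus offset to report genomic coordinates).
    """
    aligner = aligner or _make_affine_aligner()
    aln = aligner.align(reference, sequence)[0]
    ref_blocks, query_blocks = aln.aligned
    cigar: list[tuple[str, int]] = []
    start = int(ref_blocks[0][0]) + ref_start
    if query_blocks[0][0] > 0:
        cigar.append(("S", int(query_blocks[0][0])))
    prev_r = prev_q = None
    for (rs, re_), (qs, qe) in zip(ref_blocks, query_blocks):
        if prev_r is not None:
            if rs > prev_r:
                cigar.append(("D", int(rs - prev_r)))
            if qs > prev_q:
                cigar.append(("I", int(qs - prev_q)))
        cigar.append(("M", int(re_ - rs)))
        prev_r, prev_q = int(re_), int(qe)
    if prev_q < len(sequence):
        cigar.append(("S", len(sequence) - prev_q))
    quals = [quality] * len(sequence) if quality is not None else None
    return AlignedRead(read_id, reference_name, start, cigar, sequence, quals)


def align_sim_reads(
    reads: Sequence[SimRead], reference: str, reference_name: str = "ref",
    ref_start: int = 1,
) -> list[AlignedRead]:
    aligner = _make_affine_aligner()
    return [
        align_read_affine(
            r.read_id, r.sequence, reference, reference_name, r.quality, aligner,
            ref_start=ref_start,
        )
        for r in reads
    ]


def align_fastq_minimap2(
    fastq_path, reference_fasta, preset: str = "map-ont"
) -> list[AlignedRead]:
    """Align a FASTQ with a minimap2 subprocess and load the resulting SAM."""
    if shutil.which("minimap2") is None:
        raise RuntimeError("minimap2 not found on PATH")
    with tempfile.NamedTemporaryFile(suffix=".sam", delete=False) as tmp:
        sam_path = tmp.name
    try:
        subprocess.run(
            ["minimap2", "-a", "-x", preset, str(reference_fasta), str(fastq_path)],
            check=True, stdout=open(sam_path, "w"), stderr=subprocess.DEVNULL,
        )
        return load_sam(sam_path)
    finally:
        Path(sam_path).unlink(missing_ok=True)


def load_sam(path) -> list[AlignedRead]:
    """Load primary mapped alignments from a SAM/BAM file via pysam."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            out.append(
                AlignedRead(
                    read_id=aln.query_name,
                    reference_name=aln.reference_name or "",
                    start=aln.reference_start + 1,
                    cigar=parse_cigar(aln.cigarstring or ""),
                    sequence=aln.query_sequence or "",
                    qualities=list(aln.query_qualities) if aln.query_qualities is not None else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# allele calling and phasing


@dataclass(frozen=True)
class SNVSite:
    ref_pos: int  # 1-based position on the alignment reference
    ref: str
    alt: str
    name: str = ""


@dataclass
class AlleleCall:
    read_id: str
    status: str  # ref | alt | other | missing
    base: Optional[str]
    quality: Optional[int]


def call_allele(read: AlignedRead, site: SNVSite, min_baseq: int = 7) -> AlleleCall:
    """Call the read's base at a phasing SNV via a CIGAR walk.

    Insertions elsewhere in the read do not shift the call; a deletion
    spanning the site, a soft-clipped/unaligned site, or a base below
    ``min_baseq`` yields ``missing``.
    """
    if not read.mapped:
        return AlleleCall(read.read_id, "missing", None, None)
    ref = read.start
    query = 0
    base = None
    qual = None
    if not (read.start <= site.ref_pos <= read.reference_end()):
        return AlleleCall(read.read_id, "missing", None, None)
    for op, n in read.cigar:
        consumes_ref = op in REF_CONSUMING
        consumes_query = op in QUERY_CONSUMING
        if consumes_ref and ref <= site.ref_pos < ref + n:
            if op in "M=X":
                q_idx = query + (site.ref_pos - ref)
                base = read.sequence[q_idx]
                if read.qualities is not None:
                    qual = read.qualities[q_idx]
            break  # D/N over the site -> missing
        if consumes_ref:
            ref += n
        if consumes_query:
            query += n
    if base is None:
        return AlleleCall(read.read_id, "missing", None, qual)
    if qual is not None and qual < min_baseq:
        return AlleleCall(read.read_id, "missing", base, qual)
    b = base.upper()
    if b == site.ref.upper():
        status = "ref"
    elif b == site.alt.upper():
        status = "alt"
    else:
        status = "other"
    return AlleleCall(read.read_id, status, base, qual)


def call_alleles(
    reads: Iterable[AlignedRead], site: SNVSite, min_baseq: int = 7
) -> pd.DataFrame:
    rows = []
    for read in reads:
        if read.secondary or read.supplementary:
            continue
        c = call_allele(read, site, min_baseq=min_baseq)
        rows.append((c.read_id, c.status, c.base, c.quality))
    return pd.DataFrame(rows, columns=["read_id", "status", "base", "quality"])


@dataclass
class PhaseResult:
    table: np.ndarray  # rows: site-A ref/alt, cols: site-B ref/alt
    verdict: str  # cis | trans | ambiguous
    labels: pd.DataFrame  # read_id, haplotype in {A_ref_side, A_alt_side, None}
    n_excluded: int  # reads missing/other at either site


def phase_by_linked_snv(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    min_reads: int = 20,
    odds_threshold: float = 4.0,
) -> PhaseResult:
    """Phase two SNVs from per-read co-occurrence of their allele calls.

    ``cis`` when concordant pairs (refA·refB + altA·altB) outnumber
    discordant pairs by at least ``odds_threshold``; ``trans`` for the
    reverse; ``ambiguous`` otherwise or when fewer than ``min_reads``
    doubly-informative reads exist.  Reads missing a call at either site are
    excluded from the table but counted in ``n_excluded``.
    """
    merged = calls_a.merge(calls_b, on="read_id", suffixes=("_a", "_b"))
    informative = merged[
        merged.status_a.isin(["ref", "alt"]) & merged.status_b.isin(["ref", "alt"])
    ]
    n_excluded = len(merged) - len(informative)
    table = np.zeros((2, 2), dtype=int)
    for (sa, sb), group in informative.groupby(["status_a", "status_b"]):
        table[int(sa == "alt"), int(sb == "alt")] = len(group)
    concordant = int(table[0, 0] + table[1, 1])
    discordant = int(table[0, 1] + table[1, 0])
    if len(informative) < min_reads:
        warnings.warn(
            f"only {len(informative)} doubly-informative reads (< {min_reads}); "
            "phase is ambiguous"
        )
        verdict = "ambiguous"
    elif concordant >= odds_threshold * max(discordant, 1) and concordant > discordant:
        verdict = "cis"
    elif discordant >= odds_threshold * max(concordant, 1) and discordant > concordant:
        verdict = "trans"
    else:
        verdict = "ambiguous"
    # per-read haplotype labels keyed to the site-A allele; a read whose two
    # calls contradict the verdict is a suspected miscall and stays unlabelled
    def _b_to_a(status_b: str) -> str:
        if verdict == "cis":
            return status_b
        return "ref" if status_b == "alt" else "alt"

    def label(row) -> Optional[str]:
        a_ok = row.status_a in ("ref", "alt")
        b_ok = row.status_b in ("ref", "alt")
        if a_ok and b_ok and verdict in ("cis", "trans"):
            implied = _b_to_a(row.status_b)
            return f"A_{row.status_a}_side" if implied == row.status_a else None
        if a_ok:
            return f"A_{row.status_a}_side"
        if b_ok and verdict in ("cis", "trans"):
            return f"A_{_b_to_a(row.status_b)}_side"
        return None

    labels = pd.DataFrame(
        {"read_id": merged.read_id, "haplotype": merged.apply(label, axis=1)}
    )
    return PhaseResult(table, verdict, labels, n_excluded)
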