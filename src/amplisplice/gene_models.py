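"""Transcript models, splice-event application and protein-consequence annotation.

A :class:`GeneModel` describes one transcript of a gene as an ordered list of
exons on a genomic contig, together with the CDS boundaries in transcript
space and (optionally) the reference nucleotide sequence of the locus.
Splice events (exon skipping, alternate acceptor/donor usage, inclusion of a
noncanonical exon, intron retention) are applied at the exon-structure level
and yield a modified transcript plus the net length change; the protein-level
consequence of a modification is annotated by translating the original and
modified coding sequences and comparing them.

Coordinate conventions
----------------------
* Genomic coordinates are 1-based and inclusive (VCF/HGVS convention).
* Transcript coordinates are 1-based from the transcription start.
* Exons are stored in transcription order: ascending genomic position on the
  ``+`` strand, descending on the ``-`` strand.

The HGVS protein notation emitted here is a deliberately small subset
("HGVS-p-lite"): ``p.(XaaN_YaaMdel)``, ``p.(XaaN*)`` and
``p.(XaaNYyyfs*K)``.  Deletions are left-aligned against the original
protein; no 3'-rule repositioning is attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqUtils import seq3


class StructuralModelError(ValueError):
    """The exon structure of a gene model is inconsistent."""


class EventSpecError(ValueError):
    """A splice event references structure absent from the gene model."""


class ConsequenceUnavailableError(ValueError):
    """Protein consequence requested on a coordinate-only (sequence-less) model."""


EVENT_KINDS = (
    "canonical",
    "exon_skip",
    "alt_acceptor",
    "alt_donor",
    "alt_exon_inclusion",
    "intron_retention",
)


@dataclass(frozen=True)
class SpliceEventSpec:
    """A catalogued mis-splicing event.

    Parameters are interpreted per ``kind``:

    ``exon_skip``
        ``exons``: 1-based exon indices (transcription order) removed.
    ``alt_acceptor`` / ``alt_donor``
        ``exon``: affected exon index; ``offset``: signed shift of the splice
        site in the transcription direction.  A positive acceptor offset
        moves the acceptor downstream and trims the exon (the study's
        "alternate splice acceptor site 14 bp downstream" is ``offset=+14``);
        a positive donor offset extends the exon into the intron.
    ``alt_exon_inclusion``
        ``interval``: genomic (start, end) of the noncanonical exon, which
        must not overlap catalogued exons.
    ``intron_retention``
        ``intron``: 1-based index of the retained intron (between exon i and
        exon i+1).
    """

    event_id: str
    kind: str
    exons: tuple[int, ...] = ()
    exon: Optional[int] = None
    offset: int = 0
    interval: Optional[tuple[int, int]] = None
    intron: Optional[int] = None

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise EventSpecError(f"unknown event kind {self.kind!r}")
        if self.kind in ("alt_acceptor", "alt_donor") and self.offset == 0:
            raise EventSpecError("alt acceptor/donor offset must be nonzero")


@dataclass(frozen=True)
class ProteinConsequence:
    category: str  # no_change | inframe_deletion | frameshift | stop_gain
    first_affected_codon: Optional[int] = None
    hgvs_p: str = ""
    deleted_codons: Optional[int] = None
    fs_stop_offset: Optional[int] = None


@dataclass
class GeneModel:
    """One transcript of a gene as ordered exons on a genomic contig."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    sequence: Optional[str] = None
    seq_offset: int = 1  # genomic coordinate of sequence[0]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.strand not in "+-":
            raise StructuralModelError(f"strand must be + or -, got {self.strand!r}")
        for s, e in self.exons:
            if s > e:
                raise StructuralModelError(f"exon interval ({s}, {e}) reversed")
        ordered = self.exons if self.strand == "+" else self.exons[::-1]
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise StructuralModelError(
                    "exons overlap or are not sorted in transcription order"
                )
        spliced = sum(e - s + 1 for s, e in self.exons)
        if not (1 <= self.cds_start <= self.cds_end <= spliced):
            raise StructuralModelError(
                f"CDS [{self.cds_start}, {self.cds_end}] outside spliced length {spliced}"
            )
        if self.sequence is not None:
            lo, hi = self.span
            if lo < self.seq_offset or hi > self.seq_offset + len(self.sequence) - 1:
                raise StructuralModelError("exon intervals fall outside provided sequence")

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    def genomic_slice(self, start: int, end: int) -> str:
        """Forward-strand genomic sequence of [start, end], 1-based inclusive."""
        if self.sequence is None:
            raise ConsequenceUnavailableError(
                f"gene model {self.gene_id} carries no sequence"
            )
        return self.sequence[start - self.seq_offset : end - self.seq_offset + 1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Introns in transcription order as genomic (start, end)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return out


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CoordinateMap:
    """Result of mapping a genomic position into transcript space."""

    kind: str  # "exonic" | "intronic"
    t_pos: int  # exonic: the transcript coordinate; intronic: the anchor exon edge
    offset: int = 0  # intronic HGVS-style signed offset (e.g. -7), 0 when exonic

    @property
    def cds_label(self) -> str:
        return f"{self.t_pos}" if self.kind == "exonic" else f"{self.t_pos}{self.offset:+d}"


@dataclass
class TranscriptModel:
    """A spliced transcript: sequence, exon-offset table and junction chain."""

    model: GeneModel
    exons: list[tuple[int, int]]  # transcription order, genomic coords
    offsets: list[int]  # transcript coordinate of each exon's first base
    junctions: list[tuple[int, int]]  # (donor, acceptor) genomic coordinates
    sequence: Optional[str]
    cds_start: int
    cds_end: int

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def gene_id(self) -> str:
        return self.model.gene_id

    @property
    def strand(self) -> str:
        return self.model.strand

    def cds_sequence(self) -> str:
        if self.sequence is None:
            raise ConsequenceUnavailableError("coordinate-only transcript model")
        return self.sequence[self.cds_start - 1 : self.cds_end]

    def genomic_segments(self) -> list[tuple[int, int]]:
        """Exonic genomic intervals, a convenience alias."""
        return list(self.exons)

    # -- coordinate mapping ------------------------------------------------

    def to_transcript(self, pos: int) -> CoordinateMap:
        """Map a genomic position to transcript space (``map_coordinate``).

        Exonic positions return the exact transcript coordinate; intronic
        positions return the nearest exon edge in transcript space with an
        HGVS-style signed offset (negative upstream of an acceptor, positive
        downstream of a donor; ties go to the donor side).
        """
        lo, hi = self.model.span
        if not (lo <= pos <= hi):
            raise ValueError(f"position {pos} outside locus span [{lo}, {hi}]")
        plus = self.strand == "+"
        for (s, e), off in zip(self.exons, self.offsets):
            if s <= pos <= e:
                t = off + (pos - s if plus else e - pos)
                return CoordinateMap("exonic", t)
        # intronic: locate the flanking exon pair in transcription order
        for i, ((s1, e1), (s2, e2)) in enumerate(zip(self.exons, self.exons[1:])):
            if plus:
                inside = e1 < pos < s2
                d_donor = pos - e1
                d_accept = s2 - pos
            else:
                inside = e2 < pos < s1
                d_donor = s1 - pos
                d_accept = pos - e2
            if inside:
                donor_t = self.offsets[i] + (e1 - s1 if plus else s1 - e1) * 0 + (
                    self.exons[i][1] - self.exons[i][0]
                )
                acceptor_t = self.offsets[i + 1]
                if d_donor <= d_accept:
                    return CoordinateMap("intronic", donor_t, +d_donor)
                return CoordinateMap("intronic", acceptor_t, -d_accept)
        raise ValueError(f"position {pos} not locatable in transcript")

    def to_genomic(self, t_pos: int) -> int:
        """Inverse of :meth:`to_transcript` for exonic transcript coordinates."""
        if not (1 <= t_pos <= self.spliced_length):
            raise ValueError(f"transcript position {t_pos} out of range")
        plus = self.strand == "+"
        for (s, e), off in zip(self.exons, self.offsets):
            length = e - s + 1
            if off <= t_pos < off + length:
                return s + (t_pos - off) if plus else e - (t_pos - off)
        raise AssertionError("unreachable")


def build_transcript(model: GeneModel) -> TranscriptModel:
    """Splice a gene model into a transcript.

    Returns the spliced sequence (reverse-complemented for ``-`` strand
    models), the cumulative exon-offset table and the (donor, acceptor)
    junction chain in genomic coordinates.
    """
    model.validate()
    offsets = []
    pos = 1
    for s, e in model.exons:
        offsets.append(pos)
        pos += e - s + 1
    junctions = []
    plus = model.strand == "+"
    for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
        donor = e1 if plus else s1
        acceptor = s2 if plus else e2
        junctions.append((donor, acceptor))
    seq = None
    if model.sequence is not None:
        parts = []
        for s, e in model.exons:
            chunk = model.genomic_slice(s, e)
            parts.append(chunk if plus else reverse_complement(chunk))
        seq = "".join(parts)
    return TranscriptModel(
        model=model,
        exons=list(model.exons),
        offsets=offsets,
        junctions=junctions,
        sequence=seq,
        cds_start=model.cds_start,
        cds_end=model.cds_end,
    )


def map_coordinate(transcript: TranscriptModel, pos: int) -> CoordinateMap:
    """Functional alias for :meth:`TranscriptModel.to_transcript`."""
    return transcript.to_transcript(pos)


# ---------------------------------------------------------------------------
# splice-event application


def _modified_exons(model: GeneModel, event: SpliceEventSpec) -> list[tuple[int, int]]:
    exons = list(model.exons)
    n = len(exons)
    plus = model.strand == "+"
    kind = event.kind
    if kind == "canonical":
        return exons
    if kind == "exon_skip":
        if not event.exons:
            raise EventSpecError("exon_skip requires exon indices")
        bad = [i for i in event.exons if not 1 <= i <= n]
        if bad:
            raise EventSpecError(f"exon indices {bad} absent from {n}-exon model")
        return [ex for i, ex in enumerate(exons, 1) if i not in set(event.exons)]
    if kind in ("alt_acceptor", "alt_donor"):
        i = event.exon
        if i is None or not 1 <= i <= n:
            raise EventSpecError(f"exon index {i} absent from {n}-exon model")
        s, e = exons[i - 1]
        off = event.offset
        if kind == "alt_acceptor":
            # shift the 5' (acceptor) edge downstream (+) or upstream (-)
            s, e = (s + off, e) if plus else (s, e - off)
        else:
            # shift the 3' (donor) edge downstream (+) or upstream (-)
            s, e = (s, e + off) if plus else (s - off, e)
        if s > e:
            raise EventSpecError("splice-site offset collapses the exon")
        exons[i - 1] = (s, e)
        return exons
    if kind == "alt_exon_inclusion":
        if event.interval is None:
            raise EventSpecError("alt_exon_inclusion requires a genomic interval")
        a, b = event.interval
        if a > b:
            raise EventSpecError("alternate-exon interval reversed")
        for s, e in exons:
            if a <= e and s <= b:
                raise EventSpecError("alternate exon overlaps a catalogued exon")
        exons.append((a, b))
        exons.sort(key=lambda x: x[0], reverse=not plus)
        return exons
    if kind == "intron_retention":
        i = event.intron
        if i is None or not 1 <= i <= n - 1:
            raise EventSpecError(f"intron index {i} absent ({n - 1} introns)")
        s1, e1 = exons[i - 1]
        s2, e2 = exons[i]
        merged = (min(s1, s2), max(e1, e2))
        return exons[: i - 1] + [merged] + exons[i + 1 :]
    raise EventSpecError(f"unknown event kind {kind!r}")


def apply_splice_event(
    transcript: TranscriptModel, event: SpliceEventSpec
) -> tuple[TranscriptModel, int]:
    """Apply a splice event and return the modified transcript and length delta.

    The modified transcript's CDS start stays anchored to the genomic base of
    the original CDS start (events removing that base are rejected); the CDS
    end is provisionally extended to the transcript end — downstream
    consequence annotation translates to the first in-frame stop.
    """
    model = transcript.model
    new_exons = _modified_exons(model, event)
    if not new_exons:
        raise EventSpecError("event removes every exon")
    cds_start_g = transcript.to_genomic(transcript.cds_start)
    modified_model = GeneModel(
        gene_id=model.gene_id,
        chrom=model.chrom,
        strand=model.strand,
        exons=new_exons,
        cds_start=1,  # provisional; fixed below
        cds_end=sum(e - s + 1 for s, e in new_exons),
        sequence=model.sequence,
        seq_offset=model.seq_offset,
    )
    modified = build_transcript(modified_model)
    if event.kind != "canonical":
        cmap = modified.to_transcript(cds_start_g)
        if cmap.kind != "exonic":
            raise EventSpecError("event removes the CDS start codon anchor")
        modified.cds_start = cmap.t_pos
        modified.model.cds_start = cmap.t_pos
    else:
        modified.cds_start = transcript.cds_start
        modified.cds_end = transcript.cds_end
        modified.model.cds_start = transcript.cds_start
        modified.model.cds_end = transcript.cds_end
    delta = modified.spliced_length - transcript.spliced_length
    return modified, delta


# ---------------------------------------------------------------------------
# protein consequence


def _translate(cds: str) -> str:
    """Translate up to and including the first stop ('*'); standard table only."""
    prot = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3].upper()
        if codon in standard_dna_table.stop_codons:
            prot.append("*")
            break
        prot.append(str(Seq(codon).translate()))
    return "".join(prot)


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def annotate_consequence(
    original: TranscriptModel, modified: TranscriptModel
) -> ProteinConsequence:
    """Annotate the protein-level consequence of a transcript modification.

    Both transcripts must carry sequence and share the CDS start anchor.  The
    original CDS must begin with ATG.  The modified protein is obtained by
    translating from the anchored CDS start to the first stop; categories:

    * identical protein -> ``no_change``
    * first altered codon is a stop -> ``stop_gain`` (``p.(XaaN*)``)
    * net length change a multiple of 3, no premature stop ->
      ``inframe_deletion`` with ``deleted_codons = |delta| / 3``
      (``p.(XaaN_YaaMdel)``, left-aligned)
    * otherwise -> ``frameshift`` with ``fs_stop_offset`` counting codons
      from the first altered residue to the new stop (``p.(XaaNYyyfs*K)``)
    """
    if original.sequence is None or modified.sequence is None:
        raise ConsequenceUnavailableError("consequence requires transcript sequence")
    orig_cds = original.cds_sequence()
    if not orig_cds.upper().startswith("ATG"):
        raise ConsequenceUnavailableError("non-ATG CDS start unsupported")
    if len(orig_cds) % 3:
        raise ConsequenceUnavailableError("original CDS length not a codon multiple")
    # translate both from the anchored CDS start to the first in-frame stop so
    # that identical transcripts always compare equal
    p_orig = _translate(original.sequence[original.cds_start - 1 :])
    p_mod = _translate(modified.sequence[modified.cds_start - 1 :])
    if p_mod == p_orig:
        return ProteinConsequence("no_change")
    delta = modified.spliced_length - original.spliced_length
    k = next(
        (i for i, (a, b) in enumerate(zip(p_orig, p_mod)) if a != b),
        min(len(p_orig), len(p_mod)),
    )
    n = k + 1
    if delta % 3 == 0:
        # in frame: the modified protein ends at the *expected* stop unless a
        # premature one arose at the modification junction
        d = abs(delta) // 3
        expected_len = len(p_orig) + delta // 3  # both strings carry their stop
        premature = "*" in p_mod and len(p_mod) < expected_len
        if premature:
            stop_i = p_mod.index("*")
            xxx = _aa3(p_orig[stop_i]) if stop_i < len(p_orig) else "Ter"
            return ProteinConsequence("stop_gain", stop_i + 1, f"p.({xxx}{stop_i + 1}*)")
        if d == 0:
            # delta-zero junction substitutions are outside HGVS-p-lite
            return ProteinConsequence("no_change")
        if delta < 0:
            last = min(k + d, len(p_orig))
            hgvs = f"p.({_aa3(p_orig[k])}{n}_{_aa3(p_orig[last - 1])}{last}del)"
        else:
            hgvs = f"p.({_aa3(p_orig[k])}{n}ins{d})"
        return ProteinConsequence("inframe_deletion", n, hgvs, deleted_codons=d)
    if k < len(p_mod) and p_mod[k] == "*":
        # frame disruption whose first altered codon is already a stop
        return ProteinConsequence(
            "stop_gain", n, f"p.({_aa3(p_orig[k]) if k < len(p_orig) else 'Ter'}{n}*)"
        )
    stop = p_mod.find("*", k)
    fs_off = stop - k + 1 if stop >= 0 else None
    yyy = _aa3(p_mod[k]) if k < len(p_mod) else "Ter"
    xxx = _aa3(p_orig[k]) if k < len(p_orig) else "Ter"
    tail = f"fs*{fs_off}" if fs_off is not None else "fs*?"
    return ProteinConsequence(
        "frameshift", n, f"p.({xxx}{n}{yyy}{tail})", fs_stop_offset=fs_off
    )


# ---------------------------------------------------------------------------
# I/O: gene-model TSV (+ optional locus FASTA) and BED12

TSV_COLUMNS = ["gene_id", "chrom", "strand", "exon_index", "start", "end"]


def write_gene_model_tsv(model: GeneModel, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(TSV_COLUMNS + ["cds_start", "cds_end"])
        for i, (s, e) in enumerate(model.exons, 1):
            w.writerow(
                [model.gene_id, model.chrom, model.strand, i, s, e,
                 model.cds_start, model.cds_end]
            )


def read_gene_model_tsv(path, sequence: Optional[str] = None, seq_offset: int = 1) -> GeneModel:
    """Read a gene model from the 6+-column exon TSV (1-based inclusive)."""
    rows = []
    with open(path) as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            rows.append(row)
    if not rows:
        raise StructuralModelError(f"empty gene model table {path}")
    rows.sort(key=lambda r: int(r["exon_index"]))
    first = rows[0]
    return GeneModel(
        gene_id=first["gene_id"],
        chrom=first["chrom"],
        strand=first["strand"],
        exons=[(int(r["start"]), int(r["end"])) for r in rows],
        cds_start=int(first.get("cds_start", 1)),
        cds_end=int(first.get("cds_end", 1)),
        sequence=sequence,
        seq_offset=seq_offset,
    )


def read_locus_fasta(path) -> str:
    """Read the (single) locus sequence from a FASTA file."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise StructuralModelError(
            f"expected exactly one locus sequence in {path}, found {len(records)}"
        )
    return str(records[0].seq)


def write_events_tsv(events: dict[str, SpliceEventSpec], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["event_id", "kind", "params"])
        for ev in events.values():
            if ev.kind == "exon_skip":
                params = "exons=" + ",".join(map(str, ev.exons))
            elif ev.kind in ("alt_acceptor", "alt_donor"):
                params = f"exon={ev.exon};offset={ev.offset}"
            elif ev.kind == "alt_exon_inclusion":
                params = f"interval={ev.interval[0]}-{ev.interval[1]}"
            elif ev.kind == "intron_retention":
                params = f"intron={ev.intron}"
            else:
                params = ""
            w.writerow([ev.event_id, ev.kind, params])


def read_events_tsv(path) -> dict[str, SpliceEventSpec]:
    """Read a splice-event catalogue table (event_id, kind, params).

    ``params`` is a semicolon-joined key=value list: ``exons=4,5`` (skip),
    ``exon=8;offset=14`` (alt acceptor/donor), ``interval=100-200``
    (alternate exon), ``intron=3`` (retention); empty for ``canonical``.
    """
    events: dict[str, SpliceEventSpec] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            kw: dict = {}
            for item in (row.get("params") or "").split(";"):
                if "=" not in item:
                    continue
                key, _, val = item.partition("=")
                key = key.strip()
                if key == "exons":
                    kw["exons"] = tuple(int(x) for x in val.split(",") if x)
                elif key == "interval":
                    a, _, b = val.partition("-")
                    kw["interval"] = (int(a), int(b))
                elif key in ("exon", "offset", "intron"):
                    kw[key] = int(val)
            events[row["event_id"]] = SpliceEventSpec(row["event_id"], row["kind"], **kw)
    return events


def read_bed12(path, cds_start: int = 1, cds_end: Optional[int] = None,
               sequence: Optional[str] = None, seq_offset: int = 1) -> GeneModel:
    """Read exon structure from a BED12 line (0-based half-open -> 1-based)."""
    with open(path) as fh:
        line = next(l for l in fh if l.strip() and not l.startswith(("#", "track")))
    f = line.rstrip("\n").split("\t")
    chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    starts = [int(x) for x in f[11].rstrip(",").split(",")]
    exons = [
        (chrom_start + st + 1, chrom_start + st + sz) for st, sz in zip(starts, sizes)
    ]
    if strand == "-":
        exons = exons[::-1]
    spliced = sum(sz for sz in sizes)
    return GeneModel(
        gene_id=name,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=spliced if cds_end is None else cds_end,
        sequence=sequence,
        seq_offset=seq_offset,
    )
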