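import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from amplisplice.gene_models import (
    ConsequenceUnavailableError,
    EventSpecError,
    GeneModel,
    SpliceEventSpec,
    StructuralModelError,
    annotate_consequence,
    apply_splice_event,
    build_transcript,
    map_coordinate,
    read_gene_model_tsv,
    write_gene_model_tsv,
)

from conftest import make_model


class TestBuildTranscript:
    def test_spliced_length_is_sum_of_exon_lengths(self):
        tx = build_transcript(make_model([10, 20, 30]))
        assert tx.spliced_length == 60
        assert len(tx.junctions) == 2

    def test_single_exon_has_empty_junction_chain(self):
        tx = build_transcript(make_model([60]))
        assert tx.junctions == []

    def test_minus_strand_yields_reverse_complement(self):
        # genomic layout: AAA (exon, 1-3), NN intron, CCC (exon, 6-8);
        # transcription order on '-' starts from the CCC exon
        model = GeneModel(
            gene_id="m", chrom="c", strand="-",
            exons=[(6, 8), (1, 3)], cds_start=1, cds_end=6,
            sequence="AAATTCCC", seq_offset=1,
        )
        tx = build_transcript(model)
        assert tx.sequence == "GGGTTT"
        assert tx.junctions == [(6, 3)]

    def test_overlapping_exons_rejected(self):
        with pytest.raises(StructuralModelError):
            GeneModel("g", "c", "+", [(1, 10), (5, 20)], 1, 10)

    def test_unsorted_exons_rejected(self):
        with pytest.raises(StructuralModelError):
            GeneModel("g", "c", "+", [(20, 30), (1, 10)], 1, 10)


class TestMapCoordinate:
    def test_first_base_of_exon_one(self):
        tx = build_transcript(make_model([10, 20, 30], locus_start=100))
        cmap = map_coordinate(tx, 100)
        assert (cmap.kind, cmap.t_pos) == ("exonic", 1)

    def test_intronic_offset_minus_7_before_acceptor(self):
        # exon1: 1-10, intron 11-60, exon2: 61-80
        tx = build_transcript(make_model([10, 20, 30]))
        cmap = map_coordinate(tx, 61 - 7)
        assert cmap.kind == "intronic"
        assert cmap.offset == -7
        assert cmap.t_pos == 11  # acceptor's transcript coordinate
        assert cmap.cds_label == "11-7"

    def test_donor_side_positive_offset(self):
        tx = build_transcript(make_model([10, 20, 30]))
        cmap = map_coordinate(tx, 10 + 3)
        assert (cmap.kind, cmap.offset, cmap.t_pos) == ("intronic", 3, 10)

    def test_out_of_range_raises(self):
        tx = build_transcript(make_model([10, 20, 30]))
        with pytest.raises(ValueError):
            map_coordinate(tx, 10_000)

    @settings(derandomize=True, max_examples=50)
    @given(t_pos=st.integers(min_value=1, max_value=60), minus=st.booleans())
    def test_roundtrip_identity_on_exonic_positions(self, t_pos, minus):
        tx = build_transcript(make_model([10, 20, 30], strand="-" if minus else "+"))
        g = tx.to_genomic(t_pos)
        cmap = tx.to_transcript(g)
        assert (cmap.kind, cmap.t_pos) == ("exonic", t_pos)


class TestApplySpliceEvent:
    def test_exon_skip_delta_and_junction_fusion(self):
        # 5-exon toy, exon 3 of length 89 skipped
        model = make_model([100, 100, 89, 100, 100])
        tx = build_transcript(model)
        mod, delta = apply_splice_event(
            tx, SpliceEventSpec("skip3", "exon_skip", exons=(3,))
        )
        assert delta == -89
        donor2 = model.exons[1][1]
        acceptor4 = model.exons[3][0]
        assert (donor2, acceptor4) in mod.junctions

    def test_alt_acceptor_plus_14_trims_exon(self):
        model = make_model([100] * 8)
        tx = build_transcript(model)
        mod, delta = apply_splice_event(
            tx, SpliceEventSpec("aa", "alt_acceptor", exon=8, offset=14)
        )
        assert delta == -14

    def test_canonical_event_is_identity(self):
        tx = build_transcript(make_model([10, 20, 30]))
        mod, delta = apply_splice_event(tx, SpliceEventSpec("c", "canonical"))
        assert delta == 0
        assert mod.exons == tx.exons
        assert mod.sequence == tx.sequence

    def test_intron_retention_inserts_full_intron(self):
        tx = build_transcript(make_model([10, 20, 30], intron_length=77))
        mod, delta = apply_splice_event(
            tx, SpliceEventSpec("ir", "intron_retention", intron=1)
        )
        assert delta == 77

    def test_alt_exon_inclusion_inserts_in_order(self):
        model = make_model([10, 20, 30], intron_length=50)
        tx = build_transcript(model)
        # intron 1 spans 11..60; insert a 12-bp alternate exon inside it
        mod, delta = apply_splice_event(
            tx, SpliceEventSpec("ax", "alt_exon_inclusion", interval=(21, 32))
        )
        assert delta == 12
        assert mod.exons[1] == (21, 32)

    @pytest.mark.parametrize(
        "event",
        [
            SpliceEventSpec("bad", "exon_skip", exons=(9,)),
            SpliceEventSpec("bad", "intron_retention", intron=5),
            SpliceEventSpec("bad", "alt_exon_inclusion", interval=(5, 15)),
        ],
    )
    def test_invalid_events_raise(self, event):
        tx = build_transcript(make_model([10, 20, 30]))
        with pytest.raises(EventSpecError):
            apply_splice_event(tx, event)

    def test_length_conservation_all_kinds(self):
        tx = build_transcript(make_model([30, 30, 30, 30], intron_length=40))
        events = [
            SpliceEventSpec("a", "exon_skip", exons=(2,)),
            SpliceEventSpec("b", "alt_acceptor", exon=3, offset=5),
            SpliceEventSpec("c", "alt_donor", exon=2, offset=-4),
            SpliceEventSpec("d", "intron_retention", intron=2),
            SpliceEventSpec("e", "canonical"),
        ]
        for ev in events:
            mod, delta = apply_splice_event(tx, ev)
            assert mod.spliced_length == tx.spliced_length + delta


def _ala_model(n_exons=3, exon_len=30, intron_length=50):
    """Model whose CDS is a poly-alanine chain: no stop can arise in frame 0.

    The 3' UTR is a TAAA repeat, which terminates every reading frame within
    a few codons — so frameshifts always reach a stop on the transcript.
    """
    spliced = n_exons * exon_len
    utr_len = min(16, spliced // 4)
    n_codons = (spliced - utr_len - 6) // 3
    cds_len = 6 + 3 * n_codons
    seq_t = "ATG" + "GCT" * n_codons + "TAA"
    seq_t += ("TAAA" * spliced)[: spliced - len(seq_t)]
    model = make_model([exon_len] * n_exons, intron_length, cds_start=1,
                       cds_end=cds_len)
    # paint the designed transcript back into the exons of the genomic sequence
    g = list(model.sequence)
    off = 0
    for s, e in model.exons:
        g[s - 1 : e] = list(seq_t[off : off + e - s + 1])
        off += e - s + 1
    model.sequence = "".join(g)
    return model


class TestAnnotateConsequence:
    def test_inframe_deletion_of_six_bases(self):
        model = _ala_model()
        tx = build_transcript(model)
        mod, delta = apply_splice_event(
            tx, SpliceEventSpec("aa", "alt_acceptor", exon=2, offset=6)
        )
        cons = annotate_consequence(tx, mod)
        assert cons.category == "inframe_deletion"
        assert cons.deleted_codons == 2
        assert cons.hgvs_p.endswith("del)")

    def test_frameshift_matches_translation_oracle(self):
        model = _ala_model()
        tx = build_transcript(model)
        mod, delta = apply_splice_event(
            tx, SpliceEventSpec("aa", "alt_acceptor", exon=2, offset=14)
        )
        cons = annotate_consequence(tx, mod)
        assert cons.category == "frameshift"
        # oracle: translate the shifted frame directly and find the first stop
        shifted = str(Seq(mod.sequence[mod.cds_start - 1 :]).translate())
        orig = str(Seq(tx.sequence[tx.cds_start - 1 :]).translate())
        k = next(i for i, (a, b) in enumerate(zip(orig, shifted)) if a != b)
        assert cons.fs_stop_offset == shifted.index("*", k) - k + 1

    def test_skip_fusing_taa_is_stop_gain(self):
        # exon1 ends ...T; exon3 starts AA...: skipping exon2 fuses T|AA
        e1, e2, e3 = "ATGGCTGCTT", "GCTGCTGCTG", "AAGCTGCTTAAGCT"
        model = make_model(
            [10, 10, 14], intron_length=20, cds_start=1, cds_end=30,
        )
        g = list(model.sequence)
        for (s, e), content in zip(model.exons, (e1, e2, e3)):
            g[s - 1 : e] = list(content)
        model.sequence = "".join(g)
        tx = build_transcript(model)
        mod, _ = apply_splice_event(tx, SpliceEventSpec("s2", "exon_skip", exons=(2,)))
        cons = annotate_consequence(tx, mod)
        assert cons.category == "stop_gain"
        import re

        assert re.fullmatch(r"p\.\([A-Z][a-z]{2}\d+\*\)", cons.hgvs_p)
        assert cons.hgvs_p.endswith(f"{cons.first_affected_codon}*)")

    def test_coordinate_only_model_raises(self):
        model = make_model([12, 12])
        model.sequence = None
        tx = build_transcript(model)
        with pytest.raises(ConsequenceUnavailableError):
            annotate_consequence(tx, tx)

    def test_non_atg_start_rejected(self):
        model = make_model([30, 30], seed=3)
        tx = build_transcript(model)
        if tx.cds_sequence().startswith("ATG"):
            pytest.skip("random sequence happened to start with ATG")
        with pytest.raises(ConsequenceUnavailableError):
            annotate_consequence(tx, tx)

    def test_random_events_agree_with_translation_oracle(self):
        """Category trichotomy against direct translation, 100 random events."""
        rng = np.random.default_rng(99)
        n_checked = 0
        while n_checked < 100:
            n_exons = int(rng.integers(3, 6))
            exon_len = int(rng.integers(12, 40)) // 3 * 3
            model = _ala_model(n_exons, exon_len)
            tx = build_transcript(model)
            kind = rng.choice(["exon_skip", "alt_acceptor", "alt_donor",
                               "intron_retention"])
            if kind == "exon_skip":
                ev = SpliceEventSpec("e", kind, exons=(int(rng.integers(2, n_exons + 1)),))
            elif kind == "intron_retention":
                ev = SpliceEventSpec("e", kind, intron=int(rng.integers(1, n_exons)))
            else:
                ev = SpliceEventSpec(
                    "e", kind, exon=int(rng.integers(2, n_exons + 1)),
                    offset=int(rng.choice([-7, -3, 4, 5, 6, 8])),
                )
            try:
                mod, delta = apply_splice_event(tx, ev)
            except (EventSpecError, StructuralModelError):
                # e.g. a donor shift running past the locus end
                continue
            cons = annotate_consequence(tx, mod)
            assert mod.spliced_length == tx.spliced_length + delta
            p_orig = str(Seq(tx.sequence[tx.cds_start - 1 :]).translate()).split("*")[0]
            p_mod = str(Seq(mod.sequence[mod.cds_start - 1 :]).translate()).split("*")[0]
            categories = {"no_change", "inframe_deletion", "frameshift", "stop_gain"}
            assert cons.category in categories
            if p_orig == p_mod and len(p_mod) * 3 >= tx.cds_end - tx.cds_start - 2:
                assert cons.category == "no_change"
            elif cons.category == "no_change":
                assert p_orig == p_mod
            if cons.category == "inframe_deletion":
                assert delta % 3 == 0 and delta != 0
                assert cons.deleted_codons == abs(delta) // 3
            if cons.category == "frameshift":
                assert delta % 3 != 0
                if cons.fs_stop_offset is not None:
                    assert cons.fs_stop_offset >= 1
            n_checked += 1


class TestModelIO:
    def test_tsv_roundtrip(self, tmp_path):
        model = make_model([10, 20, 30], cds_start=5, cds_end=55)
        path = tmp_path / "model.tsv"
        write_gene_model_tsv(model, path)
        back = read_gene_model_tsv(path)
        assert back.exons == model.exons
        assert (back.cds_start, back.cds_end) == (5, 55)
        assert back.strand == model.strand

    def test_events_tsv_roundtrip(self, tmp_path):
        from amplisplice.gene_models import read_events_tsv, write_events_tsv

        events = {
            "canonical": SpliceEventSpec("canonical", "canonical"),
            "skip45": SpliceEventSpec("skip45", "exon_skip", exons=(4, 5)),
            "aa8": SpliceEventSpec("aa8", "alt_acceptor", exon=8, offset=14),
            "alt6": SpliceEventSpec("alt6", "alt_exon_inclusion", interval=(100, 183)),
            "ir2": SpliceEventSpec("ir2", "intron_retention", intron=2),
        }
        path = tmp_path / "events.tsv"
        write_events_tsv(events, path)
        assert read_events_tsv(path) == events

    def test_locus_fasta_reader(self, tmp_path):
        from amplisplice.gene_models import read_locus_fasta

        p = tmp_path / "locus.fa"
        p.write_text(">toy\nACGTACGT\nAAAA\n")
        assert read_locus_fasta(p) == "ACGTACGTAAAA"
        p.write_text(">a\nACGT\n>b\nAAAA\n")
        with pytest.raises(StructuralModelError):
            read_locus_fasta(p)
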