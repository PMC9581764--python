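import numpy as np
import pytest

from amplisplice.gene_models import GeneModel
from amplisplice.simulate import ErrorModel
from amplisplice.workflows import coq5_skip_analysis, pdss1_inclusion_analysis


def make_model(
    exon_lengths,
    intron_length=50,
    cds_start=1,
    cds_end=None,
    sequence=None,
    strand="+",
    seed=0,
    locus_start=1,
):
    """Assemble a toy forward/reverse gene model with the given exon lengths."""
    rng = np.random.default_rng(seed)
    spliced = sum(exon_lengths)
    cds_end = cds_end if cds_end is not None else spliced
    exons = []
    pos = locus_start
    for length in exon_lengths:
        exons.append((pos, pos + length - 1))
        pos += length + intron_length
    locus_len = pos - locus_start - intron_length
    if sequence is None:
        sequence = "".join(rng.choice(list("ACGT"), size=locus_len))
    if strand == "-":
        exons = exons[::-1]
    return GeneModel(
        gene_id="toy",
        chrom="toy_chr",
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        sequence=sequence,
        seq_offset=locus_start,
    )


@pytest.fixture(scope="session")
def coq5_zero():
    """Zero-error COQ5-style replica at the published mixtures (100 reads/allele)."""
    return coq5_skip_analysis(seed=1)


@pytest.fixture(scope="session")
def coq5_noisy():
    """COQ5-style replica at default nanopore-like error rates, 500 reads/allele."""
    return coq5_skip_analysis(seed=11, err=ErrorModel(seed=11), reads_per_allele=500)


@pytest.fixture(scope="session")
def pdss1_small():
    """Zero-error PDSS1-style replica scaled down for fast unit checks."""
    return pdss1_inclusion_analysis(seed=1, a_reads=40, g_reads=160)


@pytest.fixture(scope="session")
def pdss1_full():
    """Zero-error PDSS1-style replica at the published depths (400 + 1619 reads)."""
    return pdss1_inclusion_analysis(seed=1)
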