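"""Shared fixtures: tiny hand-built genomes/models and small simulations."""

from __future__ import annotations

import pytest

from microintron import (
    GenomeSequence,
    SimulationConfig,
    TranscriptModel,
    make_genome,
)
from microintron.genome_io import reverse_complement


def build_genome(exon_seqs: list[str], intron_seqs: list[str],
                 strand: str = "+", seq_id: str = "chrT",
                 pad: str = "CCCCC", cds=None,
                 transcript_id: str = "tx1") -> tuple[GenomeSequence, TranscriptModel]:
    """Assemble a genome from transcript-orientation exon/intron sequences.

    ``cds`` is a spliced-transcript interval; it is mapped to genomic
    coordinates.  For strand '-', the layout is reverse-complemented onto
    the genome so that extraction reproduces the given sequences.
    """
    assert len(exon_seqs) == len(intron_seqs) + 1
    layout = []
    exon_layout = []
    pos = 0
    for i, e in enumerate(exon_seqs):
        exon_layout.append((pos, pos + len(e)))
        layout.append(e)
        pos += len(e)
        if i < len(intron_seqs):
            layout.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    gene = "".join(layout)
    offset = len(pad)
    genome_seq = pad + (gene if strand == "+" else reverse_complement(gene)) + pad

    def to_genomic(layout_interval):
        s, e = layout_interval
        if strand == "+":
            return (offset + s, offset + e)
        return (offset + len(gene) - e, offset + len(gene) - s)

    exons = sorted(to_genomic(iv) for iv in exon_layout)

    cds_genomic = None
    if cds is not None:
        t_start, t_end = cds
        # map spliced coords to layout coords
        def spliced_to_layout(t):
            acc = 0
            for (ls, le), e in zip(exon_layout, exon_seqs):
                if t < acc + len(e):
                    return ls + (t - acc)
                acc += len(e)
            raise AssertionError
        ls = spliced_to_layout(t_start)
        le = spliced_to_layout(t_end - 1) + 1
        cds_genomic = to_genomic((ls, le))

    model = TranscriptModel(
        transcript_id=transcript_id, gene_id="g1", seq_id=seq_id,
        strand=strand, exons=exons, cds=cds_genomic,
    )
    return GenomeSequence(seq_id, genome_seq), model


@pytest.fixture
def simple_locus():
    """Plus-strand two-exon gene with one canonical 43-nt intron in the CDS."""
    exon1 = "ATGAAACCCGGGTTTACCGATTACA"          # 25 nt, starts ATG
    exon2 = "GGATCCAAGCTTGGCACTGGCCGTA"          # 25 nt
    intron = "GT" + "GGGAGGGCTGGGAGGATCCAGGGACTCGAGGGTAGGCCC"[:39] + "AG"
    assert len(intron) == 43
    genome, model = build_genome([exon1, exon2], [intron],
                                 cds=(0, 48))       # UTR3 of 2 nt
    return genome, model, intron


@pytest.fixture(scope="session")
def small_sim():
    """A small full simulation shared across tests (read-only)."""
    cfg = SimulationConfig(seed=11, n_genes=15)
    genome, models, truth = make_genome(cfg)
    return cfg, genome, models, truth
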