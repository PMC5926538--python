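"""Shared fixtures: toy annotations, genomes, and a small synthetic run."""

from __future__ import annotations

import pytest

from syntelnc.models import Annotation, GeneRecord, GenomeSequence, TranscriptModel


def make_gene(
    gene_id="g1",
    symbol="SYM1",
    chrom="chr1",
    start=100,
    end=200,
    strand="+",
    biotype="protein_coding",
):
    return GeneRecord(gene_id, symbol, chrom, start, end, strand, biotype)


def make_transcript(
    transcript_id="t1",
    gene_id="g1",
    chrom="chr1",
    strand="+",
    exons=((100, 200),),
):
    return TranscriptModel(transcript_id, gene_id, chrom, strand, tuple(exons))


def make_annotation(genes=(), transcripts=()):
    ann = Annotation()
    for g in genes:
        ann.add_gene(g)
    for t in transcripts:
        ann.add_transcript(t)
    return ann


@pytest.fixture
def toy_genome():
    return GenomeSequence({"chr1": "ACGTTA" * 200, "chr2": "TTGACA" * 200})


@pytest.fixture
def gene_factory():
    return make_gene


@pytest.fixture
def transcript_factory():
    return make_transcript


@pytest.fixture
def annotation_factory():
    return make_annotation


@pytest.fixture(scope="session")
def small_sim_config():
    from syntelnc.synthetic import SimulationConfig

    return SimulationConfig(
        seed=11,
        n_chroms=2,
        genes_per_chrom=15,
        n_planted_lncRNAs=12,
        replicates_per_tissue=3,
        n_individuals=4,
        n_housekeeping=6,
        n_tissue_specific=6,
        n_coexpressed_pairs=4,
    )


@pytest.fixture(scope="session")
def genome_pair(small_sim_config):
    from syntelnc.synthetic import simulate_genome_pair

    return simulate_genome_pair(small_sim_config)
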