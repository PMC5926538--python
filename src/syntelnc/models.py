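"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive throughout (GTF convention); conversion to
0-based half-open happens only at the BED boundary in :mod:`syntelnc.annotation_io`.
Strand is one of ``+``, ``-`` or ``.`` (unknown). Unstranded models arise
naturally from RNA-seq assembly: the aligner infers strand from splice sites,
which is impossible for mono-exonic transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

STRANDS = ("+", "-", ".")
BIOTYPES = ("protein_coding", "pseudogene", "lncRNA", "other")

#: sentinel for unknown strand
UNKNOWN = "."


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene locus.

    ``symbol`` is the cross-species matching key (HGNC-style); it may be empty
    for genes without an assigned symbol, which are then invisible to the
    synteny scan.
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: bad biotype {self.biotype!r}")

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered chain of exons on one chromosome."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        prev_end = 0
        for s, e in exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon {s}>{e}")
            if s <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        """Summed exon length (transcript length, not genomic span)."""
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """Ordered intron intervals; the identity key for 'precise reconstruction'."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )


@dataclass
class Annotation:
    """A set of genes and transcripts read from one GTF/GFF3 file."""

    genes: Dict[str, GeneRecord] = field(default_factory=dict)
    transcripts: Dict[str, TranscriptModel] = field(default_factory=dict)

    def add_gene(self, g: GeneRecord) -> None:
        if g.gene_id in self.genes:
            raise ValueError(f"duplicate gene_id {g.gene_id}")
        self.genes[g.gene_id] = g

    def add_transcript(self, t: TranscriptModel) -> None:
        self.transcripts[t.transcript_id] = t

    def transcripts_of(self, gene_id: str) -> List[TranscriptModel]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    def by_chrom(self, biotypes: Optional[set] = None) -> Dict[str, List[GeneRecord]]:
        out: Dict[str, List[GeneRecord]] = {}
        for g in self.genes.values():
            if biotypes is not None and g.biotype not in biotypes:
                continue
            out.setdefault(g.chrom, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        return out


class GenomeSequence:
    """chrom -> uppercase nucleotide string over {A,C,G,T,N}."""

    def __init__(self, seqs: Dict[str, str]):
        self._seqs = {c: s.upper() for c, s in seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def chroms(self) -> List[str]:
        return sorted(self._seqs)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Substring in 1-based inclusive coordinates."""
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq):
            raise IndexError(
                f"{chrom}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start - 1 : end]

    def items(self):
        return self._seqs.items()
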