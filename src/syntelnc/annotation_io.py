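"""Annotation, sequence and interval I/O.

Reads GTF 2.2 (``gene_id "x"; transcript_id "y";`` attributes) and GFF3
(``ID=``/``Parent=`` chains), covering both an Ensembl-style GTF and an
NCBI-style GFF3 through a configurable biotype map instead of hard-coded
dialect logic. Internal coordinates are 1-based inclusive; BED output is the
only place the 0-based half-open convention appears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import Annotation, GeneRecord, GenomeSequence, TranscriptModel, UNKNOWN

log = logging.getLogger(__name__)

#: default translation of source biotype strings into the closed internal set
DEFAULT_BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "mRNA": "protein_coding",
    "pseudogene": "pseudogene",
    "processed_pseudogene": "pseudogene",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "lnc_RNA": "lncRNA",
}


class AnnotationParseError(ValueError):
    """Raised with the offending file line number on malformed input."""


def _parse_gtf_attributes(attr: str, path: str, lineno: int) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise AnnotationParseError(
                f"{path}:{lineno}: malformed GTF attribute {chunk!r}"
            )
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _parse_gff3_attributes(attr: str, path: str, lineno: int) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise AnnotationParseError(
                f"{path}:{lineno}: malformed GFF3 attribute {chunk!r}"
            )
        key, _, value = chunk.partition("=")
        out[key] = value
    return out


@dataclass
class _RawTranscript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]


def read_annotation(
    path: str,
    biotype_map: Optional[Dict[str, str]] = None,
) -> Annotation:
    """Parse a GTF or GFF3 file into gene and transcript models.

    The dialect is detected per line from the attribute column. Gene spans are
    taken from explicit ``gene`` lines when present, else computed as the
    min/max over the gene's transcripts. Features whose biotype does not map
    through ``biotype_map`` become ``other``. A transcript whose exons fall on
    multiple chromosomes is rejected and logged, not fatal.
    """
    bmap = dict(DEFAULT_BIOTYPE_MAP)
    if biotype_map:
        bmap.update(biotype_map)

    gene_lines: Dict[str, dict] = {}
    raw_tx: Dict[str, _RawTranscript] = {}
    gff3_parent_gene: Dict[str, str] = {}  # transcript ID -> gene ID (GFF3)
    rejected: set = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if strand not in ("+", "-"):
                strand = UNKNOWN
            is_gff3 = "=" in attr and '"' not in attr.split(";")[0]
            if is_gff3:
                attrs = _parse_gff3_attributes(attr, path, lineno)
            else:
                attrs = _parse_gtf_attributes(attr, path, lineno)

            if ftype == "gene":
                gid = attrs.get("gene_id") or attrs.get("ID")
                if gid is None:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: gene line without gene_id/ID"
                    )
                biotype_src = (
                    attrs.get("gene_biotype")
                    or attrs.get("biotype")
                    or attrs.get("gene_type")
                    or ""
                )
                gene_lines[gid] = dict(
                    gene_id=gid,
                    symbol=attrs.get("gene_name") or attrs.get("Name") or "",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    biotype=bmap.get(biotype_src, "other"),
                )
            elif ftype in ("transcript", "mRNA", "lnc_RNA", "ncRNA"):
                tid = attrs.get("transcript_id") or attrs.get("ID")
                gid = attrs.get("gene_id") or attrs.get("Parent")
                if tid is None or gid is None:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: transcript line without ids"
                    )
                gff3_parent_gene[tid] = gid
                raw_tx.setdefault(
                    tid, _RawTranscript(tid, gid, chrom, strand, [])
                )
            elif ftype == "exon":
                if is_gff3:
                    tid = attrs.get("Parent")
                    gid = gff3_parent_gene.get(tid, tid)
                else:
                    tid = attrs.get("transcript_id")
                    gid = attrs.get("gene_id")
                if tid is None:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: exon line without transcript id"
                    )
                rt = raw_tx.setdefault(
                    tid, _RawTranscript(tid, gid or tid, chrom, strand, [])
                )
                if rt.chrom != chrom:
                    if tid not in rejected:
                        log.warning(
                            "%s:%d: transcript %s has exons on multiple "
                            "chromosomes; record rejected",
                            path,
                            lineno,
                            tid,
                        )
                        rejected.add(tid)
                    continue
                rt.exons.append((start, end))
                if rt.strand == UNKNOWN and strand != UNKNOWN:
                    rt.strand = strand

    ann = Annotation()
    tx_by_gene: Dict[str, List[TranscriptModel]] = {}
    for rt in raw_tx.values():
        if rt.transcript_id in rejected or not rt.exons:
            continue
        t = TranscriptModel(
            transcript_id=rt.transcript_id,
            gene_id=rt.gene_id,
            chrom=rt.chrom,
            strand=rt.strand,
            exons=tuple(sorted(rt.exons)),
        )
        ann.add_transcript(t)
        tx_by_gene.setdefault(t.gene_id, []).append(t)

    seen_gene_ids = set(gene_lines) | set(tx_by_gene)
    for gid in sorted(seen_gene_ids):
        if gid in gene_lines:
            ann.add_gene(GeneRecord(**gene_lines[gid]))
        else:
            txs = tx_by_gene[gid]
            strand = txs[0].strand
            ann.add_gene(
                GeneRecord(
                    gene_id=gid,
                    symbol="",
                    chrom=txs[0].chrom,
                    start=min(t.start for t in txs),
                    end=max(t.end for t in txs),
                    strand=strand,
                    biotype="other",
                )
            )
    return ann


_BIOTYPE_GTF = {v: v for v in ("protein_coding", "pseudogene", "lncRNA", "other")}


def write_gtf(ann: Annotation, path: str, source: str = "syntelnc") -> None:
    """Write an annotation back to GTF; composes with :func:`read_annotation`."""
    with open(path, "w") as fh:
        for gid in sorted(ann.genes):
            g = ann.genes[gid]
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            if g.symbol:
                attrs += f' gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in sorted(ann.transcripts_of(gid), key=lambda t: t.transcript_id):
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\t{source}\ttranscript\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t{tattrs}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{t.chrom}\t{source}\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{tattrs}\n"
                    )


def read_fasta(path: str) -> GenomeSequence:
    return GenomeSequence(
        {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
    )


def write_fasta(genome: GenomeSequence, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sorted(genome.items())
    ]
    SeqIO.write(records, path, "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_transcript_sequence(t: TranscriptModel, genome: GenomeSequence) -> str:
    """5'->3' concatenated exon sequence.

    Reverse-complemented for minus-strand transcripts; unknown strand falls
    back to the plus-strand concatenation.
    """
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom} absent from genome")
    seq = "".join(genome.fetch(t.chrom, s, e) for s, e in t.exons)
    if t.strand == "-":
        return reverse_complement(seq)
    return seq


@dataclass(frozen=True)
class BedInterval:
    """A named genomic interval in internal (1-based inclusive) coordinates."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


def write_bed(intervals: Sequence[BedInterval], path: str) -> None:
    """Emit BED6 (0-based half-open); internal (1,10) becomes ``0 10``."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_bed(path: str) -> List[BedInterval]:
    out: List[BedInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(
                BedInterval(
                    chrom=f[0],
                    start=int(f[1]) + 1,
                    end=int(f[2]),
                    name=f[3] if len(f) > 3 else ".",
                    score=float(f[4]) if len(f) > 4 else 0.0,
                    strand=f[5] if len(f) > 5 else ".",
                )
            )
    return out
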