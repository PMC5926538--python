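"""Positional classification of candidate lncRNAs relative to known genes.

A model overlapping a known gene is sense/antisense (or
``overlap_strand_unknown`` when the model is unstranded); otherwise, if its
nearest transcription start site is closer than 5 kb it is up- or downstream
of that gene on the same or opposite strand; otherwise it is intergenic,
binned by distance to the nearest TSS irrespective of strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .models import Annotation, GeneRecord, UNKNOWN

log = logging.getLogger(__name__)

LABELS = (
    "sense",
    "antisense",
    "overlap_strand_unknown",
    "upstream_same",
    "upstream_opposite",
    "downstream_same",
    "downstream_opposite",
    "intergenic",
)

#: half-open intergenic distance bins in bp, labelled as in kb/Mb
INTERGENIC_BINS: Tuple[Tuple[int, Optional[int], str], ...] = (
    (5_000, 10_000, "5-10kb"),
    (10_000, 20_000, "10-20kb"),
    (20_000, 50_000, "20-50kb"),
    (50_000, 100_000, "50-100kb"),
    (100_000, 500_000, "100-500kb"),
    (500_000, 1_000_000, "500kb-1Mb"),
    (1_000_000, None, ">=1Mb"),
)

TSS_WINDOW = 5_000


@dataclass(frozen=True)
class PositionalClass:
    model_id: str
    label: str
    intergenic_bin: str  # bin label, or "none" unless intergenic
    nearest_tss_distance: int
    nearest_gene_id: str


def intergenic_bin(distance: int) -> str:
    for lo, hi, label in INTERGENIC_BINS:
        if distance >= lo and (hi is None or distance < hi):
            return label
    raise ValueError(f"distance {distance} below the intergenic range")


def _tss_positions(
    reference: Annotation, tss_source: str
) -> Dict[str, List[Tuple[int, str]]]:
    """chrom -> sorted [(tss, gene_id)]; strand-aware transcript or gene starts."""
    out: Dict[str, List[Tuple[int, str]]] = {}
    if tss_source == "transcript_starts" and reference.transcripts:
        for t in reference.transcripts.values():
            tss = t.end if t.strand == "-" else t.start
            out.setdefault(t.chrom, []).append((tss, t.gene_id))
    else:
        for g in reference.genes.values():
            tss = g.end if g.strand == "-" else g.start
            out.setdefault(g.chrom, []).append((tss, g.gene_id))
    for v in out.values():
        v.sort()
    return out


def _span_tss_distance(span: Tuple[int, int], tss: int) -> int:
    """Minimum endpoint distance; 0 when the TSS falls inside the span."""
    s, e = span
    if s <= tss <= e:
        return 0
    return min(abs(s - tss), abs(e - tss))


def classify_lncRNAs(
    models: Annotation,
    reference: Annotation,
    tss_source: str = "auto",
) -> List[PositionalClass]:
    """Assign exactly one positional label to every model.

    ``tss_source``: ``transcript_starts`` (per-transcript TSS, used when the
    reference carries transcripts), ``gene_start``, or ``auto`` (transcript
    starts when available, else gene starts).
    """
    if tss_source == "auto":
        tss_source = "transcript_starts" if reference.transcripts else "gene_start"
    if tss_source not in ("transcript_starts", "gene_start"):
        raise ValueError(f"bad tss_source {tss_source!r}")

    tss_by_chrom = _tss_positions(reference, tss_source)
    genes_by_chrom = reference.by_chrom()

    out: List[PositionalClass] = []
    for gid in sorted(models.genes):
        model = models.genes[gid]
        ref_genes = genes_by_chrom.get(model.chrom, [])
        if not ref_genes:
            log.warning(
                "model %s on chromosome %s with no reference gene", gid, model.chrom
            )
            out.append(
                PositionalClass(gid, "intergenic", ">=1Mb", 10**9, "")
            )
            continue

        # overlap with a known gene wins; largest overlap breaks ties
        best_overlap, overlap_gene = 0, None
        for g in ref_genes:
            ov = min(model.end, g.end) - max(model.start, g.start) + 1
            if ov > best_overlap:
                best_overlap, overlap_gene = ov, g

        # nearest TSS irrespective of strand
        nearest_d, nearest_gene = None, None
        for tss, g_id in tss_by_chrom.get(model.chrom, []):
            d = _span_tss_distance(model.span, tss)
            if nearest_d is None or d < nearest_d:
                nearest_d, nearest_gene = d, g_id

        if overlap_gene is not None:
            if model.strand == UNKNOWN:
                label = "overlap_strand_unknown"
            elif overlap_gene.strand == UNKNOWN or model.strand == overlap_gene.strand:
                label = "sense"
            else:
                label = "antisense"
            out.append(
                PositionalClass(gid, label, "none", nearest_d, overlap_gene.gene_id)
            )
            continue

        if nearest_d < TSS_WINDOW:
            gene = reference.genes[nearest_gene]
            tss = gene.end if gene.strand == "-" else gene.start
            # model 5' of the gene's TSS (in the gene's reading direction)
            if gene.strand == "-":
                is_upstream = model.start > tss
            else:
                is_upstream = model.end < tss
            same = model.strand == UNKNOWN or gene.strand == UNKNOWN or (
                model.strand == gene.strand
            )
            side = "upstream" if is_upstream else "downstream"
            rel = "same" if same else "opposite"
            out.append(
                PositionalClass(
                    gid, f"{side}_{rel}", "none", nearest_d, nearest_gene
                )
            )
            continue

        out.append(
            PositionalClass(
                gid, "intergenic", intergenic_bin(nearest_d), nearest_d, nearest_gene
            )
        )
    return out


def classification_table(classes: List[PositionalClass]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                model_id=c.model_id,
                label=c.label,
                intergenic_bin=c.intergenic_bin,
                nearest_tss_distance=c.nearest_tss_distance,
                nearest_gene_id=c.nearest_gene_id,
            )
            for c in classes
        ]
    )
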