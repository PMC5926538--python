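"""Reproducibility of lncRNA models across merged per-individual assemblies.

With n individuals there are 2^n - 1 non-empty subsets of assemblies; each
subset's transcript sets are merged (StringTie-merge-like: multi-exon models
deduplicated by intron chain with outermost termini, mono-exon models
single-linkage merged at >= 95% reciprocal overlap) and each reference model
is tested for precise reconstruction: identical intron chain for multi-exon
models, >= 95% reciprocal overlap for mono-exon models. Reconstruction is
monotone over subset inclusion, because merging is a union operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from .models import TranscriptModel

RECIPROCAL_OVERLAP = 0.95


@dataclass
class ReconstructionReport:
    model_id: str
    n_subsets_total: int
    n_subsets_reconstructed: int
    per_subset: int  # bitmask; bit k set iff reconstructed in subset k+1
    in_all_subsets: bool
    in_any_subset: bool
    n_libraries_reconstructed: int  # singleton-subset variant


def _reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0] + 1), ov / (b[1] - b[0] + 1))


def merge_models(
    transcript_sets: Sequence[Iterable[TranscriptModel]],
) -> List[TranscriptModel]:
    """Union of transcripts, deduplicated the way an assembly merge would.

    Multi-exon transcripts with the same (chrom, strand, intron chain)
    collapse to one model with the outermost termini. Mono-exon transcripts
    on one chrom/strand are single-linkage clustered at >= 95% reciprocal
    overlap; each cluster's merged extent is the union of its members.
    """
    multi: Dict[Tuple, List[TranscriptModel]] = {}
    mono: Dict[Tuple[str, str], List[TranscriptModel]] = {}
    for ts in transcript_sets:
        for t in ts:
            if t.n_exons > 1:
                multi.setdefault((t.chrom, t.strand, t.introns), []).append(t)
            else:
                mono.setdefault((t.chrom, t.strand), []).append(t)

    merged: List[TranscriptModel] = []
    for (chrom, strand, introns), members in sorted(
        multi.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
    ):
        start = min(t.start for t in members)
        end = max(t.end for t in members)
        first = (start, introns[0][0] - 1)
        last = (introns[-1][1] + 1, end)
        inner = [
            (introns[k][1] + 1, introns[k + 1][0] - 1)
            for k in range(len(introns) - 1)
        ]
        exons = tuple([first] + inner + [last])
        merged.append(
            TranscriptModel(
                transcript_id=f"merged_{chrom}_{strand}_{start}_{end}_{len(introns)}",
                gene_id="merged",
                chrom=chrom,
                strand=strand,
                exons=exons,
            )
        )

    for (chrom, strand), members in sorted(mono.items()):
        members = sorted(members, key=lambda t: (t.start, t.end))
        clusters: List[List[TranscriptModel]] = []
        for t in members:
            hit = None
            for c in clusters:
                if any(
                    _reciprocal_overlap(t.exons[0], u.exons[0]) >= RECIPROCAL_OVERLAP
                    for u in c
                ):
                    hit = c
                    break
            if hit is None:
                clusters.append([t])
            else:
                hit.append(t)
        for c in clusters:
            start = min(t.start for t in c)
            end = max(t.end for t in c)
            merged.append(
                TranscriptModel(
                    transcript_id=f"merged_{chrom}_{strand}_{start}_{end}_mono",
                    gene_id="merged",
                    chrom=chrom,
                    strand=strand,
                    exons=((start, end),),
                )
            )
    return merged


def is_reconstructed(
    reference: TranscriptModel, merged: Sequence[TranscriptModel]
) -> bool:
    """Precise reconstruction: exact intron chain, or 95% reciprocal overlap
    for mono-exon models."""
    if reference.n_exons > 1:
        key = (reference.chrom, reference.strand, reference.introns)
        return any(
            (t.chrom, t.strand, t.introns) == key for t in merged if t.n_exons > 1
        )
    return any(
        t.n_exons == 1
        and t.chrom == reference.chrom
        and t.strand == reference.strand
        and _reciprocal_overlap(t.exons[0], reference.exons[0]) >= RECIPROCAL_OVERLAP
        for t in merged
    )


def subset_reproducibility(
    per_individual: Mapping[str, Sequence[TranscriptModel]],
    reference_models: Sequence[TranscriptModel],
) -> List[ReconstructionReport]:
    """Reconstruction status of each reference model over all 2^n - 1 subsets.

    Subset k (1 <= k <= 2^n - 1) contains individual i (sorted by id) iff bit
    i of k is set; the per-subset result is returned as a bitmask in that
    canonical order. n is capped at 16.
    """
    individuals = sorted(per_individual)
    n = len(individuals)
    if n > 16:
        raise ValueError(f"{n} individuals: enumerate up to 16, sample beyond that")
    n_subsets = 2**n - 1

    reconstructed_in: Dict[str, int] = {t.transcript_id: 0 for t in reference_models}
    singleton_counts: Dict[str, int] = {t.transcript_id: 0 for t in reference_models}
    for k in range(1, n_subsets + 1):
        chosen = [individuals[i] for i in range(n) if k >> i & 1]
        merged = merge_models([per_individual[ind] for ind in chosen])
        singleton = (k & (k - 1)) == 0
        for ref in reference_models:
            if is_reconstructed(ref, merged):
                reconstructed_in[ref.transcript_id] |= 1 << (k - 1)
                if singleton:
                    singleton_counts[ref.transcript_id] += 1

    reports = []
    for ref in reference_models:
        mask = reconstructed_in[ref.transcript_id]
        count = bin(mask).count("1")
        reports.append(
            ReconstructionReport(
                model_id=ref.transcript_id,
                n_subsets_total=n_subsets,
                n_subsets_reconstructed=count,
                per_subset=mask,
                in_all_subsets=count == n_subsets,
                in_any_subset=count > 0,
                n_libraries_reconstructed=singleton_counts[ref.transcript_id],
            )
        )
    return reports


def report_table(reports: Sequence[ReconstructionReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                model_id=r.model_id,
                n_subsets_total=r.n_subsets_total,
                n_subsets_reconstructed=r.n_subsets_reconstructed,
                in_all_subsets=r.in_all_subsets,
                in_any_subset=r.in_any_subset,
                n_libraries_reconstructed=r.n_libraries_reconstructed,
            )
            for r in reports
        ]
    )
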