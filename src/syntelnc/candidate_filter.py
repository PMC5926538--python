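"""Longlist and shortlist filters for candidate lncRNAs.

The longlist keeps assembled gene models that look like lncRNAs on structural
grounds: transcript length > 200 bp (>= 500 bp for mono-exonic models, which a
single read pair could otherwise satisfy), overlap of at most 1 bp with any
protein-coding or pseudogene span on the same strand, a single transcript
model per gene, and absence from an explicit previously-protein-coding
exclusion list. The shortlist then demands three independent non-coding
classifications (CPC, CPAT, PLEK) and no blastp/HMMER homology for the
longest ORF, all thresholds configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .annotation_io import reverse_complement
from .models import Annotation, GeneRecord, UNKNOWN

#: primary exclusion reasons, in cascade order
REASONS = (
    "too_short",
    "single_exon_too_short",
    "overlaps_coding",
    "multi_transcript",
    "previously_coding",
    "cpc_fail",
    "cpat_fail",
    "plek_fail",
    "blastp_hit",
    "hmmer_hit",
)

STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}


@dataclass(frozen=True)
class Orf:
    """An open reading frame; nucleotide extent includes the stop codon."""

    start: int  # 0-based offset in the searched sequence
    end: int  # exclusive
    frame: int  # 0..2 forward, 3..5 on the reverse complement
    peptide: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FilterDecision:
    model_id: str
    stage: str  # longlist | shortlist
    verdict: str  # retained | excluded
    reason: str = ""  # first failing rule, or empty when retained


@dataclass
class FilterThresholds:
    """Shortlist score thresholds; defaults follow the standard cut-offs of this filter scheme."""

    min_len_multi: int = 200  # strict: transcript length must exceed this
    min_len_mono: int = 500  # inclusive: mono-exonic length >= this
    max_overlap_bp: int = 1  # same-strand overlap with coding/pseudogene spans
    cpc_max: float = -0.5  # non-coding iff cpc_score < cpc_max (strict)
    cpat_threshold: float = 0.58
    cpat_higher_is_noncoding: bool = False
    evalue_threshold: float = 1e-5


def find_longest_orf(seq: str, search_reverse: bool = False) -> Optional[Orf]:
    """Longest ATG..stop ORF (stop included); ties broken by 5'-most start.

    With ``search_reverse`` (unstranded models) the reverse complement is
    searched too, in frames 3-5; forward wins ties.
    """
    seq = seq.upper()
    best: Optional[Orf] = None
    strands = [(0, seq)]
    if search_reverse:
        strands.append((3, reverse_complement(seq)))
    for frame_base, s in strands:
        n = len(s)
        for frame in range(3):
            i = frame
            open_start = None
            while i + 3 <= n:
                codon = s[i : i + 3]
                if open_start is None:
                    if codon == "ATG":
                        open_start = i
                elif codon in STOPS:
                    cand = Orf(
                        start=open_start,
                        end=i + 3,
                        frame=frame_base + frame,
                        peptide=_translate(s[open_start : i]),
                    )
                    if _better(cand, best):
                        best = cand
                    open_start = None
                i += 3
    return best


def _translate(cds: str) -> str:
    return "".join(
        _CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3)
    )


def _better(cand: Orf, best: Optional[Orf]) -> bool:
    if best is None:
        return True
    if cand.length != best.length:
        return cand.length > best.length
    # ties: forward strand wins, then the 5'-most start
    return (cand.frame >= 3, cand.start, cand.frame) < (
        best.frame >= 3,
        best.start,
        best.frame,
    )


def _overlap_bp(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def build_longlist(
    models: Annotation,
    reference: Annotation,
    exclusion_ids: Optional[Set[str]] = None,
    thresholds: Optional[FilterThresholds] = None,
) -> Tuple[List[str], List[FilterDecision]]:
    """Structural longlist filter over assembled gene models.

    Returns retained gene ids and one decision per gene model; an excluded
    model carries the first failing rule in the fixed cascade order.
    Unknown-strand models are screened for coding overlap against both
    strands (conservative).
    """
    th = thresholds or FilterThresholds()
    exclusion_ids = exclusion_ids or set()

    ref_chroms = {g.chrom for g in reference.genes.values()}
    coding_by_chrom: Dict[str, List[GeneRecord]] = {}
    for g in reference.genes.values():
        if g.biotype in ("protein_coding", "pseudogene"):
            coding_by_chrom.setdefault(g.chrom, []).append(g)

    retained: List[str] = []
    decisions: List[FilterDecision] = []
    for gid in sorted(models.genes):
        gene = models.genes[gid]
        txs = models.transcripts_of(gid)
        if not txs:
            continue
        if gene.chrom not in ref_chroms:
            raise ValueError(
                f"model {gid} on chromosome {gene.chrom} unknown to the reference"
            )
        longest = max(txs, key=lambda t: t.length)
        reason = ""
        if longest.n_exons > 1:
            if longest.length <= th.min_len_multi:
                reason = "too_short"
        else:
            if longest.length < th.min_len_mono:
                reason = "single_exon_too_short"
        if not reason:
            for ref_gene in coding_by_chrom.get(gene.chrom, ()):
                same_strand = (
                    gene.strand == UNKNOWN
                    or ref_gene.strand == UNKNOWN
                    or gene.strand == ref_gene.strand
                )
                if same_strand and _overlap_bp(gene.span, ref_gene.span) > th.max_overlap_bp:
                    reason = "overlaps_coding"
                    break
        if not reason and len(txs) > 1:
            reason = "multi_transcript"
        if not reason and gid in exclusion_ids:
            reason = "previously_coding"

        if reason:
            decisions.append(FilterDecision(gid, "longlist", "excluded", reason))
        else:
            decisions.append(FilterDecision(gid, "longlist", "retained"))
            retained.append(gid)
    return retained, decisions


def _is_absent(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def build_shortlist(
    longlist_ids: Sequence[str],
    scores: pd.DataFrame,
    thresholds: Optional[FilterThresholds] = None,
) -> Tuple[List[str], List[FilterDecision]]:
    """Coding-potential gate: three non-coding calls plus no homology hits.

    ``scores`` columns: model_id, cpc_score, cpat_prob, plek_label,
    blastp_best_evalue, hmmer_best_evalue (NaN/empty = no hit). Every
    longlist model must have a score record.
    """
    th = thresholds or FilterThresholds()
    table = scores.set_index("model_id")
    missing = [mid for mid in longlist_ids if mid not in table.index]
    if missing:
        raise ValueError(f"missing score records for: {missing}")

    retained: List[str] = []
    decisions: List[FilterDecision] = []
    for mid in sorted(longlist_ids):
        row = table.loc[mid]
        cpat_prob = float(row["cpat_prob"])
        if not 0.0 <= cpat_prob <= 1.0:
            raise ValueError(f"{mid}: cpat_prob {cpat_prob} outside [0,1]")
        if th.cpat_higher_is_noncoding:
            cpat_ok = cpat_prob > th.cpat_threshold
        else:
            cpat_ok = cpat_prob < th.cpat_threshold
        reason = ""
        if not float(row["cpc_score"]) < th.cpc_max:
            reason = "cpc_fail"
        elif not cpat_ok:
            reason = "cpat_fail"
        elif str(row["plek_label"]) != "noncoding":
            reason = "plek_fail"
        elif not (
            _is_absent(row["blastp_best_evalue"])
            or float(row["blastp_best_evalue"]) > th.evalue_threshold
        ):
            reason = "blastp_hit"
        elif not (
            _is_absent(row["hmmer_best_evalue"])
            or float(row["hmmer_best_evalue"]) > th.evalue_threshold
        ):
            reason = "hmmer_hit"
        if reason:
            decisions.append(FilterDecision(mid, "shortlist", "excluded", reason))
        else:
            decisions.append(FilterDecision(mid, "shortlist", "retained"))
            retained.append(mid)
    return retained, decisions


def summarize_filters(
    decisions: Iterable[FilterDecision],
    mono_exonic_ids: Optional[Set[str]] = None,
) -> pd.DataFrame:
    """One-row accounting table: list sizes, shortlist %, mono-exonic %.

    Percentages are rounded to the nearest integer, matching the style in
    which such accounting is usually reported (e.g. a 12,296-model shortlist
    from a 30,677-model longlist reads as 40%).
    """
    decisions = list(decisions)
    longlist = [d for d in decisions if d.stage == "longlist"]
    shortlist = [d for d in decisions if d.stage == "shortlist"]
    n_long = sum(1 for d in longlist if d.verdict == "retained")
    short_ids = [d.model_id for d in shortlist if d.verdict == "retained"]
    n_short = len(short_ids)
    # when only shortlist decisions are supplied, the longlist size is the
    # number of models the shortlist stage saw
    denom = n_long if n_long else len(shortlist)
    pct = round(100.0 * n_short / denom) if denom else 0
    if mono_exonic_ids is not None and n_short:
        n_mono = sum(1 for mid in short_ids if mid in mono_exonic_ids)
        mono_pct = round(100.0 * n_mono / n_short)
    else:
        n_mono, mono_pct = 0, 0
    reason_counts: Dict[str, int] = {r: 0 for r in REASONS}
    for d in decisions:
        if d.verdict == "excluded":
            reason_counts[d.reason] += 1
    row = dict(
        longlist_size=denom,
        shortlist_size=n_short,
        shortlist_pct=pct,
        mono_exonic=n_mono,
        mono_exonic_pct=mono_pct,
        **{f"excluded_{r}": c for r, c in reason_counts.items()},
    )
    return pd.DataFrame([row])
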