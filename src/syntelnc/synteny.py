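"""Gene-triple synteny blocks and their intersection across a species pair.

A sliding window over each chromosome (genes sorted by start, restricted to
protein-coding genes carrying a symbol) yields one triple per focal gene with
both neighbours; triples whose ordered symbol sequence occurs in both species
define syntenic blocks, each carrying the two intergenic intervals per
species. Candidate lncRNAs are then assigned to block positions by genomic
containment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .models import Annotation, GeneRecord

log = logging.getLogger(__name__)

POSITIONS = ("upstream", "downstream")  # interval between genes 1-2 / 2-3


@dataclass(frozen=True)
class GeneTriple:
    upstream: GeneRecord
    focal: GeneRecord
    downstream: GeneRecord

    @property
    def symbols(self) -> Tuple[str, str, str]:
        return (
            self.upstream.symbol.upper(),
            self.focal.symbol.upper(),
            self.downstream.symbol.upper(),
        )

    def interval(self, position: str) -> Tuple[str, int, int]:
        """Intergenic interval (chrom, start, end); empty when genes abut."""
        if position == "upstream":
            a, b = self.upstream, self.focal
        elif position == "downstream":
            a, b = self.focal, self.downstream
        else:
            raise ValueError(position)
        return (a.chrom, a.end + 1, b.start - 1)


@dataclass
class SyntenicBlock:
    block_id: str
    symbols: Tuple[str, str, str]
    triple_a: GeneTriple
    triple_b: GeneTriple
    orientation: str = "same"  # or "reversed"

    def interval(self, species: str, position: str) -> Tuple[str, int, int]:
        """Interval for the slot named from species A's perspective.

        For a reversed block, species B's genes run in the opposite order, so
        A's upstream slot corresponds to B's downstream interval.
        """
        if species == "A":
            return self.triple_a.interval(position)
        if self.orientation == "same":
            return self.triple_b.interval(position)
        other = "downstream" if position == "upstream" else "upstream"
        return self.triple_b.interval(other)


def enumerate_triples(
    annotation: Annotation,
    biotypes: Optional[Set[str]] = None,
    skip_unnamed: bool = True,
) -> List[GeneTriple]:
    """All consecutive gene triples per chromosome, first/last genes excluded.

    Only genes of the scanned biotypes participate; symbol-less genes are
    skipped entirely by default (they neither anchor nor break adjacency).
    """
    biotypes = biotypes if biotypes is not None else {"protein_coding"}
    triples: List[GeneTriple] = []
    for chrom in sorted(annotation.by_chrom(biotypes)):
        genes = annotation.by_chrom(biotypes)[chrom]
        if skip_unnamed:
            genes = [g for g in genes if g.symbol]
        for i in range(1, len(genes) - 1):
            triples.append(GeneTriple(genes[i - 1], genes[i], genes[i + 1]))
    return triples


def match_blocks(
    triples_a: Sequence[GeneTriple],
    triples_b: Sequence[GeneTriple],
    allow_reversed: bool = False,
) -> List[SyntenicBlock]:
    """Blocks whose ordered symbol triple is identical in both species.

    Duplicate symbol triples within a species (tandem paralog arrays) are
    dropped with a warning to avoid ambiguous matching. With
    ``allow_reversed``, a triple matching the other species in reverse order
    also matches, flagged ``orientation='reversed'``.
    """

    def unique_index(triples: Sequence[GeneTriple], name: str):
        seen: Dict[Tuple[str, str, str], GeneTriple] = {}
        dupes: Set[Tuple[str, str, str]] = set()
        for t in triples:
            key = t.symbols
            if key in seen:
                dupes.add(key)
            else:
                seen[key] = t
        if dupes:
            log.warning(
                "%s: %d duplicate symbol triples dropped from matching",
                name,
                len(dupes),
            )
        return {k: v for k, v in seen.items() if k not in dupes}

    idx_a = unique_index(triples_a, "species A")
    idx_b = unique_index(triples_b, "species B")

    blocks: List[SyntenicBlock] = []
    n = 0
    for key in sorted(idx_a):
        if key in idx_b:
            blocks.append(
                SyntenicBlock(f"block{n:05d}", key, idx_a[key], idx_b[key], "same")
            )
            n += 1
        elif allow_reversed and key[::-1] in idx_b and key != key[::-1]:
            blocks.append(
                SyntenicBlock(
                    f"block{n:05d}", key, idx_a[key], idx_b[key[::-1]], "reversed"
                )
            )
            n += 1
    return blocks


#: presence map: (block_id, position) -> species -> list of lncRNA gene ids
PresenceTable = Dict[Tuple[str, str], Dict[str, List[str]]]


def assign_lncRNAs_to_blocks(
    blocks: Sequence[SyntenicBlock],
    lnc_models: Dict[str, Annotation],
    containment: float = 1.0,
) -> PresenceTable:
    """Flag which block positions hold a lncRNA in which species.

    A lncRNA occupies a position when at least ``containment`` of its genomic
    span lies within the corresponding intergenic interval (default: full
    containment).
    """
    presence: PresenceTable = {}
    for block in blocks:
        for position in POSITIONS:
            slot: Dict[str, List[str]] = {}
            for species, ann in sorted(lnc_models.items()):
                hits: List[str] = []
                chrom, s, e = block.interval(species, position)
                if e < s:  # genes abut: empty interval
                    slot[species] = hits
                    continue
                for gid in sorted(ann.genes):
                    g = ann.genes[gid]
                    if g.chrom != chrom:
                        continue
                    ov = min(g.end, e) - max(g.start, s) + 1
                    if ov > 0 and ov / len(g) >= containment:
                        hits.append(gid)
                slot[species] = hits
            presence[(block.block_id, position)] = slot
    return presence


def conserved_positions(presence: PresenceTable) -> List[Tuple[str, str]]:
    """Block positions occupied by a lncRNA in both species."""
    return sorted(
        key
        for key, slot in presence.items()
        if all(len(v) > 0 for v in slot.values()) and len(slot) >= 2
    )


def synteny_report(
    blocks: Sequence[SyntenicBlock],
    presence: PresenceTable,
) -> pd.DataFrame:
    """Per-pair accounting: blocks, unique genes, conserved lncRNAs, % blocks.

    A lncRNA is counted once per occupied conserved position; the percentage
    of blocks with at least one positionally conserved lncRNA is rounded to
    two decimals.
    """
    n_blocks = len(blocks)
    gene_ids: Set[str] = set()
    for b in blocks:
        for t in (b.triple_a, b.triple_b):
            gene_ids.update(
                g.gene_id for g in (t.upstream, t.focal, t.downstream)
            )
    unique_symbols: Set[str] = set()
    for b in blocks:
        unique_symbols.update(b.symbols)
    conserved = conserved_positions(presence)
    blocks_hit = {bid for bid, _pos in conserved}
    pct = round(100.0 * len(blocks_hit) / n_blocks, 2) if n_blocks else 0.0
    return pd.DataFrame(
        [
            dict(
                n_blocks=n_blocks,
                n_unique_genes=len(unique_symbols),
                n_conserved_lncRNAs=len(conserved),
                pct_blocks_with_conserved=pct,
            )
        ]
    )


def percent_blocks_with_conserved(n_blocks: int, n_blocks_hit: int) -> float:
    """block-conservation percentage, two decimals."""
    return round(100.0 * n_blocks_hit / n_blocks, 2) if n_blocks else 0.0
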