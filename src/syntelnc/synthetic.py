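"""Synthetic paired genomes, expression matrices and score tables with known truth.

The generators emulate the statistical structure the downstream analysis
assumes: two genomes sharing gene order (with occasional local rearrangement),
orthologous intergenic lncRNAs planted at a controlled substitution
divergence, stochastic per-species capture of each lncRNA by "assembly",
TPM abundance tables with planted housekeeping / tissue-specific /
co-expressed genes, coding-potential tables with planted coding contaminants,
and per-individual transcript captures with dropout for the reproducibility
analysis.

Each generator draws from its own RNG stream seeded ``cfg.seed + offset`` so
that adding one generator never reshuffles another's output; a fixed seed
gives byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import Annotation, GeneRecord, GenomeSequence, TranscriptModel

_BASES = np.array(list("ACGT"))

# per-generator RNG stream offsets
_OFF_GENOME = 0
_OFF_EXPRESSION = 101
_OFF_SCORES = 202
_OFF_CAPTURES = 303

#: default tissue panel with organ-system group labels
DEFAULT_TISSUES = (
    ("cortex", "CNS"),
    ("cerebellum", "CNS"),
    ("liver", "digestive"),
    ("rumen", "digestive"),
    ("kidney", "urinary"),
    ("spleen", "immune"),
    ("thymus", "immune"),
    ("lung", "respiratory"),
    ("muscle", "musculoskeletal"),
    ("skin", "integument"),
)


@dataclass
class SimulationConfig:
    """Knobs for all generators; defaults are the study conditions."""

    seed: int = 0
    n_chroms: int = 3
    genes_per_chrom: int = 30
    intergenic_len: Tuple[int, int] = (1500, 3000)
    n_planted_lncRNAs: int = 40
    lncRNA_len: Tuple[int, int] = (500, 1000)
    divergence_mu: float = 0.05
    indel_rate: float = 0.0
    p_capture: float = 0.7
    rearrangement_rate: float = 0.1
    tissues: Tuple[Tuple[str, str], ...] = DEFAULT_TISSUES
    replicates_per_tissue: int = 4
    n_individuals: int = 6
    n_housekeeping: int = 15
    n_tissue_specific: int = 15
    n_coexpressed_pairs: int = 8
    noise_sd: float = 0.15
    dropout_p: float = 0.3
    exons_per_gene: Tuple[int, int] = (2, 3)
    exon_len: Tuple[int, int] = (150, 400)
    intron_len: Tuple[int, int] = (80, 250)

    def validate(self) -> None:
        for p, name in (
            (self.divergence_mu, "divergence_mu"),
            (self.indel_rate, "indel_rate"),
            (self.p_capture, "p_capture"),
            (self.rearrangement_rate, "rearrangement_rate"),
            (self.dropout_p, "dropout_p"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0,1]")
        for c, name in (
            (self.n_chroms, "n_chroms"),
            (self.genes_per_chrom, "genes_per_chrom"),
            (self.n_planted_lncRNAs, "n_planted_lncRNAs"),
            (self.replicates_per_tissue, "replicates_per_tissue"),
        ):
            if c < 0:
                raise ValueError(f"{name}={c} negative")
        n_slots = self.n_chroms * max(0, self.genes_per_chrom - 1)
        if self.n_planted_lncRNAs > n_slots:
            raise ValueError(
                f"{self.n_planted_lncRNAs} planted lncRNAs but only "
                f"{n_slots} intergenic slots"
            )


@dataclass
class PlantedLncRNA:
    """Ground truth for one planted orthologous lncRNA."""

    lnc_id: str
    chrom: str
    a_start: int
    a_end: int
    flank_left: str
    flank_right: str
    sequence_a: str
    planted_in_b: bool
    b_chrom: str = ""
    b_start: int = 0
    b_end: int = 0
    sequence_b: str = ""
    n_substitutions: int = 0
    captured_a: bool = False
    captured_b: bool = False
    #: symbol of the flanking gene the lncRNA was planted next to
    #: (enhancer-like geometry: a few tens of bp from one gene edge)
    adjacent_symbol: str = ""


@dataclass
class SyntheticTruth:
    """Everything the generators planted, for downstream verification."""

    ortholog_pairs: List[PlantedLncRNA] = field(default_factory=list)
    rearranged_windows: List[Tuple[str, int]] = field(default_factory=list)
    specific_genes: Dict[str, str] = field(default_factory=dict)
    coexpressed_pairs: List[Tuple[str, str, str]] = field(default_factory=list)
    per_library_presence: Optional[pd.DataFrame] = None


@dataclass
class SpeciesData:
    """One simulated species: genome, reference genes, assembled lncRNA models."""

    name: str
    genome: GenomeSequence
    reference: Annotation  # protein-coding genes with symbols
    lnc_models: Annotation  # captured ("assembled") candidate lncRNAs


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def mutate(seq: str, mu: float, rng: np.random.Generator) -> Tuple[str, int]:
    """Substitute each base independently with probability ``mu``.

    Substitutions always change the base (uniform over the other three).
    Returns the mutated sequence and the substitution count.
    """
    if mu == 0.0:
        return seq, 0
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < mu
    n = int(hit.sum())
    if n:
        for i in np.flatnonzero(hit):
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return "".join(arr), n


def _build_gene_layout(
    cfg: SimulationConfig, rng: np.random.Generator
) -> List[List[dict]]:
    """Sample per-chromosome gene structures (exon chains) and symbols.

    Returned structures are species-independent; both species reuse the same
    exon chains so orthologs are structurally identical.
    """
    layout = []
    idx = 0
    for _c in range(cfg.n_chroms):
        genes = []
        for _g in range(cfg.genes_per_chrom):
            n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
            ex_lens = rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1, size=n_ex)
            in_lens = rng.integers(
                cfg.intron_len[0], cfg.intron_len[1] + 1, size=max(0, n_ex - 1)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                dict(
                    symbol=f"SYM{idx:04d}",
                    exon_lens=[int(x) for x in ex_lens],
                    intron_lens=[int(x) for x in in_lens],
                    strand=strand,
                )
            )
            idx += 1
        layout.append(genes)
    return layout


def _place_species(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    species: str,
    layout: List[List[dict]],
    order: List[List[int]],
) -> Tuple[Annotation, Dict[str, str], Dict[Tuple[str, str], Tuple[str, int, int]]]:
    """Lay genes on chromosomes in the given per-chromosome order.

    Returns the reference annotation, chrom sequences (mutable strings), and a
    map (left_symbol, right_symbol) -> (chrom, gap_start, gap_end) for every
    adjacent gene pair.
    """
    ann = Annotation()
    seqs: Dict[str, str] = {}
    gaps: Dict[Tuple[str, str], Tuple[str, int, int]] = {}
    for ci, perm in enumerate(order):
        chrom = f"chr{ci + 1}"
        pos = 1
        parts: List[str] = []
        prev_symbol = None
        prev_end = 0
        for rank, gi in enumerate(perm):
            g = layout[ci][gi]
            gap = int(rng.integers(cfg.intergenic_len[0], cfg.intergenic_len[1] + 1))
            parts.append(_random_seq(rng, gap))
            gstart = pos + gap
            exons = []
            p = gstart
            for k, el in enumerate(g["exon_lens"]):
                exons.append((p, p + el - 1))
                p += el
                if k < len(g["intron_lens"]):
                    p += g["intron_lens"][k]
            gend = exons[-1][1]
            glen = gend - gstart + 1
            parts.append(_random_seq(rng, glen))
            gid = f"{species}_G{g['symbol'][3:]}"
            ann.add_gene(
                GeneRecord(
                    gene_id=gid,
                    symbol=g["symbol"],
                    chrom=chrom,
                    start=gstart,
                    end=gend,
                    strand=g["strand"],
                    biotype="protein_coding",
                )
            )
            ann.add_transcript(
                TranscriptModel(
                    transcript_id=f"{gid}.1",
                    gene_id=gid,
                    chrom=chrom,
                    strand=g["strand"],
                    exons=tuple(exons),
                )
            )
            if prev_symbol is not None:
                gaps[(prev_symbol, g["symbol"])] = (chrom, prev_end + 1, gstart - 1)
            prev_symbol = g["symbol"]
            prev_end = gend
            pos = gend + 1
        tail = int(rng.integers(cfg.intergenic_len[0], cfg.intergenic_len[1] + 1))
        parts.append(_random_seq(rng, tail))
        seqs[chrom] = "".join(parts)
    return ann, seqs, gaps


def _splice(seq: str, start: int, end: int, insert: str) -> str:
    """Overwrite seq[start-1:end] (1-based inclusive) with ``insert``."""
    assert len(insert) == end - start + 1
    return seq[: start - 1] + insert + seq[end:]


def simulate_genome_pair(
    cfg: SimulationConfig,
) -> Tuple[SpeciesData, SpeciesData, SyntheticTruth]:
    """Generate species A and B sharing gene order plus planted ortholog lncRNAs.

    Background intergenic sequence is i.i.d. uniform and independent between
    species, so any cross-species alignment signal comes from the planted
    copies alone. Species B's copy of each planted lncRNA carries independent
    substitutions at rate ``divergence_mu``; B's gene order is locally
    shuffled per 3-gene window with probability ``rearrangement_rate``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + _OFF_GENOME)
    truth = SyntheticTruth()

    layout = _build_gene_layout(cfg, rng)
    order_a = [list(range(cfg.genes_per_chrom)) for _ in range(cfg.n_chroms)]

    # species B order: permute 3-gene windows at the rearrangement rate
    order_b: List[List[int]] = []
    for ci in range(cfg.n_chroms):
        perm = list(range(cfg.genes_per_chrom))
        for w0 in range(0, cfg.genes_per_chrom - 2, 3):
            if rng.random() < cfg.rearrangement_rate:
                window = perm[w0 : w0 + 3]
                while True:
                    shuffled = list(rng.permutation(window))
                    if shuffled != window:
                        break
                perm[w0 : w0 + 3] = shuffled
                truth.rearranged_windows.append((f"chr{ci + 1}", w0))
        order_b.append(perm)

    ann_a, seqs_a, gaps_a = _place_species(cfg, rng, "A", layout, order_a)
    ann_b, seqs_b, gaps_b = _place_species(cfg, rng, "B", layout, order_b)

    # choose intergenic slots in species A (between consecutive genes)
    slot_keys = sorted(gaps_a)
    chosen = rng.choice(len(slot_keys), size=cfg.n_planted_lncRNAs, replace=False)
    margin = 30
    lnc_a = Annotation()
    lnc_b = Annotation()
    for li, si in enumerate(sorted(int(x) for x in chosen)):
        left, right = slot_keys[si]
        chrom, gs, ge = gaps_a[(left, right)]
        gap_len = ge - gs + 1
        length = None
        for _try in range(50):
            cand = int(rng.integers(cfg.lncRNA_len[0], cfg.lncRNA_len[1] + 1))
            if cand <= gap_len - 2 * margin:
                length = cand
                break
        if length is None:
            raise ValueError(
                f"intergenic slot {left}-{right} ({gap_len} bp) cannot hold a "
                f"lncRNA from range {cfg.lncRNA_len}"
            )
        # enhancer-like geometry: plant a few tens of bp from one gene edge
        near_left = bool(rng.random() < 0.5)
        if near_left:
            a_start = gs + margin
        else:
            a_start = ge - margin - length + 1
        a_end = a_start + length - 1
        seq_a = seqs_a[chrom][a_start - 1 : a_end]

        rec = PlantedLncRNA(
            lnc_id=f"LNC{li:03d}",
            chrom=chrom,
            a_start=a_start,
            a_end=a_end,
            flank_left=left,
            flank_right=right,
            sequence_a=seq_a,
            planted_in_b=False,
            adjacent_symbol=left if near_left else right,
        )

        # plant the diverged copy in B if the flanking pair is still adjacent
        if (left, right) in gaps_b:
            b_chrom, bgs, bge = gaps_b[(left, right)]
            b_gap = bge - bgs + 1
            if b_gap - 2 * margin >= length:
                seq_b, nsub = mutate(seq_a, cfg.divergence_mu, rng)
                boff = int(rng.integers(0, b_gap - 2 * margin - length + 1))
                b_start = bgs + margin + boff
                b_end = b_start + length - 1
                seqs_b[b_chrom] = _splice(seqs_b[b_chrom], b_start, b_end, seq_b)
                rec.planted_in_b = True
                rec.b_chrom = b_chrom
                rec.b_start = b_start
                rec.b_end = b_end
                rec.sequence_b = seq_b
                rec.n_substitutions = nsub

        rec.captured_a = bool(rng.random() < cfg.p_capture)
        rec.captured_b = rec.planted_in_b and bool(rng.random() < cfg.p_capture)

        # mono-exonic assembled models; strand unknown half the time, as for
        # unspliced transcripts whose strand the aligner cannot infer
        strand = "+" if rng.random() < 0.5 else "."
        if rec.captured_a:
            gid = f"A_{rec.lnc_id}"
            lnc_a.add_gene(
                GeneRecord(gid, "", chrom, a_start, a_end, strand, "lncRNA")
            )
            lnc_a.add_transcript(
                TranscriptModel(f"{gid}.1", gid, chrom, strand, ((a_start, a_end),))
            )
        if rec.captured_b:
            gid = f"B_{rec.lnc_id}"
            lnc_b.add_gene(
                GeneRecord(
                    gid, "", rec.b_chrom, rec.b_start, rec.b_end, strand, "lncRNA"
                )
            )
            lnc_b.add_transcript(
                TranscriptModel(
                    f"{gid}.1", gid, rec.b_chrom, strand, ((rec.b_start, rec.b_end),)
                )
            )
        truth.ortholog_pairs.append(rec)

    a = SpeciesData("A", GenomeSequence(seqs_a), ann_a, lnc_a)
    b = SpeciesData("B", GenomeSequence(seqs_b), ann_b, lnc_b)
    return a, b, truth


def simulate_expression(
    cfg: SimulationConfig,
    annotation: Annotation,
    coexpressed_pairs: Optional[List[Tuple[str, str]]] = None,
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame, SyntheticTruth]:
    """Per-sample Kallisto-style abundance tables plus metadata and truth.

    Housekeeping genes share a flat tissue profile; tissue-specific genes are
    nonzero in exactly one tissue; each co-expressed (lncRNA, coding) pair
    shares a latent tissue profile with independent lognormal noise. Every
    sample's TPM column sums to 1e6 and est_counts are consistent with
    tpm x eff_length up to one per-sample scale factor.
    """
    if len(cfg.tissues) < 2 or cfg.replicates_per_tissue < 2:
        raise ValueError("need >= 2 tissues and >= 2 replicates")
    rng = np.random.default_rng(cfg.seed + _OFF_EXPRESSION)
    truth = SyntheticTruth()

    transcripts = sorted(annotation.transcripts.values(), key=lambda t: t.transcript_id)
    tx_ids = [t.transcript_id for t in transcripts]
    lengths = np.array([t.length for t in transcripts], dtype=float)
    eff = np.maximum(lengths - 200.0, 1.0)
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}

    coding = sorted(
        g.gene_id
        for g in annotation.genes.values()
        if g.biotype == "protein_coding"
    )
    lncs = sorted(
        g.gene_id for g in annotation.genes.values() if g.biotype == "lncRNA"
    )
    pairs = list(coexpressed_pairs or [])
    flat = [g for p in pairs for g in p]
    paired = set(flat)
    if len(flat) != len(paired):
        raise ValueError("a gene may belong to at most one co-expressed pair")
    free_coding = [g for g in coding if g not in paired]
    need = cfg.n_housekeeping + cfg.n_tissue_specific
    if len(free_coding) < need:
        raise ValueError(
            f"{len(free_coding)} unpaired coding genes < {need} planted categories"
        )
    pick = rng.choice(len(free_coding), size=need, replace=False)
    hk = [free_coding[i] for i in sorted(pick[: cfg.n_housekeeping])]
    ts = [free_coding[i] for i in sorted(pick[cfg.n_housekeeping :])]

    tissue_names = [t for t, _g in cfg.tissues]
    n_t = len(tissue_names)

    # per-gene mean profile over tissues
    profile: Dict[str, np.ndarray] = {}
    for g in hk:
        profile[g] = np.full(n_t, 100.0)
        truth.specific_genes[g] = "housekeeping"
    for g in ts:
        t_idx = int(rng.integers(n_t))
        v = np.zeros(n_t)
        v[t_idx] = 500.0
        profile[g] = v
        truth.specific_genes[g] = f"tissue_specific:{tissue_names[t_idx]}"
    for pi, (lnc, gene) in enumerate(pairs):
        latent = 30.0 * np.exp(rng.normal(0.0, 2.0, size=n_t))
        profile[lnc] = latent * float(np.exp(rng.normal(0.0, 0.2)))
        profile[gene] = latent * float(np.exp(rng.normal(0.0, 0.2)))
        truth.coexpressed_pairs.append((lnc, gene, f"program{pi}"))
    for g in sorted(set(gene_of.values())):
        if g not in profile:
            base = float(np.exp(rng.normal(np.log(50.0), 1.0)))
            profile[g] = base * np.exp(rng.normal(0.0, 0.3, size=n_t))

    meta_rows = []
    tables: Dict[str, pd.DataFrame] = {}
    for ti, (tissue, group) in enumerate(cfg.tissues):
        for rep in range(1, cfg.replicates_per_tissue + 1):
            sample = f"{tissue}_r{rep}"
            meta_rows.append(
                dict(sample=sample, tissue=tissue, replicate=rep, group=group)
            )
            raw = np.array(
                [
                    profile[gene_of[tid]][ti]
                    * float(np.exp(rng.normal(0.0, cfg.noise_sd)))
                    if profile[gene_of[tid]][ti] > 0
                    else 0.0
                    for tid in tx_ids
                ]
            )
            total = raw.sum()
            tpm = raw / total * 1e6 if total > 0 else raw
            n_frags = float(rng.integers(1_000_000, 2_000_001))
            w = tpm * eff
            counts = w / w.sum() * n_frags if w.sum() > 0 else w
            tables[sample] = pd.DataFrame(
                dict(
                    target_id=tx_ids,
                    length=lengths.astype(int),
                    eff_length=eff,
                    est_counts=counts,
                    tpm=tpm,
                )
            )
    meta = pd.DataFrame(meta_rows)
    return tables, meta, truth


def simulate_coding_scores(
    cfg: SimulationConfig,
    candidate_ids: Sequence[str],
    planted_coding_ids: Sequence[str],
) -> pd.DataFrame:
    """Coding-potential score table with planted coding contaminants.

    Clean candidates satisfy every shortlist criterion (CPC < -0.5, CPAT on
    the non-coding side of 0.58, PLEK 'noncoding', no homology hits); each
    planted contaminant violates at least one, chosen at random.
    """
    planted = set(planted_coding_ids)
    unknown = planted - set(candidate_ids)
    if unknown:
        raise ValueError(f"planted_coding ids not in candidates: {sorted(unknown)}")
    rng = np.random.default_rng(cfg.seed + _OFF_SCORES)
    rows = []
    for mid in candidate_ids:
        row = dict(
            model_id=mid,
            cpc_score=float(rng.uniform(-3.0, -1.0)),
            cpat_prob=float(rng.uniform(0.01, 0.30)),
            plek_label="noncoding",
            blastp_best_evalue=np.nan,
            hmmer_best_evalue=np.nan,
        )
        if mid in planted:
            modes = [m for m in range(5) if rng.random() < 0.5]
            if not modes:
                modes = [int(rng.integers(5))]
            if 0 in modes:
                row["cpc_score"] = float(rng.uniform(0.5, 3.0))
            if 1 in modes:
                row["cpat_prob"] = float(rng.uniform(0.70, 0.99))
            if 2 in modes:
                row["plek_label"] = "coding"
            if 3 in modes:
                row["blastp_best_evalue"] = float(10.0 ** rng.uniform(-12, -6))
            if 4 in modes:
                row["hmmer_best_evalue"] = float(10.0 ** rng.uniform(-12, -6))
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_library_captures(
    cfg: SimulationConfig,
    annotation: Annotation,
) -> Tuple[Dict[str, List[TranscriptModel]], pd.DataFrame]:
    """Per-individual transcript captures with dropout.

    Each transcript is fully captured in an individual's assembly with
    probability ``1 - dropout_p``; otherwise it is absent (half the time) or
    truncated (one exon dropped, or 40% of a mono-exon trimmed), which breaks
    precise reconstruction. The returned presence table records full capture.
    """
    if cfg.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    rng = np.random.default_rng(cfg.seed + _OFF_CAPTURES)
    transcripts = sorted(annotation.transcripts.values(), key=lambda t: t.transcript_id)
    individuals = [f"ind{i + 1}" for i in range(cfg.n_individuals)]
    captures: Dict[str, List[TranscriptModel]] = {ind: [] for ind in individuals}
    presence = pd.DataFrame(
        False, index=[t.transcript_id for t in transcripts], columns=individuals
    )
    for ind in individuals:
        for t in transcripts:
            u = rng.random()
            if u < 1.0 - cfg.dropout_p:
                captures[ind].append(t)
                presence.loc[t.transcript_id, ind] = True
            elif u < 1.0 - cfg.dropout_p / 2.0:
                captures[ind].append(_truncate(t, rng))
            # else: absent from this individual's assembly
    return captures, presence


def _truncate(t: TranscriptModel, rng: np.random.Generator) -> TranscriptModel:
    if t.n_exons > 1:
        drop_first = rng.random() < 0.5
        exons = t.exons[1:] if drop_first else t.exons[:-1]
    else:
        s, e = t.exons[0]
        cut = max(1, int(0.4 * (e - s + 1)))
        exons = ((s + cut, e),) if rng.random() < 0.5 else ((s, e - cut),)
    return TranscriptModel(
        transcript_id=t.transcript_id + "_trunc",
        gene_id=t.gene_id,
        chrom=t.chrom,
        strand=t.strand,
        exons=exons,
    )


def simulate_program_matrix(
    k: int,
    genes_per_program: int,
    n_samples: int = 24,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Expression matrix with ``k`` disjoint co-expression programs.

    Genes within a program share a latent sample profile times independent
    lognormal noise; the default noise keeps within-program Pearson r on the
    raw TPM scale above the 0.95 graph threshold (replicate-level variation
    of ~10%), while between-program r stays near zero. Used to probe
    Markov-clustering recovery.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    labels: Dict[str, int] = {}
    for p in range(k):
        latent = np.exp(rng.normal(0.0, 2.0, size=n_samples))
        for g in range(genes_per_program):
            gid = f"P{p}_g{g}"
            rows[gid] = latent * np.exp(rng.normal(0.0, noise_sd, size=n_samples))
            labels[gid] = p
    mat = pd.DataFrame(
        rows, index=[f"s{j}" for j in range(n_samples)]
    ).T
    return mat, labels
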