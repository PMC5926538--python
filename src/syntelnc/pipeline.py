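"""End-to-end orchestration: filter -> classify -> synteny -> crossmap ->
quantify -> network -> proximity -> reconstruct, with a manifest of inputs
and parameters so a rerun with the same seed is byte-identical.

The demo runs the whole chain on a synthetic species pair with known ground
truth; the stage functions are also reusable on user-supplied files through
the CLI.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import annotation_io as aio
from . import candidate_filter as cf
from . import crossmap as cm
from . import expression as ex
from . import network as nw
from . import positional as pc
from . import proximity as px
from . import reconstruction as rc
from . import synteny as sy
from .models import Annotation
from .synthetic import SimulationConfig, simulate_coding_scores, simulate_expression, \
    simulate_genome_pair, simulate_library_captures

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat run configuration; unknown keys are rejected at load time."""

    seed: int = 0
    out_dir: str = "syntelnc_out"
    min_len_multi: int = 200
    min_len_mono: int = 500
    max_overlap_bp: int = 1
    cpc_max: float = -0.5
    cpat_threshold: float = 0.58
    cpat_higher_is_noncoding: bool = False
    evalue_threshold: float = 1e-5
    tss_window: int = 5000
    min_run: int = 20
    correlation_threshold: float = 0.95
    inflation: float = 2.2
    s_randomizations: int = 1000
    contaminant_fraction: float = 0.2
    n_reconstruction_models: int = 40

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def thresholds(self) -> cf.FilterThresholds:
        return cf.FilterThresholds(
            min_len_multi=self.min_len_multi,
            min_len_mono=self.min_len_mono,
            max_overlap_bp=self.max_overlap_bp,
            cpc_max=self.cpc_max,
            cpat_threshold=self.cpat_threshold,
            cpat_higher_is_noncoding=self.cpat_higher_is_noncoding,
            evalue_threshold=self.evalue_threshold,
        )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_demo(
    config: Optional[PipelineConfig] = None,
    sim: Optional[SimulationConfig] = None,
) -> Dict[str, object]:
    """Full synthetic run; returns all in-memory stage results keyed by stage."""
    config = config or PipelineConfig()
    sim = sim or SimulationConfig(seed=config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {"config": config, "sim": sim}

    # --- simulate ---------------------------------------------------------
    sp_a, sp_b, truth = simulate_genome_pair(sim)
    results.update(species_a=sp_a, species_b=sp_b, truth=truth)
    aio.write_fasta(sp_a.genome, str(out / "speciesA.fa"))
    aio.write_fasta(sp_b.genome, str(out / "speciesB.fa"))
    aio.write_gtf(sp_a.reference, str(out / "speciesA.ref.gtf"))
    aio.write_gtf(sp_b.reference, str(out / "speciesB.ref.gtf"))
    aio.write_gtf(sp_a.lnc_models, str(out / "speciesA.lnc.gtf"))
    aio.write_gtf(sp_b.lnc_models, str(out / "speciesB.lnc.gtf"))

    # --- longlist / shortlist --------------------------------------------
    rng = np.random.default_rng(sim.seed + 77)
    candidates = sorted(sp_a.lnc_models.genes)
    n_cont = int(round(config.contaminant_fraction * len(candidates)))
    contaminants = sorted(
        candidates[i] for i in rng.choice(len(candidates), size=n_cont, replace=False)
    )
    scores = simulate_coding_scores(sim, candidates, contaminants)
    _write_tsv(scores, out / "speciesA.scores.tsv")
    longlist, long_dec = cf.build_longlist(
        sp_a.lnc_models, sp_a.reference, thresholds=config.thresholds()
    )
    shortlist, short_dec = cf.build_shortlist(longlist, scores, config.thresholds())
    mono = {
        gid
        for gid in shortlist
        if all(t.n_exons == 1 for t in sp_a.lnc_models.transcripts_of(gid))
    }
    summary = cf.summarize_filters(long_dec + short_dec, mono)
    _write_tsv(summary, out / "filter_summary.tsv")
    results.update(
        contaminants=contaminants,
        longlist=longlist,
        shortlist=shortlist,
        filter_summary=summary,
    )

    shortlisted = Annotation()
    for gid in shortlist:
        shortlisted.add_gene(sp_a.lnc_models.genes[gid])
        for t in sp_a.lnc_models.transcripts_of(gid):
            shortlisted.add_transcript(t)

    # --- positional classification ---------------------------------------
    classes = pc.classify_lncRNAs(shortlisted, sp_a.reference)
    _write_tsv(pc.classification_table(classes), out / "speciesA.classes.tsv")
    results["classes"] = classes

    # --- synteny ----------------------------------------------------------
    triples_a = sy.enumerate_triples(sp_a.reference)
    triples_b = sy.enumerate_triples(sp_b.reference)
    blocks = sy.match_blocks(triples_a, triples_b)
    presence = sy.assign_lncRNAs_to_blocks(
        blocks, {"A": shortlisted, "B": sp_b.lnc_models}
    )
    _write_tsv(sy.synteny_report(blocks, presence), out / "synteny_report.tsv")
    results.update(blocks=blocks, presence=presence)

    # --- cross-species mapping -------------------------------------------
    seq_a = {
        gid: aio.extract_transcript_sequence(
            sp_a.lnc_models.transcripts_of(gid)[0], sp_a.genome
        )
        for gid in shortlisted.genes
    }
    seq_b = {
        gid: aio.extract_transcript_sequence(
            sp_b.lnc_models.transcripts_of(gid)[0], sp_b.genome
        )
        for gid in sp_b.lnc_models.genes
    }
    inf_ab, row_ab = cm.crossmap_pair(
        blocks, presence, seq_a, sp_b.genome, "A", "B", min_run=config.min_run
    )
    inf_ba, row_ba = cm.crossmap_pair(
        blocks, presence, seq_b, sp_a.genome, "B", "A", min_run=config.min_run
    )
    crossmap_table = pd.concat([row_ab, row_ba], ignore_index=True)
    _write_tsv(crossmap_table, out / "crossmap_report.tsv")
    aio.write_bed(
        [
            aio.BedInterval(i.chrom, i.start, i.end, i.id, i.run_length, i.strand)
            for i in inf_ab + inf_ba
        ],
        str(out / "inferred_lncRNAs.bed"),
    )
    results.update(
        inferred_ab=inf_ab, inferred_ba=inf_ba, crossmap_table=crossmap_table
    )

    # --- expression -------------------------------------------------------
    quantified = Annotation()
    for g in sp_a.reference.genes.values():
        quantified.add_gene(g)
    for t in sp_a.reference.transcripts.values():
        quantified.add_transcript(t)
    for gid in shortlisted.genes:
        quantified.add_gene(shortlisted.genes[gid])
        for t in shortlisted.transcripts_of(gid):
            quantified.add_transcript(t)
    pairs = []
    used_partners = set()
    sym_to_gid = {g.symbol: g.gene_id for g in sp_a.reference.genes.values()}
    for rec in truth.ortholog_pairs:
        lnc_gid = f"A_{rec.lnc_id}"
        partner = sym_to_gid[rec.adjacent_symbol]
        if rec.captured_a and lnc_gid in quantified.genes and partner not in used_partners:
            pairs.append((lnc_gid, partner))
            used_partners.add(partner)
        if len(pairs) >= sim.n_coexpressed_pairs:
            break
    tables, meta, expr_truth = simulate_expression(sim, quantified, pairs)
    tx2gene = {t.transcript_id: t.gene_id for t in quantified.transcripts.values()}
    matrix = ex.aggregate_to_genes(tables, tx2gene, meta)
    gene_summary = ex.summarize(matrix)
    _write_tsv(gene_summary, out / "gene_expression_summary.tsv")
    results.update(
        quantified=quantified,
        matrix=matrix,
        gene_summary=gene_summary,
        expr_truth=expr_truth,
        coexpressed_pairs=pairs,
    )

    # --- network ----------------------------------------------------------
    graph = nw.build_graph(matrix.tpm, threshold=config.correlation_threshold)
    assignment = nw.mcl_cluster(graph, inflation=config.inflation)
    biotype_of = {g.gene_id: g.biotype for g in quantified.genes.values()}
    composition = nw.cluster_composition(assignment, biotype_of)
    _write_tsv(composition, out / "cluster_composition.tsv")
    results.update(graph=graph, clusters=assignment, composition=composition)

    # --- proximity --------------------------------------------------------
    coding_genes = [
        g for g in quantified.genes.values() if g.biotype == "protein_coding"
    ]
    prox_rows = []
    for lnc_gid, _partner in pairs:
        lnc = quantified.genes[lnc_gid]
        interval = (lnc.chrom, lnc.start, lnc.end)
        cid = assignment.clusters.get(lnc_gid)
        cluster_members = [
            quantified.genes[g]
            for g in (assignment.members(cid) if cid is not None else [])
            if g in quantified.genes
            and quantified.genes[g].biotype == "protein_coding"
        ]
        same_chrom = [g for g in cluster_members if g.chrom == lnc.chrom]
        if not same_chrom:
            continue
        res = px.cluster_distance_test(
            lnc_gid,
            interval,
            same_chrom,
            [g for g in coding_genes if g.chrom == lnc.chrom],
            s=config.s_randomizations,
            seed=config.seed,
        )
        prox_rows.append(
            dict(
                lnc_id=res.lnc_id,
                observed=res.observed,
                q=res.q,
                p_literal=res.p_literal,
                p_empirical=res.p_empirical,
                s=res.s,
                y=res.comparator_set_size,
                seed=res.seed,
            )
        )
    prox_table = pd.DataFrame(prox_rows)
    if not prox_table.empty:
        prox_table["p_bh"] = px.benjamini_hochberg(prox_table["p_empirical"])
        _write_tsv(prox_table, out / "proximity_tests.tsv")
    results["proximity_table"] = prox_table

    # --- reconstruction ---------------------------------------------------
    ref_models = sorted(
        quantified.transcripts.values(), key=lambda t: t.transcript_id
    )[: config.n_reconstruction_models]
    ref_ann = Annotation()
    for t in ref_models:
        ref_ann.add_gene(quantified.genes[t.gene_id])
        ref_ann.add_transcript(t)
    captures, presence_lib = simulate_library_captures(sim, ref_ann)
    reports = rc.subset_reproducibility(captures, ref_models)
    _write_tsv(rc.report_table(reports), out / "reconstruction_report.tsv")
    results.update(
        captures=captures, library_presence=presence_lib, reconstruction=reports
    )

    # --- manifest ---------------------------------------------------------
    manifest = dict(
        parameters=dict(config=asdict(config), sim=_sim_dict(sim)),
        artifacts={
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def _sim_dict(sim: SimulationConfig) -> dict:
    d = asdict(sim)
    d["tissues"] = [list(t) for t in d["tissues"]]
    return d
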