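"""Global alignment, gapless identity runs, and cross-species inference."""

import random
import re

import numpy as np
import pytest

from syntelnc import crossmap as cm
from syntelnc import synteny as sy
from syntelnc.annotation_io import extract_transcript_sequence, reverse_complement
from syntelnc.models import GenomeSequence
from syntelnc.synthetic import SimulationConfig, mutate, simulate_genome_pair

MATCH, MIS, OPEN, EXT = 5.0, -4.0, 10.0, 0.5


def brute_force_score(q, t):
    """Exhaustive recursion over all global alignments; terminal gaps free."""
    n, m = len(q), len(t)
    best = [-1e18]

    def rec(i, j, score, state):
        if i == n and j == m:
            if score > best[0]:
                best[0] = score
            return
        if i < n and j < m:
            s = MATCH if q[i] == t[j] and q[i] != "N" else MIS
            rec(i + 1, j + 1, score + s, 0)
        if i < n:
            free = j == 0 or j == m
            cost = 0.0 if free else (EXT if state == 1 else OPEN + EXT)
            rec(i + 1, j, score - cost, 1)
        if j < m:
            free = i == 0 or i == n
            cost = 0.0 if free else (EXT if state == 2 else OPEN + EXT)
            rec(i, j + 1, score - cost, 2)

    rec(0, 0, 0.0, 0)
    return best[0]


def scan_longest_run(aq, at):
    """Independent regex-style scan for the longest clean identity run."""
    marks = "".join(
        "1" if a == b and a != "-" and a != "N" else "0" for a, b in zip(aq, at)
    )
    runs = re.findall(r"1+", marks)
    return max((len(r) for r in runs), default=0)


class TestNeedlemanWunsch:
    def test_identical_sequences(self):
        r = cm.needleman_wunsch("ACGTACGT", "ACGTACGT")
        assert r.score == 40.0
        assert r.identity_pct == 100.0
        assert r.longest_gapless_identity_run == 8
        assert r.target_aligned_span == (1, 8)

    def test_disjoint_alphabets(self):
        r = cm.needleman_wunsch("AAAA", "TTTT")
        assert r.identity_pct == 0.0
        assert r.longest_gapless_identity_run == 0

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            cm.needleman_wunsch("", "ACGT")

    def test_score_matches_bruteforce(self):
        rng = random.Random(41)
        for _ in range(150):
            q = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
            t = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
            assert cm.needleman_wunsch(q, t).score == pytest.approx(
                brute_force_score(q, t)
            )

    def test_alignment_rebuilds_inputs(self):
        rng = random.Random(42)
        for _ in range(100):
            q = "".join(rng.choice("ACGTN") for _ in range(rng.randint(1, 50)))
            t = "".join(rng.choice("ACGTN") for _ in range(rng.randint(1, 70)))
            r = cm.needleman_wunsch(q, t)
            assert r.aligned_query.replace("-", "") == q
            assert r.aligned_target.replace("-", "") == t
            assert len(r.aligned_query) == len(r.aligned_target)

    def test_score_agrees_with_biopython(self):
        aligner_mod = pytest.importorskip("Bio.Align")
        aligner = aligner_mod.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = MATCH
        aligner.mismatch_score = MIS
        aligner.open_gap_score = -(OPEN + EXT)
        aligner.extend_gap_score = -EXT
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
        rng = random.Random(43)
        for _ in range(40):
            q = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 30)))
            t = "".join(rng.choice("ACGT") for _ in range(rng.randint(3, 40)))
            assert cm.needleman_wunsch(q, t).score == pytest.approx(
                aligner.score(t, q)
            )

    def test_self_score_scales_with_length(self):
        rng = random.Random(44)
        for n in (1, 5, 20, 100):
            x = "".join(rng.choice("ACGT") for _ in range(n))
            assert cm.needleman_wunsch(x, x).score == 5.0 * n


class TestIdentityRun:
    def test_twenty_matches_flanked_by_mismatches(self):
        core = "A" * 20
        aq = "T" + core + "T"
        at = "G" + core + "G"
        assert cm.longest_identity_run(aq, at) == 20

    def test_gap_breaks_run(self):
        aq = "A" * 19 + "-" + "A" * 19
        at = "A" * 19 + "C" + "A" * 19
        assert cm.longest_identity_run(aq, at) == 19

    def test_n_never_matches(self):
        assert cm.longest_identity_run("ANA", "ANA") == 1
        assert cm.longest_identity_run("NNNN", "NNNN") == 0

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            cm.longest_identity_run("AC", "A")

    def test_matches_independent_scan(self):
        rng = random.Random(45)
        for _ in range(200):
            n = rng.randint(1, 60)
            aq = "".join(rng.choice("ACGTN-") for _ in range(n))
            at = "".join(rng.choice("ACGTN-") for _ in range(n))
            assert cm.longest_identity_run(aq, at) == scan_longest_run(aq, at)

    def test_strand_consistency(self):
        # the optimal score is symmetric under reverse-complementing both
        # sequences; for substitution-diverged homologs the optimal alignment
        # is the unique gapless diagonal, so the run length is symmetric too
        rng = np.random.default_rng(46)
        for _ in range(20):
            q = "".join(rng.choice(list("ACGT"), size=int(rng.integers(40, 90))))
            t, _n = mutate(q, 0.05, rng)
            fwd = cm.needleman_wunsch(q, t)
            rev = cm.needleman_wunsch(
                reverse_complement(q), reverse_complement(t)
            )
            assert fwd.score == rev.score
            assert (
                fwd.longest_gapless_identity_run
                == rev.longest_gapless_identity_run
            )
        for _ in range(20):  # unrelated pairs: score symmetry still holds
            q = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 60))))
            t = "".join(rng.choice(list("ACGT"), size=int(rng.integers(40, 90))))
            assert (
                cm.needleman_wunsch(q, t).score
                == cm.needleman_wunsch(
                    reverse_complement(q), reverse_complement(t)
                ).score
            )


def _one_block_setup(interval_seq, flank=2_000):
    """A single syntenic block whose upstream interval holds interval_seq."""
    from tests.conftest import make_annotation, make_gene

    g1_end = flank
    i_start = g1_end + 1
    i_end = g1_end + len(interval_seq)
    genes = [
        make_gene("g1", "A", "chr1", 1, g1_end, "+"),
        make_gene("g2", "B", "chr1", i_end + 1, i_end + flank, "+"),
        make_gene("g3", "C", "chr1", i_end + flank + 100, i_end + 2 * flank, "+"),
    ]
    ann = make_annotation(genes)
    triples = sy.enumerate_triples(ann)
    blocks = sy.match_blocks(triples, triples)
    rng = np.random.default_rng(1)
    chrom = (
        "".join(rng.choice(list("ACGT"), size=g1_end))
        + interval_seq
        + "".join(rng.choice(list("ACGT"), size=2 * flank + 100))
    )
    return blocks[0], GenomeSequence({"chr1": chrom}), (i_start, i_end)


class TestMapIntoBlock:
    def test_identical_planted_sequence_recovered(self):
        rng = np.random.default_rng(2)
        lnc = "".join(rng.choice(list("ACGT"), size=400))
        pad = "".join(rng.choice(list("ACGT"), size=300))
        pad2 = "".join(rng.choice(list("ACGT"), size=250))
        block, genome, (i_start, _e) = _one_block_setup(pad + lnc + pad2)
        inf = cm.map_lncRNA_into_block(
            "lnc1", lnc, block, "upstream", genome, target_species="B"
        )
        assert inf is not None
        assert inf.run_length == 400
        assert inf.sequence == lnc
        assert inf.start == i_start + 300
        assert inf.strand == "+"

    def test_minus_strand_copy_detected(self):
        rng = np.random.default_rng(3)
        lnc = "".join(rng.choice(list("ACGT"), size=300))
        planted = reverse_complement(lnc)
        pad = "".join(rng.choice(list("ACGT"), size=200))
        block, genome, _span = _one_block_setup(pad + planted + pad)
        inf = cm.map_lncRNA_into_block("lnc1", lnc, block, "upstream", genome)
        assert inf is not None
        assert inf.strand == "-"
        assert inf.sequence == planted

    def test_random_interval_rejected(self):
        rng = np.random.default_rng(4)
        lnc = "".join(rng.choice(list("ACGT"), size=400))
        noise = "".join(rng.choice(list("ACGT"), size=1_000))
        block, genome, _span = _one_block_setup(noise)
        assert (
            cm.map_lncRNA_into_block("lnc1", lnc, block, "upstream", genome)
            is None
        )

    def test_acceptance_implies_shared_20mer(self):
        rng = np.random.default_rng(5)
        for trial in range(30):
            lnc = "".join(rng.choice(list("ACGT"), size=250))
            mutated, _n = mutate(lnc, 0.08, rng)
            pad = "".join(rng.choice(list("ACGT"), size=150))
            block, genome, _span = _one_block_setup(pad + mutated + pad)
            inf = cm.map_lncRNA_into_block("lnc", lnc, block, "upstream", genome)
            if inf is None:
                continue
            interval = pad + mutated + pad
            seq = lnc if inf.strand == "+" else reverse_complement(lnc)
            shared = any(
                seq[k : k + 20] in interval for k in range(len(seq) - 19)
            )
            assert shared

    def test_run_extract_mode_is_contained(self):
        rng = np.random.default_rng(6)
        lnc = "".join(rng.choice(list("ACGT"), size=400))
        mutated, _ = mutate(lnc, 0.05, rng)
        pad = "".join(rng.choice(list("ACGT"), size=200))
        block, genome, _span = _one_block_setup(pad + mutated + pad)
        full = cm.map_lncRNA_into_block("l", lnc, block, "upstream", genome)
        run = cm.map_lncRNA_into_block(
            "l", lnc, block, "upstream", genome, extract="run"
        )
        if full is not None and run is not None:
            assert run.start >= full.start
            assert run.end <= full.end
            assert len(run.sequence) >= 20


class TestReporting:
    def test_pair_report_percentages(self):
        row = cm.pair_report_row("cattle", "goat", 2593, 1213, 5964, 1213).iloc[0]
        assert row["pct_mapped"] == 46.78
        assert row["pct_regions_inferred"] == 20.34

    def test_zero_inferences_row(self):
        row = cm.pair_report_row("A", "B", 0, 0, 10, 0).iloc[0]
        assert row["pct_mapped"] == 0.0
        assert row["pct_regions_inferred"] == 0.0

    def test_per_target_totals(self):
        import pandas as pd

        rows = pd.concat(
            [
                cm.pair_report_row("goat", "cattle", 2593, 286, 5964, 286),
                cm.pair_report_row("human", "cattle", 163, 16, 886, 16),
                cm.pair_report_row("sheep", "cattle", 2939, 775, 5854, 775),
            ],
            ignore_index=True,
        )
        totals = cm.aggregate_mapped_by_target(rows)
        assert totals["cattle"] == 1077
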