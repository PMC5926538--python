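"""Longlist/shortlist cascade and the longest-ORF finder."""

import random
import re

import numpy as np
import pandas as pd
import pytest

from syntelnc import candidate_filter as cf
from syntelnc.annotation_io import reverse_complement
from tests.conftest import make_annotation, make_gene, make_transcript


def brute_force_longest_orf(seq, search_reverse=False):
    """Enumerate every ATG..stop span directly; independent of the scanner."""
    best = None
    strands = [(0, seq)]
    if search_reverse:
        strands.append((3, reverse_complement(seq)))
    for base, s in strands:
        for i in range(len(s) - 2):
            if s[i : i + 3] != "ATG":
                continue
            for j in range(i + 3, len(s) - 2, 3):
                if s[j : j + 3] in cf.STOPS:
                    length = j + 3 - i
                    if best is None or length > best[0]:
                        best = (length, base, i)
                    break
    return best  # (length, strand_base, start) or None


class TestLongestOrf:
    def test_minimal_orf(self):
        orf = cf.find_longest_orf("ATGAAATAA")
        assert orf.length == 9
        assert orf.peptide == "MK"

    def test_no_orf(self):
        assert cf.find_longest_orf("CCCCCC") is None

    def test_longer_orf_wins(self):
        # 45-nt ORF in frame 0 after a 30-nt ORF
        short = "ATG" + "AAA" * 8 + "TAA"  # 30 nt
        long_ = "ATG" + "GGG" * 13 + "TGA"  # 45 nt
        seq = short + "C" + long_
        orf = cf.find_longest_orf(seq)
        assert orf.length == 45

    def test_matches_bruteforce_enumeration(self):
        rng = random.Random(13)
        for _ in range(200):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 80)))
            rev = rng.random() < 0.5
            got = cf.find_longest_orf(seq, search_reverse=rev)
            exp = brute_force_longest_orf(seq, search_reverse=rev)
            if exp is None:
                assert got is None
            else:
                assert got is not None and got.length == exp[0]

    def test_reverse_strand_found_only_when_requested(self):
        seq = reverse_complement("ATG" + "CAT" * 20 + "TAA")
        assert cf.find_longest_orf(seq, search_reverse=False) is None or (
            cf.find_longest_orf(seq, search_reverse=False).length
            < cf.find_longest_orf(seq, search_reverse=True).length
        )
        assert cf.find_longest_orf(seq, search_reverse=True).length == 66


def _models_with(length, n_exons, strand="+", chrom="chr1", start=10_000, gid="m1"):
    if n_exons == 1:
        exons = ((start, start + length - 1),)
    else:
        half = length // 2
        exons = (
            (start, start + half - 1),
            (start + half + 100, start + half + 100 + (length - half) - 1),
        )
    g = make_gene(gid, "", chrom, exons[0][0], exons[-1][1], strand, "lncRNA")
    t = make_transcript(f"{gid}.1", gid, chrom, strand, exons)
    return make_annotation([g], [t])


REFERENCE = make_annotation(
    [
        make_gene("pc1", "PC1", "chr1", 1000, 2000, "+", "protein_coding"),
        make_gene("ps1", "PS1", "chr1", 50_000, 51_000, "-", "pseudogene"),
    ]
)


class TestLonglist:
    def test_short_multi_exon_excluded(self):
        models = _models_with(180, 2)
        retained, dec = cf.build_longlist(models, REFERENCE)
        assert retained == []
        assert dec[0].reason == "too_short"

    def test_short_mono_exon_excluded(self):
        models = _models_with(450, 1)
        _, dec = cf.build_longlist(models, REFERENCE)
        assert dec[0].reason == "single_exon_too_short"

    def test_boundary_lengths(self):
        # multi-exon: strictly more than 200; mono-exon: at least 500
        assert cf.build_longlist(_models_with(201, 2), REFERENCE)[0] == ["m1"]
        assert cf.build_longlist(_models_with(200, 2), REFERENCE)[0] == []
        assert cf.build_longlist(_models_with(500, 1), REFERENCE)[0] == ["m1"]
        assert cf.build_longlist(_models_with(499, 1), REFERENCE)[0] == []

    def test_one_bp_overlap_tolerated(self):
        # 600 bp mono-exon ending exactly 1 bp into the coding span
        models = _models_with(600, 1, start=401)  # spans 401..1000, pc1 at 1000
        retained, _ = cf.build_longlist(models, REFERENCE)
        assert retained == ["m1"]

    def test_two_bp_overlap_excluded_same_strand_only(self):
        models = _models_with(600, 1, start=402)  # spans 402..1001: 2 bp overlap
        _, dec = cf.build_longlist(models, REFERENCE)
        assert dec[0].reason == "overlaps_coding"
        # opposite strand: tolerated
        opp = _models_with(600, 1, start=402, strand="-")
        retained, _ = cf.build_longlist(opp, REFERENCE)
        assert retained == ["m1"]

    def test_unknown_strand_screened_against_both(self):
        unk = _models_with(600, 1, start=402, strand=".")
        _, dec = cf.build_longlist(unk, REFERENCE)
        assert dec[0].reason == "overlaps_coding"

    def test_multi_transcript_excluded(self):
        models = _models_with(600, 1)
        models.add_transcript(
            make_transcript("m1.2", "m1", "chr1", "+", ((10_000, 10_599),))
        )
        _, dec = cf.build_longlist(models, REFERENCE)
        assert dec[0].reason == "multi_transcript"

    def test_exclusion_list(self):
        models = _models_with(600, 1)
        _, dec = cf.build_longlist(models, REFERENCE, exclusion_ids={"m1"})
        assert dec[0].reason == "previously_coding"

    def test_unknown_chromosome_raises(self):
        models = _models_with(600, 1, chrom="chrUn")
        with pytest.raises(ValueError, match="chrUn"):
            cf.build_longlist(models, REFERENCE)


def _score_row(mid="m1", cpc=-1.0, cpat=0.1, plek="noncoding", blastp=np.nan, hmmer=np.nan):
    return dict(
        model_id=mid,
        cpc_score=cpc,
        cpat_prob=cpat,
        plek_label=plek,
        blastp_best_evalue=blastp,
        hmmer_best_evalue=hmmer,
    )


class TestShortlist:
    def test_clean_record_retained(self):
        scores = pd.DataFrame([_score_row()])
        retained, _ = cf.build_shortlist(["m1"], scores)
        assert retained == ["m1"]

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            (dict(cpc=-0.5), "cpc_fail"),  # strict inequality at the boundary
            (dict(cpc=0.3), "cpc_fail"),
            (dict(cpat=0.58), "cpat_fail"),
            (dict(cpat=0.9), "cpat_fail"),
            (dict(plek="coding"), "plek_fail"),
            (dict(blastp=1e-6), "blastp_hit"),
            (dict(blastp=1e-5), "blastp_hit"),  # threshold value itself is a hit
            (dict(hmmer=1e-6), "hmmer_hit"),
        ],
    )
    def test_single_criterion_failures(self, kwargs, reason):
        scores = pd.DataFrame([_score_row(**kwargs)])
        retained, dec = cf.build_shortlist(["m1"], scores)
        assert retained == []
        assert dec[0].reason == reason

    def test_evalue_above_threshold_is_no_hit(self):
        scores = pd.DataFrame([_score_row(blastp=1e-4, hmmer=0.5)])
        retained, _ = cf.build_shortlist(["m1"], scores)
        assert retained == ["m1"]

    def test_missing_record_raises_with_ids(self):
        scores = pd.DataFrame([_score_row("other")])
        with pytest.raises(ValueError, match="m1"):
            cf.build_shortlist(["m1"], scores)

    def test_cpat_direction_switch(self):
        th = cf.FilterThresholds(cpat_higher_is_noncoding=True)
        scores = pd.DataFrame([_score_row(cpat=0.9)])
        retained, _ = cf.build_shortlist(["m1"], scores, th)
        assert retained == ["m1"]
        scores = pd.DataFrame([_score_row(cpat=0.1)])
        retained, dec = cf.build_shortlist(["m1"], scores, th)
        assert dec[0].reason == "cpat_fail"

    def test_order_deterministic_under_permutation(self):
        rng = random.Random(3)
        rows = [
            _score_row(
                f"m{i}",
                cpc=rng.choice([-2.0, -0.5, 1.0]),
                cpat=rng.choice([0.1, 0.7]),
                plek=rng.choice(["noncoding", "coding"]),
                blastp=rng.choice([np.nan, 1e-8]),
            )
            for i in range(30)
        ]
        ids = [r["model_id"] for r in rows]
        base = cf.build_shortlist(ids, pd.DataFrame(rows))
        rng.shuffle(rows)
        shuffled_ids = list(ids)
        rng.shuffle(shuffled_ids)
        again = cf.build_shortlist(shuffled_ids, pd.DataFrame(rows))
        assert base[0] == again[0]
        assert {(d.model_id, d.reason) for d in base[1]} == {
            (d.model_id, d.reason) for d in again[1]
        }


class TestSummaries:
    def test_accounting_style_percentages(self):
        decisions = [
            cf.FilterDecision(f"m{i}", "longlist", "retained") for i in range(30_677)
        ] + [
            cf.FilterDecision(f"m{i}", "shortlist", "retained" if i < 12_296 else "excluded",
                              "" if i < 12_296 else "cpc_fail")
            for i in range(30_677)
        ]
        mono = {f"m{i}" for i in range(6_956)}
        row = cf.summarize_filters(decisions, mono).iloc[0]
        assert row["longlist_size"] == 30_677
        assert row["shortlist_size"] == 12_296
        assert row["shortlist_pct"] == 40
        assert row["mono_exonic_pct"] == 57

    def test_empty_decisions(self):
        row = cf.summarize_filters([]).iloc[0]
        assert row["longlist_size"] == 0
        assert row["shortlist_size"] == 0
        assert row["shortlist_pct"] == 0


class TestSyntheticPlantedTruth:
    def test_contaminants_excluded_clean_retained(self, small_sim_config, genome_pair):
        from syntelnc.synthetic import simulate_coding_scores

        sp_a, _b, truth = genome_pair
        candidates = sorted(sp_a.lnc_models.genes)
        contaminants = candidates[::3]
        scores = simulate_coding_scores(small_sim_config, candidates, contaminants)
        retained, long_dec = cf.build_longlist(sp_a.lnc_models, sp_a.reference)
        assert set(retained) == set(candidates)  # structurally clean by design
        short, _ = cf.build_shortlist(retained, scores)
        assert set(short) == set(candidates) - set(contaminants)

    def test_no_shortlisted_model_overlaps_coding(self, genome_pair):
        sp_a, _b, _t = genome_pair
        retained, _ = cf.build_longlist(sp_a.lnc_models, sp_a.reference)
        coding = [
            g
            for g in sp_a.reference.genes.values()
            if g.biotype in ("protein_coding", "pseudogene")
        ]
        for gid in retained:
            m = sp_a.lnc_models.genes[gid]
            for g in coding:
                if g.chrom != m.chrom:
                    continue
                ov = min(m.end, g.end) - max(m.start, g.start) + 1
                same = m.strand == "." or m.strand == g.strand
                if same:
                    assert ov <= 1
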