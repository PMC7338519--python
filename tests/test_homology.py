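"""Seed-and-extend homology search, the Smith-Waterman oracle, and
locus-context classification."""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align

from conftest import random_dna
from fernplast.homology import (HomologySearchParams, Scoring,
                                classify_locus_context, seed_extend_search,
                                smith_waterman, summarize_contexts)
from fernplast.model import (Feature, FeatureKind, Interval, Plastome, find_igs,
                             revcomp)
from fernplast.simulate import (CassetteSpec, SimConfig, plant_morffo_cassette,
                                simulate_plastome)
from fernplast.stemloops import find_stem_loops


def _biopython_local_score(a: str, b: str, sc: Scoring) -> float:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = sc.match
    al.mismatch_score = sc.mismatch
    al.open_gap_score = sc.gap_open + sc.gap_extend
    al.extend_gap_score = sc.gap_extend
    return al.score(a, b)


class TestSmithWaterman:
    def test_identical_short(self):
        aln = smith_waterman("ACGT", "ACGT")
        assert aln.score == 4 and aln.identity == 1.0 and aln.aln_len == 4

    def test_disjoint_content_scores_zero(self):
        aln = smith_waterman("AAAA", "GGGG")
        assert aln.score == 0 and aln.aligned_a == ""

    def test_gap_cost_scheme(self):
        # deleting 2 bases costs open + 2*extend = 6; 20 matches remain
        a = "ACGTACGTACCGTTGCAGCATT"
        b = a[:10] + a[12:]
        aln = smith_waterman(a, b)
        assert aln.score == 20 - 6

    @pytest.mark.parametrize("seed", range(10))
    def test_score_matches_biopython_local_aligner(self, seed):
        a = random_dna(seed, 300)
        b = random_dna(seed + 100, 300)
        sc = Scoring()
        assert smith_waterman(a, b, sc).score == _biopython_local_score(a, b, sc)

    def test_cell_cap(self):
        with pytest.raises(ValueError):
            smith_waterman("A" * 2000, "A" * 2000, max_cells=10_000)


@pytest.fixture(scope="module")
def target():
    p, _ = simulate_plastome(SimConfig(seed=31, genome_bp=60_000, ir_bp=9_000,
                                       ssc_bp=12_000))
    return p


class TestSeedExtend:
    def test_verbatim_150bp_found_exactly(self, target):
        start = 5_000
        q = target.sequence[start : start + 150]
        (h,) = seed_extend_search([("q", q)], target)
        assert (h.aln_len, h.identity, h.strand) == (150, 1.0, "+")
        assert h.target_interval == Interval(start, start + 150)
        assert h.query_interval == Interval(0, 150)

    def test_80bp_fails_length_rule(self, target):
        q = target.sequence[5_000 : 5_080]
        assert seed_extend_search([("q", q)], target) == []

    def test_reverse_strand_hit(self, target):
        q = revcomp(target.sequence[7_000 : 7_200])
        (h,) = seed_extend_search([("q", q)], target)
        assert h.strand == "-" and h.target_interval == Interval(7_000, 7_200)
        assert h.identity == 1.0

    def test_mutated_query_matches_sw_oracle(self, target):
        rng = np.random.default_rng(8)
        start = 20_000
        q = list(target.sequence[start : start + 300])
        for i in rng.choice(300, size=15, replace=False):  # 5% substitutions
            q[i] = "ACGT"[(("ACGT".index(q[i])) + 1) % 4]
        q = "".join(q)
        (h,) = seed_extend_search([("q", q)], target)
        oracle = smith_waterman(q, target.sequence[start - 50 : start + 350])
        assert h.score == oracle.score
        assert h.identity == pytest.approx(oracle.identity)

    def test_query_shorter_than_seed_skipped(self, target, caplog):
        assert seed_extend_search([("tiny", "ACGTACGT")], target) == []

    def test_hit_identity_rederivable(self, target):
        q = target.sequence[40_000:40_400]
        (h,) = seed_extend_search([("q", q)], target)
        assert h.recompute_identity() == pytest.approx(h.identity)

    @pytest.mark.parametrize("seed", range(5))
    def test_sw_score_upper_bounds_search_score(self, seed):
        a = random_dna(seed + 500, 200)
        b = random_dna(seed + 600, 200)
        t = Plastome(id="t", sequence=b, circular=False)
        params = HomologySearchParams(min_hit_len=12, min_identity=0.0)
        hits = seed_extend_search([("q", a)], t, params)
        best = smith_waterman(a, b).score
        for h in hits:
            assert h.score <= best

    def test_min_hit_len_below_seed_rejected(self):
        with pytest.raises(ValueError):
            HomologySearchParams(seed_k=12, min_hit_len=10).validate()


@pytest.fixture(scope="module")
def planted(target):
    p, truth = plant_morffo_cassette(target, CassetteSpec(), seed=9)
    hits = seed_extend_search([(truth.query_id, truth.query_seq)], p)
    sls = find_stem_loops(p.sequence)
    return p, truth, hits, sls


class TestContextClassification:
    def test_igs_locus_label_and_trna_flag(self, planted):
        p, truth, hits, sls = planted
        (locus,) = classify_locus_context(hits, p, sls)
        assert locus.locus_label == "rrn16-trnV-GAC"
        assert locus.trna_flanked  # trnV-GAC is a tRNA gene
        assert locus.stemloop_flanked
        assert len(locus.flanking_stemloops) >= 2

    def test_cds_cds_igs_not_trna_flanked(self):
        feats = [Feature("cdsA", FeatureKind.CDS, "+", [Interval(100, 400)]),
                 Feature("cdsB", FeatureKind.CDS, "+", [Interval(1600, 1900)])]
        seq = random_dna(77, 2000)
        p = Plastome(id="c", sequence=seq, circular=False, features=feats)
        q = seq[800:1000]
        hits = seed_extend_search([("q", q)], p)
        (locus,) = classify_locus_context(hits, p, [])
        assert locus.locus_label == "cdsA-cdsB"
        assert not locus.trna_flanked and not locus.stemloop_flanked

    def test_ablating_one_end_clears_flag(self, planted):
        # removing every stem-loop near the right end of the merged region
        # (including the planted one) must clear the both-ends flag
        p, truth, hits, sls = planted
        (locus,) = classify_locus_context(hits, p, sls)
        mend = locus.merged_region.end
        kept = [s for s in sls if s.end <= mend - 50 or s.start >= mend + 50]
        (ablated,) = classify_locus_context(hits, p, kept)
        assert not ablated.stemloop_flanked

    def test_unplaced_hit(self):
        seq = random_dna(88, 2000)
        p = Plastome(id="u", sequence=seq, circular=False, features=[])
        hits = seed_extend_search([("q", seq[500:700])], p)
        (locus,) = classify_locus_context(hits, p, [])
        assert locus.locus_label == "unplaced"
        assert not locus.trna_flanked and not locus.stemloop_flanked


class TestSummarize:
    def test_zero_loci(self):
        s = summarize_contexts([])
        assert s.n_loci == 0 and s.frac_trna_flanked is None

    def test_fraction_computed_from_counts(self):
        from fernplast.homology import MorffoLocus

        loci = [MorffoLocus(f"l{i}", [], i < 3, False, []) for i in range(4)]
        s = summarize_contexts(loci)
        assert s.n_trna_flanked == 3 and s.frac_trna_flanked == 0.75

    def test_binomial_recovery_of_planted_fraction(self):
        from fernplast.homology import MorffoLocus
        from scipy.stats import binom

        rng = np.random.default_rng(123)
        flags = rng.random(200) < 0.75
        loci = [MorffoLocus(f"l{i}", [], bool(f), False, [])
                for i, f in enumerate(flags)]
        s = summarize_contexts(loci)
        lo, hi = binom.ppf([0.005, 0.995], 200, 0.75) / 200
        assert lo <= s.frac_trna_flanked <= hi
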