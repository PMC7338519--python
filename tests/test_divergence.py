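"""Pairwise alignment, masked percent identity, and the intra- vs
inter-specific comparison."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_dna
from fernplast.divergence import (GAP_IN_A, MATCH, MISMATCH, AlignmentResult,
                                  align_pair, identity_comparison,
                                  percent_identity)
from fernplast.model import Interval, Plastome
from fernplast.simulate import DivergenceSpec, SimConfig, mutate_genome, simulate_plastome


def linear(seq: str, gid: str = "a") -> Plastome:
    return Plastome(id=gid, sequence=seq, circular=False)


class TestAlignPair:
    def test_identical_all_match(self):
        s = random_dna(1, 1000)
        aln = align_pair(linear(s, "a"), linear(s, "b"), mode="exact-dp")
        c = aln.counts()
        assert c["match"] == 1000 and c["mismatch"] == c["gap_in_a"] == 0

    def test_internal_deletion_gap_columns(self):
        s = random_dna(2, 1000)
        t = s[:500] + s[510:]
        aln = align_pair(linear(s, "a"), linear(t, "b"), mode="exact-dp")
        c = aln.counts()
        assert c["gap_in_b"] == 10 and c["match"] == 990 and c["mismatch"] == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair(linear(random_dna(1, 100)), Plastome(id="e", sequence=""))

    def test_position_maps_monotone_and_classes_partition(self):
        s = random_dna(3, 2000)
        a = linear(s, "a")
        b, _ = mutate_genome(a, DivergenceSpec(background_sub_rate=0.03,
                                               background_indel_rate=0.004),
                             seed=4, new_id="b")
        aln = align_pair(a, b, mode="exact-dp")
        for pos in (aln.pos_a, aln.pos_b):
            real = pos[pos >= 0]
            assert (np.diff(real) > 0).all()
        assert aln.n_columns == sum(aln.counts().values())

    @pytest.mark.parametrize("seed", range(10))
    def test_anchor_chain_equals_exact_dp(self, seed):
        a = linear(random_dna(700 + seed, 3000), "a")
        b, _ = mutate_genome(a, DivergenceSpec(background_sub_rate=0.045,
                                               background_indel_rate=0.005),
                             seed=800 + seed, new_id="b")
        e = percent_identity(align_pair(a, b, mode="exact-dp"))
        c = percent_identity(align_pair(a, b, mode="anchor-chain"))
        assert e.pct_identity == c.pct_identity

    def test_exact_cap_enforced(self):
        a = linear(random_dna(1, 20_000), "a")
        b = linear(random_dna(2, 20_000), "b")
        with pytest.raises(ValueError):
            align_pair(a, b, mode="exact-dp", exact_cap=10_000)


def synthetic_alignment(n=100, mismatch_at=(50,)):
    cls = np.full(n, MATCH, dtype=np.int8)
    for i in mismatch_at:
        cls[i] = MISMATCH
    pos = np.arange(n, dtype=np.int64)
    a = linear(random_dna(5, n), "a")
    b = linear(random_dna(6, n), "b")
    return AlignmentResult(a_id="a", b_id="b", cls=cls, pos_a=pos.copy(),
                           pos_b=pos.copy(), a_plastome=a, b_plastome=b)


class TestPercentIdentity:
    def test_unmasked_99(self):
        aln = synthetic_alignment()
        r = percent_identity(aln)
        assert (r.pct_identity, r.matches, r.counted_columns) == (99.0, 99, 100)

    def test_mask_covering_mismatch_gives_100(self):
        aln = synthetic_alignment()
        r = percent_identity(aln, masks=[("a", Interval(50, 51))])
        assert r.pct_identity == 100.0 and r.masked_columns == 1

    def test_gap_columns_count_as_differences(self):
        aln = synthetic_alignment()
        aln.cls[10] = GAP_IN_A
        aln.pos_a[10] = -1
        r = percent_identity(aln)
        assert r.pct_identity == 98.0
        r2 = percent_identity(aln, count_gap_columns=False)
        assert r2.counted_columns == 99

    def test_unknown_mask_locus_named_in_error(self):
        aln = synthetic_alignment()
        with pytest.raises(KeyError, match="trnZ"):
            percent_identity(aln, masks=[("a", "trnZ-rrn99")])

    def test_symmetry(self):
        a = linear(random_dna(7, 2000), "a")
        b, _ = mutate_genome(a, DivergenceSpec(background_sub_rate=0.02), 9, "b")
        ab = percent_identity(align_pair(a, b, mode="exact-dp"))
        ba = percent_identity(align_pair(b, a, mode="exact-dp"))
        assert ab.pct_identity == ba.pct_identity

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(cols=st.sets(st.integers(0, 99), min_size=1, max_size=20))
    def test_masking_monotonicity(self, cols):
        aln = synthetic_alignment(mismatch_at=tuple(range(0, 100, 7)))
        base = percent_identity(aln)
        masks = [("a", Interval(c, c + 1)) for c in cols]
        masked = percent_identity(aln, masks=masks)
        mm_cols = set(range(0, 100, 7))
        if cols <= mm_cols:  # masking only mismatches cannot lower identity
            assert masked.pct_identity >= base.pct_identity
        if not (cols & mm_cols):  # masking only matches cannot raise it
            assert masked.pct_identity <= base.pct_identity


class TestHotspotContrast:
    def test_masked_vs_unmasked(self):
        cfg = SimConfig(seed=41, genome_bp=60_000, ir_bp=9_000, ssc_bp=12_000)
        p, _ = simulate_plastome(cfg)
        p.id = "A"
        d = DivergenceSpec(background_sub_rate=0.018,
                           hotspot_locus="rrn16-trnV-GAC",
                           hotspot_sub_rate=0.3, hotspot_insert_bp=3000)
        q, _ = mutate_genome(p, d, seed=42, new_id="B")
        aln = align_pair(p, q, mode="anchor-chain")
        unmasked = percent_identity(aln)
        masked = percent_identity(aln, masks=[("A", "rrn16-trnV-GAC"),
                                              ("B", "rrn16-trnV-GAC")])
        assert abs(masked.pct_identity - 98.2) < 0.3
        assert unmasked.pct_identity <= masked.pct_identity - 2.0


class TestIdentityComparison:
    def test_identical_intraspecific_pair(self):
        s = random_dna(1, 2000)
        classes, summary = identity_comparison(
            [(linear(s, "x1"), linear(s, "x2"), "intraspecific")])
        assert classes[0].pct_identity == 100.0
        assert summary.loc["intraspecific", "min"] == 100.0

    def test_cohort_classes_disjoint(self):
        base = linear(random_dna(9, 4000), "sp1")
        pairs = []
        for i in range(3):
            m, _ = mutate_genome(base, DivergenceSpec(background_sub_rate=0.002),
                                 seed=20 + i, new_id=f"sp1_{i}")
            pairs.append((base, m, "intraspecific"))
        for i in range(3):
            m, _ = mutate_genome(base, DivergenceSpec(background_sub_rate=0.02),
                                 seed=30 + i, new_id=f"sp2_{i}")
            pairs.append((base, m, "interspecific"))
        _, summary = identity_comparison(pairs, mode="exact-dp")
        assert summary.loc["intraspecific", "min"] > summary.loc["interspecific", "max"]

    def test_empty_class_absent_from_summary(self):
        s = random_dna(1, 1000)
        _, summary = identity_comparison(
            [(linear(s, "x1"), linear(s, "x2"), "intraspecific")])
        assert "interspecific" not in summary.index

    def test_needs_pairs(self):
        with pytest.raises(ValueError):
            identity_comparison([])
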