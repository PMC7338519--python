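"""Data model, coordinate conventions, I/O round trips, IGS extraction."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_dna, toy_plastome
from fernplast.io import (read_fasta_gff3, read_genbank, write_fasta_gff3,
                          write_genbank)
from fernplast.model import (Feature, FeatureKind, Interval, Plastome,
                             extract_subsequence, find_igs, intergenic_regions,
                             revcomp, translate)

GENBANK_TOY = """\
LOCUS       toyrec                   300 bp    DNA     linear   PLN 01-JAN-2000
DEFINITION  toy record.
ACCESSION   toyrec
VERSION     toyrec
FEATURES             Location/Qualifiers
     source          1..300
     CDS             101..200
                     /gene="gA"
     tRNA            complement(210..280)
                     /gene="trnX"
ORIGIN
{origin}
//
"""


def _origin_block(seq: str) -> str:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        parts = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {parts}")
    return "\n".join(lines)


class TestIntervals:
    def test_span_and_validation(self):
        iv = Interval(100, 200)
        assert iv.span() == 100
        iv.validate(300)
        with pytest.raises(ValueError):
            Interval(200, 100).validate(300)

    def test_wrapping_span(self):
        iv = Interval(250, 50, wraps_origin=True)
        assert iv.span(300) == 100
        iv.validate(300)

    def test_contains_wrapping(self):
        iv = Interval(250, 50, wraps_origin=True)
        assert iv.contains(280) and iv.contains(10) and not iv.contains(100)


class TestGenBankIO:
    def test_one_based_conversion(self, tmp_path):
        seq = random_dna(1, 300)
        path = tmp_path / "toy.gb"
        path.write_text(GENBANK_TOY.format(origin=_origin_block(seq)))
        (p,) = read_genbank(path)
        ga = p.feature_by_name("gA")
        assert ga.location == [Interval(100, 200)]
        assert ga.kind is FeatureKind.CDS
        trn = p.feature_by_name("trnX")
        assert trn.location == [Interval(209, 280)]
        assert trn.strand == "-" and trn.is_trna

    def test_wrap_origin_join(self, tmp_path):
        p = Plastome(id="circ", sequence=random_dna(2, 9100), circular=True,
                     features=[Feature("wrapg", FeatureKind.CDS, "+",
                                       [Interval(9000, 50, wraps_origin=True)])])
        path = tmp_path / "w.gb"
        write_genbank([p], path)
        text = path.read_text()
        assert "join(9001..9100,1..50)" in text
        (q,) = read_genbank(path)
        assert q.feature_by_name("wrapg").location == [Interval(9000, 50, True)]
        assert q.circular

    def test_empty_feature_list_roundtrip(self, tmp_path):
        p = toy_plastome(5, 500)
        path = tmp_path / "e.gb"
        write_genbank([p], path)
        (q,) = read_genbank(path)
        assert q.sequence == p.sequence and q.features == []

    def test_malformed_raises(self, tmp_path):
        path = tmp_path / "bad.gb"
        path.write_text("LOCUS garbage\nnot a genbank record\n")
        with pytest.raises(ValueError):
            read_genbank(path)


class TestFastaGff3IO:
    def test_coordinate_conversion_and_strand(self, tmp_path, tiny_annotated):
        fa, gff = tmp_path / "a.fasta", tmp_path / "a.gff3"
        write_fasta_gff3([tiny_annotated], fa, gff)
        text = gff.read_text()
        assert "\t1\t100\t" in text  # Interval(0,100) -> 1-based 1..100
        (q,) = read_fasta_gff3(fa, gff)
        assert q.feature_by_name("g2").strand == "-"
        assert q.features == tiny_annotated.features
        assert q.circular

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_roundtrip_random_genomes_both_formats(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(300, 2000))
        feats = []
        pos = 0
        kinds = list(FeatureKind)
        for i in range(rng.integers(0, 6)):
            start = pos + int(rng.integers(1, 50))
            end = start + int(rng.integers(10, 120))
            if end >= n - 1:
                break
            feats.append(Feature(f"f{i}", kinds[int(rng.integers(len(kinds)))],
                                 "+-"[int(rng.integers(2))],
                                 [Interval(start, end)]))
            pos = end
        p = Plastome(id=f"r{seed}", sequence=random_dna(seed, n),
                     circular=bool(rng.integers(2)), features=feats)
        d = tmp_path_factory.mktemp("rt")
        write_genbank([p], d / "g.gb")
        (q,) = read_genbank(d / "g.gb")
        assert (q.sequence, q.circular, q.features) == (p.sequence, p.circular, p.features)
        write_fasta_gff3([p], d / "g.fa", d / "g.gff3")
        (q2,) = read_fasta_gff3(d / "g.fa", d / "g.gff3")
        assert (q2.sequence, q2.circular, q2.features) == (p.sequence, p.circular, p.features)


class TestExtractTranslate:
    def test_wrap_extraction(self):
        p = Plastome(id="x", sequence="AAACCCGGGT", circular=True)
        assert extract_subsequence(p, Interval(8, 2, wraps_origin=True)) == "GTAA"

    def test_minus_strand_is_revcomp(self):
        p = Plastome(id="x", sequence="ATGCATGCAT", circular=False)
        assert extract_subsequence(p, Interval(0, 4), "-") == "GCAT"

    def test_full_length_identity(self):
        p = toy_plastome(7, 100)
        assert extract_subsequence(p, Interval(0, 100)) == p.sequence

    def test_wrap_on_linear_rejected(self):
        p = toy_plastome(7, 100, circular=False)
        with pytest.raises(ValueError):
            extract_subsequence(p, Interval(90, 5, wraps_origin=True))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 1000), st.integers(0, 95), st.integers(1, 40))
    def test_minus_equals_revcomp_of_plus(self, seed, start, length):
        p = toy_plastome(seed, 200)
        iv = Interval(start, min(start + length, 200))
        assert extract_subsequence(p, iv, "-") == revcomp(extract_subsequence(p, iv, "+"))

    def test_translate_basic(self):
        assert translate("ATGGCTTAA") == "MA*"
        assert translate("") == ""
        with pytest.raises(ValueError):
            translate("ATGG")

    def test_translate_table11_gtg_internal_is_valine(self):
        # internal GTG codes V; only a flagged initiator would be M
        assert translate("ATGGTGTAA") == "MV*"


class TestIntergenicRegions:
    def test_simple_gap(self):
        feats = [Feature("g1", FeatureKind.CDS, "+", [Interval(0, 100)]),
                 Feature("g2", FeatureKind.CDS, "+", [Interval(150, 250)])]
        p = Plastome(id="x", sequence=random_dna(1, 300), circular=False,
                     features=feats)
        (rec,) = intergenic_regions(p)
        assert (rec.name, rec.interval, rec.length) == ("g1-g2", Interval(100, 150), 50)

    def test_abutting_genes_no_igs(self):
        feats = [Feature("g1", FeatureKind.CDS, "+", [Interval(0, 100)]),
                 Feature("g2", FeatureKind.CDS, "+", [Interval(100, 200)])]
        p = Plastome(id="x", sequence=random_dna(1, 200), circular=False,
                     features=feats)
        assert intergenic_regions(p) == []

    def test_circular_wrap_gap(self):
        feats = [Feature("first", FeatureKind.CDS, "+", [Interval(50, 150)]),
                 Feature("last", FeatureKind.CDS, "+", [Interval(900, 1000)])]
        p = Plastome(id="x", sequence=random_dna(1, 1000), circular=True,
                     features=feats)
        recs = intergenic_regions(p)
        wrap = [r for r in recs if r.name == "last-first"]
        assert len(wrap) == 1 and wrap[0].length == 50

    def test_overlapping_pair_skipped(self):
        feats = [Feature("g1", FeatureKind.CDS, "+", [Interval(0, 120)]),
                 Feature("g2", FeatureKind.CDS, "+", [Interval(100, 200)]),
                 Feature("g3", FeatureKind.CDS, "+", [Interval(250, 300)])]
        p = Plastome(id="x", sequence=random_dna(1, 400), circular=False,
                     features=feats)
        names = [r.name for r in intergenic_regions(p)]
        assert names == ["g2-g3"]

    def test_gaps_plus_genes_tile_genome(self):
        rng = np.random.default_rng(4)
        feats = []
        pos = 0
        i = 0
        while pos < 900:
            start = pos + int(rng.integers(1, 40))
            end = min(start + int(rng.integers(10, 80)), 1000)
            if end <= start:
                break
            feats.append(Feature(f"g{i}", FeatureKind.CDS, "+", [Interval(start, end)]))
            pos = end
            i += 1
        p = Plastome(id="x", sequence=random_dna(1, 1000), circular=True,
                     features=feats)
        total = sum(r.length for r in intergenic_regions(p))
        total += sum(f.span(1000) for f in feats)
        assert total == 1000

    def test_find_igs_either_orientation(self, tiny_annotated):
        assert find_igs(tiny_annotated, "g1-g2").length == 50
        assert find_igs(tiny_annotated, "g2-g1").length == 50
        assert find_igs(tiny_annotated, "nope-g2") is None
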