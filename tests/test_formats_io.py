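"""Data model invariants, readers/writers, and coordinate-convention checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgaconcord import (Callset, CoverageTrack, IntervalSet, VariantCall,
                        read_bed, read_coverage_tsv, read_expression_tsv,
                        read_vcf, write_bed, write_coverage_tsv,
                        write_expression_tsv, write_vcf)
from wgaconcord.formats_io import ExpressionTable

from conftest import make_call, random_calls


class TestVariantCall:
    @pytest.mark.parametrize("kwargs", [
        dict(pos=0),
        dict(ref="AT"),
        dict(alt="N"),
        dict(ref="A", alt="A"),
        dict(genotype="hom_ref"),
        dict(depth=5, alt_depth=6),
        dict(qual=-1.0),
    ])
    def test_invalid_calls_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_call(**kwargs)

    def test_key_and_vaf(self):
        c = make_call(depth=20, alt_depth=8)
        assert c.key == ("chr1", 100, "G")
        assert c.vaf == pytest.approx(0.4)

    def test_callset_sorted_and_unique(self):
        a = make_call(pos=200)
        b = make_call(pos=100)
        cs = Callset("S", "wga_tumor", (a, b))
        assert [c.pos for c in cs] == [100, 200]
        with pytest.raises(ValueError, match="duplicate"):
            Callset("S", "wga_tumor", (a, a))


class TestVcf:
    def test_field_mapping_and_ad_complement(self, tmp_path):
        """A het call at depth 20 with 8 alt reads round-trips as DP=20, AD=12,8."""
        call = make_call(pos=100, genotype="het", depth=20, alt_depth=8, qual=55.0)
        cs = Callset("P1", "wga_tumor", (call,))
        path = tmp_path / "one.vcf"
        write_vcf(cs, path)
        text = path.read_text()
        assert "0/1:20:12,8" in text
        back = read_vcf(path)
        assert back.calls == cs.calls
        assert back.assay == "wga_tumor" and back.sample_id == "P1"

    def test_round_trip_random_callset(self, tmp_path):
        rng = np.random.default_rng(42)
        cs = Callset("P7", "unamplified_tumor", tuple(random_calls(rng, 100)))
        path = tmp_path / "rt.vcf"
        write_vcf(cs, path)
        assert read_vcf(path).calls == cs.calls

    def test_empty_callset_round_trip(self, tmp_path):
        cs = Callset("P1", "rna_tumor", ())
        path = tmp_path / "empty.vcf"
        write_vcf(cs, path, contigs={"chr1": 1000})
        back = read_vcf(path)
        assert len(back) == 0 and back.assay == "rna_tumor"

    def test_multiallelic_decomposed_to_one_call_per_alt(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1>\n##assay=wga_tumor\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t50\t.\tA\tG,T\t60\t.\t.\tGT:DP:AD\t1/2:30:2,14,14\n")
        cs = read_vcf(path)
        assert [(c.alt, c.genotype, c.alt_depth) for c in cs] == [
            ("G", "het", 14), ("T", "het", 14)]

    def test_non_snv_records_skipped_with_count(self, tmp_path, caplog):
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n##assay=wga_tumor\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n")
        snv = "chr1\t{p}\t.\tA\tG\t60\t.\t.\tGT:DP:AD\t0/1:30:16,14\n"
        indel = "chr1\t{p}\t.\tAT\tA\t60\t.\t.\tGT:DP:AD\t0/1:30:16,14\n"
        body = "".join(snv.format(p=p) for p in (10, 20, 30, 40, 50))
        body += "".join(indel.format(p=p) for p in (60, 70))
        path = tmp_path / "mixed.vcf"
        path.write_text(header + body)
        import logging
        with caplog.at_level(logging.INFO, logger="wgaconcord.formats_io"):
            cs = read_vcf(path)
        assert len(cs) == 5
        assert "skipped 2 non-SNV" in caplog.text


class TestIntervalSet:
    def test_merge_overlapping(self):
        ivs = IntervalSet([("chr1", 10, 20), ("chr1", 15, 30)])
        assert ivs.intervals == [("chr1", 10, 30)]

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            IntervalSet([("chr1", 20, 20)])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 20)), max_size=15),
           st.randoms(use_true_random=False))
    def test_normalization_idempotent_and_order_independent(self, raw, rnd):
        ivs = [("chr1", s, s + l) for s, l in raw]
        a = IntervalSet(ivs)
        shuffled = list(ivs)
        rnd.shuffle(shuffled)
        assert IntervalSet(shuffled).intervals == a.intervals
        assert IntervalSet(a.intervals).intervals == a.intervals  # idempotent

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 60), st.integers(1, 15)), max_size=10))
    def test_membership_matches_brute_force(self, raw):
        """1-based pos p is in 0-based (s,e) iff s < p <= e."""
        ivs = [("chr1", s, s + l) for s, l in raw]
        iset = IntervalSet(ivs)
        for p in range(1, 85):
            expect = any(s < p <= e for _, s, e in ivs)
            assert iset.contains("chr1", p) == expect

    def test_intersection_matches_position_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = IntervalSet([("chr1", int(s), int(s) + int(l))
                             for s, l in zip(rng.integers(0, 200, 8),
                                             rng.integers(1, 40, 8))])
            b = IntervalSet([("chr1", int(s), int(s) + int(l))
                             for s, l in zip(rng.integers(0, 200, 8),
                                             rng.integers(1, 40, 8))])
            inter = a.intersect(b)
            for p in range(1, 260):
                assert inter.contains("chr1", p) == (
                    a.contains("chr1", p) and b.contains("chr1", p))


class TestBedAndTsv:
    def test_bed_merge_rule(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t10\t20\nchr1\t15\t30\n")
        assert read_bed(path).intervals == [("chr1", 10, 30)]

    def test_empty_bed(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        assert len(read_bed(path)) == 0

    def test_bad_bed_raises(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t30\t20\n")
        with pytest.raises(ValueError):
            read_bed(path)

    def test_bed_round_trip(self, tmp_path):
        ivs = IntervalSet([("chr1", 5, 9), ("chr2", 0, 4), ("chr1", 20, 33)])
        path = tmp_path / "rt.bed"
        write_bed(ivs, path)
        assert read_bed(path) == ivs

    def test_coverage_queries_match_brute_force(self, tmp_path):
        rng = np.random.default_rng(1)
        positions = rng.choice(np.arange(1, 5000), size=1000, replace=False)
        depths = rng.integers(0, 90, size=1000)
        truth = {("chr1", int(p)): int(d) for p, d in zip(positions, depths)}
        path = tmp_path / "cov.tsv"
        with open(path, "w") as fh:
            for p, d in zip(positions, depths):
                fh.write(f"chr1\t{p}\t{d}\n")
        track = read_coverage_tsv(path, "S", "wga_tumor")
        for p in range(1, 5200, 7):
            assert track.depth("chr1", p) == truth.get(("chr1", p), 0)

    def test_coverage_round_trip_and_negative_error(self, tmp_path):
        track = CoverageTrack.from_pairs("S", "wga_tumor",
                                         {("chr1", 5): 10, ("chr2", 1): 0})
        path = tmp_path / "c.tsv"
        write_coverage_tsv(track, path)
        back = read_coverage_tsv(path, "S", "wga_tumor")
        assert back.depth("chr1", 5) == 10 and back.depth("chr2", 1) == 0
        bad = tmp_path / "bad.tsv"
        bad.write_text("chr1\t5\t-3\n")
        with pytest.raises(ValueError, match="negative depth"):
            read_coverage_tsv(bad, "S", "wga_tumor")

    def test_expression_round_trip_and_errors(self, tmp_path):
        expr = ExpressionTable(rows={"G1": 2.5, "G2": 0.0})
        path = tmp_path / "e.tsv"
        write_expression_tsv(expr, path)
        assert dict(read_expression_tsv(path).items()) == {"G1": 2.5, "G2": 0.0}
        bad = tmp_path / "bad.tsv"
        bad.write_text("gene\tvalue\nG1\t1\n")
        with pytest.raises(ValueError, match="header"):
            read_expression_tsv(bad)
        neg = tmp_path / "neg.tsv"
        neg.write_text("gene_id\tfpkm\nG1\t-2\n")
        with pytest.raises(ValueError, match="negative"):
            read_expression_tsv(neg)
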