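"""Readers/writers and domain-type invariants."""

import pytest

from cfdyn import (
    Effect, FormatError, Region, VariantCall, VariantKey, annotate_calls,
    read_annotation_table, read_gene_matrix, read_manifest, read_segments,
    read_vcf_calls, write_gene_matrix, write_manifest, write_segments,
    write_vcf_calls,
)
from cfdyn.data_model_io import Annotation, Segment

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def _write(tmp_path, body, name="x.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadVcf:
    def test_direct_field_mapping(self, tmp_path):
        p = _write(tmp_path, "1\t12345\t.\tC\tT\t60\tPASS\t.\tGT:DP:AD\t0/1:100:97,3\n")
        (call,) = read_vcf_calls(p, "S1")
        assert call.key == VariantKey("1", 12345, "C", "T")
        assert (call.depth, call.alt_reads, call.qual) == (100, 3, 60.0)
        assert call.vaf == pytest.approx(0.03)

    def test_empty_body(self, tmp_path):
        assert read_vcf_calls(_write(tmp_path, ""), "S1") == []

    def test_multiallelic_decomposition(self, tmp_path):
        p = _write(tmp_path, "1\t500\t.\tA\tT,G\t50\tPASS\t.\tGT:DP:AD\t0/1:100:90,6,4\n")
        calls = read_vcf_calls(p, "S1")
        assert [c.key.alt for c in calls] == ["T", "G"]
        assert [c.alt_reads for c in calls] == [6, 4]
        assert all(c.key.pos == 500 for c in calls)
        # reads conserved: ref + per-alt alt reads = DP
        assert 90 + sum(c.alt_reads for c in calls) == 100

    def test_missing_format_field_names_record(self, tmp_path):
        p = _write(tmp_path, "1\t77\t.\tC\tA\t60\tPASS\t.\tGT:DP\t0/1:100\n")
        with pytest.raises(FormatError, match="1:77"):
            read_vcf_calls(p, "S1")

    def test_unknown_sample(self, tmp_path):
        with pytest.raises(FormatError, match="S9"):
            read_vcf_calls(_write(tmp_path, ""), "S9")

    def test_roundtrip_exact(self, tmp_path):
        calls = [
            VariantCall(VariantKey("2", 100, "C", "T"), vaf=0.05, depth=200,
                        alt_reads=10, qual=45.0),
            VariantCall(VariantKey("1", 999, "T", "G"), vaf=0.5, depth=30,
                        alt_reads=15, qual=60.0),
        ]
        p = tmp_path / "rt.vcf"
        write_vcf_calls(calls, p, "S1")
        back = read_vcf_calls(p, "S1")
        got = {(c.key, c.depth, c.alt_reads) for c in back}
        assert got == {(c.key, c.depth, c.alt_reads) for c in calls}


ANN_HEADER = ("chrom\tpos\tref\talt\tgene\tregion\teffect\tprotein_change\t"
              "af_1000g\taf_panel\tcosmic_id\n")


def _ann(tmp_path, rows, name="a.tsv"):
    p = tmp_path / name
    p.write_text(ANN_HEADER + "".join(rows))
    return p


class TestAnnotationTable:
    def test_pop_af_max_one_available(self, tmp_path):
        p = _ann(tmp_path, ["1\t10\tC\tT\tTP53\texonic\tmissense\tR175H\t0.02\t.\tCOSM1\n"])
        (ann,) = read_annotation_table(p).values()
        assert ann.pop_af_max == 0.02
        assert ann.cosmic_id == "COSM1"

    def test_pop_af_all_missing_is_zero(self, tmp_path):
        p = _ann(tmp_path, ["1\t10\tC\tT\tG\texonic\tmissense\t.\t.\t.\t.\n"])
        (ann,) = read_annotation_table(p).values()
        assert ann.pop_af_max == 0.0
        assert ann.protein_change == ""

    @pytest.mark.parametrize("raw,expected", [
        ("synonymous SNV", Effect.SYNONYMOUS),
        ("nonsynonymous SNV", Effect.MISSENSE),
        ("stopgain", Effect.NONSENSE),
        ("stoploss", Effect.NONSENSE),
        ("frameshift insertion", Effect.FRAMESHIFT),
        ("nonframeshift substitution", Effect.NONFRAMESHIFT_SUBSTITUTION),
        ("splicing", Effect.SPLICE),
        ("UTR5", Effect.UTR),
        ("totally_novel", Effect.OTHER),
    ])
    def test_effect_string_mapping(self, tmp_path, raw, expected):
        p = _ann(tmp_path, [f"1\t10\tC\tT\tG\texonic\t{raw}\t.\t.\t.\t.\n"])
        (ann,) = read_annotation_table(p).values()
        assert ann.effect is expected

    def test_duplicate_key_rejected(self, tmp_path):
        row = "1\t10\tC\tT\tG\texonic\tmissense\t.\t.\t.\t.\n"
        with pytest.raises(FormatError, match="duplicate"):
            read_annotation_table(_ann(tmp_path, [row, row]))

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tpos\n1\t10\n")
        with pytest.raises(FormatError, match="missing columns"):
            read_annotation_table(p)


class TestAnnotateCalls:
    def _calls(self):
        return [VariantCall(VariantKey("1", p, "C", "T"), vaf=0.1, depth=100,
                            alt_reads=10, qual=60.0) for p in (10, 20, 30)]

    def test_partial_match_flags_unmatched(self):
        ann = {VariantKey("1", p, "C", "T"):
               Annotation("G", Region.EXONIC, Effect.MISSENSE, "", 0.0, "")
               for p in (10, 20)}
        out = annotate_calls(self._calls(), ann)
        assert [c.annotated for c in out] == [True, True, False]

    def test_empty_mapping_all_flagged(self):
        out = annotate_calls(self._calls(), {})
        assert not any(c.annotated for c in out)

    def test_extra_keys_ignored(self):
        ann = {VariantKey("9", p, "A", "G"):
               Annotation("X", Region.EXONIC, Effect.MISSENSE, "", 0.0, "")
               for p in range(100, 110)}
        out = annotate_calls(self._calls(), ann)
        assert len(out) == 3 and not any(c.annotated for c in out)


SEG_HEADER = "chrom\tstart\tend\ttcn.em\tlcn.em\n"


class TestSegments:
    def test_read_and_order(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(SEG_HEADER + "8\t2000001\t3000000\t2\t1\n8\t1\t2000000\t12\t.\n")
        segs = read_segments(p)
        assert [s.tcn for s in segs] == [12.0, 2.0]  # sorted by start
        assert segs[0].lcn is None and segs[1].lcn == 1.0
        assert (segs[0].start, segs[0].end) == (0, 2000000)  # 0-based half-open

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(SEG_HEADER + "1\t500\t100\t2\t.\n")
        with pytest.raises(FormatError, match="line 2"):
            read_segments(p)

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(SEG_HEADER + "1\t1\t1000\t2\t.\n1\t500\t2000\t2\t.\n")
        with pytest.raises(FormatError, match="overlap"):
            read_segments(p)

    def test_roundtrip(self, tmp_path):
        segs = [Segment("1", 0, 1000, 2.0, 1.0), Segment("2", 10, 20, 9.5, None)]
        p = tmp_path / "s.tsv"
        write_segments(segs, p)
        assert read_segments(p) == segs


class TestGeneMatrix:
    def test_roundtrip(self, tmp_path):
        import pandas as pd
        mat = pd.DataFrame([["res_only", "none"], ["none", "vaf_up"]],
                           index=pd.Index(["G1", "G2"], name="gene"),
                           columns=["P1", "P2"])
        p = tmp_path / "m.tsv"
        write_gene_matrix(mat, p)
        assert p.read_text().count("\n") == 3
        assert read_gene_matrix(p).equals(mat)

    def test_empty_matrix(self, tmp_path):
        import pandas as pd
        mat = pd.DataFrame(index=pd.Index([], name="gene"),
                           columns=["P1"], dtype=object)
        p = tmp_path / "m.tsv"
        write_gene_matrix(mat, p)
        assert read_gene_matrix(p).empty


def test_manifest_roundtrip(default_cohort, tmp_path):
    d, _, manifest, _ = default_cohort
    p = tmp_path / "m.yaml"
    write_manifest(manifest, p)
    back = read_manifest(p)
    assert back.patients == manifest.patients
    assert back.pairs == manifest.pairs


def test_variant_key_invariants():
    with pytest.raises(ValueError):
        VariantKey("1", 0, "C", "T")
    with pytest.raises(ValueError):
        VariantKey("1", 5, "C", "C")
    with pytest.raises(ValueError):
        VariantKey("chr99", 5, "C", "T")
    with pytest.raises(ValueError):
        VariantCall(VariantKey("1", 5, "C", "T"), vaf=0.1, depth=10,
                    alt_reads=11, qual=60.0)
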