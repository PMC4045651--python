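import json

import pandas as pd
import pytest

from duoburden import variant_io
from duoburden.model import Consequence
from .conftest import make_variant

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=2000000>
##INFO=<ID=MQ,Number=1,Type=Integer,Description="RMS mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""

ANNOTATION_HEADER = (
    "chrom\tpos\tref\talt\tgene\tconsequence\taf_1000g\taf_dbsnp"
    "\tdeleterious_votes\tdeleterious_total\n"
)


def write_vcf(tmp_path, body, name="s1.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


def write_annotation(tmp_path, rows, name="ann.tsv"):
    path = tmp_path / name
    path.write_text(ANNOTATION_HEADER + "".join(rows))
    return path


class TestReadVcf:
    def test_empty_vcf_yields_empty_list(self, tmp_path):
        path = write_vcf(tmp_path, "")
        assert variant_io.read_vcf(path, "S1") == []

    def test_allele_depths_from_ad(self, tmp_path):
        path = write_vcf(
            tmp_path, "1\t1000\t.\tA\tT\t50\t.\tMQ=60\tGT:AD:DP:GQ\t0/1:12,9:21:70\n"
        )
        (v,) = variant_io.read_vcf(path, "S1")
        assert (v.alt_depth, v.total_depth) == (9, 21)
        assert (v.genotype_quality, v.mapping_quality) == (70, 60)

    def test_multiallelic_decomposed_per_alt(self, tmp_path):
        path = write_vcf(
            tmp_path,
            "1\t1000\t.\tG\tA,T\t50\t.\tMQ=58\tGT:AD:DP:GQ\t1/2:2,11,7:20:80\n",
        )
        variants = variant_io.read_vcf(path, "S1")
        assert len(variants) == 2
        assert {(v.chrom, v.pos, v.ref) for v in variants} == {("1", 1000, "G")}
        assert {v.alt: v.alt_depth for v in variants} == {"A": 11, "T": 7}

    def test_uncarried_alt_not_emitted(self, tmp_path):
        path = write_vcf(
            tmp_path,
            "1\t1000\t.\tG\tA,T\t50\t.\tMQ=58\tGT:AD:DP:GQ\t0/2:2,0,7:9:80\n",
        )
        (v,) = variant_io.read_vcf(path, "S1")
        assert v.alt == "T"

    def test_annotation_join_and_fallback(self, tmp_path):
        vcf = write_vcf(
            tmp_path,
            "1\t1000\t.\tA\tT\t50\t.\tMQ=60\tGT:AD:DP:GQ\t0/1:10,10:20:70\n"
            "1\t2000\t.\tC\tG\t50\t.\tMQ=60\tGT:AD:DP:GQ\t0/1:10,10:20:70\n",
        )
        ann = write_annotation(
            tmp_path,
            ["1\t1000\tA\tT\tMLL3\tstopgain\t0.005\t\t3\t4\n"],
        )
        joined, orphan = variant_io.read_vcf(vcf, "S1", ann)
        assert joined.gene == "MLL3"
        assert joined.consequence is Consequence.STOPGAIN
        assert joined.pop_afs == {"1000g": 0.005}
        assert orphan.consequence is Consequence.OTHER
        assert orphan.pop_afs == {}

    def test_multi_gene_annotation_duplicates_variant(self, tmp_path):
        vcf = write_vcf(
            tmp_path, "1\t1000\t.\tA\tT\t50\t.\tMQ=60\tGT:AD:DP:GQ\t0/1:10,10:20:70\n"
        )
        ann = write_annotation(
            tmp_path,
            [
                "1\t1000\tA\tT\tGENEA\tnonsynonymous_snv\t\t\t2\t4\n",
                "1\t1000\tA\tT\tGENEB\tsplice_site\t\t\t2\t4\n",
            ],
        )
        variants = variant_io.read_vcf(vcf, "S1", ann)
        assert sorted(v.gene for v in variants) == ["GENEA", "GENEB"]

    def test_af_out_of_bounds_is_validation_error(self, tmp_path):
        ann = write_annotation(tmp_path, ["1\t1000\tA\tT\tG\tstopgain\t1.2\t\t1\t4\n"])
        with pytest.raises(variant_io.VariantParseError, match=r"af_1000g outside \[0,1\]"):
            variant_io.read_annotation_table(ann)

    def test_missing_sample_is_error(self, tmp_path):
        path = write_vcf(tmp_path, "")
        with pytest.raises(variant_io.VariantParseError, match="S2"):
            variant_io.read_vcf(path, "S2")

    def test_malformed_vcf_names_position(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(VCF_HEADER + "1\tnot_a_pos\t.\tA\tT\t50\t.\tMQ=60\tGT\t0/1\n")
        with pytest.raises(variant_io.VariantParseError):
            variant_io.read_vcf(path, "S1")


class TestGeneLists:
    def test_symbols_uppercased_and_deduplicated(self, tmp_path):
        path = tmp_path / "genes.txt"
        path.write_text("MLL3\nFLT3\nmll3\n")
        gs = variant_io.read_gene_set(path, "test")
        assert gs.genes == frozenset({"MLL3", "FLT3"})

    def test_candidate_list_intersection(self, tmp_path):
        shared = [f"SHARED{i}" for i in range(34)]
        all_genes = shared + [f"ALLG{i}" for i in range(126 - 34)]
        aml_genes = shared + [f"AMLG{i}" for i in range(655 - 34)]
        p1, p2 = tmp_path / "all.txt", tmp_path / "aml.txt"
        p1.write_text("\n".join(all_genes))
        p2.write_text("\n".join(aml_genes))
        s1 = variant_io.read_gene_set(p1, "ALL")
        s2 = variant_io.read_gene_set(p2, "AML")
        assert (len(s1), len(s2)) == (126, 655)
        assert len(s1.genes & s2.genes) == 34

    def test_blank_file_is_error(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("\n\n  \n")
        with pytest.raises(ValueError, match="no symbols"):
            variant_io.read_gene_set(path, "x")

    def test_gene_models_reject_duplicates(self, tmp_path):
        path = tmp_path / "models.tsv"
        path.write_text("gene\tcoding_length\nA\t100\nA\t200\n")
        with pytest.raises(ValueError, match="duplicate"):
            variant_io.read_gene_models(path)


class TestVariantTableRoundTrip:
    def test_round_trip_exact(self, tmp_path):
        variants = [
            make_variant(pos=10, pop_afs={"1000g": 0.004, "dbsnp": 0.0001}),
            make_variant(pos=20, ref="A", alt="AT",
                         consequence=Consequence.FRAMESHIFT_INDEL, pop_afs={}),
        ]
        path = tmp_path / "v.tsv"
        variant_io.write_variant_table(variants, path)
        assert variant_io.read_variant_table(path) == variants


class TestWriteResults:
    def test_empty_results_manifest_only(self, tmp_path):
        manifest = variant_io.write_results({}, tmp_path / "out")
        assert manifest["files"] == {}
        assert (tmp_path / "out" / "manifest.json").exists()

    def test_same_inputs_byte_identical(self, tmp_path):
        df = pd.DataFrame({"gene": ["A", "B"], "p": [0.1234567891, 0.5]})
        m1 = variant_io.write_results({"t": df}, tmp_path / "a", seed=7)
        m2 = variant_io.write_results({"t": df}, tmp_path / "b", seed=7)
        assert (tmp_path / "a" / "t.tsv").read_bytes() == (tmp_path / "b" / "t.tsv").read_bytes()
        assert m1["files"] == m2["files"]

    def test_tampering_detected(self, tmp_path):
        df = pd.DataFrame({"x": [1]})
        variant_io.write_results({"t": df}, tmp_path / "out")
        (tmp_path / "out" / "t.tsv").write_text("x\n2\n")
        with pytest.raises(variant_io.IntegrityError, match="checksum mismatch"):
            variant_io.verify_manifest(tmp_path / "out")

    def test_round_trip_preserves_values(self, tmp_path):
        df = pd.DataFrame({"gene": ["A"], "p": [1.23456789e-12]})
        variant_io.write_results({"t": df}, tmp_path / "out")
        back = pd.read_csv(tmp_path / "out" / "t.tsv", sep="\t")
        assert back["p"][0] == pytest.approx(1.23456789e-12, rel=1e-9)
        assert json.load(open(tmp_path / "out" / "manifest.json"))["files"]["t"]["n_rows"] == 1
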