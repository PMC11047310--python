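import numpy as np
import pandas as pd
import pytest

from rohscan import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    QCParams,
    apply_qc,
    hwe_exact_p,
    read_genotype_tsv,
    read_segments,
    read_population_map,
    read_vcf,
    write_bed,
    write_genotype_tsv,
    write_segments,
)
from conftest import make_matrix
from _oracles import hwe_enumeration_p

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=2>
##contig=<ID=X>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB
"""


def write_vcf(tmp_path, body, name="test.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


class TestReadVcf:
    def test_basic_mapping(self, tmp_path):
        """Two samples, three biallelic autosomal SNPs map to a 2x3 matrix
        with codes taken from the GT field, phase ignored."""
        body = (
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0|1\n"
            "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/0\n"
            "2\t150\trs3\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        )
        gm = read_vcf(write_vcf(tmp_path, body))
        assert gm.samples == ["sampleA", "sampleB"]
        assert gm.calls.shape == (2, 3)
        np.testing.assert_array_equal(gm.calls[0], [HOM_REF, HOM_ALT, HET])
        np.testing.assert_array_equal(gm.calls[1], [HET, HOM_REF, HOM_ALT])
        assert list(gm.variants["pos"]) == [100, 200, 150]

    def test_filters_non_snp_multiallelic_and_sex_chroms(self, tmp_path):
        body = (
            "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\n"
            "1\t200\t.\tA\tG,T\t.\t.\t.\tGT\t0/1\t0/2\n"   # triallelic
            "1\t300\t.\tAT\tA\t.\t.\t.\tGT\t0/0\t0/1\n"    # indel
            "X\t400\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\n"     # non-autosome
            "2\t500\t.\tC\tT\t.\t.\t.\tGT\t1/1\t0/1\n"
        )
        gm = read_vcf(write_vcf(tmp_path, body))
        assert gm.n_variants == 2
        assert gm.chromosomes() == ["1", "2"]

    def test_missing_and_half_missing_calls(self, tmp_path):
        body = (
            "1\t100\t.\tA\tG\t.\t.\t.\tGT\t./.\t0/0\n"
            "1\t200\t.\tA\tG\t.\t.\t.\tGT\t./1\t0/1\n"
        )
        gm = read_vcf(write_vcf(tmp_path, body))
        assert gm.calls[0, 0] == MISSING
        assert gm.calls[0, 1] == MISSING  # half-missing coded MISSING
        assert gm.calls[1, 1] == HET

    def test_empty_and_unreadable(self, tmp_path):
        with pytest.raises(ValueError, match="no usable"):
            read_vcf(write_vcf(tmp_path, "X\t1\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\n"))
        with pytest.raises(FileNotFoundError):
            read_vcf(tmp_path / "nope.vcf")

    def test_vcf_tsv_round_trip(self, tmp_path):
        body = (
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t./.\n"
            "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t1/1\t0/1\n"
        )
        gm = read_vcf(write_vcf(tmp_path, body))
        write_genotype_tsv(gm, tmp_path / "g.tsv")
        back = read_genotype_tsv(tmp_path / "g.tsv")
        assert back.samples == gm.samples
        np.testing.assert_array_equal(back.calls, gm.calls)
        pd.testing.assert_frame_equal(back.variants, gm.variants)


class TestHweExact:
    def test_perfect_proportions_are_modal(self):
        """(25, 50, 25) is the modal configuration at p=q=0.5, so every
        other heterozygote count is no more likely and p = 1."""
        assert hwe_exact_p(25, 50, 25) == pytest.approx(1.0)

    def test_het_deficit_is_extreme(self):
        assert hwe_exact_p(50, 0, 50) < 1e-3

    def test_monomorphic_site(self):
        assert hwe_exact_p(1, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 42) == 1.0

    def test_all_missing_signalled(self):
        with pytest.raises(ValueError):
            hwe_exact_p(0, 0, 0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(60):
            n = int(rng.integers(1, 101))
            n_het = int(rng.integers(0, n + 1))
            n_ref = int(rng.integers(0, n - n_het + 1))
            n_alt = n - n_het - n_ref
            p_impl = hwe_exact_p(n_ref, n_het, n_alt)
            p_oracle = hwe_enumeration_p(n_ref, n_het, n_alt)
            assert abs(p_impl - p_oracle) < 1e-9


class TestApplyQc:
    def test_disabled_thresholds_are_identity(self):
        rng = np.random.default_rng(0)
        gm = make_matrix(rng.choice([0, 1, 2, -1], size=(6, 40)))
        params = QCParams(max_geno_missing=None, min_maf=None,
                         hwe_p_threshold=None, max_sample_missing=None)
        out, report = apply_qc(gm, params)
        np.testing.assert_array_equal(out.calls, gm.calls)
        assert report.n_variants_out == gm.n_variants

    def test_snp_missingness_threshold(self):
        calls = np.zeros((10, 3), dtype=np.int8)
        calls[:3, 1] = MISSING  # SNP 1 missing in 3/10 samples
        gm = make_matrix(calls)
        out, report = apply_qc(
            gm, QCParams(max_geno_missing=0.1, min_maf=None,
                         hwe_p_threshold=None, max_sample_missing=None)
        )
        assert report.snps_removed_missing == 1
        assert list(out.variants["id"]) == ["snp0", "snp2"]

    def test_sample_missingness_runs_first(self):
        calls = np.zeros((4, 10), dtype=np.int8)
        calls[0, :5] = MISSING  # sample 0: 50% missing
        gm = make_matrix(calls)
        out, report = apply_qc(
            gm, QCParams(max_geno_missing=0.1, min_maf=None,
                         hwe_p_threshold=None, max_sample_missing=0.1)
        )
        assert report.samples_removed_missing == 1
        # with the bad sample gone, no SNP exceeds 10% missingness
        assert report.snps_removed_missing == 0
        assert out.n_samples == 3

    def test_hwe_step_removes_het_deficit_snp(self):
        """A SNP with counts (50, 0, 50) fails the exact test far below
        1e-3 and is removed; a well-behaved SNP stays."""
        bad = np.array([HOM_REF] * 50 + [HOM_ALT] * 50, dtype=np.int8)
        good = np.array(([HOM_REF] * 25 + [HET] * 50 + [HOM_ALT] * 25), dtype=np.int8)
        gm = make_matrix(np.column_stack([bad, good]))
        out, report = apply_qc(
            gm, QCParams(max_geno_missing=None, min_maf=None,
                         hwe_p_threshold=1e-3, max_sample_missing=None)
        )
        assert report.snps_removed_hwe == 1
        assert list(out.variants["id"]) == ["snp1"]

    def test_maf_filter_and_roh_profile(self):
        rare = np.array([HOM_REF] * 99 + [HET], dtype=np.int8)  # MAF 0.005
        common = np.array([HOM_REF] * 25 + [HET] * 50 + [HOM_ALT] * 25, dtype=np.int8)
        gm = make_matrix(np.column_stack([rare, common]))
        out, _ = apply_qc(gm, QCParams(hwe_p_threshold=None))
        assert list(out.variants["id"]) == ["snp1"]
        out_roh, _ = apply_qc(gm, QCParams.roh_profile())
        assert out_roh.n_variants == 2  # MAF disabled for the ROH profile

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([0, 1, 2, -1], size=(30, 80), p=[0.4, 0.3, 0.25, 0.05])
        gm = make_matrix(calls)
        once, _ = apply_qc(gm, QCParams())
        twice, report = apply_qc(once, QCParams())
        np.testing.assert_array_equal(once.calls, twice.calls)
        assert report.samples_removed_missing == 0
        assert report.snps_removed_missing == report.snps_removed_hwe == report.snps_removed_maf == 0

    def test_exhausting_step_named(self):
        gm = make_matrix(np.full((4, 3), MISSING, dtype=np.int8))
        with pytest.raises(ValueError, match="sample-missingness"):
            apply_qc(gm, QCParams())


class TestWriters:
    def test_bed_coordinate_convention(self, tmp_path):
        intervals = pd.DataFrame({"chrom": ["chr1"], "start_bp": [100], "end_bp": [299]})
        write_bed(intervals, tmp_path / "x.bed")
        assert (tmp_path / "x.bed").read_text() == "chr1\t99\t299\n"

    def test_empty_segment_list_gives_header_only(self, tmp_path):
        empty = pd.DataFrame(columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"])
        write_segments(empty, tmp_path / "s.tsv")
        lines = (tmp_path / "s.tsv").read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t")[0] == "sample_id"

    def test_segment_round_trip(self, tmp_path):
        segs = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "chrom": ["1", "2"],
                "start_bp": [1000, 5000],
                "end_bp": [300_000, 900_000],
                "n_snps": [40, 80],
                "length_kb": [299.001, 895.001],
            }
        )
        write_segments(segs, tmp_path / "s.tsv", population_map={"a": "IMC", "b": "HSC"})
        back = read_segments(tmp_path / "s.tsv")
        assert list(back["population"]) == ["IMC", "HSC"]
        pd.testing.assert_frame_equal(back[segs.columns], segs)

    def test_population_map(self, tmp_path):
        (tmp_path / "pop.tsv").write_text("sample_id\tpopulation\ns1\tIMC\ns2\tHSC\n")
        pm = read_population_map(tmp_path / "pop.tsv")
        assert pm["s1"] == "IMC" and pm["s2"] == "HSC"
        (tmp_path / "dup.tsv").write_text("sample_id\tpopulation\ns1\tIMC\ns1\tHSC\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_population_map(tmp_path / "dup.tsv")
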