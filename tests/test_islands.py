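import numpy as np
import pandas as pd
import pytest

from rohscan import annotate_intervals, call_islands, incidence, island_threshold
from rohscan.islands import read_gene_intervals
from _oracles import naive_incidence, quadratic_overlaps, sort_percentile_threshold


def variant_map(n, chrom="1", spacing=10_000):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * spacing,
            "id": [f"snp{i}" for i in range(n)],
            "ref": "A",
            "alt": "G",
        }
    )


def seg(sample, chrom, start, end):
    return dict(
        sample_id=sample, chrom=chrom, start_bp=start, end_bp=end,
        n_snps=30, length_kb=(end - start + 1) / 1000.0,
    )


class TestIncidence:
    def test_no_segments_all_zero(self):
        track = incidence(pd.DataFrame(columns=["sample_id", "chrom", "start_bp", "end_bp"]),
                          variant_map(50), ["a", "b"])
        assert (track["incidence"] == 0).all()

    def test_single_sample_coverage(self):
        segs = pd.DataFrame([seg("a", "1", 100_000, 200_000)])  # SNPs 10..20
        track = incidence(segs, variant_map(50), ["a"])
        covered = (track["pos"] >= 100_000) & (track["pos"] <= 200_000)
        assert (track.loc[covered, "incidence"] == 1.0).all()
        assert (track.loc[~covered, "incidence"] == 0.0).all()

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            incidence(pd.DataFrame([seg("a", "1", 1, 2)]), variant_map(5), [])

    def test_matches_stabbing_oracle(self):
        rng = np.random.default_rng(41)
        variants = pd.concat(
            [variant_map(60, chrom="1"), variant_map(40, chrom="2")], ignore_index=True
        )
        samples = [f"s{i}" for i in range(6)]
        rows = []
        for s in samples[:5]:
            for _ in range(rng.integers(0, 4)):
                chrom = str(rng.integers(1, 3))
                start = int(rng.integers(1, 500_000))
                rows.append(seg(s, chrom, start, start + int(rng.integers(10_000, 300_000))))
        segs = pd.DataFrame(rows)
        track = incidence(segs, variants, samples)
        oracle = naive_incidence(
            [(r.sample_id, r.chrom, r.start_bp, r.end_bp) for r in segs.itertuples()],
            list(zip(variants["chrom"], variants["pos"])),
            samples,
        )
        np.testing.assert_allclose(track["incidence"], oracle)


class TestThreshold:
    def test_constructed_quantile(self):
        """10,000 SNPs, 10 at 0.9 and the rest at 0.1: the top-0.1% value
        is 0.9 and only strictly greater SNPs would qualify (none here)."""
        inc = np.full(10_000, 0.1)
        inc[5_000 : 5_010] = 0.9
        track = variant_map(10_000).assign(incidence=inc)
        thr = island_threshold(track, 0.001)
        assert thr == pytest.approx(0.9)
        assert call_islands(track, thr, min_snps=1).empty

    def test_constant_track_yields_no_islands(self):
        track = variant_map(1000).assign(incidence=0.4)
        thr = island_threshold(track)
        assert call_islands(track, thr).empty

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 5000))
        track = variant_map(n).assign(incidence=rng.random(n).round(3))
        assert island_threshold(track, 0.001) == sort_percentile_threshold(
            track["incidence"], 0.001
        )

    def test_islands_bounded_by_top_fraction(self):
        """Strict '>' keeps the number of island SNPs at or below the
        nominal top-0.1% budget plus ties excluded."""
        rng = np.random.default_rng(99)
        n = 20_000
        track = variant_map(n).assign(incidence=rng.random(n))
        thr = island_threshold(track, 0.001)
        islands = call_islands(track, thr, min_snps=1)
        assert islands["n_snps"].sum() <= int(np.ceil(0.001 * n))


class TestCallIslands:
    def test_min_snps_filter(self):
        inc = np.zeros(100)
        inc[50] = 0.9
        track = variant_map(100).assign(incidence=inc)
        assert call_islands(track, 0.5, min_snps=2).empty
        assert len(call_islands(track, 0.5, min_snps=1)) == 1

    def test_runs_split_by_subthreshold_snp(self):
        inc = np.zeros(100)
        inc[10:15] = 0.9
        inc[15] = 0.1
        inc[16:20] = 0.9
        track = variant_map(100).assign(incidence=inc)
        islands = call_islands(track, 0.5, min_snps=2)
        assert len(islands) == 2
        assert islands.loc[0, "end_bp"] < islands.loc[1, "start_bp"]

    def test_maximality_and_flanks(self):
        inc = np.zeros(60)
        inc[20:30] = 0.8
        track = variant_map(60).assign(incidence=inc)
        isl = call_islands(track, 0.5, min_snps=2)
        assert len(isl) == 1
        assert isl.loc[0, "start_bp"] == 210_000  # pos of SNP index 20
        assert isl.loc[0, "n_snps"] == 10
        assert isl.loc[0, "peak_incidence"] == pytest.approx(0.8)


class TestAnnotate:
    def islands_df(self):
        return pd.DataFrame(
            {"chrom": ["1", "1"], "start_bp": [1000, 50_000],
             "end_bp": [2000, 60_000], "n_snps": [5, 5], "peak_incidence": [0.9, 0.8]}
        )

    def test_abutting_gene_not_listed(self):
        genes = pd.DataFrame({"chrom": ["1"], "start_bp": [2001], "end_bp": [3000], "name": ["G1"]})
        out = annotate_intervals(self.islands_df(), genes)
        assert out.loc[0, "genes"] == ""

    def test_containing_gene_listed(self):
        genes = pd.DataFrame({"chrom": ["1"], "start_bp": [500], "end_bp": [10_000], "name": ["G1"]})
        out = annotate_intervals(self.islands_df(), genes)
        assert out.loc[0, "genes"] == "G1"
        assert out.loc[1, "genes"] == ""

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        islands = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2"], size=12),
                "start_bp": rng.integers(1, 900_000, size=12),
            }
        )
        islands["end_bp"] = islands["start_bp"] + rng.integers(1, 200_000, size=12)
        genes = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2"], size=20),
                "start_bp": rng.integers(1, 1_000_000, size=20),
                "name": [f"g{i}" for i in range(20)],
            }
        )
        genes["end_bp"] = genes["start_bp"] + rng.integers(1, 100_000, size=20)
        out = annotate_intervals(islands, genes)
        oracle = quadratic_overlaps(
            list(zip(islands["chrom"], islands["start_bp"], islands["end_bp"])),
            list(zip(genes["chrom"], genes["start_bp"], genes["end_bp"], genes["name"])),
        )
        for i in range(len(islands)):
            got = sorted(out.loc[i, "genes"].split(",")) if out.loc[i, "genes"] else []
            assert got == oracle[i]

    def test_read_bed_and_gff3(self, tmp_path):
        (tmp_path / "g.bed").write_text("1\t99\t299\tFGF5\n2\t0\t100\tKIT\n")
        bed = read_gene_intervals(tmp_path / "g.bed")
        assert bed.loc[0, "start_bp"] == 100 and bed.loc[0, "end_bp"] == 299
        (tmp_path / "g.gff3").write_text(
            "##gff-version 3\n"
            "1\t.\tgene\t100\t299\t.\t+\t.\tID=gene1;Name=FGF5\n"
            "1\t.\texon\t100\t150\t.\t+\t.\tID=exon1\n"
        )
        gff = read_gene_intervals(tmp_path / "g.gff3")
        assert len(gff) == 1
        assert gff.loc[0, "name"] == "FGF5"
        assert gff.loc[0, "start_bp"] == 100
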