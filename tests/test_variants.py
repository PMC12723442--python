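import numpy as np
import pandas as pd
import pytest

from gestaltqtl import variants
from gestaltqtl.variants import VariantDataError

from conftest import make_genotype_matrix


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\tS5\tM1
chr1\t100\tL1\tA\tT\t.\tPASS\t.\tGT:DP\t0/0:10\t0/1:12\t1/1:9\t./.:0\t0/1:15\t0:20
chr1\t200\tL2\tA\tT\t.\tPASS\t.\tGT:DP\t0/0:8\t0/0:7\t0/1:11\t1/1:13\t0/0:9\t1:18
chr1\t300\tL3\tA\tC,T\t.\tPASS\t.\tGT:DP\t0/0:9\t0/1:9\t0/2:9\t1/1:9\t0/0:9\t0:9
chr1\t400\tL4\tA\tAT\t.\tPASS\t.\tGT:DP\t0/0:9\t0/1:9\t0/0:9\t1/1:9\t0/0:9\t0:9
chr1\t500\tL5\tA\tG\t.\tPASS\t.\tGT:DP\t0/1:9\t0/0:9\t0/0:9\t0/0:9\t1/1:9\t0/1:9
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_TEXT)
    cmap = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3", "S4", "S5", "M1"],
            "colony_id": ["C1", "C1", "C1", "C2", "C2", "H"],
            "ploidy": [2, 2, 2, 2, 2, 1],
        }
    )
    return path, cmap


class TestReadVcf:
    def test_dosage_coding_and_shape(self, toy_vcf):
        path, cmap = toy_vcf
        gm = variants.read_vcf(path, cmap)
        assert gm.dosage.shape == (6, 5)
        # 0/0, 0/1, 1/1, ./. -> 0, 1, 2, NaN
        assert gm.dosage[0, 0] == 0 and gm.dosage[1, 0] == 1 and gm.dosage[2, 0] == 2
        assert np.isnan(gm.dosage[3, 0])
        assert gm.depth[1, 0] == 12

    def test_haploid_sample_flagged_ploidy_one(self, toy_vcf):
        path, cmap = toy_vcf
        gm = variants.read_vcf(path, cmap)
        m1 = gm.samples.set_index("sample_id").loc["M1"]
        assert m1["ploidy"] == 1
        assert gm.dosage[5, 0] == 0 and gm.dosage[5, 1] == 1
        # diploid-coded heterozygous call on the haploid sample (artifact)
        assert gm.het[5, 4]

    def test_unknown_sample_errors_with_name(self, toy_vcf):
        path, cmap = toy_vcf
        with pytest.raises(VariantDataError, match="M1"):
            variants.read_vcf(path, cmap[cmap.sample_id != "M1"])


class TestBiallelicFilter:
    def test_multiallelic_and_indel_removed(self, toy_vcf):
        path, cmap = toy_vcf
        gm = variants.read_vcf(path, cmap)
        report = variants.FilterReport()
        out = variants.drop_non_biallelic(gm, report)
        assert out.loci["locus_id"].tolist() == ["L1", "L2", "L5"]
        assert report.stages[0]["loci_removed"] == 2

    def test_all_biallelic_identity(self):
        gm = make_genotype_matrix(np.zeros((3, 4)))
        out = variants.drop_non_biallelic(gm)
        assert out.n_loci == 4


class TestSampleMissingness:
    def test_sixty_percent_missing_removed_at_half(self):
        d = np.zeros((2, 10))
        d[0, :6] = np.nan  # 60% missing
        gm = make_genotype_matrix(d)
        out = variants.filter_samples_missingness(gm, 0.5)
        assert out.samples["sample_id"].tolist() == ["S2"]

    def test_complete_sample_kept(self):
        gm = make_genotype_matrix(np.ones((2, 5)))
        out = variants.filter_samples_missingness(gm, 0.5)
        assert out.n_samples == 2

    def test_survivors_match_brute_force(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(10, 40)).astype(float)
        miss = rng.random((10, 40)) < rng.uniform(0, 0.9, size=(10, 1))
        d[miss] = np.nan
        gm = make_genotype_matrix(d)
        out = variants.filter_samples_missingness(gm, 0.4)
        expected = [f"S{i + 1}" for i in range(10)
                    if np.isnan(d[i]).sum() / 40 <= 0.4]
        assert out.samples["sample_id"].tolist() == expected

    def test_all_removed_errors(self):
        d = np.full((2, 4), np.nan)
        d[:, 0] = 1
        gm = make_genotype_matrix(d)
        with pytest.raises(VariantDataError):
            variants.filter_samples_missingness(gm, 0.5)


class TestLocusFilters:
    def test_call_rate_below_threshold_removed(self):
        d = np.ones((10, 1))
        d[:3, 0] = np.nan  # 7/10 called < 0.8
        gm = make_genotype_matrix(d)
        out = variants.filter_loci(gm, min_call_rate=0.8, min_maf=0.0)
        assert out.n_loci == 0

    def test_all_heterozygous_locus_kept(self):
        gm = make_genotype_matrix(np.ones((10, 1)))
        out = variants.filter_loci(gm)
        assert out.n_loci == 1  # f = 0.5 -> MAF 0.5

    def test_hand_computed_maf_boundary(self):
        # 12 samples, dosages 0 x 9 and 1 x 3: f = 3/24 = 0.125 < 0.15
        d = np.zeros((12, 1))
        d[:3, 0] = 1
        gm = make_genotype_matrix(d)
        out = variants.filter_loci(gm, min_maf=0.15)
        assert out.n_loci == 0
        out2 = variants.filter_loci(gm, min_maf=0.125)
        assert out2.n_loci == 1

    def test_depth_masking_happens_before_maf(self):
        # depth-masking the only ALT carriers leaves a monomorphic locus
        d = np.array([[1.0], [1.0], [0.0], [0.0], [0.0]])
        depth = np.full((5, 1), 12.0)
        depth[0, 0] = depth[1, 0] = 3.0  # below min_depth
        gm = make_genotype_matrix(d, depth=depth)
        out = variants.filter_loci(gm, min_call_rate=0.5, min_depth=6, min_maf=0.05)
        assert out.n_loci == 0

    def test_excess_depth_masked(self):
        d = np.ones((4, 1))
        depth = np.full((4, 1), 12.0)
        depth[0, 0] = 300.0
        gm = make_genotype_matrix(d, depth=depth)
        out = variants.filter_loci(gm, min_call_rate=0.9, min_maf=0.0)
        assert out.n_loci == 0  # call rate 3/4 after masking


class TestHaploidBlacklist:
    def test_no_heterozygous_calls_empty(self):
        gm = make_genotype_matrix(np.zeros((2, 3)), ploidy=[1, 1])
        bl = variants.haploid_blacklist(gm)
        assert bl.empty

    def test_no_haploids_warns(self):
        gm = make_genotype_matrix(np.ones((2, 3)))
        with pytest.warns(UserWarning):
            bl = variants.haploid_blacklist(gm)
        assert bl.empty

    def test_600bp_window_boundaries(self):
        # het (diploid-coded dosage 1) at chr1:10000
        d = np.array([[0.0, 1.0, 0.0, 0.0]])
        gm = make_genotype_matrix(d, ploidy=[1], bp=[9500, 10000, 10601, 12000])
        bl = variants.haploid_blacklist(gm, radius_bp=600)
        assert bl.iloc[0][["start", "end"]].tolist() == [9400, 10600]
        target = make_genotype_matrix(np.zeros((2, 4)), bp=[9500, 10000, 10601, 12000])
        kept = variants.apply_blacklist(target, bl)
        assert kept.loci["bp"].tolist() == [10601, 12000]

    def test_nearby_hets_merge_into_one_interval(self):
        d = np.array([[1.0, 1.0]])
        gm = make_genotype_matrix(d, ploidy=[1], bp=[10000, 10500])
        bl = variants.haploid_blacklist(gm, radius_bp=600)
        assert len(bl) == 1
        assert bl.iloc[0][["start", "end"]].tolist() == [9400, 11100]

    def test_removal_is_idempotent(self):
        d = np.array([[0.0, 1.0, 0.0]])
        gm = make_genotype_matrix(d, ploidy=[1], bp=[100, 5000, 9000])
        bl = variants.haploid_blacklist(gm, radius_bp=600)
        target = make_genotype_matrix(np.zeros((2, 3)), bp=[100, 5000, 9000])
        once = variants.apply_blacklist(target, bl)
        twice = variants.apply_blacklist(once, bl)
        assert once.loci.equals(twice.loci)


class TestExcessCoverage:
    def test_uniform_depth_passes(self):
        gm = make_genotype_matrix(np.ones((5, 3)), depth=np.full((5, 3), 12.0))
        out = variants.excess_coverage_filter(gm, max_mean_depth=20.0)
        assert out.n_loci == 3

    def test_mean_depth_strictly_above_cutoff_removed(self):
        depth = np.full((4, 2), 12.0)
        depth[:, 1] = 21.0
        gm = make_genotype_matrix(np.ones((4, 2)), depth=depth)
        out = variants.excess_coverage_filter(gm, max_mean_depth=20.0)
        assert out.loci["locus_id"].tolist() == ["L1"]

    def test_default_threshold_matches_brute_force(self):
        rng = np.random.default_rng(3)
        depth = rng.gamma(4, 3, size=(8, 30))
        gm = make_genotype_matrix(np.ones((8, 30)), depth=depth)
        out = variants.excess_coverage_filter(gm)
        means = depth.mean(axis=0)
        cutoff = means.mean() + 2 * means.std()
        expected = [f"L{j + 1}" for j in range(30) if not means[j] > cutoff]
        assert out.loci["locus_id"].tolist() == expected


class TestColonyRequirementAndGenotypes:
    def test_colony_of_three_with_one_missing_fails_locus(self):
        d = np.ones((3, 2))
        d[0, 0] = np.nan
        gm = make_genotype_matrix(d, colonies=["C1"] * 3)
        mask = variants.require_colony_calls(gm, min_per_colony=3)
        assert mask.tolist() == [False, True]

    def test_complete_data_all_pass(self):
        gm = make_genotype_matrix(np.ones((6, 4)), colonies=["C1"] * 3 + ["C2"] * 3)
        assert variants.require_colony_calls(gm, 3).all()

    def test_mask_matches_brute_force_counts(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, size=(8, 25)).astype(float)
        d[rng.random((8, 25)) < 0.3] = np.nan
        colonies = ["C1"] * 4 + ["C2"] * 4
        gm = make_genotype_matrix(d, colonies=colonies)
        mask = variants.require_colony_calls(gm, 3)
        for j in range(25):
            c1 = (~np.isnan(d[:4, j])).sum()
            c2 = (~np.isnan(d[4:, j])).sum()
            assert mask[j] == (c1 >= 3 and c2 >= 3)

    def test_small_colony_errors_with_name(self):
        gm = make_genotype_matrix(np.ones((4, 2)), colonies=["C1"] * 3 + ["Ctiny"])
        with pytest.raises(VariantDataError, match="Ctiny"):
            variants.require_colony_calls(gm, 3)

    def test_worked_colony_genotype_example(self):
        # genotypes 00,01,01,11,11,11 coded 0,1,1,2,2,2 -> mean 4/3
        d = np.array([[0.0], [1.0], [1.0], [2.0], [2.0], [2.0]])
        gm = make_genotype_matrix(d, colonies=["C1"] * 6)
        cgm = variants.colony_genotypes(gm, min_per_colony=3)
        assert cgm.mean_dosage[0, 0] == pytest.approx(4.0 / 3.0, abs=1e-12)

    def test_fixed_points_and_missing_handling(self):
        d = np.array([[0.0, 2.0, 0.0], [0.0, 2.0, 2.0], [0.0, 2.0, np.nan]])
        gm = make_genotype_matrix(d, colonies=["C1"] * 3)
        cgm = variants.colony_genotypes(gm, min_per_colony=2)
        assert cgm.mean_dosage[0, 0] == 0.0
        assert cgm.mean_dosage[0, 1] == 2.0
        assert cgm.mean_dosage[0, 2] == 1.0  # mean over the two called
        assert cgm.n_called[0, 2] == 2

    def test_below_minimum_calls_is_missing(self):
        d = np.array([[0.0], [2.0], [np.nan]])
        gm = make_genotype_matrix(d, colonies=["C1"] * 3)
        cgm = variants.colony_genotypes(gm, min_per_colony=3)
        assert np.isnan(cgm.mean_dosage[0, 0])


class TestCascadeProperties:
    def test_clean_fixture_passes_untouched(self, fixture_dir):
        """No missingness + uniform depth + common alleles -> filters are identity."""
        gm = variants.read_vcf(fixture_dir["vcf"], fixture_dir["colonies"])
        gm.depth[:] = 12.0
        maf = gm.maf()
        gm = gm.subset(locus_mask=maf >= 0.2)
        n0 = gm.n_loci
        report = variants.FilterReport()
        out = variants.drop_non_biallelic(gm, report)
        out = variants.filter_samples_missingness(out, 0.5, report)
        hap = out.subset(sample_mask=out.samples["ploidy"].to_numpy() == 1)
        bl = variants.haploid_blacklist(hap)
        out = variants.apply_blacklist(out, bl, report)
        out = variants.filter_loci(out, 0.8, 6, 250, 0.15, report)
        out = variants.excess_coverage_filter(out, 20.0, report)
        out = variants.filter_samples_missingness(out, 0.6, report)
        assert out.n_loci == n0
        assert out.n_samples == gm.n_samples
        assert all(s["loci_removed"] == 0 and s["samples_removed"] == 0
                   for s in report.stages)

    def test_report_counts_reconcile(self, toy_vcf):
        path, cmap = toy_vcf
        gm = variants.read_vcf(path, cmap)
        report = variants.FilterReport()
        report.add("input", gm.n_loci, gm.n_samples)
        out = variants.drop_non_biallelic(gm, report)
        out = variants.filter_loci(out, min_call_rate=0.8, min_maf=0.0, report=report)
        for prev, cur in zip(report.stages, report.stages[1:]):
            assert cur["n_loci"] == prev["n_loci"] - cur["loci_removed"]
            assert cur["n_samples"] == prev["n_samples"] - cur["samples_removed"]

    def test_colony_mean_dosage_is_twice_allele_frequency(self, fixture_dir):
        gm = variants.read_vcf(fixture_dir["vcf"], fixture_dir["colonies"])
        workers = gm.subset(sample_mask=gm.samples["ploidy"].to_numpy() == 2)
        cgm = variants.colony_genotypes(workers, min_per_colony=3)
        assert np.nanmin(cgm.mean_dosage) >= 0.0
        assert np.nanmax(cgm.mean_dosage) <= 2.0
        # per-colony check against allele frequency of called genotypes
        c0 = cgm.colonies[0]
        rows = workers.samples["colony_id"].to_numpy() == c0
        freq = np.nanmean(workers.dosage[rows], axis=0) / 2.0
        assert np.allclose(cgm.mean_dosage[0], 2.0 * freq, equal_nan=True)


class TestWriteVcf:
    def test_round_trip_preserves_dosage_and_depth(self, fixture_dir, tmp_path):
        gm = variants.read_vcf(fixture_dir["vcf"], fixture_dir["colonies"])
        out = tmp_path / "filtered.vcf"
        variants.write_vcf(gm, out)
        cmap = variants.read_colony_map(fixture_dir["colonies"])
        back = variants.read_vcf(out, cmap)
        assert np.array_equal(gm.dosage, back.dosage, equal_nan=True)
        assert np.array_equal(gm.depth, back.depth, equal_nan=True)
        assert gm.loci["locus_id"].tolist() == back.loci["locus_id"].tolist()
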