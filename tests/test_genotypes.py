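"""Read-count I/O, the retention filters, ratio genotypes, and LSMeans."""

import numpy as np
import pandas as pd
import pytest

import tetragp as tg
from tetragp.genotypes import FilterThresholds, apply_filters, lsmeans, read_counts_vcf


def toy_rc(ao, ro, missing=None):
    ao = np.asarray(ao)
    n, m = ao.shape
    return tg.ReadCountMatrix(
        ao, ro, [f"i{k}" for k in range(n)], [f"m{j}" for j in range(m)], missing
    )


def toy_map(n_markers, chrom=None):
    chrom = chrom if chrom is not None else np.ones(n_markers, int)
    return tg.MarkerMap(
        [f"m{j}" for j in range(n_markers)],
        chrom,
        np.arange(n_markers) * 100,
        np.arange(n_markers, dtype=float),
    )


NOOP = FilterThresholds(
    min_site_mean_depth=0, min_datapoint_depth=0, max_missing=1.0, min_maf=0.0
)


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        rc = toy_rc(
            [[3, 0], [5, 2], [1, 7]],
            [[9, 4], [0, 2], [3, 1]],
            missing=[[False, True], [False, False], [False, False]],
        )
        rc.write_tsv(tmp_path / "ao.tsv", tmp_path / "ro.tsv")
        back = tg.read_counts(tmp_path / "ao.tsv", tmp_path / "ro.tsv")
        assert back.equals(rc)

    def test_mismatched_files_error(self, tmp_path):
        rc = toy_rc([[3, 0]], [[9, 4]])
        rc.write_tsv(tmp_path / "ao.tsv", tmp_path / "ro.tsv")
        rc2 = toy_rc([[3]], [[9]])
        rc2.write_tsv(tmp_path / "ao2.tsv", tmp_path / "ro2.tsv")
        with pytest.raises(ValueError, match="disagree"):
            tg.read_counts(tmp_path / "ao.tsv", tmp_path / "ro2.tsv")

    def test_vcf_allele_depths(self, tmp_path):
        """AD per sample is (ref, alt): depths (9,3) map to RO=9, AO=3;
        multiallelic records are skipped."""
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\tsnp1\tA\tC\t50\t.\tMQ=40\tGT:AD\t0/1:9,3\n"
            "1\t200\tsnp2\tA\tC,G\t50\t.\tMQ=40\tGT:AD\t0/1:5,2,1\n"
            "1\t300\tsnp3\tA\tC\t5\t.\tMQ=40\tGT:AD\t0/1:4,4\n"
        )
        rc = read_counts_vcf(vcf)
        assert list(rc.marker_ids) == ["snp1"]  # multiallelic + low QUAL dropped
        assert rc.ao[0, 0] == 3 and rc.ro[0, 0] == 9


class TestFilters:
    def test_site_depth_filter_drops_shallow_marker(self):
        # marker m1 has site-mean depth 50 (< 60); m0 has 70
        ao = [[30, 20], [40, 30], [30, 25], [40, 25]]
        ro = [[40, 30], [30, 20], [40, 25], [30, 25]]
        rc = toy_rc(ao, ro)
        th = FilterThresholds(min_site_mean_depth=60, min_datapoint_depth=0,
                              max_missing=1.0, min_maf=0.0)
        out, report = apply_filters(rc, toy_map(2), th)
        assert list(out.marker_ids) == ["m0"]
        assert report.markers_dropped_site_depth == 1

    def test_noop_thresholds_identity(self):
        rc = toy_rc([[3, 0], [5, 2]], [[9, 4], [0, 2]])
        out, report = apply_filters(rc, toy_map(2), NOOP)
        assert out.equals(rc)
        assert report.markers_out == 2 and report.individuals_out == 2

    def test_maf_filter_hand_computed(self):
        """4 individuals with read ratios (1.0, 1.0, 0.9, 0.98) at m0: mean
        frequency 0.97, MAF 0.03 < 0.05 -> dropped.  m1 stays (MAF 0.5)."""
        ao = [[10, 5], [10, 5], [9, 5], [49, 5]]
        ro = [[0, 5], [0, 5], [1, 5], [1, 5]]
        rc = toy_rc(ao, ro)
        th = FilterThresholds(min_site_mean_depth=0, min_datapoint_depth=0,
                              max_missing=1.0, min_maf=0.05)
        out, report = apply_filters(rc, toy_map(2), th)
        assert list(out.marker_ids) == ["m1"]
        assert report.markers_dropped_maf == 1

    def test_datapoint_depth_sets_missing_then_missing_fraction_drops(self):
        # i0 has depth-1 datapoints at 2 of 3 markers -> 2/3 missing -> dropped
        ao = [[1, 0, 3], [5, 4, 3], [5, 4, 3], [5, 4, 3]]
        ro = [[0, 1, 3], [5, 4, 3], [5, 4, 3], [5, 4, 3]]
        rc = toy_rc(ao, ro)
        th = FilterThresholds(min_site_mean_depth=0, min_datapoint_depth=2,
                              max_missing=0.5, min_maf=0.0)
        out, report = apply_filters(rc, toy_map(3), th)
        assert report.datapoints_set_missing_depth == 2
        assert report.individuals_dropped_missing == 1
        assert "i0" not in out.individual_ids

    def test_chromosome_whitelist(self):
        rc = toy_rc([[3, 4], [5, 6]], [[3, 4], [5, 6]])
        mm = toy_map(2, chrom=[1, 2])
        th = FilterThresholds(min_site_mean_depth=0, min_datapoint_depth=0,
                              max_missing=1.0, min_maf=0.0,
                              chrom_whitelist=frozenset({1}))
        out, report = apply_filters(rc, mm, th)
        assert list(out.marker_ids) == ["m0"]
        assert report.markers_dropped_chrom == 1

    def test_filters_idempotent(self):
        rng = np.random.default_rng(0)
        ao = rng.poisson(30, (20, 30))
        ro = rng.poisson(30, (20, 30))
        rc = toy_rc(ao, ro)
        th = FilterThresholds(min_site_mean_depth=55, min_datapoint_depth=2,
                              max_missing=0.2, min_maf=0.05)
        once, _ = apply_filters(rc, toy_map(30), th)
        twice, rep2 = apply_filters(once, toy_map(30), th)
        assert twice.equals(once)

    def test_all_filtered_errors(self):
        rc = toy_rc([[1, 1]], [[1, 1]] )
        th = FilterThresholds(min_site_mean_depth=1000)
        with pytest.raises(ValueError, match="all markers"):
            apply_filters(rc, toy_map(2), th)


class TestRatioGenotypes:
    @pytest.mark.parametrize(
        "ao,ro,expected",
        [(3, 9, 0.25), (0, 7, 0.0), (7, 0, 1.0), (1, 1, 0.5)],
    )
    def test_ratio_formula(self, ao, ro, expected):
        rc = toy_rc([[ao]], [[ro]])
        m = tg.ratio_genotypes(rc)
        assert m.m[0, 0] == pytest.approx(expected)

    def test_zero_depth_names_cell(self):
        rc = toy_rc([[3, 0]], [[9, 0]])
        with pytest.raises(ValueError, match="m1"):
            tg.ratio_genotypes(rc)

    def test_missing_cells_mean_imputed(self):
        rc = toy_rc(
            [[4, 2], [4, 6], [0, 2]],
            [[4, 2], [4, 2], [0, 2]],
            missing=[[False, False], [False, False], [True, False]],
        )
        m = tg.ratio_genotypes(rc)
        assert m.m[2, 0] == pytest.approx(0.5)  # column mean of (0.5, 0.5)
        with pytest.raises(ValueError, match="imputation disabled"):
            tg.ratio_genotypes(rc, impute_missing=False)

    def test_ratios_converge_to_dosage_fraction(self):
        """At high depth the ratio genotype estimates dosage/4: the per-cell
        binomial sd at depth 500 is at most sqrt(.25/500) ~ 0.022, so errors
        beyond 0.1 (4.5 sd) indicate a broken sampler, and the RMS error must
        match the binomial law."""
        rng = np.random.default_rng(1)
        d = rng.integers(0, 5, size=(40, 60))
        rc = tg.simulate_read_counts(
            d, [f"i{k}" for k in range(40)], [f"m{j}" for j in range(60)],
            mean_depth=500, error_rate=0.0, seed=2,
        )
        m = tg.ratio_genotypes(rc)
        err = m.m - d / 4.0
        assert np.max(np.abs(err)) < 0.1
        p = d / 4.0
        expected_rms = np.sqrt(np.mean(p * (1 - p) / 500))
        assert np.sqrt(np.mean(err**2)) == pytest.approx(expected_rms, rel=0.15)


class TestLSMeans:
    def test_balanced_equals_group_means(self):
        rec = pd.DataFrame(
            {
                "individual": ["a", "a", "b", "b", "c", "c"],
                "year": [1, 2, 1, 2, 1, 2],
                "value": [3.0, 5.0, 1.0, 3.0, 4.0, 8.0],
            }
        )
        ls = lsmeans(rec)
        assert ls["a"] == pytest.approx(4.0)
        assert ls["b"] == pytest.approx(2.0)
        assert ls["c"] == pytest.approx(6.0)

    def test_unbalanced_matches_normal_equations(self):
        """One missing cell; the oracle solves the 4-parameter least-squares
        system directly from the explicit design matrix."""
        rec = pd.DataFrame(
            {
                "individual": ["a", "a", "b", "b", "c"],  # c unobserved in year 2
                "year": [1, 2, 1, 2, 1],
                "value": [3.0, 5.0, 1.0, 3.5, 4.0],
            }
        )
        # columns: intercept, b, c, year2
        X = np.array(
            [
                [1, 0, 0, 0],
                [1, 0, 0, 1],
                [1, 1, 0, 0],
                [1, 1, 0, 1],
                [1, 0, 1, 0],
            ],
            dtype=float,
        )
        y = rec["value"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        expected = {
            "a": beta[0] + beta[3] / 2,
            "b": beta[0] + beta[1] + beta[3] / 2,
            "c": beta[0] + beta[2] + beta[3] / 2,
        }
        ls = lsmeans(rec)
        for g, v in expected.items():
            assert ls[g] == pytest.approx(v, abs=1e-10)

    def test_single_year_degenerates_to_means(self):
        rec = pd.DataFrame(
            {"individual": ["a", "a", "b"], "year": [1, 1, 1], "value": [2.0, 4.0, 7.0]}
        )
        ls = lsmeans(rec)
        assert ls["a"] == pytest.approx(3.0)
        assert ls["b"] == pytest.approx(7.0)

    def test_confounded_design_errors(self):
        rec = pd.DataFrame(
            {"individual": ["a", "b"], "year": [1, 2], "value": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="rank"):
            lsmeans(rec)
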