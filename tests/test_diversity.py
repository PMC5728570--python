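"""Weir-Cockerham theta, subsampling, window scan, regions and gene queries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from panelpop import (
    Region,
    candidate_genes,
    fst_weir_cockerham,
    fst_window_scan,
    select_balanced_unrelated,
    top_regions,
)
from panelpop.diversity import DiversityError, read_annotation, regions_to_bed
from panelpop.matrix import MAJOR, MINOR, MISSING
from panelpop.structure import DistanceMatrix

from conftest import make_gm


def two_group_gm(p1_calls, p2_calls):
    calls = np.array(p1_calls + p2_calls, dtype=np.int8)
    gm = make_gm(calls)
    labels = ["A"] * len(p1_calls) + ["B"] * len(p2_calls)
    return gm, labels


class TestSelectBalancedUnrelated:
    def test_target_equals_group_size_identity(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
        dm = DistanceMatrix(d, ["a", "b", "c"])
        assert select_balanced_unrelated(dm, ["g"] * 3, 3) == ["a", "b", "c"]

    def test_duplicate_pair_member_removed_first(self):
        # a and b are identical (D = 0); one of them must go first
        d = np.array(
            [[0, 0, 5, 6], [0, 0, 5, 6], [5, 5, 0, 7], [6, 6, 7, 0]], float
        )
        dm = DistanceMatrix(d, ["a", "b", "c", "d"])
        kept = select_balanced_unrelated(dm, ["g"] * 4, 3)
        assert len({"a", "b"} & set(kept)) == 1
        assert {"c", "d"} <= set(kept)

    def test_small_group_raises_with_group_name(self):
        d = np.zeros((3, 3))
        dm = DistanceMatrix(d, ["a", "b", "c"])
        with pytest.raises(DiversityError, match="g2"):
            select_balanced_unrelated(dm, ["g1", "g1", "g2"], 2)

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        x = rng.random((10, 2))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, [f"n{i}" for i in range(10)])
        labels = ["g"] * 10
        assert select_balanced_unrelated(dm, labels, 5) == select_balanced_unrelated(
            dm, labels, 5
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_kept_set_spreads_out(self, seed):
        """Greedy kin-removal lands in the top 30% of all same-size subsets
        by minimum within-set pairwise distance (calibrated bound)."""
        rng = np.random.default_rng(seed)
        n, target = 8, 4
        x = rng.random((n, 2))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        names = [f"n{i}" for i in range(n)]
        kept = select_balanced_unrelated(
            DistanceMatrix(d, names), ["g"] * n, target
        )
        kidx = [names.index(k) for k in kept]

        def minpd(idx):
            sub = d[np.ix_(list(idx), list(idx))].copy()
            np.fill_diagonal(sub, np.inf)
            return sub.min()

        all_md = sorted(
            minpd(c) for c in itertools.combinations(range(n), target)
        )
        rank = np.searchsorted(all_md, minpd(kidx)) / len(all_md)
        assert rank >= 0.7


class TestWeirCockerham:
    def test_fixation_hand_case_theta_one(self):
        """Two groups of 4, fixed for opposite alleles: MSG=0, MSP=2, theta=1."""
        gm, labels = two_group_gm([[MINOR]] * 4, [[MAJOR]] * 4)
        res = fst_weir_cockerham(gm, labels)
        assert res.msg[0] == 0.0
        assert res.msp[0] == pytest.approx(2.0)
        assert res.n_c[0] == pytest.approx(4.0)
        assert res.theta[0] == pytest.approx(1.0)
        assert res.overall == pytest.approx(1.0)

    def test_identical_frequencies_theta_near_zero(self):
        rng = np.random.default_rng(17)
        block = rng.choice([0, 2], size=(100, 200), p=[0.6, 0.4]).astype(np.int8)
        block2 = rng.choice([0, 2], size=(100, 200), p=[0.6, 0.4]).astype(np.int8)
        gm = make_gm(np.vstack([block, block2]))
        labels = ["A"] * 100 + ["B"] * 100
        res = fst_weir_cockerham(gm, labels)
        assert abs(res.overall) < 0.05

    def test_allele_label_invariance(self):
        rng = np.random.default_rng(19)
        calls = rng.choice([0, 2], size=(30, 50)).astype(np.int8)
        labels = ["A"] * 15 + ["B"] * 15
        t1 = fst_weir_cockerham(make_gm(calls), labels).theta
        t2 = fst_weir_cockerham(make_gm(2 - calls), labels).theta
        np.testing.assert_allclose(t1, t2, atol=1e-12, equal_nan=True)

    def test_monomorphic_locus_flagged_excluded(self):
        gm, labels = two_group_gm(
            [[MAJOR, MINOR], [MAJOR, MAJOR]], [[MAJOR, MINOR], [MAJOR, MAJOR]]
        )
        res = fst_weir_cockerham(gm, labels)
        assert np.isnan(res.theta[0])  # monomorphic everywhere
        assert np.isfinite(res.theta[1])
        assert res.overall == pytest.approx(res.theta[1])

    def test_groups_with_insufficient_calls_undefined(self):
        gm, labels = two_group_gm(
            [[MINOR], [MINOR]], [[MISSING], [MAJOR]]
        )
        res = fst_weir_cockerham(gm, labels)
        assert np.isnan(res.theta[0])  # group B has a single non-missing call

    def test_single_group_rejected(self):
        gm = make_gm([[0], [2]])
        with pytest.raises(DiversityError):
            fst_weir_cockerham(gm, ["A", "A"])

    def test_ratio_of_sums_variant_differs_but_close(self, default_truth):
        gm = default_truth.complete.take_sites(np.arange(2000))
        labels = default_truth.group_labels
        mean = fst_weir_cockerham(gm, labels, overall_method="mean")
        ratio = fst_weir_cockerham(gm, labels, overall_method="ratio")
        assert mean.overall != ratio.overall
        assert abs(mean.overall - ratio.overall) < 0.2


class TestWindowScan:
    def make_fst(self, thetas, chroms=None, positions=None):
        n = len(thetas)
        chroms = chroms or ["1"] * n
        positions = positions or list(range(10, 10 * n + 10, 10))
        gm = make_gm(
            np.tile(np.array([[0], [2]], dtype=np.int8), (1, n)),
            chrom=chroms,
        )
        res = fst_weir_cockerham(gm, ["A", "B"])
        res.theta = np.asarray(thetas, dtype=float)
        res.sites = pd.DataFrame({"chrom": chroms, "pos": positions})
        return res

    def test_constant_theta_constant_windows(self):
        scan = fst_window_scan(self.make_fst([0.3] * 10), window_snps=4)
        np.testing.assert_allclose(scan["mean_theta"], 0.3)

    def test_hand_average_window_of_three(self):
        scan = fst_window_scan(self.make_fst([0.1, 0.2, 0.6]), window_snps=3)
        assert len(scan) == 1
        assert scan["mean_theta"].iloc[0] == pytest.approx(0.3)
        assert scan["start_pos"].iloc[0] == 10
        assert scan["end_pos"].iloc[0] == 30

    def test_windows_never_span_chromosomes(self):
        thetas = [0.1] * 6 + [0.9] * 6
        chroms = ["1"] * 6 + ["2"] * 6
        scan = fst_window_scan(self.make_fst(thetas, chroms=chroms), window_snps=4)
        means = set(np.round(scan["mean_theta"], 6))
        assert means == {0.1, 0.9}  # no mixed-chromosome window

    def test_undefined_loci_skipped(self):
        thetas = [0.2, np.nan, 0.4]
        scan = fst_window_scan(self.make_fst(thetas), window_snps=2)
        np.testing.assert_allclose(scan["mean_theta"], [0.3])
        assert scan["start_pos"].iloc[0] == 10 and scan["end_pos"].iloc[0] == 30

    def test_short_chromosome_warns_and_skips(self):
        thetas = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
        chroms = ["1"] * 5 + ["2"] * 2
        with pytest.warns(UserWarning, match="skipped"):
            scan = fst_window_scan(
                self.make_fst(thetas, chroms=chroms), window_snps=3
            )
        assert set(scan["chrom"]) == {"1"}


class TestRegions:
    def test_region_size_is_marker_span(self):
        r = Region("7", 36258886, 41462768, 0.3039)
        assert r.size == 5_203_882

    def test_overlapping_windows_coalesce_to_union(self):
        scan = pd.DataFrame(
            {
                "chrom": ["1", "1", "1"],
                "start_pos": [100, 150, 220],
                "end_pos": [200, 260, 300],
                "mean_theta": [0.5, 0.4, 0.3],
            }
        )
        regions = top_regions(scan, 2)
        assert len(regions) == 1
        assert (regions[0].first_pos, regions[0].last_pos) == (100, 300)
        assert regions[0].mean_theta == 0.5  # max window mean

    def test_equal_mean_windows_deterministic_order(self):
        scan = pd.DataFrame(
            {
                "chrom": ["2", "1"],
                "start_pos": [500, 100],
                "end_pos": [600, 200],
                "mean_theta": [0.4, 0.4],
            }
        )
        regions = top_regions(scan, 2)
        assert [(r.chrom, r.first_pos) for r in regions] == [("1", 100), ("2", 500)]

    def test_more_regions_than_windows_warns(self):
        scan = pd.DataFrame(
            {"chrom": ["1"], "start_pos": [10], "end_pos": [50], "mean_theta": [0.2]}
        )
        with pytest.warns(UserWarning):
            regions = top_regions(scan, 3)
        assert len(regions) == 1

    def test_bed_conversion_zero_based_half_open(self, tmp_path):
        p = tmp_path / "r.bed"
        regions_to_bed([Region("1", 101, 200, 0.5)], str(p))
        chrom, start, end, _ = p.read_text().split()
        assert (chrom, int(start), int(end)) == ("1", 100, 200)

    def test_window_means_recompute_from_per_locus(self, default_truth):
        gm = default_truth.complete.take_sites(np.arange(1000))
        res = fst_weir_cockerham(gm, default_truth.group_labels)
        scan = fst_window_scan(res, window_snps=70)
        theta = res.theta[np.isfinite(res.theta)]
        np.testing.assert_allclose(
            scan["mean_theta"].iloc[0], theta[:70].mean(), atol=1e-12
        )


class TestCandidateGenes:
    def annotation(self):
        return pd.DataFrame(
            {
                "chrom": ["1", "1", "1", "9"],
                "start": [90, 19_990, 31_001, 5],
                "end": [120, 19_995, 31_005, 50],
                "gene_id": ["inside", "edge", "outside", "offpanel"],
                "description": ["d1", "d2", "d3", "d4"],
            }
        )

    def make_fst_at(self, pos=30_000, theta=0.9):
        gm = make_gm([[MAJOR], [MINOR], [MAJOR], [MINOR]])
        res = fst_weir_cockerham(gm, ["A", "A", "B", "B"])
        res.sites = pd.DataFrame({"chrom": ["1"], "pos": [pos]})
        res.theta = np.array([theta])
        return res

    def test_gene_spanning_snp_distance_zero(self):
        res = self.make_fst_at(pos=100)
        with pytest.warns(UserWarning, match="not in panel"):
            hits = candidate_genes(res, self.annotation(), theta_min=0.5)
        inside = [h for h in hits if h.gene_id == "inside"]
        assert inside and inside[0].distance == 0

    def test_closed_interval_boundary_at_ten_kb(self):
        # SNP at 30,000: gene ending exactly at 20,000 - 10 = ...
        ann = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "start": [19_000, 18_000],
                "end": [20_000, 19_999],
                "gene_id": ["at_edge", "past_edge"],
                "description": ["", ""],
            }
        )
        res = self.make_fst_at(pos=30_000)
        hits = candidate_genes(res, ann, half_window=10_000, theta_min=0.5)
        ids = {h.gene_id for h in hits}
        assert ids == {"at_edge"}
        assert hits[0].distance == 10_000

    def test_theta_threshold_filters_snps(self):
        res = self.make_fst_at(pos=100, theta=0.3)
        hits = candidate_genes(
            res, self.annotation()[:3], theta_min=0.5
        )
        assert hits == []

    def test_gff3_and_tsv_annotation_readers(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t100\t500\t.\t+\t.\tID=gene1;description=kinase\n"
            "1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=t1;Parent=gene1\n"
            "2\tsrc\tgene\t900\t950\t.\t-\t.\tID=gene2\n"
        )
        df = read_annotation(str(gff))
        assert df["gene_id"].tolist() == ["gene1", "gene2"]
        assert df["description"].iloc[0] == "kinase"
        assert df[["start", "end"]].iloc[0].tolist() == [100, 500]

        tsv = tmp_path / "genes.tsv"
        tsv.write_text("1\t100\t500\tgene1\tkinase\n2\t900\t950\tgene2\n")
        df2 = read_annotation(str(tsv))
        assert df2["gene_id"].tolist() == ["gene1", "gene2"]
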