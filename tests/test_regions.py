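import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from omvar.models import Alignment, LabelMap
from omvar.regions import (
    annotate_region_features,
    classify_coverage_state,
    estimate_gap_size,
    flag_complex_candidate,
    permutation_overlap_test,
)


class TestCoverageState:
    def _tracks(self, n=1000, cov=100, scaf=1):
        return {"chr1": np.full(n, cov, float)}, {"chr1": np.full(n, scaf, int)}

    def test_high_coverage_single_scaffold_low_complexity(self):
        cov, scaf = self._tracks(cov=100, scaf=1)
        rc = classify_coverage_state(cov, scaf)
        assert list(rc.intervals["region_class"]) == ["low_complexity"]

    def test_high_coverage_no_scaffold_complex_candidate(self):
        cov, scaf = self._tracks(cov=100, scaf=0)
        rc = classify_coverage_state(cov, scaf)
        assert list(rc.intervals["region_class"]) == ["complex_candidate"]

    def test_two_scaffolds_complex_candidate(self):
        cov, scaf = self._tracks(cov=100, scaf=2)
        rc = classify_coverage_state(cov, scaf)
        assert list(rc.intervals["region_class"]) == ["complex_candidate"]

    def test_fifty_x_autosome_low_coverage(self):
        cov, scaf = self._tracks(cov=50, scaf=1)
        rc = classify_coverage_state(cov, scaf)
        assert list(rc.intervals["region_class"]) == ["low_coverage"]

    def test_chr_y_threshold_override(self):
        cov = {"chrY": np.full(100, 50.0)}
        scaf = {"chrY": np.ones(100, int)}
        rc = classify_coverage_state(cov, scaf, cov_threshold_by_chrom={"chrY": 46.0})
        assert list(rc.intervals["region_class"]) == ["low_complexity"]

    def test_partition_covers_whole_track(self):
        cov = {"chr1": np.concatenate([np.full(300, 100.0), np.full(200, 10.0), np.full(500, 100.0)])}
        scaf = {"chr1": np.concatenate([np.ones(300, int), np.ones(200, int), np.full(500, 2, int)])}
        rc = classify_coverage_state(cov, scaf)
        assert rc.total_length() == 1000
        assert rc.total_length("low_coverage") == 200
        assert rc.total_length("complex_candidate") == 500

    def test_track_length_mismatch_error(self):
        with pytest.raises(ValueError, match="differ in length"):
            classify_coverage_state(
                {"chr1": np.ones(10)}, {"chr1": np.ones(5, int)}
            )

    def test_inaccessible_overrides(self):
        cov, scaf = self._tracks(cov=100, scaf=1)
        rc = classify_coverage_state(cov, scaf, inaccessible=[("chr1", 100, 300)])
        assert rc.total_length("inaccessible") == 200


class TestComplexFlag:
    def test_mixed_recurrent_svs_complex(self):
        inv = {"sv_type": "inversion", "size": 50_000, "cohort_count": 3}
        dup = {"sv_type": "duplication", "size": 40_000, "cohort_count": 2}
        indel = {"sv_type": "deletion", "size": 15_000, "cohort_count": 4}
        assert flag_complex_candidate(("chr1", 0, 1e6), [inv, dup, indel])

    def test_indels_only_none_over_100kb_not_complex(self):
        svs = [
            {"sv_type": "deletion", "size": s, "cohort_count": 3}
            for s in (20_000, 30_000, 50_000)
        ]
        assert not flag_complex_candidate(("chr1", 0, 1e6), svs)

    def test_indels_only_with_large_one_complex(self):
        svs = [
            {"sv_type": "deletion", "size": s, "cohort_count": 3}
            for s in (20_000, 30_000, 150_000)
        ]
        assert flag_complex_candidate(("chr1", 0, 1e6), svs)

    def test_two_svs_below_threshold(self):
        svs = [
            {"sv_type": "inversion", "size": 50_000, "cohort_count": 5},
            {"sv_type": "duplication", "size": 50_000, "cohort_count": 5},
        ]
        assert not flag_complex_candidate(("chr1", 0, 1e6), svs)

    def test_singletons_and_small_indels_dropped(self):
        svs = [
            {"sv_type": "inversion", "size": 50_000, "cohort_count": 1},  # singleton
            {"sv_type": "deletion", "size": 8_000, "cohort_count": 5},  # <=10 kb indel
            {"sv_type": "duplication", "size": 50_000, "cohort_count": 3},
            {"sv_type": "inversion", "size": 20_000, "cohort_count": 2},
        ]
        assert not flag_complex_candidate(("chr1", 0, 1e6), svs)


CHROM_LENGTHS = {"chr1": 10_000_000.0}


class TestPermutationTest:
    def test_self_overlap_attains_minimum_p(self):
        regions = [("chr1", 1_000_000, 1_100_000), ("chr1", 5_000_000, 5_200_000)]
        p = permutation_overlap_test(regions, regions, [], CHROM_LENGTHS, n_perm=200, seed=1)
        assert p <= 0.05

    def test_empty_feature_p_one(self):
        regions = [("chr1", 1_000_000, 1_100_000)]
        p = permutation_overlap_test(regions, [], [], CHROM_LENGTHS, n_perm=100, seed=2)
        assert p == 1.0

    def test_region_larger_than_any_gap_errors(self):
        with pytest.raises(ValueError, match="allowed gap"):
            permutation_overlap_test(
                [("chr1", 0, 9_000_000)],
                [],
                [("chr1", 4_000_000, 6_000_000)],
                CHROM_LENGTHS,
                n_perm=10,
                seed=3,
            )

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(4)
        pvals = []
        for run in range(60):
            regions = [
                ("chr1", s, s + 100_000)
                for s in rng.uniform(0, 9.9e6 - 1e5, 5)
            ]
            feature = [
                ("chr1", s, s + 50_000)
                for s in rng.uniform(0, 9.9e6 - 5e4, 20)
            ]
            pvals.append(
                permutation_overlap_test(regions, feature, [], CHROM_LENGTHS,
                                         n_perm=200, seed=1000 + run)
            )
        # conservative validity check at alpha 0.01
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_excluded_space_never_used(self):
        # features only inside the excluded region: permuted regions cannot
        # land there, so permuted overlap counts are all zero
        regions = [("chr1", 8_000_000, 8_100_000)]
        feature = [("chr1", 4_500_000, 4_600_000)]
        excluded = [("chr1", 4_000_000, 5_000_000)]
        p = permutation_overlap_test(regions, feature, excluded, CHROM_LENGTHS,
                                     n_perm=300, seed=5)
        assert p == 1.0  # observed overlap 0 >= all-zero permutations


class TestAnnotate:
    def test_segdup_filters_applied(self):
        segdups = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [100_000, 300_000, 600_000],
                "end": [108_000, 330_000, 650_000],
                "identity": [0.99, 0.90, 0.97],
            }
        )
        out = annotate_region_features([("chr1", 0, 1_000_000)], segdups=segdups)
        # 8-kb SD fails length filter; 0.90 identity fails identity filter
        assert out.loc[0, "segdup_bp"] == 50_000

    def test_tandem_repeat_score_filter(self):
        trs = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [100_000, 400_000],
                "end": [130_000, 410_000],
                "score": [1_500, 2_500],
            }
        )
        out = annotate_region_features([("chr1", 0, 1_000_000)], tandem_repeats=trs)
        assert out.loc[0, "tandem_repeat_bp"] == 10_000

    def test_missing_filter_column_errors(self):
        segdups = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [20_000]})
        with pytest.raises(KeyError, match="identity"):
            annotate_region_features([("chr1", 0, 1_000_000)], segdups=segdups)

    def test_subtelomeric_and_pericentromeric_zones(self):
        out = annotate_region_features(
            [("chr1", 5_000_000, 5_100_000), ("chr1", 60_000_000, 60_100_000),
             ("chr1", 95_000_000, 95_200_000)],
            chrom_lengths={"chr1": 200_000_000.0},
            centromeres={"chr1": 100_000_000.0},
        )
        assert bool(out.loc[0, "subtelomeric"])  # 5 Mb from the start
        assert not bool(out.loc[1, "subtelomeric"])
        assert bool(out.loc[2, "pericentromeric"])  # within 9 Mb of centromere


class TestGapSize:
    def _setup(self):
        rpos = np.arange(10_000.0, 500_000.0, 10_000.0)
        ref = LabelMap("chr1", "reference", 500_000.0, rpos)
        return ref

    def _alignment(self, ref, qpos, pairs):
        a = Alignment("contig1", "chr1", "+", pairs, 100.0)
        qmap = LabelMap("contig1", "contig", float(max(qpos) + 10_000), np.asarray(qpos, float))
        return a, {"contig1": qmap}

    def test_gap_filled_with_declared_size(self):
        ref = self._setup()
        gap = ("chr1", 200_000.0, 210_000.0)  # declared size 10 kb
        # contig pairs labels at 190k (idx 18) and 220k (idx 21); its own
        # distance across is 10k (flank 10k+10k) + true gap content 10 kb
        a, qmaps = self._alignment(ref, [50_000.0, 80_000.0], [(0, 18), (1, 21)])
        est = estimate_gap_size(gap, [a], ref, qmaps)
        assert est == pytest.approx(10_000.0, abs=1.0)

    def test_zero_size_gap(self):
        ref = self._setup()
        gap = ("chr1", 200_000.0, 200_000.0)
        a, qmaps = self._alignment(ref, [50_000.0, 80_000.0], [(0, 18), (1, 21)])
        est = estimate_gap_size(gap, [a], ref, qmaps)
        assert est == pytest.approx(0.0, abs=1.0)

    def test_negative_estimate_for_deletion_spanning_gap(self):
        ref = self._setup()
        gap = ("chr1", 200_000.0, 210_000.0)
        # query distance 20 kb shorter than flanks+gap: net -20 kb + 10 kb gap
        a, qmaps = self._alignment(ref, [50_000.0, 60_000.0], [(0, 18), (1, 21)])
        est = estimate_gap_size(gap, [a], ref, qmaps)
        assert est == pytest.approx(-10_000.0, abs=1.0)

    def test_no_spanning_alignment_unsized(self):
        ref = self._setup()
        gap = ("chr1", 200_000.0, 210_000.0)
        a, qmaps = self._alignment(ref, [50_000.0, 60_000.0], [(0, 5), (1, 8)])
        assert estimate_gap_size(gap, [a], ref, qmaps) is None
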