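import numpy as np
import pandas as pd
import pytest

from sscatac import core

from conftest import intensity_matrix, rank_mean_oracle


class TestReadPeaksBed:
    def test_parses_bed3_with_autogenerated_ids(self, tmp_path):
        p = tmp_path / "peaks.bed"
        p.write_text("chr1\t100\t600\nchr1\t700\t900\nchr2\t0\t50\n")
        peaks = core.read_peaks_bed(p)
        assert len(peaks) == 3
        assert peaks.ids == ["chr1:100-600", "chr1:700-900", "chr2:0-50"]
        assert peaks.peaks[0].interval == core.GenomicInterval("chr1", 100, 600)

    def test_inverted_interval_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t600\nchr1\t600\t100\n")
        with pytest.raises(ValueError, match="bad.bed:2"):
            core.read_peaks_bed(p)

    def test_too_few_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\n")
        with pytest.raises(ValueError, match=">=3"):
            core.read_peaks_bed(p)

    def test_name_column_used_when_present(self, tmp_path):
        p = tmp_path / "named.bed"
        p.write_text("chr1\t10\t20\tmyPeak\t0\t+\n")
        assert core.read_peaks_bed(p).ids == ["myPeak"]


class TestCountMatrixIO:
    def test_round_trip_is_lossless(self, tmp_path, tiny_matrix):
        out = tmp_path / "m.tsv"
        core.write_matrix(tiny_matrix, out)
        back = core.read_count_matrix(out)
        pd.testing.assert_frame_equal(back.raw, tiny_matrix.raw)

    def test_duplicate_peak_id_rejected(self, tmp_path):
        out = tmp_path / "dup.tsv"
        out.write_text("peak_id\ts1\np1\t3\np1\t4\n")
        with pytest.raises(ValueError, match="duplicate"):
            core.read_count_matrix(out)

    def test_non_integer_counts_rejected(self):
        df = pd.DataFrame({"s1": [1.5], "s2": [2.0]}, index=["p1"])
        with pytest.raises(ValueError, match="integer"):
            core.AccessibilityMatrix(df)

    def test_negative_counts_rejected(self):
        df = pd.DataFrame({"s1": [-1], "s2": [2]}, index=["p1"])
        with pytest.raises(ValueError, match="non-negative"):
            core.AccessibilityMatrix(df)


class TestQuantileNormalize:
    def test_two_column_example(self):
        df = pd.DataFrame({"a": [1, 3], "b": [2, 4]}, index=["p1", "p2"])
        m = core.quantile_normalize(core.AccessibilityMatrix(df))
        expected = np.array([[1.5, 1.5], [3.5, 3.5]])
        np.testing.assert_allclose(m.normalized.to_numpy(), expected)

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [5, 1, 9], "b": [5, 1, 9]}, index=list("xyz"))
        m = core.quantile_normalize(core.AccessibilityMatrix(df))
        np.testing.assert_allclose(m.normalized.to_numpy(), df.to_numpy())

    def test_sorted_columns_identical_on_random_tie_free_matrix(self):
        rng = np.random.default_rng(0)
        # tie-free columns share the reference exactly; tied values receive
        # their rank block's mean instead (see the oracle test below)
        X = rng.permutation(np.arange(250)).reshape(50, 5)
        m = core.quantile_normalize(
            core.AccessibilityMatrix(pd.DataFrame(X, index=[f"p{i}" for i in range(50)]))
        )
        s = np.sort(m.normalized.to_numpy(), axis=0)
        for j in range(1, 5):
            np.testing.assert_array_equal(s[:, 0], s[:, j])

    def test_ties_match_rank_mean_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 8, size=(40, 4)).astype(float)  # many ties
        df = pd.DataFrame(X, index=[f"p{i}" for i in range(40)])
        m = core.quantile_normalize(core.AccessibilityMatrix(df))
        np.testing.assert_allclose(m.normalized.to_numpy(), rank_mean_oracle(X))

    def test_grand_sum_conserved_without_ties(self):
        rng = np.random.default_rng(2)
        X = rng.permutation(np.arange(1, 201)).reshape(50, 4).astype(float)
        df = pd.DataFrame(X, index=[f"p{i}" for i in range(50)])
        m = core.quantile_normalize(core.AccessibilityMatrix(df))
        col_sums = m.normalized.sum(axis=0).to_numpy()
        np.testing.assert_allclose(col_sums, X.sum(axis=0).mean())

    def test_column_sums_equal_even_with_ties(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            rng.integers(0, 5, size=(30, 3)), index=[f"p{i}" for i in range(30)]
        )
        m = core.quantile_normalize(core.AccessibilityMatrix(df))
        sums = m.normalized.sum(axis=0).to_numpy()
        assert np.ptp(sums) < 1e-9 * max(1.0, sums[0])

    def test_single_column_rejected(self):
        df = pd.DataFrame({"only": [1, 2]}, index=["p1", "p2"])
        with pytest.raises(ValueError, match=">= 2"):
            core.quantile_normalize(core.AccessibilityMatrix(df))


class TestIntensity:
    def test_log2_with_pseudocount(self, tiny_matrix):
        tiny_matrix.normalized = pd.DataFrame(
            {"s1": [3.0, 0.0], "s2": [1.0, 7.0]}, index=tiny_matrix.raw.index
        )
        core.intensity(tiny_matrix)
        np.testing.assert_allclose(
            tiny_matrix.intensity.to_numpy(), [[2.0, 1.0], [0.0, 3.0]]
        )

    def test_monotone_in_normalized_value(self, tiny_matrix):
        tiny_matrix.normalized = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [3.0, 4.0]}, index=tiny_matrix.raw.index
        )
        core.intensity(tiny_matrix)
        flat = np.ravel(tiny_matrix.intensity.to_numpy(), order="F")
        assert (np.diff(flat) > 0).all()

    def test_requires_normalization_first(self, tiny_matrix):
        with pytest.raises(ValueError, match="normalize"):
            core.intensity(tiny_matrix)


def _peakset(coords):
    return core.PeakSet(
        [core.Peak(core.GenomicInterval(c, s, e), f"{c}:{s}-{e}") for c, s, e in coords]
    )


class TestNearestGene:
    def test_picks_nearest_tss_with_signed_distance(self):
        peaks = _peakset([("chr1", 400, 600)])  # center 500
        genes = [
            core.GeneModel("far", "chr1", 5000),
            core.GeneModel("near", "chr1", 400),
        ]
        ann = core.annotate_nearest_gene(peaks, genes)
        assert ann.iloc[0]["gene_id"] == "near"
        assert ann.iloc[0]["distance"] == 100

    def test_equidistant_tie_breaks_lexicographically(self):
        peaks = _peakset([("chr1", 450, 550)])  # center 500
        genes = [
            core.GeneModel("geneB", "chr1", 400),
            core.GeneModel("geneA", "chr1", 600),
        ]
        ann = core.annotate_nearest_gene(peaks, genes)
        assert ann.iloc[0]["gene_id"] == "geneA"

    def test_chromosome_without_genes_gives_na(self):
        peaks = _peakset([("chrX", 0, 100)])
        ann = core.annotate_nearest_gene(peaks, [core.GeneModel("g", "chr1", 5)])
        assert ann.iloc[0]["gene_id"] == "NA"
        assert np.isnan(ann.iloc[0]["distance"])

    def test_matches_brute_force_on_random_instance(self):
        rng = np.random.default_rng(4)
        starts = rng.integers(0, 100_000, size=20)
        peaks = _peakset([("chr1", int(s), int(s) + 200) for s in np.unique(starts)])
        genes = [
            core.GeneModel(f"g{k:02d}", "chr1", int(t))
            for k, t in enumerate(rng.integers(0, 100_000, size=10))
        ]
        ann = core.annotate_nearest_gene(peaks, genes)
        for p in peaks:
            c = p.interval.center
            best = min(genes, key=lambda g: (abs(c - g.tss), g.gene_id))
            assert ann.loc[p.peak_id, "gene_id"] == best.gene_id


class TestClassifyDistal:
    @pytest.mark.parametrize(
        "center,expected", [(1399, "proximal"), (1401, "distal"), (401, "proximal")]
    )
    def test_threshold_boundaries(self, center, expected):
        peaks = _peakset([("chr1", center - 100, center + 100)])
        genes = [core.GeneModel("g", "chr1", 400)]
        assert core.classify_distal(peaks, genes).iloc[0] == expected

    def test_min_dist_zero_makes_nonzero_distances_distal(self):
        peaks = _peakset([("chr1", 400, 600), ("chr1", 300, 500)])
        genes = [core.GeneModel("g", "chr1", 500)]
        labels = core.classify_distal(peaks, genes, min_dist=0)
        assert labels.tolist() == ["proximal", "distal"]  # center 500 vs 400


class TestGeneAccessibility:
    def test_sums_assigned_peak_intensities(self):
        m = intensity_matrix(np.array([[2.0, 1.0], [3.0, 5.0], [7.0, 1.0]]))
        ann = pd.DataFrame(
            {"gene_id": ["gA", "gA", "gB"], "distance": [0, 0, 0]},
            index=m.intensity.index,
        )
        acc = core.gene_accessibility(m, ann)
        np.testing.assert_allclose(acc.loc["gA"].to_numpy(), [5.0, 6.0])
        np.testing.assert_allclose(acc.loc["gB"].to_numpy(), [7.0, 1.0])

    def test_invariant_to_peak_order(self):
        vals = np.array([[2.0, 1.0], [3.0, 5.0], [7.0, 1.0]])
        m1 = intensity_matrix(vals)
        ann = pd.DataFrame(
            {"gene_id": ["gA", "gB", "gA"], "distance": [0, 0, 0]},
            index=m1.intensity.index,
        )
        acc1 = core.gene_accessibility(m1, ann)
        perm = [2, 0, 1]
        m2 = intensity_matrix(vals[perm])
        m2.intensity.index = m1.intensity.index[perm]
        m2.normalized.index = m1.intensity.index[perm]
        acc2 = core.gene_accessibility(m2, ann)
        pd.testing.assert_frame_equal(acc1.sort_index(), acc2.sort_index())

    def test_unassigned_genes_absent(self):
        m = intensity_matrix(np.array([[2.0, 1.0]]))
        ann = pd.DataFrame({"gene_id": ["NA"], "distance": [np.nan]}, index=m.intensity.index)
        assert core.gene_accessibility(m, ann).empty


class TestSampleCorrelation:
    def test_duplicate_and_negated_samples(self):
        base = np.array([1.0, 2.0, 5.0, 3.0])
        m = intensity_matrix(np.column_stack([base, base, -base]), ["a", "b", "c"])
        corr, _ = core.sample_correlation(m)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_leaf_order_separates_planted_groups(self):
        rng = np.random.default_rng(5)
        g1 = np.tile(rng.normal(0, 1, size=(60, 1)), (1, 2)) + rng.normal(0, 0.05, (60, 2))
        g2 = np.tile(rng.normal(4, 1, size=(60, 1)), (1, 2)) + rng.normal(0, 0.05, (60, 2))
        m = intensity_matrix(np.column_stack([g1[:, 0], g2[:, 0], g1[:, 1], g2[:, 1]]),
                             ["a1", "b1", "a2", "b2"])
        _, order = core.sample_correlation(m)
        assert {order[0], order[1]} in ({"a1", "a2"}, {"b1", "b2"})

    def test_zero_variance_sample_warns(self):
        m = intensity_matrix(np.array([[1.0, 2.0], [1.0, 3.0]]), ["flat", "ok"])
        with pytest.warns(UserWarning, match="zero-variance"):
            corr, _ = core.sample_correlation(m)
        assert np.isnan(corr.loc["flat", "ok"])


class TestQuantileNormalizeProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        X=hnp.arrays(
            np.int64,
            shape=st.tuples(st.integers(2, 30), st.integers(2, 5)),
            elements=st.integers(0, 50),
        )
    )
    def test_matches_oracle_and_equalizes_column_sums(self, X):
        df = pd.DataFrame(X, index=[f"p{i}" for i in range(X.shape[0])])
        m = core.quantile_normalize(core.AccessibilityMatrix(df))
        out = m.normalized.to_numpy()
        np.testing.assert_allclose(out, rank_mean_oracle(X.astype(float)), atol=1e-9)
        sums = out.sum(axis=0)
        assert np.ptp(sums) <= 1e-9 * max(1.0, abs(sums[0]))
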