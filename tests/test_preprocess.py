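"""Preprocessing: Y-gene removal, size factors, batch adjustment, filtering,
variance stabilization and PCA QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hervscope import (
    CountMatrix,
    GeneAnnotation,
    SampleDesign,
    batch_adjust,
    drop_y_genes,
    jaccard_filter,
    pca_qc,
    size_factors,
    synthetic,
    vst,
)

from conftest import small_matrix


class TestDropYGenes:
    GENES = [
        GeneAnnotation("g1", "chr1", 0, 100),
        GeneAnnotation("g2", "chrY", 0, 100),
        GeneAnnotation("g3", "Y", 200, 300),
    ]

    def test_no_y_identity(self):
        m = small_matrix([[1, 2], [3, 4]], ["case", "control"])
        out = drop_y_genes(m, [GeneAnnotation("f1", "chr1", 0, 10)])
        assert out.counts.equals(m.counts)

    def test_removes_y_genes_only(self):
        m = small_matrix([[1, 1], [2, 2], [3, 3], [4, 4], [5, 5]],
                         ["case", "control"])
        genes = [
            GeneAnnotation("f1", "chr1", 0, 10),
            GeneAnnotation("f2", "chrY", 0, 10),
            GeneAnnotation("f3", "Y", 0, 10),
        ]
        out = drop_y_genes(m, genes)
        assert out.feature_ids == ["f1", "f4", "f5"]
        assert out.counts.loc["f1"].tolist() == [1, 1]

    def test_herv_on_y_retained(self):
        """The rule targets genes: an unannotated (HERV) feature on Y stays."""
        m = small_matrix([[1, 1], [2, 2]], ["case", "control"])
        genes = [GeneAnnotation("f1", "chrY", 0, 10)]  # f2 is a HERV locus
        out = drop_y_genes(m, genes)
        assert out.feature_ids == ["f2"]


class TestSizeFactors:
    def test_identical_samples(self):
        m = small_matrix([[10, 10], [5, 5]], ["case", "control"])
        np.testing.assert_allclose(size_factors(m), [1.0, 1.0])

    def test_doubled_sample_closed_form(self):
        """sample2 = 2 x sample1 gives factors (1/sqrt(2), sqrt(2))."""
        m = small_matrix([[10, 20], [7, 14], [100, 200]], ["case", "control"])
        np.testing.assert_allclose(
            size_factors(m), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_global_scale_invariance(self):
        """Median-of-ratios is invariant to scaling every sample by c: the
        geometric-mean reference absorbs the constant."""
        m1 = small_matrix([[10, 20], [7, 14]], ["case", "control"])
        m2 = small_matrix([[30, 60], [21, 42]], ["case", "control"])
        np.testing.assert_allclose(size_factors(m2), size_factors(m1).to_numpy())

    def test_single_sample_scaling(self):
        """Scaling one sample by c splits into (c^-1/2, c^1/2) for two samples."""
        m1 = small_matrix([[10, 10], [7, 7], [100, 100]], ["case", "control"])
        m2 = small_matrix([[10, 30], [7, 21], [100, 300]], ["case", "control"])
        np.testing.assert_allclose(
            size_factors(m2),
            size_factors(m1).to_numpy() * [1 / np.sqrt(3), np.sqrt(3)],
        )

    def test_no_all_nonzero_feature(self):
        m = small_matrix([[0, 5], [5, 0]], ["case", "control"])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(m)


class TestBatchAdjust:
    def test_single_batch_identity(self, balanced_design):
        m, _ = synthetic.simulate_counts(balanced_design, 50, seed=1)
        out = batch_adjust(m)
        assert out.counts.equals(m.counts)

    def test_confounded_design_refused(self):
        samples = [SampleDesign("s1", "case", "b1"), SampleDesign("s2", "case", "b1"),
                   SampleDesign("s3", "control", "b2"), SampleDesign("s4", "control", "b2")]
        counts = pd.DataFrame(np.ones((3, 4), dtype=int),
                              index=["f1", "f2", "f3"],
                              columns=[s.sample_id for s in samples])
        with pytest.raises(ValueError, match="confounded"):
            batch_adjust(CountMatrix(counts, samples))

    def test_planted_shift_removed(self, batch_design):
        """2x batch shift, no condition effect: >=95% of features end within
        a 10% batch-mean ratio after adjustment."""
        m, _ = synthetic.simulate_counts(
            batch_design, 500, frac_de=0.0, dispersion=0.1,
            batch_log2_shift=1.0, seed=3,
        )
        out = batch_adjust(m)
        b = out.batches
        arr = out.counts.to_numpy(dtype=float)
        ratio = arr[:, b == "b2"].mean(axis=1) / np.maximum(
            arr[:, b == "b1"].mean(axis=1), 1e-9
        )
        assert np.mean((ratio >= 0.9) & (ratio <= 1.1)) >= 0.95

    def test_counts_stay_non_negative_integers(self, batch_design):
        m, _ = synthetic.simulate_counts(batch_design, 100, batch_log2_shift=1.0, seed=4)
        out = batch_adjust(m)
        arr = out.counts.to_numpy()
        assert (arr >= 0).all()
        assert np.issubdtype(arr.dtype, np.integer)

    def test_condition_effect_preserved(self, batch_design):
        """Planted lfc=1 with batch shift 1: median recovered lfc within 0.2."""
        from hervscope import nb_wald_de

        m, truth = synthetic.simulate_counts(
            batch_design, 500, frac_de=0.2, lfc_magnitude=1.0,
            dispersion=0.1, batch_log2_shift=1.0, seed=4,
        )
        res = nb_wald_de(batch_adjust(m)).set_index("feature_id")
        de = sorted(truth.true_de_set)
        oriented = res.loc[de, "log2fc"].to_numpy() * np.array(
            [np.sign(truth.true_log2fc[f]) for f in de]
        )
        assert abs(np.median(oriented) - 1.0) <= 0.2

    def test_metadata_preserved(self, batch_design):
        m, _ = synthetic.simulate_counts(batch_design, 50, batch_log2_shift=1.0, seed=5)
        out = batch_adjust(m)
        assert out.samples == m.samples
        assert out.sample_ids == m.sample_ids


class TestJaccardFilter:
    def test_all_high_matrix_keeps_everything(self):
        m = small_matrix(np.full((20, 4), 100), ["case", "case", "control", "control"])
        res = jaccard_filter(m)
        assert res.matrix.counts.shape[0] == 20
        assert res.threshold == min(s for s, _ in res.similarity_curve)

    def test_separable_instance(self):
        """Informative features all kept, >=90% of scattered noise removed."""
        rng = np.random.default_rng(0)
        info = rng.poisson(100, size=(100, 10))
        noise = (rng.random((100, 10)) < 0.2).astype(int)
        m = small_matrix(np.vstack([info, noise]),
                         ["case"] * 5 + ["control"] * 5)
        res = jaccard_filter(m)
        kept = set(res.matrix.feature_ids)
        assert all(f"f{i + 1}" in kept for i in range(100))
        n_noise_kept = sum(1 for i in range(100, 200) if f"f{i + 1}" in kept)
        assert n_noise_kept <= 10

    def test_never_removes_feature_above_threshold(self):
        rng = np.random.default_rng(1)
        m = small_matrix(rng.poisson(20, size=(50, 6)),
                         ["case"] * 3 + ["control"] * 3)
        res = jaccard_filter(m)
        norm = m.counts.to_numpy() / size_factors(m).to_numpy()[None, :]
        must_keep = norm.min(axis=1) > res.threshold
        kept = set(res.matrix.feature_ids)
        assert all(f in kept for f, keep in zip(m.feature_ids, must_keep) if keep)

    def test_all_zero_rejected(self):
        m = small_matrix(np.zeros((3, 4), dtype=int),
                         ["case", "case", "control", "control"])
        with pytest.raises(ValueError):
            jaccard_filter(m)


class TestVST:
    def test_formula_values(self):
        m = small_matrix([[0, 7], [7, 0]], ["case", "control"])
        x = vst(m, np.array([1.0, 1.0]))
        assert x.iloc[0, 0] == 0.0
        assert x.iloc[0, 1] == pytest.approx(3.0)  # log2(8)

    def test_monotone_within_sample(self):
        m = small_matrix([[1, 9], [5, 2], [20, 30]], ["case", "control"])
        x = vst(m, np.array([1.3, 0.8]))
        for j in range(2):
            order_c = np.argsort(m.counts.to_numpy()[:, j])
            order_x = np.argsort(x.to_numpy()[:, j])
            assert (order_c == order_x).all()

    def test_variance_stabilization(self, balanced_design):
        """Replicate variance grows sublinearly with the mean across tiers."""
        m, _ = synthetic.simulate_counts(
            balanced_design, 900, frac_de=0.0, dispersion=0.1, seed=6,
            baseline_range=(5, 5000),
        )
        x = vst(m, np.ones(len(balanced_design)))
        mean_raw = m.counts.to_numpy().mean(axis=1)
        var_vst = x.to_numpy().var(axis=1, ddof=1)
        tiers = np.digitize(mean_raw, np.quantile(mean_raw, [1 / 3, 2 / 3]))
        tier_var = [var_vst[tiers == t].mean() for t in range(3)]
        tier_mean = [mean_raw[tiers == t].mean() for t in range(3)]
        # raw variance ratio across tiers ~ mean ratio squared; VST much flatter
        assert tier_var[2] / tier_var[0] < tier_mean[2] / tier_mean[0]


class TestPCAQC:
    def test_collinear_samples(self):
        base = np.arange(1, 11, dtype=float)
        x = pd.DataFrame(np.column_stack([base, 2 * base, 3 * base]),
                         columns=["s1", "s2", "s3"])
        res = pca_qc(x, 2)
        assert res.variance_explained[0] > 0.999

    def test_variance_fractions_valid(self, balanced_design):
        m, _ = synthetic.simulate_counts(balanced_design, 100, seed=7)
        res = pca_qc(vst(m, size_factors(m)), 5)
        ve = res.variance_explained
        assert np.all(np.diff(ve) <= 1e-12)
        assert np.all((ve >= 0) & (ve <= 1)) and ve.sum() <= 1 + 1e-9

    def test_truncation_warns(self):
        x = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)),
                         columns=["a", "b", "c"])
        with pytest.warns(UserWarning, match="truncated"):
            res = pca_qc(x, 10)
        assert res.scores.shape[1] <= 2

    def test_batch_separation_drops_after_adjustment(self, batch_design):
        """PC1 separates batches before correction; the two-sample t statistic
        falls by at least half afterwards."""
        m, _ = synthetic.simulate_counts(
            batch_design, 500, frac_de=0.0, dispersion=0.1,
            batch_log2_shift=1.0, seed=3,
        )
        adj = batch_adjust(m)
        b = m.batches
        t_stats = []
        for mat in (m, adj):
            scores = pca_qc(vst(mat, size_factors(mat)), 2).scores.to_numpy()
            t = stats.ttest_ind(scores[b == "b1", 0], scores[b == "b2", 0]).statistic
            t_stats.append(abs(t))
        assert t_stats[1] <= 0.5 * t_stats[0]
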