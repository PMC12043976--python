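import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from epimn.multiome import (
    CellFeatureMatrix,
    bimodal_lrt,
    differential_accessibility,
    differential_expression,
    lognormalize_rna,
    lsi,
    tfidf_atac,
    wilcoxon_gaussian,
)


def make_matrix(counts, modality="RNA", conditions=None, cell_type="skeletal MN"):
    counts = np.asarray(counts)
    n = counts.shape[0]
    conditions = conditions or ["Ctrl"] * (n // 2) + ["KO"] * (n - n // 2)
    meta = pd.DataFrame(
        {
            "condition": conditions,
            "cell_type": [cell_type] * n,
            "sample_id": [f"s{i%2}" for i in range(n)],
        }
    )
    if modality == "RNA":
        fmeta = pd.DataFrame({"gene_id": [f"g{j}" for j in range(counts.shape[1])]})
    else:
        fmeta = pd.DataFrame(
            {
                "feature_id": [f"p{j}" for j in range(counts.shape[1])],
                "chrom": "chr1",
                "start": np.arange(counts.shape[1]) * 1000,
                "end": np.arange(counts.shape[1]) * 1000 + 500,
            }
        )
    return CellFeatureMatrix(sp.csr_matrix(counts), modality, meta, fmeta)


class TestLogNormalize:
    def test_stated_formula(self):
        counts = np.zeros((1, 3))
        counts[0] = [10, 9990, 0]
        norm = lognormalize_rna(sp.csr_matrix(counts)).toarray()
        assert norm[0, 0] == pytest.approx(np.log(11))
        assert norm[0, 2] == 0.0

    def test_scale_invariance_per_cell(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(5, 30))
        counts[:, 0] += 1  # no zero-total cells
        a = lognormalize_rna(sp.csr_matrix(counts)).toarray()
        b = lognormalize_rna(sp.csr_matrix(counts * 2)).toarray()
        assert np.allclose(a, b)

    def test_zero_total_cell_is_error(self):
        counts = np.array([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="zero-total"):
            lognormalize_rna(sp.csr_matrix(counts))


class TestTfidf:
    def test_feature_in_all_cells_has_idf_one(self):
        counts = np.ones((4, 2))
        norm, keep = tfidf_atac(sp.csr_matrix(counts))
        # tf = 1/2, idf = 1 -> ln(1 + 1e4 * 0.5)
        assert np.allclose(norm.toarray(), np.log1p(1e4 * 0.5))
        assert list(keep) == [0, 1]

    def test_rare_feature_formula(self):
        counts = np.zeros((100, 2))
        counts[:, 0] = 1          # universal feature keeps totals nonzero
        counts[0, 1] = 1          # rare feature in one cell
        norm, keep = tfidf_atac(sp.csr_matrix(counts))
        # cell 0 total 2: tf = 1/2, idf = 100 -> ln(1 + 1e4 * 50)
        assert norm.toarray()[0, 1] == pytest.approx(np.log1p(1e4 * 50))

    def test_all_zero_feature_dropped_with_warning(self):
        counts = np.ones((4, 3))
        counts[:, 2] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            norm, keep = tfidf_atac(sp.csr_matrix(counts))
        assert norm.shape[1] == 2
        assert np.isfinite(norm.toarray()).all()


class TestLsi:
    def test_rank_two_matrix(self):
        rng = np.random.default_rng(1)
        a = rng.random((40, 2)) @ rng.random((2, 30))
        emb = lsi(sp.csr_matrix(a), n_components=6, use_range=(1, 6))
        assert (emb.singular_values[2:] < 1e-8).all()

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(2)
        a = sp.csr_matrix(rng.poisson(1.0, size=(50, 40)).astype(float))
        e1 = lsi(a, n_components=10, seed=11)
        e2 = lsi(a, n_components=10, seed=11)
        assert np.array_equal(e1.scores, e2.scores)

    def test_selected_returns_requested_range(self):
        rng = np.random.default_rng(3)
        a = sp.csr_matrix(rng.poisson(1.0, size=(30, 20)).astype(float))
        emb = lsi(a, n_components=10, use_range=(2, 10))
        assert emb.selected().shape == (30, 9)

    def test_too_many_components(self):
        with pytest.raises(ValueError):
            lsi(sp.csr_matrix(np.ones((5, 4))), n_components=6, use_range=(1, 6))


class TestBimodalLrt:
    def test_identical_groups_p_one(self):
        v = np.array([0, 0, 1.5, 2.0, 0, 2.5] * 4)
        assert bimodal_lrt(v, v.copy()) == 1.0

    def test_all_zero_both_groups(self):
        z = np.zeros(10)
        assert bimodal_lrt(z, z) == 1.0

    def test_detection_only_extreme(self):
        """group1 all zero vs group2 all nonzero at one value: the Gaussian
        terms cancel under the shared variance floor and the statistic is the
        binomial detection LRT, 2 * 2n * ln 2."""
        g1 = np.zeros(20)
        g2 = np.full(20, 3.3)
        p = bimodal_lrt(g1, g2)
        expected_stat = 2 * 40 * np.log(2)
        assert p == pytest.approx(stats.chi2.sf(expected_stat, 2), rel=1e-9)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            bimodal_lrt(np.ones(2), np.ones(5))

    def test_mean_shift_detected(self):
        rng = np.random.default_rng(4)
        g1 = rng.normal(1.0, 0.3, 50)
        g2 = rng.normal(2.5, 0.3, 50)
        assert bimodal_lrt(g1, g2) < 1e-10


class TestWilcoxon:
    def test_identical_groups(self):
        v = np.arange(10.0)
        _, p = wilcoxon_gaussian(v, v.copy())
        assert p >= 0.99

    def test_large_shift(self):
        rng = np.random.default_rng(5)
        g1 = rng.normal(0, 1, 30)
        z, p = wilcoxon_gaussian(g1, g1 + 10)
        assert p < 1e-6
        assert z < 0

    def test_all_tied(self):
        z, p = wilcoxon_gaussian(np.ones(5), np.ones(5))
        assert (z, p) == (0.0, 1.0)

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            g1 = np.round(rng.normal(0, 1, 25), 1)  # rounded -> ties
            g2 = np.round(rng.normal(0.3, 1, 20), 1)
            _, p = wilcoxon_gaussian(g1, g2)
            ref = stats.mannwhitneyu(g1, g2, alternative="two-sided",
                                     method="asymptotic").pvalue
            assert p == pytest.approx(ref, rel=1e-9)

    def test_close_to_exact_for_small_samples(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            g1 = rng.normal(0, 1, 8)
            g2 = rng.normal(rng.uniform(-1, 1), 1, 8)
            _, p = wilcoxon_gaussian(g1, g2)
            exact = stats.mannwhitneyu(g1, g2, alternative="two-sided",
                                       method="exact").pvalue
            assert abs(p - exact) <= 0.02


class TestDifferentialExpression:
    def test_single_gene_padj_equals_p(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(3.0, size=(40, 1)) + 1
        mat = make_matrix(counts)
        (rec,) = differential_expression(mat, "skeletal MN", "Ctrl", "KO")
        assert rec.p_adj == pytest.approx(rec.p)

    def test_missing_cell_type_errors(self):
        mat = make_matrix(np.ones((10, 2)))
        with pytest.raises(ValueError, match="cell_type"):
            differential_expression(mat, "visceral MN", "Ctrl", "KO")

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(2.0, size=(60, 15)) + (rng.random((60, 15)) < 0.5)
        mat = make_matrix(counts)
        fwd = differential_expression(mat, "skeletal MN", "Ctrl", "KO")
        rev = differential_expression(mat, "skeletal MN", "KO", "Ctrl")
        for a, b in zip(fwd, rev):
            assert a.feature_id == b.feature_id
            assert a.log2fc == pytest.approx(-b.log2fc)
            assert a.p == pytest.approx(b.p)
            assert (a.pct_1, a.pct_2) == (b.pct_2, b.pct_1)

    def test_planted_effect_called_with_correct_sign(self):
        rng = np.random.default_rng(10)
        base = rng.poisson(3.0, size=(120, 10))
        base[60:, 0] *= 8  # strong KO up-regulation of gene 0
        mat = make_matrix(base + 1)
        recs = differential_expression(mat, "skeletal MN", "KO", "Ctrl")
        by_id = {r.feature_id: r for r in recs}
        assert by_id["g0"].klass == "up"


class TestDifferentialAccessibility:
    def _planted(self, seed=11, strength=0.6):
        rng = np.random.default_rng(seed)
        n = 120
        counts = (rng.random((n, 20)) < 0.25).astype(int)
        counts[n // 2:, 0] = (rng.random(n // 2) < 0.25 + strength).astype(int)
        return make_matrix(counts, modality="ATAC")

    def test_open_closed_swap_symmetry(self):
        mat = self._planted()
        fwd = differential_accessibility(mat, "skeletal MN", "KO", "Ctrl")
        rev = differential_accessibility(mat, "skeletal MN", "Ctrl", "KO")
        f_by = {r.feature_id: r for r in fwd}
        r_by = {r.feature_id: r for r in rev}
        assert f_by["p0"].klass == "open"
        assert r_by["p0"].klass == "closed"
        for fid in f_by:
            assert f_by[fid].p == pytest.approx(r_by[fid].p)
            assert f_by[fid].log2fc == pytest.approx(-r_by[fid].log2fc)

    def test_rule_requires_fold_change_and_pct(self):
        """A significant p alone does not open a peak: the log2fc > 0.1 and
        pct_1 > 5 gates must also hold."""
        mat = self._planted()
        recs = differential_accessibility(mat, "skeletal MN", "KO", "Ctrl")
        for r in recs:
            if r.klass == "open":
                assert r.p_adj < 0.01 and r.log2fc > 0.1 and r.pct_1 > 5
            elif r.klass == "closed":
                assert r.p_adj < 0.01 and -r.log2fc > 0.1 and r.pct_2 > 5

    def test_modality_guard(self):
        mat = self._planted()
        with pytest.raises(ValueError):
            differential_expression(mat, "skeletal MN", "KO", "Ctrl")


class TestNormalizationPermutationInvariance:
    def test_cell_and_feature_permutations_commute(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(1.5, size=(25, 18)) + 1
        cp = rng.permutation(25)
        fp = rng.permutation(18)
        a = lognormalize_rna(sp.csr_matrix(counts)).toarray()
        b = lognormalize_rna(sp.csr_matrix(counts[cp][:, fp])).toarray()
        assert np.allclose(a[cp][:, fp], b)
        ta, _ = tfidf_atac(sp.csr_matrix(counts))
        tb, _ = tfidf_atac(sp.csr_matrix(counts[cp][:, fp]))
        assert np.allclose(ta.toarray()[cp][:, fp], tb.toarray())
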