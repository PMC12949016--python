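"""Downsampling, HVG selection, pseudobulk aggregation, VST and PCA projection."""

import numpy as np
import pandas as pd
import pytest

from xci_scope.core_io import attach_normalized
from xci_scope.pseudobulk_pca import (
    aggregate_pseudobulk,
    downsample_equal,
    hierarchical_order,
    pca_fit,
    pca_project,
    PCAModel,
    ranked_loadings,
    sample_correlation,
    select_hvg,
    size_factors,
    variance_stabilize,
)

from conftest import make_matrix


def multi_sample_matrix(rng, n_per=(30, 40, 50), n_genes=20):
    n = sum(n_per)
    counts = rng.poisson(5, size=(n, n_genes)) + 1
    samples = sum([[f"s{i}"] * k for i, k in enumerate(n_per)], [])
    return make_matrix(counts, samples=samples)


class TestDownsample:
    def test_exact_and_deterministic(self):
        rng = np.random.default_rng(0)
        m = multi_sample_matrix(rng)
        a = downsample_equal(m, 25, seed=3)
        b = downsample_equal(m, 25, seed=3)
        assert (a.cell_meta.groupby("sample_id").size() == 25).all()
        assert list(a.cell_ids) == list(b.cell_ids)

    def test_sample_at_exact_n_fully_retained(self):
        rng = np.random.default_rng(1)
        m = multi_sample_matrix(rng, n_per=(25, 40, 50))
        out = downsample_equal(m, 25, seed=0)
        assert set(out.cell_ids[out.cell_meta["sample_id"] == "s0"]) == set(
            m.cell_ids[m.cell_meta["sample_id"] == "s0"]
        )

    def test_small_sample_lowers_n_with_warning(self):
        rng = np.random.default_rng(2)
        m = multi_sample_matrix(rng, n_per=(10, 40, 50))
        out = downsample_equal(m, 25, seed=0)
        assert (out.cell_meta.groupby("sample_id").size() == 10).all()


class TestSelectHVG:
    def test_constant_gene_never_beats_varying(self):
        # large constant background keeps library sizes nearly equal, so the
        # constant gene stays (almost) constant after normalization
        counts = np.ones((20, 4), dtype=int) * 50
        counts[:, 1] = np.tile([10, 2000], 10)
        counts[:, 2] = np.tile([2000, 10], 10)
        counts[:, 3] = 100_000
        m = attach_normalized(make_matrix(counts))
        top2 = select_hvg(m, 2)
        assert "g0" not in top2 and "g3" not in top2

    def test_n_top_all_is_identity_set(self):
        rng = np.random.default_rng(3)
        m = attach_normalized(make_matrix(rng.poisson(4, size=(15, 8)) + 1))
        assert set(select_hvg(m, 8)) == set(m.gene_ids)

    def test_planted_high_variance_genes_recovered(self):
        rng = np.random.default_rng(4)
        n_cells, n_genes = 300, 100
        counts = rng.poisson(5, size=(n_cells, n_genes))
        planted = rng.choice(n_genes, 10, replace=False)
        on = rng.random(n_cells) < 0.5  # bimodal expression = high variance
        counts[np.ix_(on, planted)] += 40
        m = attach_normalized(make_matrix(counts + 1))
        top = set(select_hvg(m, 10))
        recovered = sum(f"g{j}" in top for j in planted)
        assert recovered >= 9  # >= 95% in expectation; deterministic at this seed


class TestPseudobulk:
    def test_totals_conserved_and_single_cell_sample(self):
        counts = np.array([[5, 7, 100], [1, 2, 100], [3, 4, 100]])
        m = make_matrix(counts, samples=["a", "b", "b"])
        pb = aggregate_pseudobulk(m, min_gene_count=0)
        assert pb.loc["a"].tolist() == [5, 7, 100]  # one-cell sample row == that cell
        assert pb.to_numpy().sum() == counts.sum()

    def test_low_aggregate_gene_dropped(self):
        counts = np.array([[4, 20], [5, 20]])
        m = make_matrix(counts, samples=["a", "b"])
        pb = aggregate_pseudobulk(m, min_gene_count=10)
        assert "g0" not in pb.columns  # aggregate 9 < 10


class TestVarianceStabilize:
    def test_identical_samples_unit_size_factors(self):
        pb = pd.DataFrame([[10, 20, 30]] * 3, index=["a", "b", "c"], columns=["g0", "g1", "g2"])
        sf = size_factors(pb)
        np.testing.assert_allclose(sf, 1.0)
        vst = variance_stabilize(pb)
        np.testing.assert_allclose(vst.loc["a"], np.log2(np.array([10, 20, 30]) + 1))

    def test_doubling_a_sample_is_absorbed(self):
        pb = pd.DataFrame([[10, 20, 30], [10, 20, 30]], index=["a", "b"], columns=list("xyz"))
        pb2 = pb.copy()
        pb2.loc["b"] *= 2
        vst = variance_stabilize(pb2)
        sf = size_factors(pb2)
        assert sf["b"] == pytest.approx(2 * sf["a"])
        np.testing.assert_allclose(vst.loc["a"], vst.loc["b"], rtol=1e-12)

    def test_stabilizes_variance_for_equal_expression(self):
        rng = np.random.default_rng(5)
        depth = np.array([1.0, 2.0, 4.0, 8.0])
        base = rng.poisson(50, size=(1, 200))
        pb = pd.DataFrame(
            rng.poisson(base * depth[:, None]), index=list("abcd"), columns=[f"g{j}" for j in range(200)]
        )
        vst = variance_stabilize(pb)
        raw = np.log2(pb + 1)
        assert vst.var(axis=0).mean() < raw.var(axis=0).mean()


class TestPCA:
    def _fit(self, seed=6, n_samples=6, n_genes=30):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(
            rng.normal(size=(n_samples, n_genes)),
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"g{j}" for j in range(n_genes)],
        )
        return x, pca_fit(x)

    def test_projection_of_training_rows_reproduces_scores(self):
        x, model = self._fit()
        proj = pca_project(model, x)
        np.testing.assert_allclose(proj.to_numpy(), model.scores.to_numpy(), atol=1e-8)

    def test_loadings_orthonormal_and_variance_sorted(self):
        _, model = self._fit()
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(model.n_components), atol=1e-8
        )
        assert (np.diff(model.variance_explained) <= 1e-12).all()
        assert model.variance_explained.sum() <= 1 + 1e-9

    def test_reconstruction_with_all_pcs(self):
        x, model = self._fit()
        z = (x.to_numpy() - model.center) / model.scale
        np.testing.assert_allclose(model.scores.to_numpy() @ model.loadings.T, z, atol=1e-6)

    def test_matches_sklearn_variance_ratio(self):
        from sklearn.decomposition import PCA as SKPCA

        x, model = self._fit()
        z = (x.to_numpy() - model.center) / model.scale
        sk = SKPCA().fit(z)
        np.testing.assert_allclose(
            sk.explained_variance_ratio_[: model.n_components], model.variance_explained, atol=1e-8
        )

    def test_missing_genes_policy(self):
        x, model = self._fit()
        with pytest.raises(ValueError, match="missing"):
            pca_project(model, x.iloc[:, : int(30 * 0.7)])  # 30% missing -> error
        proj = pca_project(model, x.iloc[:, :27])  # 10% missing -> zero-filled
        assert proj.shape == model.scores.shape

    def test_save_load_round_trip(self, tmp_path):
        x, model = self._fit()
        model.save(tmp_path / "model")
        loaded = PCAModel.load(tmp_path / "model")
        np.testing.assert_allclose(loaded.loadings, model.loadings, atol=1e-12)
        proj = pca_project(loaded, x)
        np.testing.assert_allclose(proj.to_numpy(), model.scores.to_numpy(), atol=1e-8)

    def test_group_separation_on_planted_programs(self):
        rng = np.random.default_rng(7)
        base = rng.poisson(20, size=(9, 60)).astype(float)
        groups = np.repeat([0, 1, 2], 3)
        for g in range(3):
            base[groups == g, g * 20 : (g + 1) * 20] *= 4  # distinct lineage programs
        x = pd.DataFrame(base, index=[f"s{i}" for i in range(9)], columns=[f"g{j}" for j in range(60)])
        model = pca_fit(np.log2(x + 1))
        from sklearn.metrics import silhouette_score

        sil = silhouette_score(model.scores.iloc[:, :2], groups)
        assert sil > 0.5


class TestLoadingsAndCorrelation:
    def test_sign_symmetry_of_ranked_loadings(self):
        rng = np.random.default_rng(8)
        x = pd.DataFrame(rng.normal(size=(5, 12)), columns=[f"g{j}" for j in range(12)])
        model = pca_fit(x)
        pos = ranked_loadings(model, 1, "positive")
        neg_of_flipped = (-pos).sort_values(ascending=True)
        flipped = model
        flipped.loadings = -flipped.loadings
        neg = ranked_loadings(flipped, 1, "negative")
        pd.testing.assert_index_equal(neg.index, pos.index)
        assert pos.index[0] == pos.abs().idxmax()

    def test_duplicate_samples_correlate_perfectly(self):
        pb = pd.DataFrame([[1.0, 2, 3, 4], [1.0, 2, 3, 4], [4.0, 3, 2, 1]], index=list("abc"))
        corr = sample_correlation(pb)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(9)
        pb = pd.DataFrame(rng.random(size=(3, 20)) + 0.1, index=list("abc"))
        c1 = sample_correlation(pb)
        pb2 = pb.copy()
        pb2.loc["a"] = np.exp(3 * pb2.loc["a"])  # rank-preserving
        c2 = sample_correlation(pb2)
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-12)

    def test_hierarchical_order_is_a_permutation(self):
        rng = np.random.default_rng(10)
        pb = pd.DataFrame(rng.normal(size=(4, 10)), index=list("abcd"))
        assert sorted(hierarchical_order(pb)) == list("abcd")
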