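import numpy as np
import pytest

from wavecrest import (
    export_loading_weights,
    fit_bulk_pca,
    project_cells,
    rescale_genes,
)

from conftest import make_expression, make_rescaled


def _random_bulk(rng, n_genes=40, n_samples=6):
    vals = rng.gamma(2.0, 50.0, size=(n_genes, n_samples)) + 1.0
    return make_expression(vals, [f"T{t}" for t in range(n_samples)], unit="normalized")


class TestFitBulkPCA:
    def test_two_samples_one_component_symmetric_scores(self, rng):
        bulk = _random_bulk(rng, n_samples=2)
        model = fit_bulk_pca(bulk, 1)
        scores = model.bulk_scores.to_numpy().ravel()
        assert scores.size == 2
        assert scores[0] == pytest.approx(-scores[1], abs=1e-9)
        with pytest.raises(ValueError):
            fit_bulk_pca(bulk, 2)  # rank limit: n_samples - 1

    def test_orthonormal_loadings(self, rng):
        bulk = _random_bulk(rng, n_genes=200, n_samples=6)
        model = fit_bulk_pca(bulk, 5)
        W = model.loadings.to_numpy()
        np.testing.assert_allclose(W.T @ W, np.eye(5), atol=1e-8)

    def test_planted_rank_one_direction_recovered(self, rng):
        # per-gene standardization equalizes loading magnitudes, so the
        # recoverable planted direction is an equal-magnitude sign pattern
        n_genes, n_samples = 100, 6
        direction = rng.choice([-1.0, 1.0], size=n_genes) / np.sqrt(n_genes)
        scores = np.linspace(-2, 2, n_samples)
        base = np.outer(np.sign(direction), scores)
        vals = 100 * np.exp(base + 0.01 * rng.normal(size=(n_genes, n_samples)))
        bulk = make_expression(vals, [f"T{t}" for t in range(n_samples)], unit="normalized")
        model = fit_bulk_pca(bulk, 2, log_transform=True)
        w1 = model.loadings["PC1"].to_numpy()
        r = np.corrcoef(w1, direction)[0, 1]
        assert abs(r) > 0.99

    def test_sign_convention_largest_loading_positive(self, rng):
        bulk = _random_bulk(rng)
        model = fit_bulk_pca(bulk, 3)
        W = model.loadings.to_numpy()
        for k in range(3):
            assert W[np.argmax(np.abs(W[:, k])), k] > 0


class TestProjectCells:
    def test_projecting_bulk_recovers_bulk_scores(self, rng):
        bulk = _random_bulk(rng)
        model = fit_bulk_pca(bulk, 3)
        rescaled = rescale_genes(bulk, log_transform=True)
        proj, dropped = project_cells(model, rescaled)
        np.testing.assert_allclose(
            proj.to_numpy(), model.bulk_scores.to_numpy(), atol=1e-9
        )
        assert dropped == []

    def test_zero_cell_maps_to_origin(self, rng):
        bulk = _random_bulk(rng)
        model = fit_bulk_pca(bulk, 2)
        cells = make_rescaled(
            np.zeros((len(model.genes), 3)), ["A"] * 3, genes=list(model.genes)
        )
        proj, _ = project_cells(model, cells)
        np.testing.assert_allclose(proj.to_numpy(), 0.0)

    def test_matches_double_loop_oracle(self, rng):
        bulk = _random_bulk(rng, n_genes=25)
        model = fit_bulk_pca(bulk, 3)
        X = rng.normal(size=(25, 4))
        cells = make_rescaled(X, ["A"] * 4, genes=list(model.genes))
        proj, _ = project_cells(model, cells)
        W = model.loadings.to_numpy()
        expected = np.zeros((4, 3))
        for j in range(4):
            for n in range(3):
                for g in range(25):
                    expected[j, n] += W[g, n] * X[g, j]
        np.testing.assert_allclose(proj.to_numpy(), expected, atol=1e-9)

    def test_projection_is_linear(self, rng):
        bulk = _random_bulk(rng, n_genes=20)
        model = fit_bulk_pca(bulk, 2)
        X1 = rng.normal(size=(20, 3))
        X2 = rng.normal(size=(20, 3))
        genes = list(model.genes)
        p1, _ = project_cells(model, make_rescaled(X1, ["A"] * 3, genes=genes))
        p2, _ = project_cells(model, make_rescaled(X2, ["A"] * 3, genes=genes))
        p12, _ = project_cells(
            model, make_rescaled(2.0 * X1 - 3.0 * X2, ["A"] * 3, genes=genes)
        )
        np.testing.assert_allclose(
            p12.to_numpy(), 2.0 * p1.to_numpy() - 3.0 * p2.to_numpy(), atol=1e-9
        )

    def test_gene_order_permutation_invariance(self, rng):
        bulk = _random_bulk(rng, n_genes=20)
        model = fit_bulk_pca(bulk, 2)
        X = rng.normal(size=(20, 3))
        genes = list(model.genes)
        perm = rng.permutation(20)
        p_orig, _ = project_cells(model, make_rescaled(X, ["A"] * 3, genes=genes))
        p_perm, _ = project_cells(
            model,
            make_rescaled(X[perm], ["A"] * 3, genes=[genes[i] for i in perm]),
        )
        np.testing.assert_allclose(p_perm.to_numpy(), p_orig.to_numpy(), atol=1e-9)

    def test_empty_intersection_errors(self, rng):
        bulk = _random_bulk(rng, n_genes=5)
        model = fit_bulk_pca(bulk, 2)
        cells = make_rescaled(np.zeros((2, 3)), ["A"] * 3, genes=["zz1", "zz2"])
        with pytest.raises(ValueError, match="shared"):
            project_cells(model, cells)


class TestExportWeights:
    def test_weights_are_absolute_loadings(self, rng):
        bulk = _random_bulk(rng)
        model = fit_bulk_pca(bulk, 2)
        w = export_loading_weights(model, 1)
        np.testing.assert_allclose(
            w.to_numpy(), np.abs(model.loadings["PC1"].to_numpy())
        )
        assert (w.to_numpy() >= 0).all()

    def test_planted_genes_get_top_weights(self, rng):
        # rank-1 trend on the first 5 genes; standardized noise genes each
        # carry unit variance, so keep them few relative to sample rank
        n_genes, n_samples = 20, 12
        vals = np.full((n_genes, n_samples), 100.0)
        trend = np.linspace(-1.5, 1.5, n_samples)
        vals[:5] = 100 * np.exp(np.outer(np.ones(5), trend))
        vals *= np.exp(0.01 * rng.normal(size=vals.shape))
        bulk = make_expression(vals, [f"T{t}" for t in range(n_samples)], unit="normalized")
        model = fit_bulk_pca(bulk, 1)
        w = export_loading_weights(model, 1)
        top5 = set(w.sort_values(ascending=False).index[:5])
        assert top5 == {"g0", "g1", "g2", "g3", "g4"}

    def test_component_out_of_range(self, rng):
        model = fit_bulk_pca(_random_bulk(rng), 2)
        with pytest.raises(IndexError):
            export_loading_weights(model, 3)
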