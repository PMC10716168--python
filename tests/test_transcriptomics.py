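"""PLS correlation, alignment, bootstrap gene inference and selection."""

import numpy as np
import pytest

from devconnectome import synthetic as syn
from devconnectome import transcriptomics as trans
from devconnectome.transcriptomics import (
    ExpressionMatrix,
    GeneWeightTable,
    PLSCorrelation,
    align,
    bootstrap_gene_weights,
    pls_fit,
    select_genes,
)


@pytest.fixture(scope="module")
def aligned(regions90, expression_bundle):
    expr, gt_expr, gt = expression_bundle
    y, X, genes, idx = align(gt.nodal_slope_field, expr, regions90)
    return y, X, genes, idx, gt_expr


class TestAlign:
    def test_cortical_subset_and_zscoring(self, aligned, regions90):
        y, X, genes, idx, _ = aligned
        assert len(y) == int(regions90.cortical.sum())
        np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(X.std(axis=0), 1, atol=1e-10)
        np.testing.assert_allclose([y.mean(), y.std()], [0, 1], atol=1e-10)

    def test_constant_gene_dropped_with_warning(self, regions90, expression_bundle):
        expr, _, gt = expression_bundle
        vals = expr.values.copy()
        vals[:, 3] = 7.0
        expr2 = ExpressionMatrix(vals, expr.gene_ids, expr.region_ids)
        with pytest.warns(UserWarning, match="constant gene"):
            y, X, genes, idx = align(gt.nodal_slope_field, expr2, regions90)
        assert expr.gene_ids[3] not in genes
        assert X.shape[1] == len(expr.gene_ids) - 1

    def test_disjoint_regions_error(self, regions90, expression_bundle):
        expr, _, gt = expression_bundle
        expr2 = ExpressionMatrix(
            expr.values, expr.gene_ids, expr.region_ids + 10000
        )
        with pytest.raises(ValueError, match="cortical regions"):
            align(gt.nodal_slope_field, expr2, regions90)

    def test_expression_tsv_roundtrip(self, tmp_path, expression_bundle):
        expr, _, _ = expression_bundle
        trans.write_expression(expr, tmp_path / "e.tsv")
        back = trans.read_expression(tmp_path / "e.tsv")
        np.testing.assert_allclose(back.values, expr.values, atol=1e-12)
        assert back.gene_ids == expr.gene_ids


class TestPLS:
    @staticmethod
    def _expand(regions, cortical_values):
        full = np.zeros(regions.n_regions)
        full[np.flatnonzero(regions.cortical)] = cortical_values
        return full

    def test_pure_component_fully_explained(self, regions90):
        # expression = planted component only, response = same component
        expr, gte = syn.simulate_expression(
            regions90, np.linspace(-1, 1, 90),
            coupling_r=1.0, noise_sd=0.0, white_sd=0.0, seed=41,
        )
        with pytest.warns(UserWarning, match="constant gene"):
            y, X, genes, idx = align(self._expand(regions90, gte.latent),
                                     expr, regions90)
        res = pls_fit(X, y, n_components=3)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-9)
        assert res.r1 == pytest.approx(1.0, abs=1e-9)

    def test_sign_flip_symmetry(self, aligned):
        y, X, *_ = aligned
        r1 = pls_fit(X, y, n_components=4)
        r2 = pls_fit(X, -y, n_components=4)
        np.testing.assert_allclose(r1.explained, r2.explained, atol=1e-10)
        # weights negate with the response: the sign convention ties the
        # score to the input response, so flipping y flips every component
        np.testing.assert_allclose(r1.weights, -r2.weights, atol=1e-10)
        assert r1.r1 >= 0 and r2.r1 >= 0

    def test_explained_fractions_sum_below_one(self, aligned):
        y, X, *_ = aligned
        res = pls_fit(X, y, n_components=10)
        assert res.explained.sum() <= 1.0 + 1e-9
        assert np.all(res.explained >= 0)

    def test_too_many_components(self, aligned):
        y, X, *_ = aligned
        with pytest.raises(ValueError, match="n_components"):
            pls_fit(X, y, n_components=len(y) + 5)

    def test_against_sklearn_pls_component1(self, aligned):
        # independent cross-check: sklearn's NIPALS PLS must give the same
        # first component direction for a univariate response
        from sklearn.cross_decomposition import PLSRegression

        y, X, *_ = aligned
        ours = pls_fit(X, y, n_components=2)
        sk = PLSRegression(n_components=2, scale=False).fit(X, y)
        w_sk = sk.x_weights_[:, 0]
        cos = abs(w_sk @ ours.weights[:, 0]) / np.linalg.norm(w_sk)
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_weight_recovery_probing_with_latent(self, regions90, expression_bundle):
        expr, gte, _ = expression_bundle
        y, X, genes, idx = align(TestPLS._expand(regions90, gte.latent),
                                 expr, regions90)
        res = pls_fit(X, y, n_components=1)
        r = np.corrcoef(np.abs(res.weights[:, 0]), np.abs(gte.true_gene_weights))[0, 1]
        assert r > 0.9


class TestBootstrap:
    def test_seed_reproducibility(self, aligned):
        y, X, genes, *_ = aligned
        t1 = bootstrap_gene_weights(X, y, gene_ids=genes, n_boot=30, seed=4)
        t2 = bootstrap_gene_weights(X, y, gene_ids=genes, n_boot=30, seed=4)
        np.testing.assert_array_equal(t1.z, t2.z)

    def test_noise_free_support_genes_dominate(self, regions90):
        expr, gte = syn.simulate_expression(
            regions90, np.linspace(-1, 1, 90), coupling_r=1.0,
            noise_sd=0.0, white_sd=1e-8, seed=42,
        )
        y, X, genes, idx = align(TestPLS._expand(regions90, gte.latent),
                                 expr, regions90)
        tab = bootstrap_gene_weights(X, y, gene_ids=genes, n_boot=50, seed=5)
        support = np.asarray(gte.true_gene_weights) != 0
        assert np.min(np.abs(tab.z[support])) > np.max(np.abs(tab.z[~support]))

    def test_zero_variance_response_rejected(self, aligned):
        _, X, genes, *_ = aligned
        with pytest.raises(ValueError, match="zero variance"):
            bootstrap_gene_weights(X, np.zeros(X.shape[0]), gene_ids=genes,
                                   n_boot=5, seed=0)


class TestSelection:
    def _table(self, p, w):
        G = len(p)
        return GeneWeightTable(
            gene_ids=[f"g{i}" for i in range(G)], weight=np.asarray(w, float),
            sd_boot=np.ones(G), z=np.asarray(w, float),
            p=np.asarray(p, float), selected=np.full(G, "none", dtype=object),
        )

    def test_all_p_one_selects_nothing(self):
        pos, neg = select_genes(self._table([1.0] * 5, [1, -1, 1, -1, 1]))
        assert pos == [] and neg == []

    def test_strongly_significant_selected_by_sign(self):
        tab = self._table([1e-9] + [0.5] * 999, [2.0] + [0.1] * 999)
        pos, neg = select_genes(tab)
        assert pos == ["g0"] and neg == []
        assert tab.selected[0] == "positive"

    def test_boundary_exactly_alpha_not_selected(self):
        G, alpha = 10, 0.01
        p = np.full(G, 1.0)
        p[0] = alpha / G  # p*G == alpha exactly: strict < excludes it
        pos, neg = select_genes(self._table(p, np.ones(G)), alpha=alpha)
        assert pos == []
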