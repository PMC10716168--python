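"""Synthetic-data generator: determinism, invariants, planted structure."""

import numpy as np
import pytest

from devconnectome import synthetic as syn
from devconnectome.io import Connectome


class TestMakeRegions:
    def test_hemisphere_mirroring(self):
        rt = syn.make_regions(90, seed=1)
        assert (rt.hemisphere == "L").sum() == 45
        np.testing.assert_allclose(
            rt.centroids[:45, 0], -rt.centroids[45:, 0]
        )
        np.testing.assert_allclose(rt.centroids[:45, 1:], rt.centroids[45:, 1:])

    def test_determinism(self):
        a = syn.make_regions(90, seed=2)
        b = syn.make_regions(90, seed=2)
        np.testing.assert_array_equal(a.centroids, b.centroids)
        assert list(a.module) == list(b.module)

    def test_eight_modules_with_subcortical(self):
        rt = syn.make_regions(90, seed=3)
        mods = set(rt.module)
        assert syn.SUBCORTICAL in mods
        assert len(mods) == 8
        assert (~rt.cortical).sum() > 0
        assert set(rt.module[~rt.cortical]) == {syn.SUBCORTICAL}

    def test_tiny_parcellation_degrades_with_warning(self):
        with pytest.warns(UserWarning, match="modules"):
            rt = syn.make_regions(4, seed=4)
        assert len(set(rt.module)) <= 4

    def test_odd_region_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            syn.make_regions(7, seed=0)


class TestSimulateCohort:
    def test_determinism_byte_identical(self, regions90):
        p = syn.CohortParams(n_subjects=10)
        c1, g1 = syn.simulate_cohort(regions90, seed=5, params=p)
        c2, g2 = syn.simulate_cohort(regions90, seed=5, params=p)
        assert c1.n_scans == c2.n_scans
        for s1, s2 in zip(c1.scans, c2.scans):
            np.testing.assert_array_equal(s1.connectome.weights, s2.connectome.weights)
        np.testing.assert_array_equal(g1.nodal_slope_field, g2.nodal_slope_field)

    def test_connectome_invariants(self, small_cohort):
        cohort, _ = small_cohort
        for s in cohort.scans[:10]:
            W = s.connectome.weights
            assert np.all(W >= 0)
            np.testing.assert_allclose(W, W.T, atol=1e-12)
            assert np.all(np.diag(W) == 0)
            assert isinstance(s.connectome, Connectome)

    def test_density_near_target(self, small_cohort):
        cohort, _ = small_cohort
        R = cohort.regions.n_regions
        iu = np.triu_indices(R, 1)
        dens = np.mean([
            np.mean(s.connectome.weights[iu] > 0) for s in cohort.scans[:5]
        ])
        assert dens == pytest.approx(0.15, abs=0.02)

    def test_noise_free_edge_slopes_exact(self, regions90):
        p = syn.CohortParams(n_subjects=12, sigma_u=0.0, sigma_b=0.0,
                             sigma_eps=0.0, dropout=0.0)
        cohort, gt = syn.simulate_cohort(regions90, seed=6, params=p)
        # per-edge OLS slope across scans equals the planted edge slope
        ages = np.array([s.age for s in cohort.scans])
        iu, ju = cohort.scans[0].connectome.edge_index()
        picks = np.random.default_rng(0).choice(len(iu), 20, replace=False)
        for k in picks:
            a, b = iu[k], ju[k]
            w = np.array([s.connectome.weights[a, b] for s in cohort.scans])
            if np.any(w == 0):  # truncation can clip the noise-free value
                continue
            slope = np.polyfit(ages, w, 1)[0]
            assert slope == pytest.approx(gt.edge_slopes[a, b], abs=1e-10)

    def test_full_dropout_single_scans(self, regions90):
        p = syn.CohortParams(n_subjects=8, dropout=1.0)
        cohort, _ = syn.simulate_cohort(regions90, seed=7, params=p)
        assert max(cohort.scans_per_subject().values()) == 1

    def test_truncation_rate_below_one_percent(self, small_cohort):
        _, gt = small_cohort
        assert gt.truncation_rate < 0.01


class TestSimulateExpression:
    def test_planted_coupling_exact(self, regions90, small_cohort):
        _, gt = small_cohort
        for r in (0.0, 0.5, 0.9):
            expr, gte = syn.simulate_expression(
                regions90, gt.nodal_slope_field, coupling_r=r, seed=8
            )
            cort = np.flatnonzero(regions90.cortical)
            a = gt.nodal_slope_field[cort]
            emp = np.corrcoef(gte.latent, a)[0, 1]
            assert emp == pytest.approx(r, abs=0.05)

    def test_support_split_half_positive(self, expression_bundle):
        _, gte, _ = expression_bundle
        w = gte.true_gene_weights
        assert (w > 0).sum() == (w < 0).sum() == 25
        assert len(gte.true_support_genes) == 50

    def test_determinism(self, regions90, small_cohort):
        _, gt = small_cohort
        e1, _ = syn.simulate_expression(regions90, gt.nodal_slope_field, seed=9)
        e2, _ = syn.simulate_expression(regions90, gt.nodal_slope_field, seed=9)
        np.testing.assert_array_equal(e1.values, e2.values)


class TestSimulateAnnotations:
    def test_every_gene_annotated_once(self, expression_bundle):
        expr, gte, _ = expression_bundle
        ann, cats, gta = syn.simulate_annotations(expr.gene_ids, gte, seed=10)
        assert set(ann) == set(expr.gene_ids)
        from devconnectome.enrichment import CELL_CLASSES

        assert set(ann.values()) <= set(CELL_CLASSES)

    def test_positive_support_concentrated_in_planted_class(self, expression_bundle):
        expr, gte, _ = expression_bundle
        ann, cats, gta = syn.simulate_annotations(expr.gene_ids, gte, seed=11)
        pos = [g for g, w in zip(expr.gene_ids, gte.true_gene_weights) if w > 0]
        frac = np.mean([ann[g] == gta.enriched_class for g in pos])
        assert frac > 0.6
        assert sorted(cats["support_pos"]) == sorted(pos)


class TestSimulateCorticalMaps:
    def test_planted_rho_one_gives_perfect_spearman(self, regions90, small_cohort):
        from scipy import stats

        _, gt = small_cohort
        maps, _ = syn.simulate_cortical_maps(
            regions90, gt.nodal_slope_field,
            target_rhos={"myelin": 1.0}, seed=12,
        )
        cort = np.flatnonzero(regions90.cortical)
        rho = stats.spearmanr(maps["myelin"].values,
                              gt.nodal_slope_field[cort]).statistic
        assert rho == pytest.approx(1.0)

    def test_six_laminas_generated(self, regions90, small_cohort):
        _, gt = small_cohort
        maps, gtm = syn.simulate_cortical_maps(regions90, gt.nodal_slope_field,
                                               seed=13)
        assert {"L1", "L2", "L3", "L4", "L5", "L6"} <= set(maps)
        planted = gtm.planted_map_correlations
        assert sum(1 for k in ("L1", "L2", "L3", "L4", "L5", "L6")
                   if planted[k] != 0) == 1
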