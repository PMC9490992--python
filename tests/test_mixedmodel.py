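import numpy as np
import pandas as pd
import pytest

import omixblup as ob
from conftest import random_psd


def _rel(values, ids=None, jitter=0.0):
    n = np.asarray(values).shape[0]
    ids = ids or [f"s{i}" for i in range(n)]
    return ob.RelationshipMatrix(ids, np.asarray(values, float),
                                 jitter_applied=jitter)


class TestAdjustPhenotypes:
    def _table(self, df, trait="y", kinds=None):
        return ob.PhenotypeTable(df, trait, kinds or {})

    def test_exactly_linear_trait_leaves_zero_residuals(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        df = pd.DataFrame({"y": 2.0 + 3.0 * x, "x": x},
                          index=[f"s{i}" for i in range(20)])
        adj = ob.adjust_phenotypes(self._table(df, kinds={"x": "continuous"}))
        np.testing.assert_allclose(adj.y_star, 0.0, atol=1e-10)

    def test_intercept_only_centers_the_trait(self):
        y = np.arange(12, dtype=float)
        df = pd.DataFrame({"y": y}, index=[f"s{i}" for i in range(12)])
        adj = ob.adjust_phenotypes(self._table(df))
        np.testing.assert_allclose(adj.y_star, y - y.mean(), atol=1e-12)
        assert abs(adj.y_star.mean()) <= 1e-10

    def test_three_level_batch_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        batch = np.array(list("aabbbccccc"))
        y = rng.normal(size=10)
        df = pd.DataFrame({"y": y, "batch": batch},
                          index=[f"s{i}" for i in range(10)])
        adj = ob.adjust_phenotypes(
            self._table(df, kinds={"batch": "categorical"}))
        X = np.column_stack([np.ones(10), batch == "b", batch == "c"]
                            ).astype(float)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(adj.y_star, y - X @ beta, atol=1e-10)

    def test_collinear_design_is_named(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=15)
        df = pd.DataFrame({"y": rng.normal(size=15), "x1": x, "x2": 2 * x},
                          index=[f"s{i}" for i in range(15)])
        with pytest.raises(ValueError, match="collinear"):
            ob.adjust_phenotypes(self._table(
                df, kinds={"x1": "continuous", "x2": "continuous"}))

    def test_missing_covariate_rows_are_dropped_and_counted(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": rng.normal(size=12),
                           "x": [np.nan] + list(rng.normal(size=11))},
                          index=[f"s{i}" for i in range(12)])
        adj = ob.adjust_phenotypes(self._table(df, kinds={"x": "continuous"}))
        assert adj.n_dropped == 1
        assert len(adj.sample_ids) == 11


class TestBlends:
    def test_blend_m_endpoints(self):
        rng = np.random.default_rng(4)
        G = _rel(random_psd(rng, 5))
        T = _rel(random_psd(rng, 5))
        np.testing.assert_allclose(ob.blend_m(G, T, 1.0).values, G.values)
        np.testing.assert_allclose(ob.blend_m(G, T, 0.0).values, T.values)
        np.testing.assert_allclose(ob.blend_m(_rel(np.eye(4)), _rel(np.eye(4)),
                                              0.3).values, np.eye(4))

    def test_blend_m_id_mismatch(self):
        G = _rel(np.eye(2), ["a", "b"])
        T = _rel(np.eye(2), ["a", "c"])
        with pytest.raises(ValueError, match="same samples"):
            ob.blend_m(G, T, 0.5)

    def test_blend_tw_endpoints_and_midpoint(self):
        T = _rel([[1.2]], ["x"])
        G22 = _rel([[1.0]], ["x"])
        np.testing.assert_allclose(ob.blend_tw(T, G22, 0.0).values, [[1.2]])
        np.testing.assert_allclose(ob.blend_tw(T, G22, 1.0).values, [[1.0]])
        np.testing.assert_allclose(ob.blend_tw(T, G22, 0.5).values, [[1.1]])

    def test_blend_tw_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            ob.blend_tw(_rel(np.eye(2)), _rel(np.eye(3)), 0.5)


class TestHybridMatrix:
    def test_t_equal_g22_collapses_to_g(self, rng):
        G = _rel(random_psd(rng, 8))
        b2 = np.arange(5, 8)
        T = G.submatrix([G.sample_ids[i] for i in b2])
        hyb = ob.build_hybrid(G, T, b2)
        np.testing.assert_allclose(hyb.values, G.values, atol=1e-12)
        np.testing.assert_allclose(ob.invert_hybrid(G, T, b2),
                                   np.linalg.inv(G.values), atol=1e-8)

    def test_worked_two_by_two_instance(self):
        G = _rel([[1.0, 0.5], [0.5, 1.0]])
        T = _rel([[1.2]], [G.sample_ids[1]])
        hyb = ob.build_hybrid(G, T, np.array([1]))
        np.testing.assert_allclose(hyb.values, [[1.05, 0.6], [0.6, 1.2]],
                                   atol=1e-12)
        Hinv = ob.invert_hybrid(G, T, np.array([1]))
        np.testing.assert_allclose(
            Hinv, [[4 / 3, -2 / 3], [-2 / 3, 7 / 6]], atol=1e-12)
        np.testing.assert_allclose(hyb.values @ Hinv, np.eye(2), atol=1e-10)

    def test_block_construction_matches_closed_form_inverse(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 41))
            nt = int(rng.integers(2, n - 1))
            G = _rel(random_psd(rng, n))
            b2 = np.sort(rng.choice(n, nt, replace=False))
            T = _rel(random_psd(rng, nt), [G.sample_ids[i] for i in b2])
            H = ob.build_hybrid(G, T, b2).values
            Hinv = ob.invert_hybrid(G, T, b2)
            assert np.abs(H @ Hinv - np.eye(n)).max() <= 1e-8

    def test_transcribed_block_holds_t(self, rng):
        G = _rel(random_psd(rng, 10))
        b2 = np.arange(6, 10)
        T = _rel(random_psd(rng, 4), [G.sample_ids[i] for i in b2])
        hyb = ob.build_hybrid(G, T, b2)
        np.testing.assert_allclose(hyb.values[np.ix_(b2, b2)], T.values,
                                   atol=1e-10)

    def test_mismatched_partition_ids_error(self, rng):
        G = _rel(random_psd(rng, 6))
        T = _rel(random_psd(rng, 2), ["nope", "wrong"])
        with pytest.raises(ValueError, match="partition"):
            ob.build_hybrid(G, T, np.array([4, 5]))


class TestREML:
    def _draw(self, K, h2, n, seed):
        rng = np.random.default_rng(seed)
        d, U = np.linalg.eigh(K.values)
        g = U @ (np.sqrt(np.clip(d, 0, None) * h2) * rng.normal(size=n))
        return g + rng.normal(scale=np.sqrt(1 - h2), size=n)

    def test_recovers_moderate_heritability(self):
        geno = ob.simulate_genotypes(400, 800, seed=21)
        K = ob.vanraden_g(geno)
        ests = [ob.reml_fit(self._draw(K, 0.5, 400, s), K).h2
                for s in range(25)]
        assert abs(np.mean(ests) - 0.5) < 0.05

    def test_heritability_identity_holds(self):
        vc = ob.VarianceComponents(1.0, 1.0, 0.5, None, None, None, 0.0, True)
        assert vc.h2 == vc.sigma_g2 / (vc.sigma_g2 + vc.sigma_e2) == 0.5
        assert vc.delta == 1.0

    def test_pure_noise_hits_zero_boundary_flagged(self):
        geno = ob.simulate_genotypes(200, 400, seed=3)
        K = ob.vanraden_g(geno)
        y = np.random.default_rng(9).normal(size=200)
        vc = ob.reml_fit(y, K)
        assert vc.h2 < 0.05
        assert vc.at_boundary
        assert vc.se_h2 is None

    def test_identity_kernel_is_non_identifiable(self):
        K = _rel(np.eye(50))
        with pytest.raises(ValueError, match="identifiab"):
            ob.reml_fit(np.random.default_rng(0).normal(size=50), K)


class TestBLUPPredict:
    def test_interpolation_limit_at_small_delta(self, rng):
        K = _rel(random_psd(rng, 12, jitter=0.2))
        y = rng.normal(size=12)
        vc = ob.VarianceComponents(1.0, 1e-10, 1.0, None, None, None, 0.0, True)
        g = ob.blup_predict(y, K, K.sample_ids, K.sample_ids, vc)
        np.testing.assert_allclose(g.gebv, y, atol=1e-6)

    def test_complete_shrinkage_at_large_delta(self, rng):
        K = _rel(random_psd(rng, 12))
        y = rng.normal(size=12)
        vc = ob.VarianceComponents(1e-12, 1e6, 0.0, None, None, None, 0.0, True)
        g = ob.blup_predict(y, K, K.sample_ids, K.sample_ids, vc)
        assert np.abs(g.gebv).max() < 1e-10

    def test_matches_conditional_mean_oracle(self, rng):
        # joint-Gaussian oracle built from explicit covariance matrices
        K = _rel(random_psd(rng, 5, jitter=0.1))
        y = rng.normal(size=5)
        sg2, se2 = 0.7, 0.9
        vc = ob.VarianceComponents(sg2, se2, sg2 / (sg2 + se2),
                                   None, None, None, 0.0, True)
        train, target = K.sample_ids[:3], K.sample_ids[3:]
        g = ob.blup_predict(y, K, train, target, vc)
        V = sg2 * K.values[:3, :3] + se2 * np.eye(3)
        C = sg2 * K.values[3:, :3]
        np.testing.assert_allclose(g.gebv, C @ np.linalg.solve(V, y[:3]),
                                   atol=1e-8)

    def test_linear_in_training_phenotypes(self, rng):
        K = _rel(random_psd(rng, 10))
        y1, y2 = rng.normal(size=10), rng.normal(size=10)
        vc = ob.VarianceComponents(1.0, 1.0, 0.5, None, None, None, 0.0, True)
        ids = K.sample_ids
        a = ob.blup_predict(y1, K, ids, ids, vc).gebv
        b = ob.blup_predict(y2, K, ids, ids, vc).gebv
        c = ob.blup_predict(2 * y1 + 3 * y2, K, ids, ids, vc).gebv
        np.testing.assert_allclose(c, 2 * a + 3 * b, atol=1e-10)


class TestFitModel:
    def test_all_five_models_run_on_study_bundle(self, study_bundle):
        bundle, _ = study_bundle
        for model in ("GBLUP", "mssBLUP", "wmssBLUP"):
            K, vc = ob.fit_model(bundle, model)
            assert K.n_samples == bundle.n_samples
            assert 0.0 <= vc.h2 <= 1.0
        full, _ = ob.make_study_bundle(n_total=80, n_transcribed=80, m=200,
                                       g=60, seed=13)
        for model in ("TBLUP", "MBLUP"):
            K, vc = ob.fit_model(full, model)
            assert 0.0 <= vc.h2 <= 1.0

    def test_wmss_with_w_one_reduces_to_gblup(self, study_bundle):
        bundle, _ = study_bundle
        Kw, vcw = ob.fit_model(bundle, "wmssBLUP", w=1.0)
        Kg, vcg = ob.fit_model(bundle, "GBLUP", genomic_kernel="cosine")
        np.testing.assert_allclose(Kw.values, Kg.values, atol=1e-10)
        assert vcw.h2 == pytest.approx(vcg.h2, abs=1e-10)

    def test_mblup_ratio_one_reduces_to_cosine_gblup(self):
        full, _ = ob.make_study_bundle(n_total=80, n_transcribed=80, m=200,
                                       g=60, seed=13)
        Km, vcm = ob.fit_model(full, "MBLUP", ratio=1.0)
        Kg, vcg = ob.fit_model(full, "GBLUP", genomic_kernel="cosine")
        np.testing.assert_allclose(Km.values, Kg.values, atol=1e-10)
        assert vcm.h2 == pytest.approx(vcg.h2, abs=1e-10)

    def test_mblup_on_partial_bundle_points_to_hybrids(self, study_bundle):
        bundle, _ = study_bundle
        with pytest.raises(ValueError, match="mssBLUP"):
            ob.fit_model(bundle, "MBLUP")
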