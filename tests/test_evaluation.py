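import numpy as np
import pytest

import omixblup as ob
from conftest import random_psd


def _rel(values, jitter=0.0):
    n = values.shape[0]
    return ob.RelationshipMatrix([f"s{i}" for i in range(n)], values,
                                 jitter_applied=jitter)


class TestPearsonAccuracy:
    def test_perfect_and_anti_correlation(self, rng):
        y = rng.normal(size=10)
        assert ob.pearson_accuracy(y, y) == pytest.approx(1.0)
        assert ob.pearson_accuracy(y, -y) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        r = ob.pearson_accuracy([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8])
        assert r == pytest.approx(0.99085, abs=1e-4)

    def test_constant_vector_is_an_error_not_zero(self):
        with pytest.raises(ValueError, match="constant"):
            ob.pearson_accuracy([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _signal_problem(n, seed, h2=0.5, m=300):
    geno = ob.simulate_genotypes(n, m, maf_range=(0.3, 0.5), seed=seed)
    K = ob.vanraden_g(geno)
    rng = np.random.default_rng(seed + 1)
    d, U = np.linalg.eigh(K.values)
    g = U @ (np.sqrt(np.clip(d, 0, None) * h2) * rng.normal(size=n))
    y = g + rng.normal(scale=np.sqrt(1 - h2), size=n)
    return y - y.mean(), K


class TestLOOCV:
    def test_one_prediction_per_sample(self):
        y, K = _signal_problem(120, seed=0)
        res = ob.loocv(y, K)
        assert res.predictions.shape == (120,)
        assert res.scheme == "loo"

    def test_refit_per_fold_matches_naive_loop_exactly(self):
        y, K = _signal_problem(15, seed=4)
        res = ob.loocv(y, K, vc_policy="refit-per-fold")
        ids = K.sample_ids
        preds = np.empty(15)
        for i in range(15):
            keep = [s for j, s in enumerate(ids) if j != i]
            vc = ob.reml_fit(y[[j for j in range(15) if j != i]],
                             K.submatrix(keep))
            preds[i] = ob.blup_predict(
                y, K, keep, [ids[i]], vc).gebv[0]
        np.testing.assert_array_equal(res.predictions, preds)
        assert res.mean_accuracy == ob.pearson_accuracy(y, preds)


class TestKFoldCV:
    def test_five_by_five_records_25_correlations(self):
        y, K = _signal_problem(100, seed=2)
        res = ob.kfold_cv(y, K, k=5, replicates=5, seed=11)
        assert len(res.fold_accuracies) == 25

    def test_folds_partition_into_equal_sizes(self):
        y, K = _signal_problem(100, seed=2)
        res = ob.kfold_cv(y, K, k=5, replicates=1, seed=0)
        labels = res.fold_assignments[0]
        assert sorted(np.bincount(labels)) == [20] * 5

    def test_same_seed_is_bitwise_reproducible(self):
        y, K = _signal_problem(60, seed=3)
        a = ob.kfold_cv(y, K, k=5, replicates=2, seed=99)
        b = ob.kfold_cv(y, K, k=5, replicates=2, seed=99)
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)
        for fa, fb in zip(a.fold_assignments, b.fold_assignments):
            np.testing.assert_array_equal(fa, fb)

    def test_permuted_phenotypes_have_no_accuracy(self):
        y, K = _signal_problem(80, seed=6)
        rng = np.random.default_rng(0)
        rs = []
        vc = ob.VarianceComponents(0.5, 0.5, 0.5, None, None, None, 0.0, True)
        ids = K.sample_ids
        for _ in range(50):
            yp = rng.permutation(y)
            g = ob.blup_predict(yp, K, ids[:60], ids[60:], vc)
            rs.append(ob.pearson_accuracy(yp[60:], g.gebv))
        assert abs(np.mean(rs)) <= 2 / np.sqrt(80)


class TestGridSearchRatio:
    def test_default_grid_has_99_points(self, rng):
        grid = np.round(np.arange(0.01, 1.00, 0.01), 2)
        assert grid.size == 99  # documents the default

    def test_endpoints_join_the_pure_models(self, transcribed_bundle):
        bundle, _ = transcribed_bundle
        adj = ob.adjust_phenotypes(bundle.pheno)
        y = adj.values_for(bundle.sample_ids)
        G = ob.cosine_g(bundle.geno)
        T = ob.cosine_t(bundle.expr, log1p=True)
        res = ob.grid_search_ratio(G, T, y, grid=np.array([0.0, 0.5, 1.0]))
        acc_t = ob.loocv(y, T).mean_accuracy
        acc_g = ob.loocv(y, G).mean_accuracy
        assert res.accuracies[0] == pytest.approx(acc_t, abs=1e-10)
        assert res.accuracies[-1] == pytest.approx(acc_g, abs=1e-10)

    def test_mediated_trait_prefers_low_ratio(self, transcribed_bundle):
        bundle, _ = transcribed_bundle
        adj = ob.adjust_phenotypes(bundle.pheno)
        y = adj.values_for(bundle.sample_ids)
        G = ob.cosine_g(bundle.geno)
        T = ob.cosine_t(bundle.expr, log1p=True)
        res = ob.grid_search_ratio(G, T, y,
                                   grid=np.round(np.arange(0.0, 1.01, 0.1), 1))
        assert res.best_value < 0.5

    def test_tie_breaks_toward_smaller_parameter(self):
        from omixblup.evaluation import _argmax_smallest
        assert _argmax_smallest(np.array([0.1, 0.2, 0.3]),
                                np.array([0.5, 0.5, 0.2])) == 0


class TestGridSearchW:
    def test_w_one_entry_equals_gblup_under_same_folds(self, study_bundle):
        bundle, _ = study_bundle
        adj = ob.adjust_phenotypes(bundle.pheno)
        y = adj.values_for(bundle.sample_ids)
        res = ob.grid_search_w(bundle, y, grid=np.array([0.5, 1.0]),
                               k=5, replicates=2, seed=21)
        G = ob.cosine_g(bundle.geno)
        acc_g = ob.kfold_cv(y, G, k=5, replicates=2, seed=21).mean_accuracy
        assert res.accuracies[-1] == pytest.approx(acc_g, abs=1e-10)

    def test_default_grid_has_11_points(self, study_bundle):
        bundle, _ = study_bundle
        adj = ob.adjust_phenotypes(bundle.pheno)
        y = adj.values_for(bundle.sample_ids)
        res = ob.grid_search_w(bundle, y, k=5, replicates=1, seed=2)
        assert res.grid.size == 11
        np.testing.assert_allclose(res.grid, np.arange(0.0, 1.01, 0.1),
                                   atol=1e-12)


class TestProportionExperiment:
    def test_default_size_list_has_seven_entries(self):
        from omixblup.evaluation import _default_proportion_sizes
        sizes = _default_proportion_sizes(240)
        assert len(sizes) == 7
        assert sizes[-1] == 240

    def test_rows_cover_requested_sizes(self, study_bundle):
        bundle, _ = study_bundle
        adj = ob.adjust_phenotypes(bundle.pheno)
        y = adj.values_for(bundle.sample_ids)
        rows = ob.proportion_experiment(bundle, y, sizes=[40, 80],
                                        replicates=1, seed=5,
                                        expr_log1p=True)
        assert [r["size"] for r in rows] == [40, 80]
        nt = len(bundle.transcribed_idx)
        assert [r["n_total"] for r in rows] == [40 + nt, 80 + nt]
        for r in rows:
            assert np.isfinite(r["accuracy_wmss"])
            assert r["improvement_abs"] == pytest.approx(
                r["accuracy_wmss"] - r["accuracy_gblup"])

    def test_oversized_request_is_an_error(self, study_bundle):
        bundle, _ = study_bundle
        adj = ob.adjust_phenotypes(bundle.pheno)
        y = adj.values_for(bundle.sample_ids)
        with pytest.raises(ValueError, match="exceeds"):
            ob.proportion_experiment(bundle, y, sizes=[10_000], seed=0)

    def test_full_pool_uses_every_untranscribed_animal(self, study_bundle):
        bundle, _ = study_bundle
        adj = ob.adjust_phenotypes(bundle.pheno)
        y = adj.values_for(bundle.sample_ids)
        pool = len(bundle.untranscribed_idx)
        rows = ob.proportion_experiment(bundle, y, sizes=[pool],
                                        replicates=1, seed=8)
        assert rows[0]["n_total"] == bundle.n_samples
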