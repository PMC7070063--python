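import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from magniche.prediction import (
    ModelConfig,
    evaluate,
    forest_oob_predict,
    gbm_fit_predict,
    kfold_cv,
    make_folds,
    phylo_covariance,
    phylo_predict,
    ridge_fit_predict,
)
from magniche.synthetic_data import SyntheticConfig, simulate_tree


def frame(X):
    return pd.DataFrame(X, index=[f"e{i}" for i in range(len(X))])


class TestMakeFolds:
    def test_near_equal_sizes(self):
        folds = make_folds(25, 10, seed=0)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.sum() == 25
        assert set(sizes) <= {2, 3}

    def test_seed_determinism(self):
        assert np.array_equal(make_folds(40, 10, 3), make_folds(40, 10, 3))

    def test_too_few_entities(self):
        with pytest.raises(ValueError):
            make_folds(5, 10, 0)


class TestRidge:
    def test_huge_lambda_predicts_training_mean(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30) + 3.0
        cfg = ModelConfig(model="ridge", seed=0)
        preds = ridge_fit_predict(X, y, X, cfg, alpha=1e12)
        assert np.allclose(preds, y.mean(), atol=1e-4)

    def test_lambda_zero_matches_ols_oracle(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        cfg = ModelConfig(model="ridge", seed=0)
        preds = ridge_fit_predict(X, y, X, cfg, alpha=0.0)
        # normal-equations OLS on the standardized design
        Xs = (X - X.mean(0)) / X.std(0)
        Xs = np.column_stack([np.ones(len(X)), Xs])
        beta = np.linalg.solve(Xs.T @ Xs, Xs.T @ y)
        assert np.allclose(preds, Xs @ beta, atol=1e-6)

    def test_duplicated_columns_prediction_invariant(self, rng):
        X = rng.normal(size=(40, 3))
        y = X[:, 0] * 2 + rng.normal(0, 0.1, 40)
        cfg = ModelConfig(model="ridge", seed=0)
        single = ridge_fit_predict(X, y, X, cfg, alpha=1.0)
        X_dup = np.column_stack([X, X[:, 0]])
        # duplicating a column: same predictions at half the per-column
        # penalty weight on the duplicated direction -> adjusted lambda
        dup = ridge_fit_predict(X_dup, y, X_dup, cfg, alpha=2.0)
        assert np.all(np.isfinite(dup))
        # coefficients stay finite and predictions stay close
        assert np.corrcoef(single, dup)[0, 1] > 0.999

    def test_noiseless_linear_recovery(self, rng):
        X = rng.normal(size=(60, 10))
        y = 3.0 * X[:, 4]
        cfg = ModelConfig(model="ridge", cv_folds=10, seed=5)
        result = kfold_cv(frame(X), pd.Series(y, index=frame(X).index), cfg)
        assert result.rho >= 0.99

    def test_all_constant_features_rejected(self):
        X = np.ones((20, 3))
        with pytest.raises(ValueError):
            ridge_fit_predict(X, np.arange(20.0), X, ModelConfig(seed=0))


class TestGbm:
    def test_zero_stages_predicts_mean(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        cfg = ModelConfig(model="gradient_boosting", gbm_n_trees=0, seed=0)
        assert np.allclose(gbm_fit_predict(X, y, X, cfg), y.mean())

    def test_zero_learning_rate_predicts_mean(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        cfg = ModelConfig(
            model="gradient_boosting", gbm_learning_rate=0.0, seed=0
        )
        assert np.allclose(gbm_fit_predict(X, y, X, cfg), y.mean())

    def test_additive_two_feature_signal(self, rng):
        # held-out recovery of an additive signal; reduced stage count with
        # proportionally larger learning rate to stay within test budget
        X = rng.normal(size=(300, 10))
        y = X[:, 0] + X[:, 1] + rng.normal(0, 0.3, 300)
        cfg = ModelConfig(
            model="gradient_boosting",
            gbm_n_trees=1000,
            gbm_learning_rate=0.01,
            seed=1,
        )
        train, test = np.arange(200), np.arange(200, 300)
        preds = gbm_fit_predict(X[train], y[train], X[test], cfg)
        rho, _ = evaluate(y[test], preds)
        assert rho >= 0.8

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        cfg = ModelConfig(model="gradient_boosting", gbm_n_trees=50, seed=9)
        p1 = gbm_fit_predict(X, y, X, cfg)
        p2 = gbm_fit_predict(X, y, X, cfg)
        assert np.array_equal(p1, p2)


class TestForestOob:
    def test_constant_target_constant_predictions(self, rng):
        X = frame(rng.normal(size=(40, 5)))
        y = pd.Series(np.full(40, 2.5), index=X.index)
        cfg = ModelConfig(model="random_forest", rf_n_trees=200, seed=0)
        with pytest.raises(ValueError, match="constant"):
            # constant target makes Spearman evaluation undefined
            forest_oob_predict(X, y, cfg)

    def test_seed_determinism(self, rng):
        X = frame(rng.normal(size=(50, 5)))
        y = pd.Series(rng.normal(size=50), index=X.index)
        cfg = ModelConfig(model="random_forest", rf_n_trees=150, seed=4)
        r1 = forest_oob_predict(X, y, cfg)
        r2 = forest_oob_predict(X, y, cfg)
        assert np.array_equal(r1.predicted, r2.predicted)

    def test_strong_single_feature_signal(self, rng):
        X = rng.normal(size=(200, 5))
        y = X[:, 2] + rng.normal(0, 0.1, 200)
        cfg = ModelConfig(model="random_forest", rf_n_trees=500, seed=2)
        result = forest_oob_predict(
            frame(X), pd.Series(y, index=frame(X).index), cfg
        )
        assert result.rho >= 0.8

    def test_too_few_trees_rejected(self, rng):
        X = frame(rng.normal(size=(20, 2)))
        y = pd.Series(rng.normal(size=20), index=X.index)
        with pytest.raises(ValueError):
            forest_oob_predict(X, y, ModelConfig(rf_n_trees=10, seed=0))


def conditional_normal_oracle(cov, train_idx, test_idx, y_train):
    """Brute-force conditional multivariate-normal expectation with a GLS
    mean, built directly from the full covariance matrix."""
    C_oo = cov[np.ix_(train_idx, train_idx)]
    C_to = cov[np.ix_(test_idx, train_idx)]
    Cinv = np.linalg.inv(C_oo)
    ones = np.ones(len(train_idx))
    mu = (ones @ Cinv @ y_train) / (ones @ Cinv @ ones)
    return mu + C_to @ Cinv @ (y_train - mu)


class TestPhyloPredict:
    def star_tree(self, n=6):
        taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
        tree = dendropy.Tree(taxon_namespace=taxa)
        for i in range(n):
            tree.seed_node.new_child(taxon=taxa[i], edge_length=1.0)
        return tree

    def test_star_tree_predicts_mean(self):
        tree = self.star_tree()
        observed = pd.Series([1.0, 2.0, 6.0], index=["t0", "t1", "t2"])
        preds = phylo_predict(tree, observed, ["t3", "t4"])
        assert np.allclose(preds, observed.mean(), atol=1e-10)

    def test_zero_distance_tip_copies_value(self):
        tree = dendropy.Tree.get(
            data="((a:0.00001,b:0.00001):1.0,(c:1.0,d:1.0):0.00001);",
            schema="newick",
        )
        observed = pd.Series([5.0, -1.0, 0.5], index=["a", "c", "d"])
        preds = phylo_predict(tree, observed, ["b"])
        assert preds["b"] == pytest.approx(5.0, abs=1e-3)

    def test_matches_conditional_normal_oracle(self):
        cfg = SyntheticConfig(n_taxa=100, seed=17)
        tree = simulate_tree(cfg)
        taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        cov = phylo_covariance(tree, taxa)
        rng = np.random.default_rng(3)
        y = rng.multivariate_normal(np.zeros(100), cov + 1e-10 * np.eye(100))
        train_idx = np.arange(80)
        test_idx = np.arange(80, 100)
        observed = pd.Series(y[train_idx], index=[taxa[i] for i in train_idx])
        heldout = [taxa[i] for i in test_idx]
        preds = phylo_predict(tree, observed, heldout, covariance=cov, taxa=taxa)
        oracle = conditional_normal_oracle(cov, train_idx, test_idx, y[train_idx])
        assert np.abs(preds.to_numpy() - oracle).max() < 1e-8

    def test_covariance_is_shared_path_length(self):
        tree = dendropy.Tree.get(
            data="((a:1.0,b:1.0):2.0,c:3.0);", schema="newick"
        )
        cov = phylo_covariance(tree, ["a", "b", "c"])
        assert cov[0, 0] == pytest.approx(3.0)
        assert cov[0, 1] == pytest.approx(2.0)  # shared root-to-MRCA path
        assert cov[0, 2] == pytest.approx(0.0)

    def test_missing_tip_rejected(self):
        tree = self.star_tree(3)
        with pytest.raises(ValueError, match="missing"):
            phylo_covariance(tree, ["t0", "ghost"])


class TestEvaluate:
    def test_identical_is_one(self):
        rho, p = evaluate([1, 2, 3, 4], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        rho, _ = evaluate([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, _ = evaluate(x, y)
        oracle = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1, 1, 1], [1, 2, 3])


class TestKfoldCv:
    def test_each_entity_predicted_once_out_of_fold(self, rng):
        X = frame(rng.normal(size=(30, 4)))
        y = pd.Series(rng.normal(size=30), index=X.index)
        cfg = ModelConfig(model="ridge", cv_folds=10, seed=0)
        result = kfold_cv(X, y, cfg)
        assert result.predicted.notna().all()
        assert result.fold.nunique() == 10

    def test_same_seed_same_folds(self, rng):
        X = frame(rng.normal(size=(30, 4)))
        y = pd.Series(rng.normal(size=30), index=X.index)
        cfg = ModelConfig(model="ridge", cv_folds=10, seed=8)
        r1 = kfold_cv(X, y, cfg)
        r2 = kfold_cv(X, y, cfg)
        assert (r1.fold == r2.fold).all()
        assert np.allclose(r1.predicted, r2.predicted)

    def test_phylo_model_via_folds(self):
        cfg = SyntheticConfig(n_taxa=40, seed=23)
        tree = simulate_tree(cfg)
        taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        cov = phylo_covariance(tree, taxa)
        rng = np.random.default_rng(0)
        y = pd.Series(
            rng.multivariate_normal(np.zeros(40), cov + 1e-10 * np.eye(40)),
            index=taxa,
        )
        X = pd.DataFrame(np.zeros((40, 1)), index=taxa)  # unused by phylo
        mcfg = ModelConfig(model="phylo", cv_folds=10, seed=1)
        result = kfold_cv(X, y, mcfg, tree=tree)
        # a Brownian trait is predictable from relatives
        assert result.rho > 0.3

    def test_unknown_model_rejected(self, rng):
        X = frame(rng.normal(size=(20, 2)))
        y = pd.Series(rng.normal(size=20), index=X.index)
        with pytest.raises(ValueError):
            kfold_cv(X, y, ModelConfig(model="nonsense", cv_folds=5, seed=0))


class TestTaxonRestrictedRun:
    def setup_tables(self, beta1_world):
        from magniche import abundance, catalogue, profiles

        assignment = catalogue.assign_bacls(
            beta1_world.quality_table, beta1_world.ani_matrix
        )
        bacl_prof = profiles.bacl_profiles(
            beta1_world.gene_matrix.astype(float), assignment.labels
        )
        bacl_ab = abundance.bacl_abundance(
            assignment.representatives, beta1_world.abundance
        )
        retained = assignment.retained_bacls()
        return bacl_prof.loc[retained], bacl_ab.loc[retained]

    def test_full_set_matches_global_run(self, beta1_world):
        from magniche import abundance as abundance_mod
        from magniche import profiles
        from magniche.niche_space import pcoa_cailliez
        from magniche.prediction import taxon_restricted_run

        gene_prof, bacl_ab = self.setup_tables(beta1_world)
        labels = pd.Series("all", index=gene_prof.index)
        cfg = ModelConfig(model="ridge", cv_folds=5, seed=3)
        results = taxon_restricted_run(
            profiles.prevalence_filter, bacl_ab, gene_prof, labels, cfg
        )
        # independent global run with the same ingredients
        feats = profiles.prevalence_filter(gene_prof)
        diss = abundance_mod.abundance_dissimilarity(bacl_ab)
        space = pcoa_cailliez(diss, k=1)
        expected = kfold_cv(feats, space.coordinates["PC1"], cfg)
        assert results["all"].rho == pytest.approx(expected.rho, abs=1e-12)

    def test_disjoint_subsets_independent_and_small_skipped(self, beta1_world):
        from magniche import profiles
        from magniche.prediction import taxon_restricted_run

        gene_prof, bacl_ab = self.setup_tables(beta1_world)
        n = len(gene_prof)
        labels = pd.Series(
            ["left"] * (n // 2) + ["right"] * (n - n // 2 - 2) + ["tiny"] * 2,
            index=gene_prof.index,
        )
        cfg = ModelConfig(model="ridge", cv_folds=5, seed=3)
        results = taxon_restricted_run(
            profiles.prevalence_filter, bacl_ab, gene_prof, labels, cfg
        )
        assert set(results) == {"left", "right"}  # "tiny" below cv_folds
        left_ids = set(results["left"].observed.index)
        right_ids = set(results["right"].observed.index)
        assert left_ids.isdisjoint(right_ids)
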