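"""Niche-placement prediction from gene content and from phylogeny.

Gene-content models (ridge with inner-CV lambda tuning, random forest with
out-of-bag validation, gradient boosting) are evaluated by 10-fold
cross-validation: every entity is predicted exactly once by a model that
never saw it.  The phylogeny-only competitor is the Brownian-motion
generalized-least-squares (phylogenetic kriging) conditional expectation,
evaluated with the same folds.  All predictions are scored with Spearman
rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.stats import spearmanr
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor

logger = logging.getLogger(__name__)

RIDGE_ALPHA_GRID = np.logspace(-4, 4, 100)


@dataclass
class ModelConfig:
    model: str = "ridge"  # ridge | random_forest | gradient_boosting | phylo
    cv_folds: int = 10
    seed: int = 0
    ridge_alphas: np.ndarray = field(default_factory=lambda: RIDGE_ALPHA_GRID)
    ridge_inner_folds: int = 5
    rf_n_trees: int = 2000
    gbm_n_trees: int = 10000
    gbm_learning_rate: float = 0.001
    gbm_max_depth: int = 2
    gbm_min_obs_per_leaf: int = 1

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.gbm_learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.rf_n_trees < 1 or self.gbm_n_trees < 0:
            raise ValueError("tree counts must be positive")


@dataclass
class PredictionResult:
    observed: pd.Series
    predicted: pd.Series
    fold: pd.Series | None
    rho: float
    p_value: float
    model: str

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"observed": self.observed, "predicted": self.predicted}
        )
        if self.fold is not None:
            out["fold"] = self.fold
        return out


def evaluate(observed, predicted) -> tuple[float, float]:
    """Spearman rho (mid-ranks) and its large-sample p-value."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size != predicted.size or observed.size < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if np.unique(observed).size < 2 or np.unique(predicted).size < 2:
        raise ValueError("Spearman rho undefined for a constant vector")
    result = spearmanr(observed, predicted)
    return float(result.statistic), float(result.pvalue)


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Random partition into k near-equal folds (sizes differ by <= 1)."""
    if n < k:
        raise ValueError(f"cannot split {n} entities into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(order, k)):
        folds[chunk] = fold
    return folds


# ---------------------------------------------------------------- ridge


def _standardize_train_test(
    X_train: np.ndarray, X_test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    mean = X_train.mean(axis=0)
    std = X_train.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)  # constant columns become all-zero
    return (X_train - mean) / std, (X_test - mean) / std


def _ridge_solve(
    X: np.ndarray, y: np.ndarray, alphas: np.ndarray
) -> np.ndarray:
    """Ridge coefficient paths via one SVD; columns correspond to alphas."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    Uty = U.T @ y
    shrink = s[:, None] / (s[:, None] ** 2 + alphas[None, :])
    return Vt.T @ (shrink * Uty[:, None])


def ridge_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    cfg: ModelConfig,
    alpha: float | None = None,
) -> np.ndarray:
    """L2-penalized regression with inner-CV lambda selection.

    Features are standardized with training-set statistics; the penalty is
    chosen from ``cfg.ridge_alphas`` by ``cfg.ridge_inner_folds``-fold CV on
    the training set (minimum mean squared error).  Passing ``alpha`` skips
    the inner CV (alpha=0 gives ordinary least squares via the SVD
    pseudo-inverse).
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if np.all(X_train.std(axis=0) == 0):
        raise ValueError("all features are constant")
    Xtr, Xte = _standardize_train_test(X_train, X_test)
    y_mean = y_train.mean()
    yc = y_train - y_mean

    if alpha is None and len(cfg.ridge_alphas) == 1:
        alpha = float(cfg.ridge_alphas[0])
    if alpha is None:
        alphas = np.asarray(cfg.ridge_alphas, dtype=float)
        k = min(cfg.ridge_inner_folds, len(yc))
        folds = make_folds(len(yc), k, cfg.seed + 7)
        sse = np.zeros(len(alphas))
        for fold in range(k):
            val = folds == fold
            coefs = _ridge_solve(Xtr[~val], yc[~val] - yc[~val].mean(), alphas)
            preds = Xtr[val] @ coefs + yc[~val].mean()
            sse += ((preds - yc[val][:, None]) ** 2).sum(axis=0)
        alpha = float(alphas[np.argmin(sse)])

    coef = _ridge_solve(Xtr, yc, np.array([alpha]))[:, 0]
    return Xte @ coef + y_mean


# ------------------------------------------------- tree-ensemble models


def gbm_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    cfg: ModelConfig,
) -> np.ndarray:
    """Stagewise boosted regression trees, squared-error loss.

    Hyperparameters follow the reference settings: 10000 stages, learning
    rate 0.001, per-tree depth limit 2, minimum 1 observation per leaf, no
    feature or row subsampling.  Zero stages or a zero learning rate reduce
    to predicting the training mean.
    """
    y_train = np.asarray(y_train, dtype=float)
    if cfg.gbm_n_trees == 0 or cfg.gbm_learning_rate == 0:
        return np.full(len(X_test), y_train.mean())
    model = HistGradientBoostingRegressor(
        loss="squared_error",
        max_iter=cfg.gbm_n_trees,
        learning_rate=cfg.gbm_learning_rate,
        max_depth=cfg.gbm_max_depth,
        max_leaf_nodes=None,
        min_samples_leaf=cfg.gbm_min_obs_per_leaf,
        l2_regularization=0.0,
        early_stopping=False,
        random_state=cfg.seed,
    )
    model.fit(np.asarray(X_train, dtype=float), y_train)
    return model.predict(np.asarray(X_test, dtype=float))


def forest_oob_predict(
    features: pd.DataFrame, target: pd.Series, cfg: ModelConfig
) -> PredictionResult:
    """Random-forest regression validated by out-of-bag predictions.

    Each entity's prediction averages only trees whose bootstrap sample
    excluded it; entities in-bag for every tree (vanishingly rare at 2000
    trees) are flagged and dropped from the evaluation.
    """
    if cfg.rf_n_trees < 100:
        raise ValueError("need at least 100 trees for stable OOB predictions")
    X = features.to_numpy(dtype=float)
    y = target.loc[features.index].to_numpy(dtype=float)
    model = RandomForestRegressor(
        n_estimators=cfg.rf_n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    oob = model.oob_prediction_
    n_oob = _oob_counts(model, len(y))
    never_oob = n_oob == 0
    if never_oob.any():
        logger.warning(
            "%d entities were in-bag for every tree; dropped from evaluation",
            int(never_oob.sum()),
        )
    mask = ~never_oob
    rho, p = evaluate(y[mask], oob[mask])
    predicted = pd.Series(oob, index=features.index)
    predicted[never_oob] = np.nan
    return PredictionResult(
        observed=pd.Series(y, index=features.index),
        predicted=predicted,
        fold=None,
        rho=rho,
        p_value=p,
        model="random_forest",
    )


def _oob_counts(model: RandomForestRegressor, n: int) -> np.ndarray:
    counts = np.zeros(n, dtype=int)
    for sample in model.estimators_samples_:
        in_bag = np.bincount(sample, minlength=n)
        counts[in_bag == 0] += 1
    return counts


# ----------------------------------------------------------- phylogeny


def phylo_covariance(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-MRCA path length."""
    label_to_leaf = {
        leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()
    }
    missing = [t for t in taxa if t not in label_to_leaf]
    if missing:
        raise ValueError(f"tips missing from tree: {missing[:5]}")
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depths[id(node)] = (depths[id(parent)] if parent else 0.0) + edge
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    cov = np.zeros((n, n))
    for i in range(n):
        cov[i, i] = depths[id(label_to_leaf[taxa[i]])]
        for j in range(i + 1, n):
            d = pdm.patristic_distance(
                label_to_leaf[taxa[i]].taxon, label_to_leaf[taxa[j]].taxon
            )
            cov[i, j] = cov[j, i] = 0.5 * (
                depths[id(label_to_leaf[taxa[i]])]
                + depths[id(label_to_leaf[taxa[j]])]
                - d
            )
    return cov


def phylo_predict(
    tree: dendropy.Tree,
    observed: pd.Series,
    heldout: list[str],
    covariance: np.ndarray | None = None,
    taxa: list[str] | None = None,
) -> pd.Series:
    """Brownian-motion conditional expectation for unobserved tips.

    Prediction for a held-out tip is mu + C_to C_oo^-1 (y - mu) with C the
    shared-path-length covariance and mu the GLS estimate of the root state
    from the observed tips.  A singular covariance (duplicated zero-length
    tips) gets an escalating diagonal jitter, logged.
    """
    train = list(observed.index)
    if covariance is None or taxa is None:
        taxa = train + [t for t in heldout if t not in train]
        covariance = phylo_covariance(tree, taxa)
    pos = {t: i for i, t in enumerate(taxa)}
    oo = np.ix_([pos[t] for t in train], [pos[t] for t in train])
    to = np.ix_([pos[t] for t in heldout], [pos[t] for t in train])
    C_oo = covariance[oo]
    C_to = covariance[to]
    y = observed.to_numpy(dtype=float)

    jitter = 0.0
    scale = np.mean(np.diag(C_oo)) or 1.0
    for attempt in range(6):
        try:
            cho = sla.cho_factor(C_oo + jitter * np.eye(len(train)))
            break
        except np.linalg.LinAlgError:
            jitter = scale * 10.0 ** (-12 + 2 * attempt)
            logger.warning("singular BM covariance; jitter %.1e applied", jitter)
    else:
        raise np.linalg.LinAlgError("BM covariance not factorizable")

    ones = np.ones(len(train))
    Cinv_y = sla.cho_solve(cho, y)
    Cinv_1 = sla.cho_solve(cho, ones)
    mu = float(ones @ Cinv_y / (ones @ Cinv_1))
    preds = mu + C_to @ sla.cho_solve(cho, y - mu)
    return pd.Series(preds, index=heldout)


# ----------------------------------------------------------- CV driver


def kfold_cv(
    features: pd.DataFrame,
    target: pd.Series,
    cfg: ModelConfig,
    tree: dendropy.Tree | None = None,
) -> PredictionResult:
    """Out-of-fold predictions: each entity predicted once by a model not
    trained on it.  ``cfg.model`` selects ridge, gradient_boosting or phylo
    (the latter needs ``tree``); random_forest uses OOB validation instead
    (see forest_oob_predict)."""
    target = target.loc[features.index]
    if target.isna().any():
        raise ValueError("missing target values")
    n = len(features)
    folds = make_folds(n, cfg.cv_folds, cfg.seed)
    predicted = pd.Series(np.nan, index=features.index, dtype=float)

    covariance = None
    taxa = None
    if cfg.model == "phylo":
        if tree is None:
            raise ValueError("phylo model needs a tree")
        taxa = list(features.index)
        covariance = phylo_covariance(tree, taxa)

    X = features.to_numpy(dtype=float)
    y = target.to_numpy(dtype=float)
    for fold in range(cfg.cv_folds):
        test_mask = folds == fold
        if cfg.model == "ridge":
            preds = ridge_fit_predict(X[~test_mask], y[~test_mask], X[test_mask], cfg)
        elif cfg.model == "gradient_boosting":
            preds = gbm_fit_predict(X[~test_mask], y[~test_mask], X[test_mask], cfg)
        elif cfg.model == "phylo":
            obs = target[~test_mask]
            held = list(target.index[test_mask])
            preds = phylo_predict(
                tree, obs, held, covariance=covariance, taxa=taxa
            ).to_numpy()
        else:
            raise ValueError(f"unknown model {cfg.model!r} for k-fold CV")
        predicted.iloc[np.flatnonzero(test_mask)] = preds

    rho, p = evaluate(y, predicted.to_numpy())
    return PredictionResult(
        observed=target,
        predicted=predicted,
        fold=pd.Series(folds, index=features.index),
        rho=rho,
        p_value=p,
        model=cfg.model,
    )


def predict_target(
    features: pd.DataFrame,
    target: pd.Series,
    cfg: ModelConfig,
    tree: dendropy.Tree | None = None,
) -> PredictionResult:
    """Dispatch on ``cfg.model``; random forests use OOB validation."""
    if cfg.model == "random_forest":
        return forest_oob_predict(features, target, cfg)
    return kfold_cv(features, target, cfg, tree=tree)


def permutation_control(
    features: pd.DataFrame,
    target: pd.Series,
    cfg: ModelConfig,
    n_perm: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """|rho| of out-of-fold predictions against shuffled targets.

    Guards against fold contamination: under a permuted target the
    out-of-fold correlation should be near zero.
    """
    rng = np.random.default_rng(seed)
    values = target.loc[features.index].to_numpy(dtype=float)
    rhos = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = pd.Series(rng.permutation(values), index=features.index)
        result = kfold_cv(features, shuffled, cfg)
        rhos[i] = abs(result.rho)
    return rhos


def taxon_restricted_run(
    mag_profiles_filtered_builder,
    abundances: pd.DataFrame,
    gene_profiles: pd.DataFrame,
    taxon_labels: pd.Series,
    cfg: ModelConfig,
    min_size: int | None = None,
) -> dict[str, PredictionResult]:
    """Re-run niche space + prediction within each taxon label.

    For every taxon with at least ``min_size`` entities (default:
    cfg.cv_folds), the prevalence filter, abundance dissimilarity, PCoA and
    the configured model are recomputed on the subset; the result maps taxon
    label to the PC1 PredictionResult.  ``mag_profiles_filtered_builder`` is
    a callable (profiles subset) -> filtered feature matrix, letting the
    caller choose the filter convention.
    """
    from magniche.abundance import abundance_dissimilarity
    from magniche.niche_space import pcoa_cailliez

    if min_size is None:
        min_size = cfg.cv_folds
    results: dict[str, PredictionResult] = {}
    for taxon in sorted(taxon_labels.unique()):
        members = taxon_labels.index[taxon_labels == taxon]
        members = [m for m in members if m in gene_profiles.index]
        if len(members) < min_size:
            logger.info("taxon %s skipped: %d < %d entities", taxon, len(members), min_size)
            continue
        feats = mag_profiles_filtered_builder(gene_profiles.loc[members])
        diss = abundance_dissimilarity(abundances.loc[members])
        space = pcoa_cailliez(diss, k=1)
        target = space.coordinates["PC1"]
        results[taxon] = predict_target(feats, target, cfg)
    return results
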