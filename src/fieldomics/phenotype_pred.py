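"""Phenotype prediction from molecular profiles.

Single-feature associations use a GLS with a rational quadratic residual
correlation estimated by REML; multi-feature models (elastic net, random
forest) are evaluated with 10-fold nested cross-validation, pooled and
median out-of-fold R^2, and permutation-based empirical p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import GridSearchCV, KFold

from .spatial_lme import LMEFit, _layout_distances, fit_gls, ratio_correlation
from .spatial_stats import bh_adjust

__all__ = [
    "SingleFeatureAssociation",
    "ModelPerformance",
    "ratio_correlation",
    "single_feature_gls",
    "single_feature_associations",
    "nested_cv_fit",
    "oob_r2",
    "permutation_pvalue",
    "permutation_pvalue_sd",
    "ENET_GRID",
    "FOREST_GRID",
    "REDUCED_ENET_GRID",
]

ENET_GRID = {
    "alpha": list(np.logspace(-3, 0, 7)),
    "l1_ratio": [0.1, 0.3, 0.5, 0.7, 0.9, 1.0],
}
REDUCED_ENET_GRID = {"alpha": [0.01, 0.1, 1.0], "l1_ratio": [0.5, 1.0]}
FOREST_GRID = {
    "max_features": ["sqrt", 0.33, "log2", None],
    "min_samples_split": [2, 3, 4, 5],
}


@dataclass(frozen=True)
class SingleFeatureAssociation:
    feature: str
    beta0: float
    beta: float
    p: float
    r2: float
    nugget: float
    range_: float
    fitted_by: str
    q: float | None = None


@dataclass
class ModelPerformance:
    pooled_r2: float
    median_r2: float
    pcc: float
    fold_predictions: pd.DataFrame  # columns: sample, fold, observed, predicted
    best_params: list[dict]
    feature_importances: pd.Series | None = None
    empirical_p: dict = field(default_factory=dict)
    n_permutations: int = 0


def single_feature_gls(
    phenotype: np.ndarray,
    feature_profile: np.ndarray,
    layout: pd.DataFrame,
    *,
    feature: str = "feature",
    spatial_lrt_cutoff: float | None = None,
) -> SingleFeatureAssociation:
    """Regress a phenotype on one feature with ratio-kernel GLS errors."""
    y = np.asarray(phenotype, dtype=float).ravel()
    x = np.asarray(feature_profile, dtype=float).ravel()
    X = np.column_stack([np.ones_like(x), x])
    dist = _layout_distances(layout)
    fit: LMEFit = fit_gls(y, X, dist, kernel="ratio", beta_names=["intercept", "beta"],
                          spatial_lrt_cutoff=spatial_lrt_cutoff)
    fitted = y.mean() + fit.beta[1] * (x - x.mean())
    ss_res = float(((y - (fit.beta[0] + fit.beta[1] * x)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return SingleFeatureAssociation(
        feature, float(fit.beta[0]), float(fit.beta[1]), float(fit.pvalues[1]),
        r2, fit.cov.nugget, fit.cov.range_, fit.fitted_by,
    )


def single_feature_associations(
    features: pd.DataFrame,
    phenotype: np.ndarray,
    layout: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """All single-feature fits for one phenotype, BH-adjusted across features."""
    records = []
    for feat, row in features.iterrows():
        try:
            assoc = single_feature_gls(phenotype, row.to_numpy(dtype=float), layout,
                                       feature=str(feat), **kwargs)
        except ValueError as exc:
            warnings.warn(f"feature {feat!r} skipped: {exc}")
            continue
        records.append({
            "feature": assoc.feature, "beta0": assoc.beta0, "beta": assoc.beta,
            "p": assoc.p, "r2": assoc.r2, "nugget": assoc.nugget,
            "range": assoc.range_, "fitted_by": assoc.fitted_by,
        })
    table = pd.DataFrame.from_records(records).set_index("feature")
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
    return table


def oob_r2(predictions, observed, mode: str = "pooled",
           folds: np.ndarray | None = None) -> float:
    """Out-of-fold R^2 = 1 - SSE/SST; can be negative.

    ``pooled`` evaluates one statistic over all pairs (SST against the mean
    of the evaluated observations); ``median`` computes per-fold R^2 and
    takes the median (requires ``folds``).
    """
    yhat = np.asarray(predictions, dtype=float).ravel()
    y = np.asarray(observed, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need >= 2 observations")
    if mode == "pooled":
        sst = float(((y - y.mean()) ** 2).sum())
        if sst == 0:
            raise ValueError("constant observed values")
        return 1.0 - float(((y - yhat) ** 2).sum()) / sst
    if mode == "median":
        if folds is None:
            raise ValueError("median mode requires fold labels")
        folds = np.asarray(folds)
        scores = []
        for f in np.unique(folds):
            m = folds == f
            yf = y[m]
            sst = float(((yf - yf.mean()) ** 2).sum())
            if sst == 0:
                warnings.warn(f"fold {f} has constant phenotype; skipped")
                continue
            scores.append(1.0 - float(((yf - yhat[m]) ** 2).sum()) / sst)
        return float(np.median(scores))
    raise ValueError(f"unknown mode {mode!r}")


def permutation_pvalue(true_score: float, permuted_scores) -> tuple[float, int, int]:
    """Empirical p = (n+1)/(k+1), n = #permutations scoring >= the true model."""
    perm = np.asarray(permuted_scores, dtype=float)
    k = perm.size
    if k < 1:
        raise ValueError("need at least one permutation")
    n = int((perm >= true_score).sum())
    return (n + 1) / (k + 1), n, k


def permutation_pvalue_sd(p_star: float, k: int) -> float:
    """Standard deviation of the empirical p-value: sqrt(p*(1-p*)/k)."""
    if not 0.0 <= p_star <= 1.0 or k < 1:
        raise ValueError("p_star must be in [0,1] and k >= 1")
    return float(np.sqrt(p_star * (1.0 - p_star) / k))


def _make_estimator(learner: str, seed: int, n_trees: int):
    if learner == "elastic_net":
        return ElasticNet(max_iter=10**6)
    if learner == "random_forest":
        return RandomForestRegressor(n_estimators=n_trees, criterion="squared_error",
                                     bootstrap=True, random_state=seed)
    raise ValueError(f"unknown learner {learner!r}")


def _enet_grid_search(Xtr, ytr, grid, inner):
    """Manual inner grid search for elastic nets; avoids estimator overhead.

    Selection metric is the mean out-of-fold R^2 across the inner folds,
    matching GridSearchCV(scoring='r2') up to tie-breaking order.
    """
    from itertools import product

    keys = list(grid)
    combos = [dict(zip(keys, v)) for v in product(*(grid[k] for k in keys))]
    splits = list(inner.split(Xtr))
    fold_data = [
        (np.asfortranarray(Xtr[itr]), ytr[itr], Xtr[ite], ytr[ite])
        for itr, ite in splits
    ]
    best, best_score = combos[0], -np.inf
    model = ElasticNet(max_iter=10**6)
    for params in combos:
        model.set_params(**params)
        scores = []
        for Xi, yi, Xv, yv in fold_data:
            model.fit(Xi, yi, check_input=False)
            resid = yv - (Xv @ model.coef_ + model.intercept_)
            sst = float(((yv - yv.mean()) ** 2).sum())
            scores.append(1.0 - float((resid**2).sum()) / sst if sst > 0 else 0.0)
        s = float(np.mean(scores))
        if s > best_score:
            best, best_score = params, s
    model.set_params(**best)
    model.fit(np.asfortranarray(Xtr), ytr, check_input=False)
    return model, best


def _run_nested_cv(X, y, learner, grid, seed, n_outer, n_inner, n_trees):
    outer = KFold(n_splits=n_outer, shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    fold_labels = np.empty(len(y), dtype=int)
    best_params = []
    importances = []
    for fold, (train, test) in enumerate(outer.split(X)):
        inner = KFold(n_splits=n_inner, shuffle=True, random_state=seed + 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if learner == "elastic_net":
                model, best = _enet_grid_search(X[train], y[train], grid, inner)
                preds[test] = X[test] @ model.coef_ + model.intercept_
            else:
                search = GridSearchCV(_make_estimator(learner, seed, n_trees), grid,
                                      cv=inner, scoring="r2", n_jobs=1, refit=True)
                search.fit(X[train], y[train])
                model, best = search.best_estimator_, dict(search.best_params_)
                preds[test] = model.predict(X[test])
        fold_labels[test] = fold
        best_params.append(best)
        if learner == "random_forest":
            importances.append(model.feature_importances_)
        else:
            importances.append(np.abs(model.coef_))
    return preds, fold_labels, best_params, np.median(np.vstack(importances), axis=0)


def nested_cv_fit(
    features: pd.DataFrame,
    phenotype: np.ndarray,
    learner: str = "elastic_net",
    *,
    seed: int = 0,
    n_permutations: int = 0,
    n_outer: int = 10,
    n_inner: int = 4,
    n_trees: int = 500,
    grid: dict | None = None,
    permutation_grid: dict | None = None,
    zscore: bool = True,
) -> ModelPerformance:
    """Nested cross-validated phenotype prediction.

    Features are rows of ``features`` (plants are columns); profiles are
    z-scored globally before modeling.  10 outer folds; hyperparameters
    tuned on 4 inner folds by mean out-of-fold R^2; the best configuration
    is refit on the whole outer-training set.  With ``n_permutations > 0``
    the phenotype is permuted and the full procedure re-run (optionally with
    ``permutation_grid`` to cap cost), giving empirical p-values for the
    pooled R^2, median R^2 and Pearson correlation.
    """
    y = np.asarray(phenotype, dtype=float).ravel()
    if len(y) < 20:
        raise ValueError("need >= 20 samples for nested cross-validation")
    X = features.to_numpy(dtype=float).T  # samples x features
    if zscore:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    if grid is None:
        grid = ENET_GRID if learner == "elastic_net" else FOREST_GRID

    preds, fold_labels, best_params, importance = _run_nested_cv(
        X, y, learner, grid, seed, n_outer, n_inner, n_trees)
    pooled = oob_r2(preds, y, "pooled")
    median = oob_r2(preds, y, "median", folds=fold_labels)
    pcc = float(np.corrcoef(preds, y)[0, 1]) if np.std(preds) > 0 else 0.0

    perf = ModelPerformance(
        pooled_r2=pooled, median_r2=median, pcc=pcc,
        fold_predictions=pd.DataFrame({
            "sample": list(features.columns), "fold": fold_labels,
            "observed": y, "predicted": preds,
        }),
        best_params=best_params,
        feature_importances=pd.Series(importance, index=features.index),
    )

    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        pgrid = permutation_grid or grid
        perm_pooled, perm_median, perm_pcc = [], [], []
        for _ in range(n_permutations):
            yp = rng.permutation(y)
            pp, fl, _, _ = _run_nested_cv(X, yp, learner, pgrid, seed,
                                          n_outer, n_inner, n_trees)
            perm_pooled.append(oob_r2(pp, yp, "pooled"))
            perm_median.append(oob_r2(pp, yp, "median", folds=fl))
            perm_pcc.append(float(np.corrcoef(pp, yp)[0, 1]) if np.std(pp) > 0 else 0.0)
        perf.empirical_p = {
            "pooled_r2": permutation_pvalue(pooled, perm_pooled)[0],
            "median_r2": permutation_pvalue(median, perm_median)[0],
            "pcc": permutation_pvalue(pcc, perm_pcc)[0],
        }
        perf.n_permutations = n_permutations
    return perf
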