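"""Self-contained synthetic benchmarks used by the acceptance suite.

Every function generates its own data from a seed, runs the relevant part
of the pipeline, and measures the result — nothing is looked up.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .coexpr_network import build_network, spatially_adjusted_correlation
from .go_prediction import neighborhood_enrichment, propagate_annotations
from .phenotype_pred import nested_cv_fit, oob_r2
from .spatial_lme import SphericalCovariance, _layout_distances, fit_gls, fit_spatial_lme
from .spatial_stats import morans_i
from .synthetic_field import (
    SimulationConfig,
    make_field_layout,
    sample_spatial_gp,
    simulate_dataset,
)

__all__ = [
    "ols_equivalence",
    "spherical_parameter_recovery",
    "moran_brute_force_deviation",
    "moran_null_mean",
    "gba_recovery",
    "nested_cv_null_calibration",
    "nested_cv_planted_signal",
]


def ols_equivalence(seed: int = 0, n_pairs: int = 1000, n_plants_rows: int = 6,
                    n_plants_cols: int = 10) -> dict:
    """Max deviation of the spatially adjusted fits from closed-form OLS.

    Simulates i.i.d. gene pairs and i.i.d. responses with group effects;
    the spatial machinery must reproduce the closed-form estimates exactly
    when no spatial structure is present.
    """
    rng = np.random.default_rng(seed)
    layout = make_field_layout(SimulationConfig(n_rows=n_plants_rows,
                                                n_cols=n_plants_cols, seed=seed))
    dist = _layout_distances(layout)
    n = len(layout)
    max_beta = max_p = 0.0
    n_gls = 0
    for _ in range(n_pairs):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        pc = spatially_adjusted_correlation(x, y, dist=dist)
        if pc.fitted_by == "GLS":
            n_gls += 1
            continue
        xz = (x - x.mean()) / x.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        beta = float(xz @ yz) / float(xz @ xz)
        rss = float(((yz - beta * xz) ** 2).sum())
        se = np.sqrt(rss / (n - 1) / float(xz @ xz))
        p = 2 * stats.t.sf(abs(beta / se), n - 1)
        max_beta = max(max_beta, abs(pc.beta - beta))
        max_p = max(max_p, abs(pc.p_raw - p))

    # multi-effect LME route on i.i.d. responses
    X = np.column_stack([np.ones(n), layout["batch"], layout["doh"],
                         layout["snp_group"]]).astype(float)
    max_beta_lme = max_p_lme = 0.0
    n_fallback = 0
    for _ in range(100):
        y = rng.standard_normal(n) + 0.3 * X[:, 2]
        fit = fit_spatial_lme(y, layout)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 4)
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
        p = 2 * stats.t.sf(np.abs(beta / se), n - 4)
        if fit.fitted_by == "OLS-fallback":
            n_fallback += 1
            max_beta_lme = max(max_beta_lme, np.abs(fit.beta - beta).max())
            max_p_lme = max(max_p_lme, np.abs(fit.pvalues - p).max())
    return {
        "max_beta_deviation": max_beta,
        "max_p_deviation": max_p,
        "gls_fraction_null_pairs": n_gls / n_pairs,
        "max_beta_deviation_lme": max_beta_lme,
        "max_p_deviation_lme": max_p_lme,
        "ols_fallback_fraction_lme": n_fallback / 100,
    }


def spherical_parameter_recovery(seed: int = 0, n_replicates: int = 100,
                                 sigma: float = 1.0, nugget: float = 0.4,
                                 range_: float = 150.0) -> dict:
    """REML recovery of (sigma, nugget, range) on 560-plant GP draws."""
    layout = make_field_layout(SimulationConfig(seed=seed))  # 10 x 56
    truth = SphericalCovariance(sigma, nugget, range_)
    rng = np.random.default_rng(seed)
    X = np.ones((len(layout), 1))
    dist = _layout_distances(layout)
    nuggets, ranges, sigmas = [], [], []
    for _ in range(n_replicates):
        y = sample_spatial_gp(layout, truth, rng)
        fit = fit_gls(y, X, dist)
        nuggets.append(fit.cov.nugget)
        ranges.append(fit.cov.range_)
        sigmas.append(fit.cov.sigma)
    return {
        "median_nugget": float(np.median(nuggets)),
        "median_range": float(np.median(ranges)),
        "median_sigma": float(np.median(sigmas)),
        "nugget_error": float(abs(np.median(nuggets) - nugget)),
        "range_error": float(abs(np.median(ranges) - range_)),
    }


def moran_brute_force_deviation(seed: int = 0, n_instances: int = 20,
                                n_plants: int = 40) -> float:
    """Max |Moran's I - literal double sum| over random small instances."""
    rng = np.random.default_rng(seed)
    layout = make_field_layout(SimulationConfig(n_rows=5, n_cols=8, seed=seed))
    layout = layout.iloc[:n_plants].reset_index(drop=True)
    xy = layout[["x", "y"]].to_numpy()
    d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
    w = np.zeros_like(d)
    off = ~np.eye(n_plants, dtype=bool)
    w[off] = 1.0 / d[off]
    worst = 0.0
    for _ in range(n_instances):
        x = rng.standard_normal(n_plants)
        res = morans_i(x, layout)
        z = x - x.mean()
        num = sum(w[i, j] * z[i] * z[j] for i in range(n_plants) for j in range(n_plants))
        brute = (n_plants / w.sum()) * num / (z**2).sum()
        worst = max(worst, abs(res.I - brute))
    return worst


def moran_null_mean(seed: int = 0, n_draws: int = 5000, n_plants: int = 30) -> dict:
    """Mean of Moran's I over i.i.d. draws; should approach -1/(N-1)."""
    rng = np.random.default_rng(seed)
    layout = make_field_layout(SimulationConfig(n_rows=5, n_cols=6, seed=seed))
    from .spatial_stats import _inverse_distance_weights
    weights = _inverse_distance_weights(layout)
    vals = [morans_i(rng.standard_normal(n_plants), weights=weights).I
            for _ in range(n_draws)]
    return {"mean_I": float(np.mean(vals)), "expected": -1.0 / (n_plants - 1)}


def _gba_config(seed: int, n_modules: int = 4, module_size: int = 10,
                n_genes: int = 50, noise_sd: float = 0.05) -> SimulationConfig:
    return SimulationConfig(
        n_rows=6, n_cols=10, n_genes=n_genes, n_metabolites=2, n_traits=1,
        n_latent_factors=n_modules,
        kernel_params=[SphericalCovariance(1.0, 0.3, 120.0 + 60.0 * k)
                       for k in range(n_modules)],
        n_modules=n_modules, module_size=module_size, noise_sd=noise_sd,
        count_model="lognormal", withheld_fraction=0.2, effect_fraction=0.0,
        seed=seed,
    )


def gba_recovery(seed: int = 0, pearson_prefilter: float | None = None,
                 q_threshold: float = 0.01, **config_kwargs) -> dict:
    """Recall of withheld planted annotations, vs a degree-rewired network.

    Builds the co-expression network from low-noise module-structured
    expression, predicts functions by neighborhood enrichment using the kept
    annotations, and scores the withheld (gene, term) pairs.  The same
    prediction is repeated on a degree-preserving rewiring of the network.
    """
    config = _gba_config(seed, **config_kwargs)
    data = simulate_dataset(config)
    layout = data["layout"]
    log2 = np.log2(data["counts"])
    net = build_network(log2, layout, alpha=0.01,
                        pearson_prefilter=pearson_prefilter)
    ontology = nx.DiGraph(data["ontology_edges"])
    annset = propagate_annotations(data["annotations"], ontology)
    withheld = data["truth"].withheld_annotations

    def recall_on(graph):
        preds = neighborhood_enrichment(graph, annset)
        if not len(preds):
            return 0.0
        hit = set(map(tuple, preds[preds["q"] <= q_threshold][["gene", "term"]]
                      .itertuples(index=False)))
        return sum(1 for pair in withheld if pair in hit) / len(withheld)

    recall = recall_on(net)
    rewired = net.copy()
    if rewired.number_of_edges() > 2:
        nx.double_edge_swap(rewired, nswap=4 * rewired.number_of_edges(),
                            max_tries=10**6, seed=seed)
    recall_rewired = recall_on(rewired)
    return {"recall_withheld": recall, "recall_rewired": recall_rewired,
            "n_withheld": len(withheld), "n_edges": net.number_of_edges()}


_CALIBRATION_GRID = {"alpha": [0.01, 0.1, 1.0], "l1_ratio": [1.0]}


def nested_cv_null_calibration(seed: int = 0, n_repetitions: int = 50,
                               k_permutations: int = 99, n_samples: int = 40,
                               n_features: int = 6) -> dict:
    """Fraction of pure-noise phenotypes with permutation p > 0.05.

    Uses a reduced hyperparameter grid (identically for the true model and
    every permutation) to keep the procedure exchangeable and affordable.
    """
    rng = np.random.default_rng(seed)
    above = 0
    pvals = []
    for rep in range(n_repetitions):
        X = pd.DataFrame(rng.standard_normal((n_features, n_samples)),
                         index=[f"f{i}" for i in range(n_features)])
        y = rng.standard_normal(n_samples)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            perf = nested_cv_fit(X, y, "elastic_net", seed=seed + rep,
                                 n_permutations=k_permutations,
                                 grid=_CALIBRATION_GRID,
                                 permutation_grid=_CALIBRATION_GRID)
        p = perf.empirical_p["pooled_r2"]
        pvals.append(p)
        above += p > 0.05
    return {"fraction_p_above_0.05": above / n_repetitions, "pvalues": pvals}


def nested_cv_planted_signal(seed: int = 0, n_samples: int = 60,
                             n_features: int = 8) -> dict:
    """Pooled out-of-fold R^2 for a noiseless linear phenotype."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n_features, n_samples)),
                     index=[f"f{i}" for i in range(n_features)])
    beta = np.zeros(n_features)
    beta[:3] = [1.0, -1.0, 0.5]
    y = beta @ X.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        perf = nested_cv_fit(X, y, "elastic_net", seed=seed)
    return {"pooled_r2": perf.pooled_r2, "median_r2": perf.median_r2,
            "pcc": perf.pcc}
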