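"""Spatially adjusted co-expression networks.

Each gene pair is fitted as y = beta * x + eps on z-scored log2 profiles,
with spherical-covariance errors estimated by REML.  Degenerate covariance
optima reduce exactly to the Pearson correlation on the z-scored profiles.
Edges pass a Bonferroni-corrected p-value threshold, or networks are cut to
a fixed edge count for cross-network comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .spatial_lme import (
    DegenerateInputError,
    SphericalCovariance,
    _layout_distances,
    fit_gls,
)

__all__ = [
    "PairCorrelation",
    "spatially_adjusted_correlation",
    "build_network",
    "pair_table",
    "threshold_to_edge_count",
    "network_stats",
]


@dataclass(frozen=True)
class PairCorrelation:
    gene_a: str
    gene_b: str
    beta: float
    p_raw: float
    p_bonferroni: float
    cov: SphericalCovariance
    fitted_by: str  # "GLS" or "OLS-equivalent"


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant profile")
    return (x - x.mean()) / sd


def spatially_adjusted_correlation(
    x: np.ndarray,
    y: np.ndarray,
    layout: pd.DataFrame | None = None,
    *,
    dist: np.ndarray | None = None,
    gene_a: str = "x",
    gene_b: str = "y",
    spatial_lrt_cutoff: float | None = None,
) -> PairCorrelation:
    """Adjusted correlation of two profiles, controlling spatial structure.

    Profiles are z-scored and ``y = beta x + eps`` is fitted by REML with a
    spherical residual covariance; a degenerate optimum (nugget 1 / zero
    range) yields exactly the Pearson coefficient and its no-intercept Wald
    p-value, reported as ``fitted_by='OLS-equivalent'``.
    """
    if dist is None:
        if layout is None:
            raise ValueError("layout or dist required")
        dist = _layout_distances(layout)
    xz = _zscore(np.asarray(x, dtype=float).ravel())
    yz = _zscore(np.asarray(y, dtype=float).ravel())
    fit = fit_gls(yz, xz[:, None], dist, kernel="spherical", beta_names=["beta"],
                  spatial_lrt_cutoff=spatial_lrt_cutoff)
    fitted_by = "OLS-equivalent" if fit.fitted_by == "OLS-fallback" else "GLS"
    return PairCorrelation(gene_a, gene_b, float(fit.beta[0]), float(fit.pvalues[0]),
                           min(1.0, float(fit.pvalues[0])), fit.cov, fitted_by)


def pair_table(
    matrix: pd.DataFrame,
    layout: pd.DataFrame,
    *,
    pearson_prefilter: float | None = None,
    spatial_lrt_cutoff: float | None = None,
) -> pd.DataFrame:
    """Fit all C(G,2) gene pairs; returns a tidy table with Bonferroni p.

    ``pearson_prefilter`` (off by default) skips the spatial fit for pairs
    whose naive |Pearson r| is below the floor, recording the Pearson result
    for them instead.
    """
    genes = list(matrix.index)
    dist = _layout_distances(layout)
    values = matrix.to_numpy(dtype=float)
    sds = values.std(axis=1, ddof=1)
    z = (values - values.mean(axis=1, keepdims=True)) / np.where(sds == 0, np.nan, sds)[:, None]
    n_pairs = len(genes) * (len(genes) - 1) // 2
    records = []
    nonzero_range = 0
    for (i, a), (j, b) in combinations(enumerate(genes), 2):
        if not (np.isfinite(z[i]).all() and np.isfinite(z[j]).all()):
            continue
        if pearson_prefilter is not None:
            naive = float(z[i] @ z[j]) / (len(z[i]) - 1)
            if abs(naive) < pearson_prefilter:
                continue
        try:
            pc = spatially_adjusted_correlation(
                z[i], z[j], dist=dist, gene_a=a, gene_b=b,
                spatial_lrt_cutoff=spatial_lrt_cutoff)
        except DegenerateInputError:
            continue
        if pc.fitted_by == "GLS":
            nonzero_range += 1
        records.append({"gene_a": a, "gene_b": b, "beta": pc.beta,
                        "p_raw": pc.p_raw,
                        "nugget": pc.cov.nugget, "range": pc.cov.range_,
                        "fitted_by": pc.fitted_by})
    table = pd.DataFrame.from_records(records)
    if len(table):
        table["p_bonferroni"] = np.minimum(1.0, table["p_raw"] * n_pairs)
    table.attrs["n_pairs_tested"] = n_pairs
    table.attrs["nonzero_range_fraction"] = nonzero_range / max(1, len(records))
    return table


def build_network(
    matrix: pd.DataFrame,
    layout: pd.DataFrame,
    alpha: float = 0.01,
    annotations: dict[str, set[str]] | None = None,
    **kwargs,
) -> nx.Graph:
    """Network of pairs whose Bonferroni-corrected p-value is <= alpha."""
    if matrix.shape[1] < 3 or matrix.shape[0] < 2:
        raise ValueError("need >= 2 genes and >= 3 plants")
    table = pair_table(matrix, layout, **kwargs)
    graph = nx.Graph()
    graph.add_nodes_from(matrix.index)
    if len(table):
        sig = table[table["p_bonferroni"] <= alpha]
        for rec in sig.itertuples(index=False):
            graph.add_edge(rec.gene_a, rec.gene_b, beta=rec.beta,
                           p_raw=rec.p_raw, p_bonferroni=rec.p_bonferroni)
    graph.graph["n_pairs_tested"] = table.attrs.get("n_pairs_tested", 0)
    graph.graph["nonzero_range_fraction"] = table.attrs.get("nonzero_range_fraction", 0.0)
    graph.graph["stats"] = network_stats(graph, annotations)
    return graph


def threshold_to_edge_count(table: pd.DataFrame, k_edges: int,
                            nodes=None) -> nx.Graph:
    """Keep exactly the ``k_edges`` strongest pairs of a pair table.

    Ascending raw p, ties by descending |beta|, then lexicographic pair id —
    deterministic across runs.
    """
    if len(table) < k_edges:
        raise ValueError(f"only {len(table)} pairs available, {k_edges} requested")
    ranked = table.assign(_abs_beta=table["beta"].abs()).sort_values(
        ["p_raw", "_abs_beta", "gene_a", "gene_b"],
        ascending=[True, False, True, True], kind="stable",
    ).head(k_edges)
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    for rec in ranked.itertuples(index=False):
        graph.add_edge(rec.gene_a, rec.gene_b, beta=rec.beta, p_raw=rec.p_raw)
    return graph


def network_stats(graph: nx.Graph, annotations: dict[str, set[str]] | None = None,
                  include_clustering: bool = True) -> dict:
    """Density 2E/(N(N-1)), average clustering and unannotated fraction.

    ``include_clustering=False`` skips the O(sum deg^2) clustering pass for
    very large graphs where only the cheap statistics are needed.
    """
    n, e = graph.number_of_nodes(), graph.number_of_edges()
    if n == 0:
        warnings.warn("empty graph")
        return {"n_nodes": 0, "n_edges": 0, "density": 0.0,
                "avg_clustering_coefficient": 0.0, "unannotated_fraction": 0.0}
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    clustering = (float(np.mean(list(nx.clustering(graph).values())))
                  if include_clustering else float("nan"))
    unannotated = 0.0
    if annotations is not None:
        unannotated = sum(1 for g in graph.nodes if not annotations.get(g)) / n
    return {"n_nodes": n, "n_edges": e, "density": density,
            "avg_clustering_coefficient": clustering,
            "unannotated_fraction": unannotated}
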