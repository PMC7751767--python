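"""Spatial autocorrelation screening and cluster/phenotype association.

Moran's I with inverse-distance weights, BH adjustment, Ward clustering of
autocorrelated feature profiles, cluster-phenotype correlation and
distance-matrix correlations between data layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

from .spatial_lme import DegenerateInputError, _layout_distances

__all__ = [
    "MoranResult",
    "FeatureCluster",
    "morans_i",
    "moran_table",
    "bh_adjust",
    "cluster_autocorrelated_features",
    "cluster_phenotype_correlation",
    "layer_distance_correlation",
]


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    sd: float
    p: float
    q: float | None = None


@dataclass
class FeatureCluster:
    cluster_id: int
    member_features: list[str]
    mean_profile: np.ndarray


def _inverse_distance_weights(layout: pd.DataFrame) -> np.ndarray:
    d = _layout_distances(layout)
    n = d.shape[0]
    off = d[~np.eye(n, dtype=bool)]
    if np.any(off == 0):
        raise ValueError("coincident plant positions give infinite inverse-distance weights")
    w = np.zeros_like(d)
    mask = ~np.eye(n, dtype=bool)
    w[mask] = 1.0 / d[mask]
    return w


def morans_i(
    x: np.ndarray,
    layout: pd.DataFrame | None = None,
    *,
    weights: np.ndarray | None = None,
    row_standardize: bool = False,
    permutations: int = 0,
    rng: np.random.Generator | int | None = None,
) -> MoranResult:
    """Global Moran's I with inverse-distance weights.

    The p-value uses the normal approximation with the randomization
    variance (sample-kurtosis corrected), two-sided; ``permutations > 0``
    switches to a permutation p-value instead.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant profile has undefined Moran's I")
    if weights is None:
        if layout is None:
            raise ValueError("either layout or weights is required")
        weights = _inverse_distance_weights(layout)
    w = 0.5 * (weights + weights.T)  # symmetrize, as the reference implementation does
    if row_standardize:
        w = w / w.sum(axis=1, keepdims=True)
        w = 0.5 * (w + w.T)
    s0 = w.sum()
    z = x - x.mean()
    m2 = (z**2).sum()
    obs = (n / s0) * float(z @ w @ z) / m2
    ei = -1.0 / (n - 1)

    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=0) + w.sum(axis=1)) ** 2).sum()
    k = n * (z**4).sum() / m2**2  # sample kurtosis
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) \
        - k * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    den = (n - 1) * (n - 2) * (n - 3) * s0**2
    var = num / den - ei**2
    sd = float(np.sqrt(max(var, 0.0)))

    if permutations:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        exceed = 0
        for _ in range(permutations):
            zp = rng.permutation(z)
            ip = (n / s0) * float(zp @ w @ zp) / m2
            if abs(ip - ei) >= abs(obs - ei):
                exceed += 1
        p = (exceed + 1) / (permutations + 1)
    else:
        p = 2.0 * stats.norm.sf(abs(obs - ei) / sd) if sd > 0 else 1.0
    return MoranResult(float(obs), float(ei), sd, float(p))


def moran_table(matrix: pd.DataFrame, layout: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Moran's I per feature (row) with BH-adjusted q-values."""
    weights = _inverse_distance_weights(layout)
    records = []
    for feat, row in matrix.iterrows():
        try:
            res = morans_i(row.to_numpy(dtype=float), weights=weights, **kwargs)
            records.append({"feature": feat, "I": res.I, "expected_I": res.expected_I,
                            "sd": res.sd, "p": res.p})
        except DegenerateInputError:
            records.append({"feature": feat, "I": np.nan, "expected_I": np.nan,
                            "sd": np.nan, "p": np.nan})
    table = pd.DataFrame.from_records(records).set_index("feature")
    ok = table["p"].notna()
    table.loc[ok, "q"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    return table


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def _zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    return pd.DataFrame((values - mean) / sd, index=matrix.index, columns=matrix.columns)


def cluster_autocorrelated_features(
    matrix: pd.DataFrame,
    moran: pd.DataFrame,
    moran_q_threshold: float = 0.01,
    k: int | None = None,
    max_k: int = 20,
) -> list[FeatureCluster]:
    """Ward-cluster z-scored profiles of features passing the Moran screen.

    ``k=None`` picks the cut (2..max_k) maximizing the mean silhouette on
    the z-scored profiles.  Equivalent to R hclust ward.D2 on Euclidean
    distances.
    """
    passing = moran.index[moran["q"] <= moran_q_threshold]
    passing = [f for f in matrix.index if f in set(passing)]
    if len(passing) < 2:
        warnings.warn("fewer than 2 features pass the Moran q-threshold; no clusters")
        return []
    profiles = _zscore_rows(matrix.loc[passing])
    values = profiles.to_numpy()
    link = hierarchy.linkage(values, method="ward")
    if k is None:
        best_k, best_score = 2, -np.inf
        for kk in range(2, min(max_k, len(passing) - 1) + 1):
            labels = hierarchy.fcluster(link, kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(values, labels)
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    labels = hierarchy.fcluster(link, k, criterion="maxclust")
    clusters = []
    for cid in np.unique(labels):
        members = [f for f, l in zip(passing, labels) if l == cid]
        clusters.append(FeatureCluster(int(cid), members,
                                       profiles.loc[members].mean(axis=0).to_numpy()))
    return clusters


def cluster_phenotype_correlation(
    clusters: list[FeatureCluster],
    phenotypes: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r of each cluster mean profile against each phenotype row.

    q-values are BH-adjusted within each phenotype across clusters.
    """
    if phenotypes.shape[1] < 3:
        raise ValueError("need at least 3 shared plants")
    records = []
    for trait, prow in phenotypes.iterrows():
        y = prow.to_numpy(dtype=float)
        for cl in clusters:
            r, p = stats.pearsonr(cl.mean_profile, y)
            records.append({"phenotype": trait, "cluster_id": cl.cluster_id,
                            "r": float(r), "p": float(p)})
    table = pd.DataFrame.from_records(records)
    if len(table):
        table["q"] = np.nan
        for trait, group in table.groupby("phenotype"):
            table.loc[group.index, "q"] = bh_adjust(group["p"].to_numpy())
    return table


def layer_distance_correlation(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame | None = None,
    layout: pd.DataFrame | None = None,
    *,
    permutations: int = 0,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Correlate inter-plant distance matrices of two data layers.

    Feature profiles are z-scored before Euclidean distances between plants
    (columns).  The second layer is either another matrix or the field
    layout (physical distances).  Returns (Pearson r, p); with
    ``permutations > 0`` the p-value is a Mantel permutation p.
    """
    da_mat = _plant_distance_matrix(matrix_a)
    if matrix_b is not None:
        if list(matrix_b.columns) != list(matrix_a.columns):
            raise ValueError("plant sets of the two layers differ")
        db_mat = _plant_distance_matrix(matrix_b)
    elif layout is not None:
        lay = layout.set_index("plant_id").loc[list(matrix_a.columns)].reset_index()
        db_mat = _layout_distances(lay)
    else:
        raise ValueError("provide matrix_b or layout")
    n = da_mat.shape[0]
    if n < 4:
        raise ValueError("need at least 4 shared plants")
    iu = np.triu_indices(n, k=1)
    da, db = da_mat[iu], db_mat[iu]
    r, p = stats.pearsonr(da, db)
    if permutations:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        exceed = 0
        for _ in range(permutations):
            perm = rng.permutation(n)
            rp, _ = stats.pearsonr(da_mat[np.ix_(perm, perm)][iu], db)
            if abs(rp) >= abs(r):
                exceed += 1
        p = (exceed + 1) / (permutations + 1)
    return float(r), float(p)


def _plant_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    z = _zscore_rows(matrix).to_numpy()
    from scipy.spatial.distance import squareform
    return squareform(pdist(z.T, metric="euclidean"))
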