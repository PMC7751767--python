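"""Expression-variability scoring: CV, mean-variance trend and normCV.

The squared coefficient of variation of each feature is compared against a
fitted mean-CV^2 trend (gamma GLM with identity link for transcripts,
log-log OLS for metabolites); normCV = log2(CV^2 / trend(mean)).  A rank
test flags ontology terms enriched toward the variable or stable end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .spatial_stats import bh_adjust

__all__ = [
    "TrendFit",
    "coefficient_of_variation",
    "fit_cv_trend",
    "norm_cv_table",
    "rank_based_go_test",
]


@dataclass
class TrendFit:
    a: float
    b: float
    model: Literal["gamma-identity", "loglog-linear"]
    excluded_fraction: float = 0.05

    def predict(self, mean):
        mean = np.asarray(mean, dtype=float)
        if self.model == "gamma-identity":
            out = self.a / mean + self.b
        else:
            out = 10.0 ** (self.a * np.log10(mean) + self.b)
        return out


def coefficient_of_variation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature mean, sample-sd CV and CV^2 on a linear-scale matrix.

    Features with non-positive mean are flagged ``excluded`` and get NaN CV.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame({
        "mean": mean, "cv": cv, "cv2": cv**2,
        "excluded": mean <= 0,
    }, index=matrix.index)


def fit_cv_trend(
    means: np.ndarray,
    cv2: np.ndarray,
    model: Literal["gamma-identity", "loglog-linear"] = "gamma-identity",
    excluded_fraction: float = 0.05,
) -> TrendFit:
    """Fit the CV^2-vs-mean trend after dropping the lowest-mean fraction.

    gamma-identity: CV^2 = a/mean + b by a gamma GLM with identity link
    (nonlinear least squares fallback on failure).  loglog-linear: OLS of
    log10(CV^2) on log10(mean).
    """
    means = np.asarray(means, dtype=float)
    cv2 = np.asarray(cv2, dtype=float)
    ok = np.isfinite(means) & np.isfinite(cv2) & (means > 0) & (cv2 > 0)
    means, cv2 = means[ok], cv2[ok]
    if excluded_fraction > 0:
        cutoff = np.quantile(means, excluded_fraction)
        keep = means > cutoff
        if keep.sum() >= 10:
            means, cv2 = means[keep], cv2[keep]
    if means.size < 10:
        raise ValueError(f"only {means.size} features available for the trend fit")
    if model == "gamma-identity":
        X = np.column_stack([1.0 / means, np.ones_like(means)])
        try:
            glm = sm.GLM(cv2, X, family=sm.families.Gamma(sm.families.links.Identity()))
            res = glm.fit()
            a, b = float(res.params[0]), float(res.params[1])
            if not np.all(a / means + b > 0):
                raise ValueError("non-positive fitted trend")
        except Exception:
            (a, b), _ = optimize.curve_fit(lambda x, a, b: a / x + b, means, cv2,
                                           p0=[1.0, float(np.median(cv2))], maxfev=10000)
        return TrendFit(a, b, "gamma-identity", excluded_fraction)
    if model == "loglog-linear":
        slope, intercept = np.polyfit(np.log10(means), np.log10(cv2), 1)
        return TrendFit(float(slope), float(intercept), "loglog-linear", excluded_fraction)
    raise ValueError(f"unknown trend model {model!r}")


def norm_cv_table(
    matrix: pd.DataFrame,
    model: Literal["gamma-identity", "loglog-linear"] = "gamma-identity",
    excluded_fraction: float = 0.05,
    flag_fraction: float = 0.10,
) -> tuple[pd.DataFrame, TrendFit]:
    """normCV = log2(CV^2 / trend(mean)) per feature, plus variability flags.

    The lowest-mean ``excluded_fraction`` of features is removed before both
    the trend fit and the scoring.  Exactly floor(flag_fraction * n_scored)
    features are flagged at each end of the decreasing-normCV ranking, ties
    broken by feature id.
    """
    cv = coefficient_of_variation(matrix)
    scored = cv[~cv["excluded"] & np.isfinite(cv["cv2"]) & (cv["cv2"] > 0)].copy()
    if excluded_fraction > 0:
        cutoff = np.quantile(scored["mean"], excluded_fraction)
        scored = scored[scored["mean"] > cutoff]
    trend = fit_cv_trend(scored["mean"].to_numpy(), scored["cv2"].to_numpy(),
                         model=model, excluded_fraction=0.0)
    scored["trend"] = trend.predict(scored["mean"].to_numpy())
    scored["norm_cv"] = np.log2(scored["cv2"] / scored["trend"])
    order = scored.loc[sorted(scored.index,
                              key=lambda f: (-scored.at[f, "norm_cv"], str(f)))]
    n_flag = int(np.floor(flag_fraction * len(order)))
    scored["highly_variable"] = False
    scored["lowly_variable"] = False
    if n_flag:
        scored.loc[order.index[:n_flag], "highly_variable"] = True
        scored.loc[order.index[-n_flag:], "lowly_variable"] = True
    return scored, trend


def rank_based_go_test(
    ranked_features: list[str],
    annotations: dict[str, set[str]] | pd.DataFrame,
    min_size: int = 5,
) -> pd.DataFrame:
    """Mann-Whitney U of each term's member ranks vs the rest.

    ``ranked_features`` is ordered from the variable end to the stable end.
    Returns per-term U, two-sided p, BH q, and a direction label indicating
    which end of the ranking members concentrate at.
    """
    if isinstance(annotations, pd.DataFrame):
        term_genes: dict[str, set[str]] = {}
        for gene, term in annotations.itertuples(index=False):
            term_genes.setdefault(term, set()).add(gene)
    else:
        term_genes = {}
        for gene, terms in annotations.items():
            for term in terms:
                term_genes.setdefault(term, set()).add(gene)
    rank_of = {f: i + 1 for i, f in enumerate(ranked_features)}
    records = []
    for term, genes in sorted(term_genes.items()):
        members = [rank_of[g] for g in genes if g in rank_of]
        if len(members) < min_size:
            continue
        others = [r for f, r in rank_of.items() if f not in genes]
        if not others:
            continue
        res = stats.mannwhitneyu(members, others, alternative="two-sided")
        direction = "variable-end" if np.median(members) < np.median(others) else "stable-end"
        records.append({"term": term, "n_members": len(members),
                        "U": float(res.statistic), "p": float(res.pvalue),
                        "direction": direction})
    table = pd.DataFrame.from_records(records)
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table = table.set_index("term")
    return table
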