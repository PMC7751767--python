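"""Count and intensity matrix preprocessing.

Transcripts: CPM filtering, median-of-ratios size factors, pseudocount +
log2.  Metabolites: log2, iterative Grubbs outlier masking, missing-value
row filtering, low-rank imputation and quantile normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalizedMatrix",
    "cpm_filter",
    "median_of_ratios_size_factors",
    "log_transform_with_pseudocount",
    "back_transform",
    "grubbs_outlier_mask",
    "impute_missing",
    "quantile_normalize",
    "preprocess_counts",
    "preprocess_metabolites",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class NormalizedMatrix:
    """A log2 feature x plant matrix plus what was done to produce it."""

    values: pd.DataFrame
    pseudocount_delta: float
    size_factors: pd.Series | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.provenance:
            raise ValueError("provenance must list at least one applied step")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        if self.values.isna().any().any():
            raise ValueError("normalized matrix must be complete")


def cpm_filter(counts: pd.DataFrame, threshold: float = 5.0, min_samples: int = 1):
    """Keep genes reaching ``threshold`` counts-per-million in >= ``min_samples``.

    Library sizes are computed on the input (pre-filter) matrix.  Returns
    (filtered counts, summary dict).
    """
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    cpm = counts.div(lib, axis=1) * 1e6
    keep = (cpm >= threshold).sum(axis=1) >= min_samples
    out = counts.loc[keep]
    return out, {"kept": int(keep.sum()), "removed": int((~keep).sum())}


def median_of_ratios_size_factors(counts: pd.DataFrame, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean pseudo-reference.

    Only genes with nonzero counts in every sample enter the reference.  If
    none exist, either raise (default) or fall back to genes positive in at
    least half the samples with the geometric mean over positive entries.
    """
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no gene has nonzero counts in all samples; "
                "set allow_pseudo_reference=True to use a partial reference"
            )
        mostly = (values > 0).sum(axis=1) >= values.shape[1] / 2
        if not mostly.any():
            raise ValueError("no usable reference genes")
        sub = values[mostly]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub, where=sub > 0), np.nan)
        geomean = np.exp(np.nanmean(logs, axis=1))
        ratios = sub / geomean[:, None]
        sf = np.nanmedian(np.where(sub > 0, ratios, np.nan), axis=0)
    else:
        sub = values[all_positive]
        geomean = np.exp(np.mean(np.log(sub), axis=1))
        sf = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def log_transform_with_pseudocount(normalized: pd.DataFrame) -> NormalizedMatrix:
    """Add half the smallest nonzero value of the whole matrix, then log2."""
    values = normalized.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("matrix must be non-negative")
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero matrix: no nonzero value to define the pseudocount")
    delta = float(nonzero.min())
    out = pd.DataFrame(np.log2(values + 0.5 * delta), index=normalized.index,
                       columns=normalized.columns)
    return NormalizedMatrix(out, pseudocount_delta=delta,
                            provenance=["log2(x + 0.5*delta)"])


def back_transform(matrix: NormalizedMatrix | pd.DataFrame, delta: float | None = None) -> pd.DataFrame:
    """Invert the log2 + pseudocount transform: 2^x - 0.5*delta.

    Restores an exact zero minimum for matrices whose smallest raw value was
    zero; used before coefficient-of-variation scoring.
    """
    if isinstance(matrix, NormalizedMatrix):
        delta = matrix.pseudocount_delta
        values = matrix.values
    else:
        if delta is None:
            raise ValueError("delta required for a bare DataFrame")
        values = matrix
    return np.exp2(values) - 0.5 * delta


def _grubbs_critical(n: int, alpha: float) -> float:
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_outlier_mask(matrix: pd.DataFrame, alpha: float = 0.01,
                        max_missing_fraction: float = 0.5):
    """Iterative two-sided Grubbs masking per row, then drop gappy rows.

    The most extreme value of a row is removed while the Grubbs statistic
    G = max|x - mean| / sd exceeds its alpha-level critical value; masked
    entries become NaN.  Rows left with more than ``max_missing_fraction``
    missing are dropped.  Rows with < 3 observed values are skipped with a
    warning.  Returns (masked matrix, info dict).
    """
    out = matrix.astype(float).copy()
    n_cols = out.shape[1]
    masked_cells: list[tuple] = []
    for idx, row in out.iterrows():
        x = row.to_numpy(dtype=float)
        obs = np.isfinite(x)
        if obs.sum() < 3:
            warnings.warn(f"row {idx!r} has < 3 observed values; Grubbs skipped")
            continue
        removals_left = int(obs.sum()) - 3
        while removals_left >= 0:
            vals = x[obs]
            n = len(vals)
            if n < 3:
                break
            sd = vals.std(ddof=1)
            if sd == 0:
                break
            dev = np.abs(vals - vals.mean())
            g = dev.max() / sd
            if g <= _grubbs_critical(n, alpha):
                break
            pos = np.flatnonzero(obs)[int(np.argmax(dev))]
            x[pos] = np.nan
            obs[pos] = False
            masked_cells.append((idx, out.columns[pos]))
            removals_left -= 1
        out.loc[idx] = x
    missing_frac = out.isna().mean(axis=1)
    dropped = list(out.index[missing_frac > max_missing_fraction])
    out = out.drop(index=dropped)
    return out, {"masked_cells": masked_cells, "dropped_rows": dropped}


def impute_missing(matrix: pd.DataFrame, rank: int | None = None,
                   tol: float = 1e-6, max_iter: int = 2000) -> pd.DataFrame:
    """Iterative truncated-SVD imputation; observed entries are untouched.

    Missing cells are initialized at row means, then repeatedly replaced by
    their rank-``rank`` SVD reconstruction until the relative change in the
    imputed values falls below ``tol``.
    """
    values = matrix.to_numpy(dtype=float)
    mask = np.isnan(values)
    if not mask.any():
        return matrix.copy()
    if mask.all(axis=1).any():
        raise ValueError("row with no observed values")
    if mask.all(axis=0).any():
        raise ValueError("column with no observed values")
    if rank is None:
        # near-full-rank hard imputation converges too slowly to be useful
        rank = min(matrix.shape[1] - 2, max(1, matrix.shape[0] // 2), 48)
    rank = max(1, min(rank, min(matrix.shape) - 1))
    row_means = np.nanmean(values, axis=1)
    filled = np.where(mask, row_means[:, None], values)
    for iteration in range(max_iter):
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        new = np.where(mask, recon, values)
        num = np.linalg.norm(new[mask] - filled[mask])
        den = np.linalg.norm(filled[mask]) + 1e-12
        filled = new
        if num / den < tol:
            break
    else:
        raise ConvergenceError(
            f"imputation did not converge in {max_iter} iterations "
            f"(last relative change {num / den:.3g}, rank {rank})"
        )
    return pd.DataFrame(filled, index=matrix.index, columns=matrix.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean quantile distribution.

    Ties within a column receive the mean of the quantile values at their
    (average) ranks, via linear interpolation on the mean sorted vector.
    """
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile normalization requires a complete matrix")
    ref = np.mean(np.sort(values, axis=0), axis=1)
    n = values.shape[0]
    out = np.empty_like(values)
    positions = np.arange(1, n + 1)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def preprocess_counts(counts: pd.DataFrame, cpm_threshold: float = 5.0) -> NormalizedMatrix:
    """CPM filter -> size-factor normalization -> pseudocount + log2."""
    filtered, summary = cpm_filter(counts, threshold=cpm_threshold)
    sf = median_of_ratios_size_factors(filtered, allow_pseudo_reference=True)
    normalized = filtered.div(sf, axis=1)
    result = log_transform_with_pseudocount(normalized)
    result.size_factors = sf
    result.provenance = [
        f"cpm_filter(threshold={cpm_threshold}): kept {summary['kept']}, removed {summary['removed']}",
        "median_of_ratios_size_factors",
        result.provenance[0],
    ]
    return result


def preprocess_metabolites(intensities: pd.DataFrame, grubbs_alpha: float = 0.01,
                           rank: int | None = None) -> NormalizedMatrix:
    """log2 -> Grubbs masking -> row filter -> imputation -> quantile normalization."""
    values = intensities.to_numpy(dtype=float)
    nonzero = values[np.isfinite(values) & (values > 0)]
    if nonzero.size == 0:
        raise ValueError("no positive intensities")
    delta = float(nonzero.min())
    # plain log2 when strictly positive; pseudocount only to rescue zeros
    shift = 0.5 * delta if np.any(values[np.isfinite(values)] <= 0) else 0.0
    logged = np.log2(values + shift)
    logged_df = pd.DataFrame(logged, index=intensities.index, columns=intensities.columns)
    masked, info = grubbs_outlier_mask(logged_df, alpha=grubbs_alpha)
    imputed = impute_missing(masked, rank=rank)
    qn = quantile_normalize(imputed)
    return NormalizedMatrix(
        qn, pseudocount_delta=delta,
        provenance=[
            "log2(x + 0.5*delta)",
            f"grubbs_outlier_mask(alpha={grubbs_alpha}): masked {len(info['masked_cells'])} cells, "
            f"dropped {len(info['dropped_rows'])} rows",
            "impute_missing (iterative SVD)",
            "quantile_normalize",
        ],
    )
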