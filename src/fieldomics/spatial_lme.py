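"""Per-feature fixed-effects models with spatially correlated residuals.

Fits, by restricted maximum likelihood (REML), models of the form

    y = X beta + eps,    eps ~ MVN(0, sigma^2 * [n I + (1 - n) C(r)])

where ``C(r)`` is a distance-based correlation matrix (spherical or rational
quadratic kernel), ``n`` is a nugget fraction in [0, 1] and ``r`` a range in
the units of the field coordinates.  Degenerate optima (``n -> 1`` or
``r -> 0``) reduce exactly to ordinary least squares and are reported as such.

The module also decomposes per-feature variance into fixed-effect, spatially
correlated and i.i.d. shares, and residualizes whole matrices by removing the
fitted fixed-effect contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SphericalCovariance",
    "LMEFit",
    "VarianceDecomposition",
    "spherical_correlation",
    "ratio_correlation",
    "fit_spatial_lme",
    "fit_gls",
    "variance_decomposition",
    "residualize_matrix",
    "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """Raised when a response or design is degenerate (constant, aliased...)."""


# ---------------------------------------------------------------------------
# correlation kernels
# ---------------------------------------------------------------------------

def spherical_correlation(d, r: float):
    """Spherical correlation: 1 - 1.5(d/r) + 0.5(d/r)^3 for d < r, else 0.

    Decreases from 1 at ``d = 0`` to exactly 0 at ``d >= r``.  The pure-nugget
    convention applies at ``r = 0``: correlation is 1 at zero distance and 0
    elsewhere.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if r < 0:
        raise ValueError("range must be non-negative")
    if r == 0:
        out = np.where(d == 0, 1.0, 0.0)
    else:
        u = np.minimum(d / r, 1.0)
        out = 1.0 - 1.5 * u + 0.5 * u**3
    if out.ndim == 0:
        return float(out)
    return out


def ratio_correlation(d, r: float):
    """Rational quadratic correlation: 1 / (1 + (d/r)^2); strictly positive."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if r <= 0:
        raise ValueError("range must be strictly positive for the ratio kernel")
    out = 1.0 / (1.0 + (d / r) ** 2)
    if out.ndim == 0:
        return float(out)
    return out


_KERNELS: dict[str, Callable] = {
    "spherical": spherical_correlation,
    "ratio": ratio_correlation,
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphericalCovariance:
    """Residual covariance parameters: overall magnitude, nugget and range.

    ``sigma`` is on the scale of the response; ``nugget`` is the i.i.d.
    fraction of residual variance; ``range_`` is in coordinate units (cm).
    ``nugget == 1`` or ``range_ == 0`` is the pure i.i.d. model.
    """

    sigma: float
    nugget: float
    range_: float
    kernel: str = "spherical"

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.nugget <= 1.0:
            raise ValueError("nugget must be in [0, 1]")
        if self.range_ < 0:
            raise ValueError("range must be >= 0")
        if self.kernel not in _KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @property
    def is_iid(self) -> bool:
        return self.nugget >= 1.0 or self.range_ == 0.0

    def correlation_matrix(self, dist: np.ndarray) -> np.ndarray:
        """Full residual correlation matrix n*I + (1-n)*C(r)."""
        corr = _KERNELS[self.kernel](dist, self.range_)
        V = self.nugget * np.eye(dist.shape[0]) + (1.0 - self.nugget) * corr
        return V

    def covariance_matrix(self, dist: np.ndarray) -> np.ndarray:
        return self.sigma**2 * self.correlation_matrix(dist)


@dataclass
class LMEFit:
    """Result of one REML (or OLS-fallback) fit."""

    beta: np.ndarray
    beta_names: list[str]
    se: np.ndarray
    pvalues: np.ndarray
    cov: SphericalCovariance
    fitted_by: str  # "REML" or "OLS-fallback"
    loglik: float  # restricted log-likelihood at the optimum
    df_resid: int
    loglik_iid: float = np.nan

    def coef(self, name: str) -> float:
        return float(self.beta[self.beta_names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.beta_names.index(name)])


@dataclass(frozen=True)
class VarianceDecomposition:
    """Per-feature R^2 shares for fixed effects, spatial and i.i.d. residuals.

    Identities (exact): r2_fix + r2_resid == 1 and r2_cov + r2_iid == r2_resid.
    The per-effect shares sum to r2_fix only approximately because the effect
    encodings are not exactly orthogonal in a finite sample.
    """

    r2_batch: float
    r2_doh: float
    r2_snp: float
    r2_fix: float
    r2_resid: float
    r2_cov: float
    r2_iid: float


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _layout_distances(layout: pd.DataFrame) -> np.ndarray:
    xy = layout[["x", "y"]].to_numpy(dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


class _ProfiledREML:
    """Restricted likelihood of (n, r), with beta and sigma^2 profiled out.

    For a fixed range the correlation matrix is eigendecomposed once, after
    which any nugget value is evaluated in O(N p) — the nugget only shifts
    the eigenvalues:  V = n I + (1-n) C  =>  eig(V) = n + (1-n) eig(C).
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, dist: np.ndarray, kernel: str):
        self.y = y
        self.X = X
        self.dist = dist
        self.kernel = _KERNELS[kernel]
        self.N, self.p = X.shape
        self._eig_cache: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def _eig(self, r: float):
        key = round(float(r), 9)
        if key not in self._eig_cache:
            C = self.kernel(self.dist, r)
            lam, Q = np.linalg.eigh(C)
            lam = np.maximum(lam, 0.0)  # clip roundoff negatives; kernels are PSD
            self._eig_cache[key] = (lam, Q.T @ self.y, Q.T @ self.X)
            if len(self._eig_cache) > 64:
                self._eig_cache.pop(next(iter(self._eig_cache)))
        return self._eig_cache[key]

    def evaluate(self, nugget: float, r: float):
        """Return (rll, beta, sigma2, XtViX_inv) at (nugget, r)."""
        lam, Qty, QtX = self._eig(r)
        w = nugget + (1.0 - nugget) * lam
        if np.any(w <= 1e-12):
            return -1e300, None, None, None
        wi = 1.0 / w
        XtViX = QtX.T @ (wi[:, None] * QtX)
        XtViy = QtX.T @ (wi * Qty)
        try:
            XtViX_inv = np.linalg.inv(XtViX)
        except np.linalg.LinAlgError:
            return -1e300, None, None, None
        beta = XtViX_inv @ XtViy
        resid = Qty - QtX @ beta
        rss = float(resid @ (wi * resid))
        dof = self.N - self.p
        if rss <= 0:
            return -1e300, None, None, None
        sigma2 = rss / dof
        logdetV = float(np.sum(np.log(w)))
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -1e300, None, None, None
        rll = -0.5 * (
            dof * (np.log(2.0 * np.pi) + 1.0 + np.log(sigma2))
            + logdetV
            + logdetXtViX
        )
        return rll, beta, sigma2, XtViX_inv

    def rll(self, nugget: float, r: float) -> float:
        return self.evaluate(nugget, r)[0]

    def best_nugget(self, r: float, lo: float = 1e-4, hi: float = 1.0 - 1e-4):
        res = optimize.minimize_scalar(
            lambda n: -self.rll(n, r), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-5},
        )
        return float(res.x), -float(res.fun)


def fit_gls(
    y: np.ndarray,
    X: np.ndarray,
    dist: np.ndarray,
    *,
    kernel: str = "spherical",
    beta_names: Sequence[str] | None = None,
    n_range_grid: int = 12,
    spatial_lrt_cutoff: float | None = None,
) -> LMEFit:
    """REML fit of ``y = X beta + eps`` with kernel-structured errors.

    The (nugget, range) restricted likelihood is profiled on a coarse range
    grid (from the minimum plant spacing to twice the field diagonal), the
    nugget is optimized per range point, and the best point is refined
    locally.  If the optimum is degenerate (nugget ~ 1, range below half the
    minimum spacing) or the spatial model does not improve the restricted
    likelihood beyond ``spatial_lrt_cutoff`` over the i.i.d. submodel, the
    exact OLS solution is returned with ``fitted_by='OLS-fallback'``.

    ``spatial_lrt_cutoff`` defaults to ``2 log(N)`` (a BIC-type penalty for
    the two covariance parameters); pass 0 to accept any improvement.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    N, p = X.shape
    if y.size != N or dist.shape != (N, N):
        raise ValueError("y, X and dist have inconsistent shapes")
    if N <= p:
        raise ValueError("more parameters than observations")
    if np.ptp(y) == 0:
        raise DegenerateInputError("response is constant")
    if np.linalg.matrix_rank(X) < p:
        raise DegenerateInputError("rank-deficient fixed-effect design (aliased effects)")
    if beta_names is None:
        beta_names = [f"b{i}" for i in range(p)]
    beta_names = list(beta_names)
    if spatial_lrt_cutoff is None:
        spatial_lrt_cutoff = 2.0 * np.log(N)

    engine = _ProfiledREML(y, X, dist, kernel)

    off = dist[np.triu_indices(N, k=1)]
    d_min = float(off.min())
    d_max = float(off.max())
    if d_min <= 0:
        raise ValueError("coincident plant positions (zero pairwise distance)")

    # i.i.d. submodel == OLS; evaluated at nugget 1 where the kernel is moot
    rll_iid, beta_ols, sigma2_ols, XtX_inv = engine.evaluate(1.0, d_min)
    if beta_ols is None:
        # perfect fit: residual variance is exactly zero
        beta_exact, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        if np.allclose(X @ beta_exact, y):
            cov = SphericalCovariance(0.0, 1.0, 0.0, kernel)
            return LMEFit(beta_exact, beta_names, np.zeros(p),
                          np.where(beta_exact != 0, 0.0, 1.0), cov,
                          "OLS-fallback", np.inf, N - p, loglik_iid=np.inf)
        raise DegenerateInputError("degenerate response/design combination")

    r_grid = np.geomspace(d_min, 2.0 * d_max, n_range_grid)
    best = (rll_iid, 1.0, 0.0)  # (rll, nugget, range)
    for r in r_grid:
        n_hat, rll = engine.best_nugget(r)
        if rll > best[0]:
            best = (rll, n_hat, float(r))

    if best[2] > 0:
        # local refinement of the range around the best grid point
        lo = best[2] / (r_grid[1] / r_grid[0])
        hi = best[2] * (r_grid[1] / r_grid[0])

        def neg_profile(r):
            return -engine.best_nugget(float(r))[1]

        res = optimize.minimize_scalar(
            neg_profile, bounds=(lo, hi), method="bounded", options={"xatol": d_min / 10}
        )
        r_ref = float(res.x)
        n_ref, rll_ref = engine.best_nugget(r_ref)
        if rll_ref > best[0]:
            best = (rll_ref, n_ref, r_ref)

    rll_best, n_best, r_best = best
    degenerate = (
        n_best > 0.999
        or r_best < 0.5 * d_min
        or not np.isfinite(rll_best)
        or 2.0 * (rll_best - rll_iid) <= spatial_lrt_cutoff
    )

    dof = N - p
    if degenerate:
        se = np.sqrt(sigma2_ols * np.diag(XtX_inv))
        tvals = beta_ols / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        cov = SphericalCovariance(float(np.sqrt(sigma2_ols)), 1.0, 0.0, kernel)
        return LMEFit(beta_ols, beta_names, se, pvals, cov, "OLS-fallback",
                      float(rll_iid), dof, loglik_iid=float(rll_iid))

    rll, beta, sigma2, XtViX_inv = engine.evaluate(n_best, r_best)
    se = np.sqrt(sigma2 * np.diag(XtViX_inv))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    cov = SphericalCovariance(float(np.sqrt(sigma2)), float(n_best), float(r_best), kernel)
    return LMEFit(beta, beta_names, se, pvals, cov, "REML", float(rll), dof,
                  loglik_iid=float(rll_iid))


# ---------------------------------------------------------------------------
# public per-feature interface
# ---------------------------------------------------------------------------

_EFFECT_COLUMNS = {"batch": "batch", "doh": "doh", "snp": "snp_group"}


def _design(layout: pd.DataFrame, effects: Iterable[str]):
    effects = list(effects)
    for e in effects:
        if e not in _EFFECT_COLUMNS:
            raise ValueError(f"unknown effect {e!r}; choose from {sorted(_EFFECT_COLUMNS)}")
    cols = [np.ones(len(layout))]
    names = ["intercept"]
    for e in effects:
        cols.append(layout[_EFFECT_COLUMNS[e]].to_numpy(dtype=float))
        names.append(e)
    return np.column_stack(cols), names


def fit_spatial_lme(
    y: np.ndarray,
    layout: pd.DataFrame,
    effects: Sequence[str] = ("batch", "doh", "snp"),
    *,
    kernel: str = "spherical",
    spatial_lrt_cutoff: float | None = None,
) -> LMEFit:
    """Fit intercept + group fixed effects with spatially correlated errors.

    ``effects`` selects any subset of {batch, doh, snp}; the design encodes
    each as a 0/1 covariate taken from the layout table.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise DegenerateInputError("response is constant")
    X, names = _design(layout, effects)
    for j, name in enumerate(names[1:], start=1):
        vals, counts = np.unique(X[:, j], return_counts=True)
        if len(vals) > 1 and counts.min() < 2:
            raise DegenerateInputError(f"effect {name!r} has a level with < 2 plants")
    dist = _layout_distances(layout)
    return fit_gls(y, X, dist, kernel=kernel, beta_names=names,
                   spatial_lrt_cutoff=spatial_lrt_cutoff)


def variance_decomposition(fit: LMEFit, layout: pd.DataFrame) -> VarianceDecomposition:
    """Split response variance into fixed-effect, spatial and i.i.d. shares.

    var(f) is the sample variance of the fitted fixed-effect contribution
    (intercept excluded) and var(eps) = sigma^2, the marginal residual
    variance (the correlation part of the covariance has unit diagonal).
    """
    sigma2 = fit.cov.sigma**2
    contribs = {}
    total_contrib = np.zeros(len(layout))
    for name in fit.beta_names:
        if name == "intercept":
            continue
        x = layout[_EFFECT_COLUMNS[name]].to_numpy(dtype=float)
        c = fit.coef(name) * x
        contribs[name] = c
        total_contrib = total_contrib + c
    var_f = float(np.var(total_contrib, ddof=1)) if contribs else 0.0
    denom = var_f + sigma2
    r2_fix = var_f / denom
    r2_resid = sigma2 / denom
    per = {name: float(np.var(c, ddof=1)) / denom for name, c in contribs.items()}
    nugget = fit.cov.nugget if not fit.cov.is_iid else 1.0
    return VarianceDecomposition(
        r2_batch=per.get("batch", 0.0),
        r2_doh=per.get("doh", 0.0),
        r2_snp=per.get("snp", 0.0),
        r2_fix=r2_fix,
        r2_resid=r2_resid,
        r2_cov=(1.0 - nugget) * r2_resid,
        r2_iid=nugget * r2_resid,
    )


def residualize_matrix(
    matrix: pd.DataFrame,
    layout: pd.DataFrame,
    effects: Sequence[str] = ("batch", "doh", "snp"),
    *,
    kernel: str = "spherical",
    spatial_lrt_cutoff: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove fitted group effects from every feature (row) of a matrix.

    The intercept is retained; only the batch/DOH/SNP contributions are
    subtracted.  Returns the residual matrix and a per-feature table of
    covariance parameters and variance shares.  Per-feature failures are
    collected as warnings, not fatal; failed features pass through unchanged
    with NaN statistics.
    """
    if list(matrix.columns) != list(layout["plant_id"]):
        layout = layout.set_index("plant_id").loc[list(matrix.columns)].reset_index()
    resid = matrix.copy()
    records = []
    for feat, row in matrix.iterrows():
        y = row.to_numpy(dtype=float)
        try:
            fit = fit_spatial_lme(y, layout, effects, kernel=kernel,
                                  spatial_lrt_cutoff=spatial_lrt_cutoff)
        except DegenerateInputError as exc:
            warnings.warn(f"feature {feat!r} skipped: {exc}")
            records.append({"feature": feat, "error": str(exc)})
            continue
        removed = np.zeros(len(y))
        for name in fit.beta_names:
            if name == "intercept":
                continue
            removed += fit.coef(name) * layout[_EFFECT_COLUMNS[name]].to_numpy(dtype=float)
        resid.loc[feat] = y - removed
        vd = variance_decomposition(fit, layout)
        records.append({
            "feature": feat,
            "sigma": fit.cov.sigma, "nugget": fit.cov.nugget, "range": fit.cov.range_,
            "fitted_by": fit.fitted_by,
            "r2_batch": vd.r2_batch, "r2_doh": vd.r2_doh, "r2_snp": vd.r2_snp,
            "r2_fix": vd.r2_fix, "r2_resid": vd.r2_resid,
            "r2_cov": vd.r2_cov, "r2_iid": vd.r2_iid,
        })
    stats_df = pd.DataFrame.from_records(records).set_index("feature")
    return resid, stats_df
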