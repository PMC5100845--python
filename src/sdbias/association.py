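"""Expression and growth-rate association analyses.

Gene-level: ordinary least squares of (log) expression on the aSD binding
score S and the codon-usage covariate Nc', with adjusted R² and AIC/BIC
model comparison, plus Spearman rank correlation.

Species-level: phylogenetic generalized least squares (PGLS) under Pagel's
λ.  The residual covariance is V(λ): the Brownian-motion covariance of the
tree (entries = shared root-to-MRCA branch length) with off-diagonal
elements multiplied by λ ∈ [0, 1]; λ is estimated by maximizing the profile
Gaussian likelihood.  λ = 0 collapses to independent tips (OLS on an
ultrametric tree); λ = 1 is pure Brownian covariance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "ModelComparison",
    "PGLSResult",
    "fit_ols",
    "compare_models",
    "spearman_correlation",
    "pgls_fit",
    "brownian_covariance",
]

logger = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    model_spec: str
    coefficients: dict[str, tuple[float, float, float]]  # name → (est, se, p)
    r2: float
    r2_adj: float
    aic: float
    bic: float
    n_obs: int
    obs_index: tuple = field(default=(), repr=False)


@dataclass
class ModelComparison:
    delta_r2_adj: float
    delta_aic: float
    delta_bic: float
    extended_preferred_aic: bool
    extended_preferred_bic: bool


@dataclass
class PGLSResult:
    lambda_hat: float
    coefficients: dict[str, tuple[float, float, float]]
    r2_adj: float
    p_slope: float
    log_likelihood: float
    n_obs: int
    at_boundary: bool = False


def _as_frame(predictors) -> pd.DataFrame:
    if isinstance(predictors, pd.DataFrame):
        return predictors
    if isinstance(predictors, pd.Series):
        return predictors.to_frame()
    raise TypeError("predictors must be a pandas Series or DataFrame")


def fit_ols(response: pd.Series, predictors) -> RegressionResult:
    """OLS of ``response`` on one or more ``predictors`` (intercept added).

    Rows with any missing value are dropped (complete-case, logged).  AIC and
    BIC come from the Gaussian log-likelihood with k counting the intercept,
    slopes and the error variance.
    """
    X = _as_frame(predictors)
    data = pd.concat([response.rename("__y__"), X], axis=1, join="inner")
    n_before = len(data)
    data = data.dropna()
    if len(data) < n_before:
        logger.info("fit_ols: dropped %d incomplete observation(s)",
                    n_before - len(data))
    if len(data) < X.shape[1] + 2:
        raise ValueError(
            f"need ≥ {X.shape[1] + 2} complete observations, have {len(data)}"
        )
    y = data["__y__"].to_numpy(dtype=float)
    Xd = sm.add_constant(data.drop(columns="__y__").astype(float))
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {Xd.shape[1]}); "
            f"columns: {list(Xd.columns)}"
        )
    fit = sm.OLS(y, Xd).fit()
    coefficients = {
        name: (float(fit.params[name]), float(fit.bse[name]), float(fit.pvalues[name]))
        for name in Xd.columns
    }
    spec = f"{response.name or 'y'} ~ " + " + ".join(X.columns)
    return RegressionResult(
        model_spec=spec,
        coefficients=coefficients,
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        aic=float(fit.aic),
        bic=float(fit.bic),
        n_obs=int(fit.nobs),
        obs_index=tuple(data.index),
    )


def compare_models(base: RegressionResult, extended: RegressionResult) -> ModelComparison:
    """ΔRadj², ΔAIC, ΔBIC of ``extended`` relative to ``base``.

    Both fits must cover the identical observation set; otherwise the
    information criteria are not comparable and an error is raised.
    """
    if base.obs_index != extended.obs_index:
        raise ValueError(
            "models were fit on different observation sets; refusing to compare"
        )
    d_aic = extended.aic - base.aic
    d_bic = extended.bic - base.bic
    return ModelComparison(
        delta_r2_adj=extended.r2_adj - base.r2_adj,
        delta_aic=d_aic,
        delta_bic=d_bic,
        extended_preferred_aic=d_aic < 0,
        extended_preferred_bic=d_bic < 0,
    )


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties) with its p-value."""
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# PGLS


def brownian_covariance(
    tree: dendropy.Tree, taxa: list[str]
) -> np.ndarray:
    """Brownian-motion covariance matrix: depth of the MRCA of each tip pair.

    ``taxa`` fixes row/column order.  Unmatched labels raise a ValueError
    listing them; branch lengths must be non-negative with positive
    root-to-tip depths.
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in leaves]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    depth = {t: leaves[t].root_distance for t in taxa}
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t: leaves[t].taxon for t in taxa}
    n = len(taxa)
    C = np.empty((n, n))
    for i, a in enumerate(taxa):
        C[i, i] = depth[a]
        for j in range(i + 1, n):
            b = taxa[j]
            mrca_depth = (depth[a] + depth[b] - pdm.patristic_distance(tx[a], tx[b])) / 2.0
            C[i, j] = C[j, i] = mrca_depth
    return C


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _gls(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS estimates and ML log-likelihood under covariance σ²·V."""
    n = len(y)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance matrix") from exc
    yw = scipy.linalg.solve_triangular(L, y, lower=True)
    Xw = scipy.linalg.solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * (math.log(2 * math.pi * sigma2_ml) + 1) + logdet)
    return beta, rss, loglik, Xw, yw


def pgls_fit(
    tree: dendropy.Tree | str | Path,
    response: pd.Series,
    predictors,
    lambda_value: float | None = None,
    tol: float = 1e-4,
) -> PGLSResult:
    """PGLS regression with Pagel's λ estimated by maximum likelihood.

    Parameters
    ----------
    tree
        A dendropy Tree, or a path to a Newick file.  Tip labels must match
        the index of ``response``/``predictors`` exactly.
    response, predictors
        Per-species values indexed by species id.
    lambda_value
        Fix λ instead of estimating it (e.g. 0 for OLS, 1 for Brownian).

    The profile likelihood over λ ∈ [0, 1] is maximized by bounded scalar
    search (tolerance ``tol``) compared against both boundaries; boundary
    optima are reported as exactly 0 or 1 with ``at_boundary=True``.
    """
    if isinstance(tree, (str, Path)):
        tree = dendropy.Tree.get(path=str(tree), schema="newick")
    X = _as_frame(predictors)
    data = pd.concat([response.rename("__y__"), X], axis=1, join="inner").dropna()
    taxa = list(data.index)
    if len(taxa) < X.shape[1] + 1:
        raise ValueError("too few species for PGLS")
    C = brownian_covariance(tree, taxa)
    y = data["__y__"].to_numpy(dtype=float)
    Xd = sm.add_constant(data.drop(columns="__y__").astype(float))
    names = list(Xd.columns)
    Xm = Xd.to_numpy(dtype=float)

    def negloglik(lam: float) -> float:
        try:
            return -_gls(y, Xm, _lambda_cov(C, lam))[2]
        except ValueError:
            return np.inf

    at_boundary = False
    if lambda_value is not None:
        lam_hat = float(lambda_value)
    else:
        res = scipy.optimize.minimize_scalar(
            negloglik, bounds=(0.0, 1.0), method="bounded",
            options={"xatol": tol},
        )
        candidates = [(negloglik(0.0), 0.0), (negloglik(1.0), 1.0),
                      (res.fun, float(res.x))]
        nll, lam_hat = min(candidates, key=lambda c: c[0])
        if lam_hat in (0.0, 1.0):
            at_boundary = True
        elif lam_hat < tol:
            lam_hat, at_boundary = 0.0, True
        elif lam_hat > 1 - tol:
            lam_hat, at_boundary = 1.0, True

    V = _lambda_cov(C, lam_hat)
    beta, rss, loglik, Xw, yw = _gls(y, Xm, V)
    n, p = Xm.shape
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    if n > p:  # a saturated fit (n == p) has no residual dof: SEs undefined
        sigma2 = rss / (n - p)
        se = np.sqrt(np.diag(XtX_inv) * sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / se
        pvals = 2 * scipy.stats.t.sf(np.abs(tvals), df=n - p)
    else:
        se = np.full(p, np.nan)
        pvals = np.full(p, np.nan)
    # GLS R²: against the intercept-only GLS fit under the same V
    beta0, rss0, _, _, _ = _gls(y, np.ones((n, 1)), V)
    r2 = 1.0 - rss / rss0 if rss0 > 0 else float("nan")
    r2_adj = (
        1.0 - (1.0 - r2) * (n - 1) / (n - p) if n > p else float("nan")
    )
    coefficients = {
        name: (float(b), float(s), float(pv))
        for name, b, s, pv in zip(names, beta, se, pvals)
    }
    slope_names = [nm for nm in names if nm != "const"]
    p_slope = coefficients[slope_names[0]][2] if slope_names else float("nan")
    return PGLSResult(
        lambda_hat=float(lam_hat),
        coefficients=coefficients,
        r2_adj=float(r2_adj),
        p_slope=float(p_slope),
        log_likelihood=float(loglik),
        n_obs=n,
        at_boundary=at_boundary,
    )
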