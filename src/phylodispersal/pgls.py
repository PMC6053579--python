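"""Phylogenetic generalized least squares with ML estimation of Pagel's lambda.

The model is y = X beta + eps with eps ~ N(0, sigma^2 V_lambda), where
V_lambda is the phylogenetic VCV with off-diagonal entries scaled by lambda.
lambda is profiled out of the Gaussian likelihood (beta and sigma^2 have
closed-form ML solutions given lambda) and maximized on [0, 1] by a coarse
grid followed by bounded scalar refinement, with the endpoints always checked
explicitly — the profile can be bimodal on small trees.

Standard errors use the residual variance rescaled by n/(n-k), giving the
conventional PGLS t-tests with df = n - k (k = number of coefficients,
intercept included); at lambda = 0 the fit reduces exactly to OLS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

from .phylo import PhyloVCV, cholesky_psd, lambda_transform

__all__ = ["PGLSFit", "pgls_fit", "profile_lambda"]


@dataclass
class PGLSFit:
    """Result of a single-tree PGLS fit."""

    coef_names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    lambda_ml: float
    sigma2: float
    log_likelihood: float
    n: int
    adj_r2: float
    species_used: tuple[str, ...]
    warnings: tuple[str, ...] = ()

    @property
    def df_resid(self) -> int:
        return self.n - len(self.coefficients)

    def summary_row(self, predictor_index: int = 1) -> dict:
        """One-line summary for the coefficient of interest (default: slope)."""
        i = predictor_index
        return {
            "predictor": self.coef_names[i],
            "b": float(self.coefficients[i]),
            "se": float(self.standard_errors[i]),
            "t": float(self.t_values[i]),
            "p": float(self.p_values[i]),
            "lambda": float(self.lambda_ml),
            "n": self.n,
            "adj_r2": float(self.adj_r2),
        }


def _gls_profile(y: np.ndarray, X: np.ndarray, Vlam: np.ndarray):
    """Closed-form GLS given a fixed covariance; returns ML pieces.

    Returns (beta, sigma2_ml, loglik, XtViX_inv, resid, L) where L is the
    Cholesky factor of Vlam.
    """
    n = len(y)
    try:
        L = cholesky_psd(Vlam)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "phylogenetic covariance matrix is not positive definite "
            f"(condition: {np.linalg.cond(Vlam):.3g})"
        ) from exc
    z = linalg.solve_triangular(L, y, lower=True)
    W = linalg.solve_triangular(L, X, lower=True)
    gram = W.T @ W
    try:
        gram_inv = linalg.inv(gram)
    except linalg.LinAlgError as exc:
        raise ValueError("singular design matrix in PGLS") from exc
    beta = gram_inv @ (W.T @ z)
    resid_w = z - W @ beta
    rss = float(resid_w @ resid_w)
    sigma2_ml = rss / n
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    if sigma2_ml <= 0 or not np.isfinite(sigma2_ml):
        loglik = np.inf if sigma2_ml == 0 else -np.inf
    else:
        loglik = -0.5 * (
            n * np.log(2 * np.pi) + n * np.log(sigma2_ml) + logdet + n
        )
    return beta, sigma2_ml, loglik, gram_inv, resid_w, L


def profile_lambda(
    y: np.ndarray, X: np.ndarray, vcv: PhyloVCV, grid_size: int = 21
) -> tuple[float, float]:
    """Maximize the profile log-likelihood of Pagel's lambda on [0, 1].

    A coarse grid locates the basin (the profile can have local optima on
    small trees); bounded Brent refinement then polishes the optimum.  The
    returned log-likelihood is never below either endpoint's by more than
    the optimizer tolerance.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    V = vcv.matrix

    def negll(lam: float) -> float:
        Vlam = lam * V + (1.0 - lam) * np.diag(np.diag(V))
        ll = _gls_profile(y, X, Vlam)[2]
        return -ll

    grid = np.linspace(0.0, 1.0, grid_size)
    vals = np.array([negll(g) for g in grid])
    if not np.all(np.isfinite(vals)):
        if np.isneginf(vals).any():  # zero residual variance: ll = +inf
            lam = float(grid[np.argmin(vals)])
            return lam, float("inf")
        raise ValueError(
            "non-finite likelihood across the lambda grid; check the VCV "
            "conditioning and response scale"
        )
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            negll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        cand = [(float(res.x), float(res.fun))]
    else:
        cand = []
    cand += [(float(grid[best]), float(vals[best])),
             (0.0, float(vals[0])), (1.0, float(vals[-1]))]
    lam, nll = min(cand, key=lambda t: t[1])
    return lam, -nll


def pgls_fit(
    y,
    X,
    vcv: PhyloVCV,
    lam: float | str = "ml",
    coef_names=None,
) -> PGLSFit:
    """Fit y = X beta + eps, eps ~ N(0, sigma^2 V_lambda), on one tree.

    Parameters
    ----------
    y, X
        Response vector and design matrix (include the intercept column),
        rows aligned to ``vcv.labels``.
    vcv
        Phylogenetic covariance from :meth:`PhyloTree.vcv`.
    lam
        ``"ml"`` (default) profiles lambda by maximum likelihood on [0, 1];
        a float fixes it.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if len(y) != n or vcv.n != n:
        raise ValueError("y, X and VCV dimensions do not agree")
    if n < k + 2:
        raise ValueError(
            f"too few species (n={n}) for {k} coefficients; need n >= k + 2"
        )
    if coef_names is None:
        coef_names = ["intercept"] + [f"x{i}" for i in range(1, k)]

    warns: list[str] = []
    if np.ptp(y) == 0:
        warns.append("constant response: lambda is unidentifiable")

    if lam == "ml":
        lam_hat, ll = profile_lambda(y, X, vcv)
        if not np.isfinite(ll):
            warns.append("zero residual variance: lambda is unidentifiable")
            lam_hat = 0.0
    else:
        lam_hat = float(lam)
        if not 0.0 <= lam_hat <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {lam_hat}")

    Vlam = lambda_transform(vcv, lam_hat).matrix
    beta, sigma2_ml, ll, gram_inv, resid_w, L = _gls_profile(y, X, Vlam)

    df = n - k
    sigma2_unbiased = sigma2_ml * n / df
    se = np.sqrt(np.clip(np.diag(gram_inv), 0, None) * sigma2_unbiased)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)

    # adjusted R^2 from GLS-transformed residual and total sums of squares
    ones = np.ones((n, 1))
    mu = _gls_profile(y, ones, Vlam)[0][0]
    z = linalg.solve_triangular(L, y - mu, lower=True)
    tss = float(z @ z)
    rss = float(resid_w @ resid_w)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df

    return PGLSFit(
        coef_names=tuple(coef_names),
        coefficients=beta,
        standard_errors=se,
        t_values=np.asarray(t, dtype=float),
        p_values=np.asarray(p, dtype=float),
        lambda_ml=lam_hat,
        sigma2=float(sigma2_unbiased),
        log_likelihood=float(ll),
        n=n,
        adj_r2=float(adj_r2),
        species_used=tuple(vcv.labels),
        warnings=tuple(warns),
    )
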