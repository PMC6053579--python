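"""Simulation studies validating the estimators under known generative truth.

Each function runs a self-contained study — generate data with known
parameters on synthetic trees, apply the package's estimator, summarize
recovery or error rates — and returns a plain dict of the quantities it
measured.  They back both the validation test suite and the reproduction
script, at whatever problem sizes the caller requests.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .dstat import d_test
from .paired import phylo_paired_t
from .pgls import pgls_fit
from .phylo import PhyloVCV
from .simulate import (
    SimulationConfig,
    _unit_depth_vcv,
    simulate_binary_trait,
    simulate_bm,
    simulate_yule_tree,
)

__all__ = [
    "d_calibration",
    "pgls_ols_agreement",
    "lambda_recovery",
    "slope_recovery",
    "pgls_type_i_error",
    "paired_null_calibration",
]


def _tree_pool(n_trees: int, n_tips: int, seed: int) -> list:
    ss = np.random.SeedSequence([seed, n_tips])
    return [
        simulate_yule_tree(n_tips, 1.0, int(s % (2**31)))
        for s in ss.generate_state(n_trees)
    ]


def d_calibration(
    n_trees: int = 100,
    n_tips: int = 50,
    prevalence: float = 0.5,
    n_perm: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
) -> dict:
    """Mean scaled D under each null regime, one trait per tree.

    Traits generated by tip randomization should average D = 1; traits from
    the Brownian threshold model should average D = 0.
    """
    rng = np.random.default_rng(seed)
    trees = _tree_pool(n_trees, n_tips, seed)
    out = {}
    for regime in ("random", "brownian"):
        ds = []
        for tree in trees:
            trait = simulate_binary_trait(tree, regime, prevalence, rng)
            res = d_test(tree, trait, n_perm=n_perm, n_sim=n_sim, seed=rng)
            ds.append(res.d_scaled)
        out[f"mean_d_{regime}"] = float(np.mean(ds))
        out[f"sd_d_{regime}"] = float(np.std(ds, ddof=1))
    out["n_trees"] = n_trees
    return out


def _ols_closed_form(y: np.ndarray, X: np.ndarray):
    """Normal-equations OLS with classical SEs; the lambda = 0 oracle."""
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - k)
    se = np.sqrt(s2 * np.diag(XtX_inv))
    return beta, se


def pgls_ols_agreement(n_instances: int = 50, seed: int = 0) -> dict:
    """Max |PGLS(lambda=0) - OLS| over random instances, for b and SE.

    With lambda fixed at 0 the phylogenetic covariance is diagonal; on an
    ultrametric tree that diagonal is constant, so the GLS solution must
    coincide with ordinary least squares exactly.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(10, 60))
        tree = simulate_yule_tree(n, 1.0, int(rng.integers(2**31)))
        V = tree.vcv()
        x = rng.standard_normal(n)
        y = rng.standard_normal(n) + rng.normal() * x
        X = np.column_stack([np.ones(n), x])
        fit = pgls_fit(y, X, V, lam=0.0)
        beta, se = _ols_closed_form(y, X)
        worst = max(
            worst,
            float(np.max(np.abs(fit.coefficients - beta))),
            float(np.max(np.abs(fit.standard_errors - se))),
        )
    return {"max_abs_diff": worst, "n_instances": n_instances}


def lambda_recovery(
    lambda_true: float,
    n_tips: int = 200,
    n_reps: int = 200,
    n_trees: int = 10,
    sigma2: float = 0.5,
    beta1: float = 1.5,
    seed: int = 0,
) -> dict:
    """Median ML lambda over replicates generated at a known lambda."""
    rng = np.random.default_rng([seed, int(lambda_true * 1000)])
    trees = _tree_pool(n_trees, n_tips, seed)
    vcvs = [_unit_depth_vcv(t) for t in trees]
    lams = []
    for r in range(n_reps):
        V = vcvs[r % n_trees]
        x = simulate_bm(V, rng)
        eps = simulate_bm(V, rng, sigma2=sigma2, lam=lambda_true)
        y = 2.0 + beta1 * x + eps
        X = np.column_stack([np.ones(V.n), x])
        fit = pgls_fit(y, X, V, lam="ml")
        lams.append(fit.lambda_ml)
    return {
        "lambda_true": lambda_true,
        "median_lambda_ml": float(np.median(lams)),
        "n_reps": n_reps,
    }


def slope_recovery(
    beta1: float = 1.5,
    n_tips: int = 100,
    n_reps: int = 500,
    sigma2: float = 0.5,
    seed: int = 0,
) -> dict:
    """Mean estimated slope (and its Monte-Carlo SE) under known truth."""
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(n_tips, 1.0, seed + 1)
    V = _unit_depth_vcv(tree)
    slopes = []
    for _ in range(n_reps):
        x = simulate_bm(V, rng)
        eps = simulate_bm(V, rng, sigma2=sigma2, lam=1.0)
        y = 2.0 + beta1 * x + eps
        X = np.column_stack([np.ones(V.n), x])
        slopes.append(pgls_fit(y, X, V, lam="ml").coefficients[1])
    slopes = np.asarray(slopes)
    return {
        "beta1_true": beta1,
        "mean_b1": float(slopes.mean()),
        "mc_se": float(slopes.std(ddof=1) / np.sqrt(n_reps)),
        "bias_pct": float(100.0 * (slopes.mean() - beta1) / beta1),
        "n_reps": n_reps,
    }


def pgls_type_i_error(
    n_tips: int = 50,
    n_reps: int = 1000,
    alpha: float = 0.05,
    sigma2: float = 0.5,
    n_trees: int = 10,
    seed: int = 0,
) -> dict:
    """Empirical size of the PGLS slope test under beta1 = 0, Brownian errors."""
    rng = np.random.default_rng(seed)
    trees = _tree_pool(n_trees, n_tips, seed + 7)
    vcvs = [_unit_depth_vcv(t) for t in trees]
    rejections = 0
    for r in range(n_reps):
        V = vcvs[r % n_trees]
        x = simulate_bm(V, rng)
        y = 2.0 + simulate_bm(V, rng, sigma2=sigma2, lam=1.0)
        X = np.column_stack([np.ones(V.n), x])
        fit = pgls_fit(y, X, V, lam="ml")
        rejections += fit.p_values[1] < alpha
    return {"alpha": alpha, "rejection_rate": rejections / n_reps,
            "n_reps": n_reps}


def paired_null_calibration(
    n_tips: int = 50,
    n_reps: int = 1000,
    alpha: float = 0.05,
    sigma2: float = 0.16,
    n_trees: int = 10,
    mean_diff: float = 0.0,
    seed: int = 0,
) -> dict:
    """Rejection rate of the phylogenetic paired t-test at a given true mean.

    With ``mean_diff = 0`` this is the empirical type-I error; with a nonzero
    mean it is power.  Differences carry Brownian covariance; the test sees
    paired distance vectors whose log10 difference is the simulated one.
    """
    rng = np.random.default_rng(seed)
    trees = _tree_pool(n_trees, n_tips, seed + 13)
    vcvs = [_unit_depth_vcv(t) for t in trees]
    rejections = 0
    for r in range(n_reps):
        V = vcvs[r % n_trees]
        d = mean_diff + simulate_bm(V, rng, sigma2=sigma2, lam=1.0)
        female = 10 ** (0.5 + simulate_bm(V, rng, sigma2=0.3))
        male = female * 10**d
        res = phylo_paired_t(male, female, V)
        rejections += res.p_value < alpha
    return {"alpha": alpha, "rejection_rate": rejections / n_reps,
            "mean_diff": mean_diff, "n_reps": n_reps}
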