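"""Phylogenetic paired t-test for within-species sex differences.

The question: across species, is the phylogenetic mean of the within-species
difference d_i = log10(male distance) - log10(female distance) distinct from
zero?  The differences are modeled as d = a 1 + eps with eps ~ N(0, sigma^2
V_lambda); lambda and sigma^2 are estimated jointly by maximum likelihood, and
the phylogenetically weighted (GLS) mean a-hat is tested against zero with a t
reference distribution on n - 1 degrees of freedom.  On a star phylogeny the
test reduces exactly to the classical paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .pgls import _gls_profile, profile_lambda
from .phylo import PhyloVCV, lambda_transform

__all__ = ["PairedTestResult", "phylo_paired_t"]


@dataclass
class PairedTestResult:
    phylo_mean_diff: float
    se_mean: float
    t_value: float
    df: int
    p_value: float
    lambda_ml: float
    n: int
    species_used: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    def summary_row(self) -> dict:
        return {
            "mean_diff": self.phylo_mean_diff,
            "se": self.se_mean,
            "t": self.t_value,
            "df": self.df,
            "p": self.p_value,
            "lambda": self.lambda_ml,
            "n": self.n,
        }


def phylo_paired_t(
    x_male, x_female, vcv: PhyloVCV, log10_transform: bool = True
) -> PairedTestResult:
    """Phylogenetic paired t-test of male vs female values.

    Parameters
    ----------
    x_male, x_female
        Per-species paired values aligned to ``vcv.labels`` — dispersal
        distances in km by default, logged (base 10) internally.  Pass
        ``log10_transform=False`` to test differences of already-transformed
        values.
    vcv
        Phylogenetic covariance for exactly the paired species.

    Notes
    -----
    The standard error of the phylogenetic mean uses the ML residual variance
    rescaled by n/(n-1), so that with a star phylogeny the statistic equals
    the ordinary one-sample t on the differences.
    """
    x_male = np.asarray(x_male, dtype=float).ravel()
    x_female = np.asarray(x_female, dtype=float).ravel()
    n = vcv.n
    if len(x_male) != n or len(x_female) != n:
        raise ValueError("input vectors must align with the VCV labels")
    if n < 3:
        raise ValueError(f"need at least 3 paired species, got {n}")
    bad = np.isnan(x_male) | np.isnan(x_female)
    if bad.any():
        missing = [vcv.labels[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"unpaired species (missing one sex): {missing}")
    if log10_transform:
        if (x_male <= 0).any() or (x_female <= 0).any():
            raise ValueError("distances must be positive for log10 transform")
        d = np.log10(x_male) - np.log10(x_female)
    else:
        d = x_male - x_female

    ones = np.ones((n, 1))
    warns: list[str] = []
    if np.ptp(d) == 0:
        # all differences identical: no within-variance to estimate
        a = float(d[0])
        lam_hat = 0.0
        warns.append("constant differences: lambda is unidentifiable")
        if a == 0.0:
            return PairedTestResult(0.0, 0.0, 0.0, n - 1, 1.0, lam_hat, n,
                                    tuple(vcv.labels), tuple(warns))
        return PairedTestResult(a, 0.0, float(np.sign(a) * np.inf), n - 1,
                                0.0, lam_hat, n, tuple(vcv.labels),
                                tuple(warns))

    lam_hat, ll = profile_lambda(d, ones, vcv)
    Vlam = lambda_transform(vcv, lam_hat).matrix
    beta, sigma2_ml, ll, gram_inv, _, _ = _gls_profile(d, ones, Vlam)
    a = float(beta[0])
    se = float(np.sqrt(sigma2_ml * (n / (n - 1)) * gram_inv[0, 0]))
    t = a / se
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return PairedTestResult(
        phylo_mean_diff=a,
        se_mean=se,
        t_value=float(t),
        df=n - 1,
        p_value=p,
        lambda_ml=float(lam_hat),
        n=n,
        species_used=tuple(vcv.labels),
        warnings=tuple(warns),
    )
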