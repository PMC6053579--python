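"""Multi-tree ensembles: run an analysis over a tree set and combine results.

Phylogenies are uncertain, so each model is refit on every tree of an
ensemble (e.g. 100 trees drawn from a posterior) and the per-tree estimates
are combined.  The reported standard error is the square root of the *total*
variance

    total_se^2 = V1^2 + V2^2,
    V1^2 = (1/N) * sum_i SE_i^2      (average parameter variance)
    V2^2 = SD(b_1..b_N)^2            (between-tree, "phylogenetic" variance)

where SD is by default the sample (n-1) standard deviation of the slopes
across trees — between-tree dispersion that does not shrink as more trees are
added.  p-values are reported as their mean with the standard error of that
mean across trees; no meta-analytic combination is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .phylo import PhyloTree

__all__ = ["EnsembleFit", "combine", "run_ensemble"]


@dataclass
class EnsembleFit:
    mean_b: float
    total_se: float
    mean_p: float
    se_p: float
    v1_sq: float
    v2_sq: float
    n_trees: int
    n_species: int
    per_tree_fits: list = field(default_factory=list, repr=False)
    failures: list = field(default_factory=list)

    def summary_row(self) -> dict:
        return {
            "b": self.mean_b,
            "se": self.total_se,
            "p": self.mean_p,
            "se_p": self.se_p,
            "n": self.n_species,
            "n_trees": self.n_trees,
        }


def combine(
    slopes: Sequence[float],
    ses: Sequence[float],
    p_values: Sequence[float],
    n_species: int = 0,
    between_tree: str = "sd",
) -> EnsembleFit:
    """Combine per-tree estimates with the total-variance rule.

    ``between_tree`` selects the convention for V2: ``"sd"`` (default) uses
    the sample standard deviation of the slopes; ``"sem"`` uses the standard
    error of their mean (SD/sqrt(N)), under which tree uncertainty vanishes
    as the ensemble grows.
    """
    b = np.asarray(slopes, dtype=float)
    se = np.asarray(ses, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if not (len(b) == len(se) == len(p)) or len(b) == 0:
        raise ValueError("slopes, SEs and p-values must be equal-length, nonempty")
    if between_tree not in ("sd", "sem"):
        raise ValueError(f"unknown between-tree convention: {between_tree}")
    N = len(b)
    v1_sq = float(np.mean(se**2))
    if N == 1:
        sd_b = 0.0
        se_p = 0.0
    else:
        # identical per-tree values must give exactly zero dispersion
        sd_b = float(np.std(b, ddof=1)) if np.ptp(b) > 0 else 0.0
        se_p = (float(np.std(p, ddof=1) / np.sqrt(N))
                if np.ptp(p) > 0 else 0.0)
    if between_tree == "sem":
        sd_b = sd_b / np.sqrt(N)
    v2_sq = sd_b**2
    return EnsembleFit(
        mean_b=float(np.mean(b)),
        total_se=float(np.sqrt(v1_sq + v2_sq)),
        mean_p=float(np.mean(p)),
        se_p=se_p,
        v1_sq=v1_sq,
        v2_sq=v2_sq,
        n_trees=N,
        n_species=n_species,
    )


def run_ensemble(
    analysis: Callable[[PhyloTree], tuple[float, float, float, object]],
    trees: Sequence[PhyloTree],
    n_species: int = 0,
    between_tree: str = "sd",
) -> EnsembleFit:
    """Apply ``analysis`` to every tree and combine the estimates.

    ``analysis(tree)`` must return ``(b, se, p, fit_object)`` for one tree,
    fit on identical data.  Trees on which the analysis raises are recorded
    in ``failures`` and excluded; if every tree fails the first error is
    re-raised.
    """
    if len(trees) == 0:
        raise ValueError("need at least one tree")
    slopes, ses, ps, fits, failures = [], [], [], [], []
    first_exc: Exception | None = None
    for i, tree in enumerate(trees):
        try:
            b, se, p, fit = analysis(tree)
        except Exception as exc:  # record, exclude, continue
            failures.append((i, f"{type(exc).__name__}: {exc}"))
            if first_exc is None:
                first_exc = exc
            continue
        slopes.append(b)
        ses.append(se)
        ps.append(p)
        fits.append(fit)
    if not slopes:
        raise RuntimeError(
            f"analysis failed on all {len(trees)} trees"
        ) from first_exc
    out = combine(slopes, ses, ps, n_species=n_species,
                  between_tree=between_tree)
    out.per_tree_fits = fits
    out.failures = failures
    return out
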