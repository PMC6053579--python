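"""Synthetic trees and trait tables with the structure the analyses assume.

The generator emulates a comparative dataset of sex-biased dispersal in
birds: an ensemble of ultrametric (pure-birth) phylogenies and a species x
population trait table whose continuous characters evolve with Brownian
covariance (optionally damped by a true Pagel's lambda), whose discrete
scores arise by thresholding latent Brownian values into the legal
categories, and whose missingness is completely at random — so that every
analysis stage, from per-population averaging to multi-tree ensembles, can be
exercised end to end without any external data.

Defaults mirror the shape of the real study system: 86 species, ensembles of
100 trees, female-biased dispersal (negative mean log10 male/female distance
ratio), roughly 30% missingness per variable group producing different
pairwise-complete sample sizes per analysis, one to three populations per
species, and a minority of species from hunted populations.
"""

from __future__ import annotations

import random as _random
from dataclasses import asdict, dataclass, replace

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath
from scipy.special import expit

from .phylo import PhyloTree, PhyloVCV, cholesky_psd, lambda_transform

__all__ = [
    "SimulationConfig",
    "simulate_trees",
    "simulate_bm",
    "simulate_regression_traits",
    "simulate_binary_trait",
    "simulate_species_table",
    "write_trees",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; the defaults define the study conditions.

    Attributes
    ----------
    n_species, n_trees
        Tips per tree and trees per ensemble.
    birth_rate
        Yule (pure-birth) speciation rate, per unit time.
    lambda_true
        Pagel's lambda of the residual covariance of continuous traits.
    sigma2
        Residual variance of the regression response, on the unit-depth tree
        scale.
    beta0, beta1
        Intercept and slope of the generative regression.
    mean_diff
        True mean of log10(male km) - log10(female km); negative means
        females disperse further.
    bias_sigma2
        Residual (phylogenetic) variance of the per-species dispersal bias.
    asr_breeding_slope
        Effect of (centered) arcsine-ASR on the breeding dispersal bias;
        0 disables the link.
    prevalence
        Target prevalence for binary traits built by thresholding.
    missing_rate
        Per-variable-group probability that a species lacks the measurement.
    populations_min, populations_max
        Range (inclusive) of population replicates per species.
    population_jitter_sd
        SD of per-population log10-scale noise around the species mean
        distance.
    hunted_fraction
        Probability a species' populations are flagged as hunted.
    seed
        Master seed; every output is a pure function of the config.
    """

    n_species: int = 86
    n_trees: int = 100
    birth_rate: float = 1.0
    lambda_true: float = 1.0
    sigma2: float = 0.5
    beta0: float = 2.0
    beta1: float = 1.5
    mean_diff: float = -0.15
    bias_sigma2: float = 0.16
    asr_breeding_slope: float = 0.0
    prevalence: float = 0.5
    missing_rate: float = 0.3
    populations_min: int = 1
    populations_max: int = 3
    population_jitter_sd: float = 0.05
    hunted_fraction: float = 0.15
    seed: int = 0

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(
    n_tips: int, birth_rate: float, seed: int
) -> PhyloTree:
    """One ultrametric pure-birth tree with tips S1..Sn."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = _random.Random(int(seed))
    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"S{i}"
    return PhyloTree(tree)


def simulate_trees(config: SimulationConfig) -> list[PhyloTree]:
    """Independent Yule trees sharing the species set S1..Sn."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(config.n_trees) % (2**31)
    return [
        simulate_yule_tree(config.n_species, config.birth_rate, int(s))
        for s in seeds
    ]


def write_trees(trees, path) -> None:
    """Write an ensemble as a Newick file, one tree per line."""
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_newick() + "\n")


# ---------------------------------------------------------------------------
# continuous and binary characters
# ---------------------------------------------------------------------------

def _unit_depth_vcv(tree: PhyloTree) -> PhyloVCV:
    """Tree VCV rescaled so the mean root-to-tip distance is 1.

    Yule tree depths vary between draws; fixing the scale makes variance
    parameters comparable across trees.
    """
    V = tree.vcv()
    scale = float(np.mean(np.diag(V.matrix)))
    return PhyloVCV(V.labels, V.matrix / scale)


def simulate_bm(
    vcv: PhyloVCV,
    rng: np.random.Generator,
    sigma2: float = 1.0,
    lam: float = 1.0,
    size: int | None = None,
) -> np.ndarray:
    """Exact multivariate-normal draws with covariance sigma2 * V_lambda.

    Near-simultaneous splits can make the tree covariance numerically
    semi-definite; a tiny diagonal ridge is added only if the factorization
    fails.
    """
    Vlam = sigma2 * lambda_transform(vcv, lam).matrix
    L = cholesky_psd(Vlam)
    if size is None:
        return L @ rng.standard_normal(vcv.n)
    return rng.standard_normal((size, vcv.n)) @ L.T


def simulate_regression_traits(
    tree: PhyloTree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """(x, y) for a generative PGLS: x Brownian, y = b0 + b1 x + phylo noise.

    x evolves by Brownian motion with unit rate; the residual has covariance
    ``sigma2 * V_lambda(lambda_true)`` on the unit-depth tree scale.  Returns
    vectors aligned to ``tree.tip_labels``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    V = _unit_depth_vcv(tree)
    x = simulate_bm(V, rng, sigma2=1.0, lam=1.0)
    eps = simulate_bm(V, rng, sigma2=config.sigma2, lam=config.lambda_true)
    y = config.beta0 + config.beta1 * x + eps
    return x, y


def simulate_binary_trait(
    tree: PhyloTree,
    regime: str,
    prevalence: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """A 0/1 tip trait under either null regime of the D statistic.

    ``regime="random"`` scatters ``round(prevalence * n)`` ones uniformly
    among tips (equivalent to a tip permutation); ``regime="brownian"``
    evolves a continuous Brownian character and assigns state 1 to the tips
    above the prevalence-matching cutoff.
    """
    n = tree.n_tips
    k = int(round(prevalence * n))
    if not 0 < k < n:
        raise ValueError("prevalence leaves a monomorphic trait")
    if regime == "random":
        trait = np.zeros(n)
        trait[rng.choice(n, size=k, replace=False)] = 1.0
        return trait
    if regime == "brownian":
        z = simulate_bm(_unit_depth_vcv(tree), rng)
        trait = np.zeros(n)
        trait[np.argsort(-z, kind="stable")[:k]] = 1.0
        return trait
    raise ValueError(f"unknown regime: {regime}")


# ---------------------------------------------------------------------------
# species trait table
# ---------------------------------------------------------------------------

def _threshold(z: np.ndarray, cuts: list[float], levels: list) -> np.ndarray:
    """Map standardized latent values into ordered categories at ``cuts``."""
    z = (z - z.mean()) / (z.std() + 1e-12)
    idx = np.searchsorted(np.asarray(cuts), z)
    return np.asarray(levels, dtype=float)[idx]


def simulate_species_table(
    tree: PhyloTree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """A per-population raw trait table consistent with ``tree``.

    Continuous characters carry Brownian structure (damped by
    ``lambda_true`` where residual-like); polygamy, dichromatism and care
    scores are thresholded latent Brownian characters, preserving
    phylogenetic signal in the discrete predictors.  Species means of the
    sex-specific distances reproduce ``mean_diff`` (and, if enabled, the
    arcsine-ASR -> breeding-bias slope) up to phylogenetic noise; population
    rows jitter around the species mean.  Missingness is applied per
    variable group, completely at random.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    V = _unit_depth_vcv(tree)
    species = list(V.labels)
    n = len(species)
    lam = config.lambda_true

    def bm(s2=1.0, l=1.0):
        return simulate_bm(V, rng, sigma2=s2, lam=l)

    # adult sex ratio (proportion of males), mildly phylogenetic, near 0.5
    asr = expit(0.4 * bm())
    asr_arc = np.arcsin(np.sqrt(asr))

    # sex-specific dispersal distances (km, log10 scale)
    log_f_natal = 0.5 + bm(0.3)
    log_f_breed = 0.0 + bm(0.3)
    natal_bias = config.mean_diff + bm(config.bias_sigma2, lam)
    breed_bias = (
        config.mean_diff
        + config.asr_breeding_slope * (asr_arc - asr_arc.mean())
        + bm(config.bias_sigma2, lam)
    )
    log_m_natal = log_f_natal + natal_bias
    log_m_breed = log_f_breed + breed_bias

    # social polygamy scores: most species monogamous, males skew higher
    male_poly = _threshold(bm(), [0.2, 0.8, 1.3, 1.8], [0, 1, 2, 3, 4])
    female_poly = _threshold(bm(), [1.3, 1.8, 2.2, 2.6], [0, 1, 2, 3, 4])

    epp = np.clip(expit(bm() - 1.2), 0.0, 1.0)

    log_f_mass = 1.5 + bm(0.5)
    log_m_mass = log_f_mass + 0.02 + 0.08 * bm()
    log_testis = 0.67 * log_m_mass - 2.0 + 0.3 * bm()

    # dichromatism: shared latent plus per-region noise; male-brighter common
    dich_latent = bm()
    dich = {
        region: _threshold(
            dich_latent + 0.5 * rng.standard_normal(n),
            [-1.6, -1.0, 0.3, 1.4],
            [-2, -1, 0, 1, 2],
        )
        for region in ("head", "back", "belly", "tail", "wings")
    }

    # parental care: female-biased on average
    care_latent = bm()
    care = {
        comp: _threshold(
            care_latent + 0.6 * rng.standard_normal(n),
            [-0.4, 0.6, 1.4, 2.0],
            [-1, -0.5, 0, 0.5, 1],
        )
        for comp in ("nest_building", "incubation", "nest_guarding",
                     "brooding", "chick_feeding", "chick_guarding")
    }

    mort_f = np.clip(expit(-0.6 + 0.5 * bm()), 0.01, 0.95)
    mort_m = np.clip(
        mort_f * 10 ** (0.02 + 0.08 * rng.standard_normal(n)), 0.01, 0.95
    )

    asr_method = rng.choice(["census", "capture"], size=n)
    hunted = rng.random(n) < config.hunted_fraction
    n_pops = rng.integers(
        config.populations_min, config.populations_max + 1, size=n
    )

    rows = []
    for i, sp in enumerate(species):
        for pop in range(1, int(n_pops[i]) + 1):
            jit = rng.normal(0.0, config.population_jitter_sd, size=4)
            rows.append({
                "species": sp,
                "population": pop,
                "natal_dispersal_male_km": 10 ** (log_m_natal[i] + jit[0]),
                "natal_dispersal_female_km": 10 ** (log_f_natal[i] + jit[1]),
                "breeding_dispersal_male_km": 10 ** (log_m_breed[i] + jit[2]),
                "breeding_dispersal_female_km": 10 ** (log_f_breed[i] + jit[3]),
                "polygamy_score_male": male_poly[i],
                "polygamy_score_female": female_poly[i],
                "epp_proportion": epp[i],
                "testis_mass_g": 10 ** log_testis[i],
                "male_mass_g": 10 ** log_m_mass[i],
                "female_mass_g": 10 ** log_f_mass[i],
                **{f"dichromatism_{r}": dich[r][i] for r in dich},
                **{f"care_{c}": care[c][i] for c in care},
                "asr_proportion_males": asr[i],
                "asr_method": asr_method[i],
                "mortality_male": mort_m[i],
                "mortality_female": mort_f[i],
                "hunted": bool(hunted[i]),
            })
    df = pd.DataFrame(rows)

    if config.missing_rate > 0:
        groups = [
            ["natal_dispersal_male_km", "natal_dispersal_female_km"],
            ["breeding_dispersal_male_km", "breeding_dispersal_female_km"],
            ["polygamy_score_male", "polygamy_score_female"],
            ["epp_proportion"],
            ["testis_mass_g"],
            ["male_mass_g", "female_mass_g"],
            [f"dichromatism_{r}" for r in dich],
            ["asr_proportion_males", "asr_method"],
            ["mortality_male", "mortality_female"],
        ]
        # species-level MCAR: a variable group is missing for all of a
        # species' populations, mimicking literature coverage gaps
        for cols in groups:
            drop = rng.random(n) < config.missing_rate
            mask = df["species"].isin(
                [sp for sp, d in zip(species, drop) if d]
            )
            df.loc[mask, cols] = np.nan
        # care components go missing independently
        for c in care:
            drop = rng.random(n) < config.missing_rate
            mask = df["species"].isin(
                [sp for sp, d in zip(species, drop) if d]
            )
            df.loc[mask, f"care_{c}"] = np.nan
    return df
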