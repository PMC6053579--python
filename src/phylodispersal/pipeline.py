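"""End-to-end analysis battery: a Table-1-shaped report from trees + traits.

Given a tree ensemble and a raw per-population trait table, the pipeline

1. collapses populations to species means and derives the sex-bias metrics;
2. runs ensemble phylogenetic paired t-tests on natal and breeding distances;
3. fits every response x predictor PGLS (responses: natal and breeding
   dispersal bias; predictors: mating-system bias, relative testes, EPP,
   care bias, SSD, dichromatism, arcsine-ASR, mortality bias) on the
   pairwise-complete species of each pair, skipping models with fewer than
   ``min_species`` species (default 10) and never fitting natal bias against
   mortality bias (natal dispersers are unobserved in mortality samples);
4. fits the natal-vs-breeding bias model;
5. runs D tests on the sign of each bias;
6. optionally reruns designated models as sensitivity variants (exclude
   hunted species, drop named species, add the ASR estimation method as a
   two-level factor covariate).

Every model records the species it used, making the differing sample sizes
across analyses auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dstat import d_test
from .ensemble import EnsembleFit, run_ensemble
from .paired import phylo_paired_t
from .pgls import pgls_fit
from .phylo import PhyloTree, normalize_label
from .traits import DISPERSAL_PAIRS, derive_traits, species_means

__all__ = ["PipelineConfig", "ModelResult", "AnalysisReport", "run_pipeline"]

RESPONSES = ("natal_bias", "breeding_bias")
PREDICTORS = (
    "mating_system_bias",
    "rel_testes",
    "epp",
    "care_bias",
    "ssd",
    "dichromatism_mean",
    "asr_arcsine",
    "mortality_bias",
)
# natal dispersal happens before individuals enter adult mortality samples
NOT_TESTED = {("natal_bias", "mortality_bias")}


@dataclass(frozen=True)
class PipelineConfig:
    min_species: int = 10
    exclude_hunted: bool = False
    drop_species: tuple[str, ...] = ()
    asr_method_covariate: bool = False
    dstat_n_perm: int = 1000
    dstat_n_sim: int = 1000
    dstat_n_trees: int = 1
    seed: int = 0


@dataclass
class ModelResult:
    response: str
    predictor: str
    n_species: int
    fit: EnsembleFit | None = None
    skipped: bool = False
    skip_reason: str = ""
    species: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()

    def summary_row(self) -> dict:
        row = {"response": self.response, "predictor": self.predictor,
               "n": self.n_species}
        if self.skipped or self.fit is None:
            row.update({"b": np.nan, "se": np.nan, "p": np.nan,
                        "se_p": np.nan, "n_trees": 0,
                        "status": f"skipped: {self.skip_reason}"})
        else:
            row.update(self.fit.summary_row())
            row["status"] = "ok"
        return row


@dataclass
class AnalysisReport:
    derived: pd.DataFrame
    paired_tests: dict
    models: list[ModelResult]
    d_tests: dict
    sensitivity: dict = field(default_factory=dict)
    log: dict = field(default_factory=dict)

    def models_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.summary_row() for m in self.models])

    def to_text(self) -> str:
        lines = ["Sex-biased dispersal analysis report", "=" * 40, ""]
        lines.append("Phylogenetic paired t-tests (log10 male - female km):")
        for kind, agg in self.paired_tests.items():
            lines.append(
                f"  {kind:9s} mean diff = {agg.mean_b:+.4f} "
                f"+/- {agg.total_se:.4f}, p = {agg.mean_p:.4f} "
                f"+/- {agg.se_p:.4f}, N = {agg.n_species} species, "
                f"{agg.n_trees} trees"
            )
        lines.append("")
        lines.append("Pairwise PGLS models (b +/- total SE, p +/- SE):")
        for m in self.models:
            row = m.summary_row()
            if row["status"] == "ok":
                lines.append(
                    f"  {m.response:14s} ~ {m.predictor:20s} "
                    f"b = {row['b']:+8.3f} +/- {row['se']:.3f}  "
                    f"p = {row['p']:.4f} +/- {row['se_p']:.4f}  "
                    f"N = {row['n']}"
                )
            else:
                lines.append(
                    f"  {m.response:14s} ~ {m.predictor:20s} {row['status']}"
                )
        lines.append("")
        lines.append("D statistic for the sign of each bias:")
        for kind, res in self.d_tests.items():
            if isinstance(res, str):
                lines.append(f"  {kind:14s} {res}")
            else:
                lines.append(
                    f"  {kind:14s} D = {res.d_scaled:+.3f}, "
                    f"P1 = {res.p_random:.4f}, P0 = {res.p_brownian:.4f}, "
                    f"prevalence = {res.prevalence:.2f}"
                )
        for name, frame in self.sensitivity.items():
            lines.append("")
            lines.append(f"Sensitivity variant: {name}")
            lines.append(frame.to_string(index=False))
        lines.append("")
        lines.append(f"log: {self.log}")
        return "\n".join(lines)


def _complete_species(derived: pd.DataFrame, cols: Sequence[str],
                      tree_tips: set[str]) -> list[str]:
    ok = derived[list(cols)].notna().all(axis=1)
    ok &= derived["species"].isin(tree_tips)
    return sorted(derived.loc[ok, "species"])


def _fit_model(
    derived: pd.DataFrame,
    response: str,
    predictor: str,
    trees: Sequence[PhyloTree],
    min_species: int,
    covariates: Sequence[str] = (),
) -> ModelResult:
    tree_tips = set(trees[0].tip_labels)
    needed = [response, predictor, *covariates]
    sp = _complete_species(derived, needed, tree_tips)
    n = len(sp)
    result = ModelResult(response=response, predictor=predictor,
                         n_species=n, species=tuple(sp),
                         covariates=tuple(covariates))
    if n < min_species:
        result.skipped = True
        result.skip_reason = f"n < {min_species} (n = {n})"
        return result
    sub = derived.set_index("species").loc[sp]
    y = sub[response].to_numpy(dtype=float)
    cols = [np.ones(n), sub[predictor].to_numpy(dtype=float)]
    names = ["intercept", predictor]
    for cov in covariates:
        v = sub[cov]
        if v.dtype == object:  # two-level factor, dummy-coded
            levels = sorted(v.dropna().unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {cov} has >2 levels: {levels}")
            cols.append((v == levels[-1]).to_numpy(dtype=float))
            names.append(f"{cov}[{levels[-1]}]")
        else:
            cols.append(v.to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols)

    def analysis(tree: PhyloTree):
        V = tree.prune(sp).vcv(order=sp)
        fit = pgls_fit(y, X, V, lam="ml", coef_names=names)
        return (float(fit.coefficients[1]), float(fit.standard_errors[1]),
                float(fit.p_values[1]), fit)

    result.fit = run_ensemble(analysis, trees, n_species=n)
    return result


def _paired_ensemble(
    species_table: pd.DataFrame,
    kind: str,
    trees: Sequence[PhyloTree],
) -> EnsembleFit | None:
    male_col, female_col = DISPERSAL_PAIRS[kind]
    tree_tips = set(trees[0].tip_labels)
    ok = species_table[[male_col, female_col]].notna().all(axis=1)
    ok &= species_table["species"].isin(tree_tips)
    sp = sorted(species_table.loc[ok, "species"])
    if len(sp) < 3:
        return None
    sub = species_table.set_index("species").loc[sp]
    male = sub[male_col].to_numpy(dtype=float)
    female = sub[female_col].to_numpy(dtype=float)

    def analysis(tree: PhyloTree):
        V = tree.prune(sp).vcv(order=sp)
        res = phylo_paired_t(male, female, V)
        return res.phylo_mean_diff, res.se_mean, res.p_value, res

    return run_ensemble(analysis, trees, n_species=len(sp))


def run_pipeline(
    trees: Sequence[PhyloTree],
    raw_table: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> AnalysisReport:
    """Run the full analysis battery; see the module docstring."""
    if not trees:
        raise ValueError("need at least one tree")
    table = raw_table.copy()
    table["species"] = table["species"].map(normalize_label)
    if config.drop_species:
        dropped = {normalize_label(s) for s in config.drop_species}
        absent = dropped - set(table["species"])
        if absent:
            raise KeyError(f"drop_species not in table: {sorted(absent)}")
        table = table[~table["species"].isin(dropped)]
    per_species = species_means(table)
    if config.exclude_hunted and "hunted" in per_species:
        per_species = per_species[
            ~per_species["hunted"].fillna(False).astype(bool)
        ]
    derived = derive_traits(per_species)

    tree_tips = set(trees[0].tip_labels)
    joinable = set(derived["species"]) & tree_tips
    if not joinable:
        raise ValueError("no species shared between trait table and trees")

    # 1. paired tests
    paired = {}
    for kind in ("natal", "breeding"):
        agg = _paired_ensemble(per_species, kind, trees)
        if agg is not None:
            paired[kind] = agg

    # 2. pairwise PGLS grid + natal-vs-breeding model
    covariates = ("asr_method",) if config.asr_method_covariate else ()
    models: list[ModelResult] = []
    for response in RESPONSES:
        for predictor in PREDICTORS:
            if (response, predictor) in NOT_TESTED:
                continue
            covs = covariates if predictor == "asr_arcsine" else ()
            models.append(_fit_model(derived, response, predictor, trees,
                                     config.min_species, covs))
    models.append(_fit_model(derived, "natal_bias", "breeding_bias", trees,
                             config.min_species))

    # 3. D tests on the sign of each bias (first dstat_n_trees trees)
    rng = np.random.default_rng(config.seed)
    d_tests: dict = {}
    for response in RESPONSES:
        sp = _complete_species(derived, [response], tree_tips)
        sub = derived.set_index("species").loc[sp, response]
        trait = (sub.to_numpy(dtype=float) > 0).astype(float)
        key = f"sign_{response}"
        if len(sp) < 3 or trait.min() == trait.max():
            d_tests[key] = "skipped: invariant or too few species"
            continue
        results = []
        for tree in trees[: config.dstat_n_trees]:
            V_tree = tree.prune(sp)
            order = list(V_tree.tip_labels)
            tvec = sub.loc[order].to_numpy(dtype=float)
            results.append(
                d_test(V_tree, (tvec > 0).astype(float),
                       n_perm=config.dstat_n_perm,
                       n_sim=config.dstat_n_sim, seed=rng)
            )
        # report the first tree's result; extra trees kept for dispersion
        d_tests[key] = results[0]

    report = AnalysisReport(
        derived=derived,
        paired_tests=paired,
        models=models,
        d_tests=d_tests,
        log={
            "seed": config.seed,
            "n_trees": len(trees),
            "n_species_table": int(per_species.shape[0]),
            "n_species_joinable": len(joinable),
            "min_species": config.min_species,
            "exclude_hunted": config.exclude_hunted,
            "drop_species": list(config.drop_species),
            "asr_method_covariate": config.asr_method_covariate,
        },
    )
    return report


def sensitivity_variants(
    trees: Sequence[PhyloTree],
    raw_table: pd.DataFrame,
    base_config: PipelineConfig = PipelineConfig(),
    exclude_hunted: bool = False,
    drop_species: Sequence[str] = (),
    add_asr_method: bool = False,
) -> dict[str, pd.DataFrame]:
    """Re-run the model grid under sensitivity variants; report side by side.

    Returns, per variant, a frame with baseline and variant b, SE and p for
    each model, so effect-size stability can be read off directly.
    """
    baseline = run_pipeline(trees, raw_table, base_config)
    base = baseline.models_frame().set_index(["response", "predictor"])
    out = {}
    variants: dict[str, PipelineConfig] = {}
    if exclude_hunted:
        variants["exclude_hunted"] = base_config.__class__(
            **{**base_config.__dict__, "exclude_hunted": True})
    if drop_species:
        variants["drop_species"] = base_config.__class__(
            **{**base_config.__dict__,
               "drop_species": tuple(drop_species)})
    if add_asr_method:
        variants["asr_method_covariate"] = base_config.__class__(
            **{**base_config.__dict__, "asr_method_covariate": True})
    for name, cfg in variants.items():
        rep = run_pipeline(trees, raw_table, cfg)
        var = rep.models_frame().set_index(["response", "predictor"])
        joined = base[["n", "b", "se", "p"]].join(
            var[["n", "b", "se", "p"]], lsuffix="_base", rsuffix="_variant"
        ).reset_index()
        out[name] = joined
    return out
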