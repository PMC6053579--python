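"""Derived sex-bias metrics and predictors from raw species trait tables.

The raw table has one row per species x population with sex-specific natal
and breeding dispersal distances (km), social polygamy scores, extra-pair
paternity, testis and body masses, plumage dichromatism region scores,
parental-care component scores, adult sex ratio (ASR) with its estimation
method, sex-specific annual mortality, and a hunted-population flag.

Derivation is in two steps: (1) collapse populations to unweighted species
means, pairing male and female dispersal estimates within a population; (2)
compute the derived metrics.  All logarithms are base 10, so a dispersal bias
of +1 means males disperse ten times further than females.  Missing inputs
propagate to missing derived values: each downstream analysis then uses its
own pairwise-complete species set.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "DISPERSAL_PAIRS",
    "RAW_COLUMNS",
    "CARE_COLUMNS",
    "DICHROMATISM_COLUMNS",
    "species_means",
    "derive_traits",
    "dispersal_bias",
    "mating_system_bias",
    "relative_testes",
    "ssd",
    "dichromatism",
    "care_bias",
    "asr_transform",
    "mortality_bias",
]

# allometric exponent relating testis mass to male body mass across birds
TESTES_ALLOMETRIC_EXPONENT = 0.67

DICHROMATISM_COLUMNS = [
    "dichromatism_head",
    "dichromatism_back",
    "dichromatism_belly",
    "dichromatism_tail",
    "dichromatism_wings",
]
CARE_COLUMNS = [
    "care_nest_building",
    "care_incubation",
    "care_nest_guarding",
    "care_brooding",
    "care_chick_feeding",
    "care_chick_guarding",
]
DISPERSAL_PAIRS = {
    "natal": ("natal_dispersal_male_km", "natal_dispersal_female_km"),
    "breeding": ("breeding_dispersal_male_km", "breeding_dispersal_female_km"),
}
RAW_COLUMNS = (
    ["species", "population"]
    + [c for pair in DISPERSAL_PAIRS.values() for c in pair]
    + ["polygamy_score_male", "polygamy_score_female", "epp_proportion",
       "testis_mass_g", "male_mass_g", "female_mass_g"]
    + DICHROMATISM_COLUMNS
    + CARE_COLUMNS
    + ["asr_proportion_males", "asr_method", "mortality_male",
       "mortality_female", "hunted"]
)

_CARE_LEVELS = {-1.0, -0.5, 0.0, 0.5, 1.0}


# ---------------------------------------------------------------------------
# scalar derivations
# ---------------------------------------------------------------------------

def dispersal_bias(male_km: float, female_km: float) -> float:
    """log10(male distance) - log10(female distance); positive = male-biased."""
    if male_km <= 0 or female_km <= 0:
        raise ValueError("dispersal distances must be positive")
    return math.log10(male_km) - math.log10(female_km)


def mating_system_bias(male_score: int, female_score: int) -> int:
    """Male minus female social polygamy score (each 0..4).

    Positive values mean social polygamy is more frequent in males (4 = common
    polygamy, >20% of individuals, including males of lekking species).
    """
    for s in (male_score, female_score):
        if s not in (0, 1, 2, 3, 4):
            raise ValueError(f"polygamy score must be an integer 0..4, got {s}")
    return int(male_score) - int(female_score)


def relative_testes(testis_mass_g: float, male_mass_g: float) -> float:
    """log10 testis mass corrected for body-mass allometry (exponent 0.67)."""
    if testis_mass_g <= 0 or male_mass_g <= 0:
        raise ValueError("masses must be positive")
    return math.log10(testis_mass_g) - TESTES_ALLOMETRIC_EXPONENT * math.log10(
        male_mass_g
    )


def ssd(male_mass_g: float, female_mass_g: float) -> float:
    """Sexual size dimorphism: log10(male mass) - log10(female mass)."""
    if male_mass_g <= 0 or female_mass_g <= 0:
        raise ValueError("masses must be positive")
    return math.log10(male_mass_g) - math.log10(female_mass_g)


def dichromatism(scores) -> tuple[float, int]:
    """Mean and sum of the five plumage-region dichromatism scores.

    Regions are head, back, belly, tail, wings; each scored -2..2 where
    positive means males are the brighter sex.
    """
    scores = list(scores)
    if len(scores) != 5:
        raise ValueError(f"expected 5 region scores, got {len(scores)}")
    for s in scores:
        if s not in (-2, -1, 0, 1, 2):
            raise ValueError(f"dichromatism scores must be integers -2..2, got {s}")
    return float(np.mean(scores)), int(np.sum(scores))


def care_bias(scores) -> float:
    """Mean relative male participation over the available care components.

    Components (up to six: nest building, incubation, nest guarding, brooding,
    chick feeding, chick guarding) are scored on a 5-point scale from -1
    (female-only care) to +1 (male-only care).  Species differ in which
    components are scored; the mean is over those available.  Returns NaN when
    no component is present.
    """
    scores = [s for s in scores if s is not None and not (
        isinstance(s, float) and math.isnan(s))]
    if not scores:
        return float("nan")
    for s in scores:
        if float(s) not in _CARE_LEVELS:
            raise ValueError(
                f"care scores must be in {{-1, -0.5, 0, 0.5, 1}}, got {s}"
            )
    return float(np.mean(scores))


def asr_transform(prop_males: float) -> float:
    """Variance-stabilizing arcsine transform of ASR: arcsin(sqrt(p)), radians."""
    if not 0.0 < prop_males <= 1.0:
        raise ValueError(f"proportion of males must be in (0, 1], got {prop_males}")
    return math.asin(math.sqrt(prop_males))


def mortality_bias(male_mortality: float, female_mortality: float) -> float:
    """log10(male annual mortality) - log10(female annual mortality)."""
    for m in (male_mortality, female_mortality):
        if not 0.0 < m < 1.0:
            raise ValueError(f"annual mortality must be in (0, 1), got {m}")
    return math.log10(male_mortality) - math.log10(female_mortality)


# ---------------------------------------------------------------------------
# table-level operations
# ---------------------------------------------------------------------------

def _validate_table(df: pd.DataFrame) -> None:
    def bad(mask, msg):
        if mask.any():
            raise ValueError(f"{msg} (rows {list(df.index[mask])[:5]})")

    for col in [c for pair in DISPERSAL_PAIRS.values() for c in pair] + [
        "testis_mass_g", "male_mass_g", "female_mass_g"
    ]:
        if col in df:
            v = pd.to_numeric(df[col], errors="coerce")
            bad(v.notna() & (v <= 0), f"{col} must be positive")
    for col in ("polygamy_score_male", "polygamy_score_female"):
        if col in df:
            v = pd.to_numeric(df[col], errors="coerce")
            bad(v.notna() & ~v.isin([0, 1, 2, 3, 4]), f"{col} must be 0..4")
    for col in DICHROMATISM_COLUMNS:
        if col in df:
            v = pd.to_numeric(df[col], errors="coerce")
            bad(v.notna() & ~v.isin([-2, -1, 0, 1, 2]), f"{col} must be -2..2")
    for col in CARE_COLUMNS:
        if col in df:
            v = pd.to_numeric(df[col], errors="coerce")
            bad(v.notna() & ~v.isin(sorted(_CARE_LEVELS)), f"{col} invalid level")
    if "epp_proportion" in df:
        v = pd.to_numeric(df["epp_proportion"], errors="coerce")
        bad(v.notna() & ((v < 0) | (v > 1)), "epp_proportion must be in [0, 1]")
    if "asr_proportion_males" in df:
        v = pd.to_numeric(df["asr_proportion_males"], errors="coerce")
        bad(v.notna() & ((v <= 0) | (v > 1)),
            "asr_proportion_males must be in (0, 1]")
    for col in ("mortality_male", "mortality_female"):
        if col in df:
            v = pd.to_numeric(df[col], errors="coerce")
            bad(v.notna() & ((v <= 0) | (v >= 1)), f"{col} must be in (0, 1)")


def species_means(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-population table to unweighted per-species means.

    Every numeric field is averaged over the populations reporting it, with
    one crucial exception: a population contributes to a dispersal-type mean
    only when it reports distances for *both* sexes of that type, because the
    sex comparison is only meaningful within a population.  ``asr_method``
    takes the first non-missing value per species; ``hunted`` is True if any
    population is hunted.  One row per species is returned, sorted by species.
    """
    df = records.copy()
    if "population" not in df:
        df["population"] = 1
    _validate_table(df)
    # mask unpaired dispersal estimates before averaging
    for male_col, female_col in DISPERSAL_PAIRS.values():
        if male_col in df and female_col in df:
            unpaired = df[male_col].isna() | df[female_col].isna()
            df.loc[unpaired, [male_col, female_col]] = np.nan

    numeric = [
        c for c in df.columns
        if c not in ("species", "population", "asr_method", "hunted")
    ]
    grouped = df.groupby("species", sort=True)
    out = grouped[numeric].mean()
    if "asr_method" in df:
        out["asr_method"] = grouped["asr_method"].apply(
            lambda s: s.dropna().iloc[0] if s.notna().any() else np.nan
        )
    if "hunted" in df:
        out["hunted"] = grouped["hunted"].apply(
            lambda s: bool(s.fillna(False).astype(bool).any())
        )
    return out.reset_index()


def derive_traits(species_table: pd.DataFrame) -> pd.DataFrame:
    """Compute the derived sex-bias metrics and predictors, one row per species.

    Input is a per-species table (use :func:`species_means` first if the raw
    table has population replicates).  A derived value is missing exactly when
    a required input is missing.
    """
    df = species_table
    if df["species"].duplicated().any():
        raise ValueError(
            "species table has duplicate species; run species_means first"
        )
    _validate_table(df)
    n = len(df)

    def col(name):
        return pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float) \
            if name in df else np.full(n, np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        out = pd.DataFrame({"species": df["species"].to_numpy()})
        out["natal_bias"] = np.log10(col("natal_dispersal_male_km")) - np.log10(
            col("natal_dispersal_female_km"))
        out["breeding_bias"] = np.log10(
            col("breeding_dispersal_male_km")) - np.log10(
            col("breeding_dispersal_female_km"))
        out["mating_system_bias"] = col("polygamy_score_male") - col(
            "polygamy_score_female")
        out["epp"] = col("epp_proportion")
        out["rel_testes"] = np.log10(col("testis_mass_g")) - \
            TESTES_ALLOMETRIC_EXPONENT * np.log10(col("male_mass_g"))
        out["ssd"] = np.log10(col("male_mass_g")) - np.log10(col("female_mass_g"))
        dichro = np.column_stack([col(c) for c in DICHROMATISM_COLUMNS])
        # dichromatism requires all five regions scored
        complete = ~np.isnan(dichro).any(axis=1)
        out["dichromatism_mean"] = np.where(complete, dichro.mean(axis=1), np.nan)
        out["dichromatism_sum"] = np.where(complete, dichro.sum(axis=1), np.nan)
        care = np.column_stack([col(c) for c in CARE_COLUMNS])
        present = ~np.isnan(care)
        any_care = present.any(axis=1)
        care_sum = np.where(present, care, 0.0).sum(axis=1)
        care_mean = care_sum / np.where(any_care, present.sum(axis=1), 1)
        out["care_bias"] = np.where(any_care, care_mean, np.nan)
        asr = col("asr_proportion_males")
        out["asr_arcsine"] = np.arcsin(np.sqrt(asr))
        out["mortality_bias"] = np.log10(col("mortality_male")) - np.log10(
            col("mortality_female"))
    out["asr_method"] = df["asr_method"].to_numpy() if "asr_method" in df \
        else np.full(n, np.nan, dtype=object)
    out["hunted"] = df["hunted"].fillna(False).astype(bool).to_numpy() \
        if "hunted" in df else np.zeros(n, dtype=bool)
    return out
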