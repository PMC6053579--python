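"""Derived trait metrics: scalar arithmetic, averaging rules, missingness."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylodispersal import derive_traits, species_means
from phylodispersal.traits import (
    asr_transform,
    care_bias,
    dichromatism,
    dispersal_bias,
    mating_system_bias,
    mortality_bias,
    relative_testes,
    ssd,
)

positive = st.floats(min_value=1e-3, max_value=1e4,
                     allow_nan=False, allow_infinity=False)
rate = st.floats(min_value=1e-3, max_value=0.999)


@pytest.mark.parametrize("func,args,expected", [
    (dispersal_bias, (10, 1), 1.0),
    (dispersal_bias, (3.7, 3.7), 0.0),
    (dispersal_bias, (2, 8), -0.60206),
    (mating_system_bias, (4, 0), 4),
    (mating_system_bias, (2, 2), 0),
    (mating_system_bias, (0, 3), -3),
    (relative_testes, (1, 1000), -2.01),
    (relative_testes, (10, 10), 0.33),
    (relative_testes, (1, 1), 0.0),
    (ssd, (100, 100), 0.0),
    (ssd, (200, 100), 0.30103),
    (ssd, (100, 200), -0.30103),
    (asr_transform, (0.5,), math.pi / 4),
    (asr_transform, (1.0,), math.pi / 2),
    (asr_transform, (0.25,), math.pi / 6),
    (mortality_bias, (0.2, 0.2), 0.0),
    (mortality_bias, (0.4, 0.1), 0.60206),
    (mortality_bias, (0.1, 0.4), -0.60206),
])
def test_scalar_metric_values(func, args, expected):
    assert func(*args) == pytest.approx(expected, abs=1e-5)


@pytest.mark.parametrize("scores,expected", [
    ((0, 0, 0, 0, 0), (0.0, 0)),
    ((2, 2, 2, 2, 2), (2.0, 10)),
    ((1, 0, -1, 2, 0), (0.4, 2)),
])
def test_dichromatism_mean_and_sum(scores, expected):
    mean, total = dichromatism(scores)
    assert mean == pytest.approx(expected[0])
    assert total == expected[1]


@pytest.mark.parametrize("scores,expected", [
    ([-1] * 6, -1.0),
    ([0.5, -0.5], 0.0),
    ([1, 1, 0.5, 0.5], 0.75),
])
def test_care_bias_mean_over_available(scores, expected):
    assert care_bias(scores) == pytest.approx(expected)


def test_care_bias_empty_is_missing_not_error():
    assert math.isnan(care_bias([]))
    assert math.isnan(care_bias([float("nan")]))


@pytest.mark.parametrize("func,args", [
    (dispersal_bias, (0, 1)),
    (dispersal_bias, (1, -2)),
    (mating_system_bias, (5, 0)),
    (relative_testes, (0, 10)),
    (ssd, (10, 0)),
    (asr_transform, (0.0,)),
    (asr_transform, (1.2,)),
    (mortality_bias, (0.0, 0.5)),
    (mortality_bias, (0.5, 1.0)),
])
def test_invalid_inputs_rejected(func, args):
    with pytest.raises(ValueError):
        func(*args)


def test_dichromatism_wrong_count_or_range_rejected():
    with pytest.raises(ValueError):
        dichromatism((1, 0, 1))
    with pytest.raises(ValueError):
        dichromatism((3, 0, 0, 0, 0))


class TestAntisymmetry:
    """Sex-swap antisymmetry of the log-ratio metrics."""

    @settings(max_examples=200, derandomize=True)
    @given(m=positive, f=positive)
    def test_dispersal_bias(self, m, f):
        assert dispersal_bias(m, f) == pytest.approx(
            -dispersal_bias(f, m), abs=1e-10)

    @settings(max_examples=200, derandomize=True)
    @given(m=positive, f=positive)
    def test_ssd(self, m, f):
        assert ssd(m, f) == pytest.approx(-ssd(f, m), abs=1e-10)

    @settings(max_examples=200, derandomize=True)
    @given(m=rate, f=rate)
    def test_mortality_bias(self, m, f):
        assert mortality_bias(m, f) == pytest.approx(
            -mortality_bias(f, m), abs=1e-10)


class TestSpeciesMeans:
    def _row(self, species, pop, **kw):
        base = {"species": species, "population": pop}
        base.update(kw)
        return base

    def test_single_population_identity(self):
        df = pd.DataFrame([self._row(
            "sp1", 1, natal_dispersal_male_km=2.0,
            natal_dispersal_female_km=4.0)])
        out = species_means(df)
        assert len(out) == 1
        assert out.loc[0, "natal_dispersal_male_km"] == 2.0

    def test_unweighted_mean_over_populations(self):
        df = pd.DataFrame([
            self._row("sp1", 1, natal_dispersal_male_km=2.0,
                      natal_dispersal_female_km=1.0),
            self._row("sp1", 2, natal_dispersal_male_km=4.0,
                      natal_dispersal_female_km=3.0),
        ])
        out = species_means(df)
        assert out.loc[0, "natal_dispersal_male_km"] == 3.0
        assert out.loc[0, "natal_dispersal_female_km"] == 2.0

    def test_unpaired_population_excluded_from_both_sexes(self):
        """A male-only population must not contribute to either sex's mean."""
        df = pd.DataFrame([
            self._row("sp1", 1, natal_dispersal_male_km=2.0,
                      natal_dispersal_female_km=1.0),
            self._row("sp1", 2, natal_dispersal_male_km=10.0,
                      natal_dispersal_female_km=np.nan),
        ])
        out = species_means(df)
        assert out.loc[0, "natal_dispersal_male_km"] == 2.0
        assert out.loc[0, "natal_dispersal_female_km"] == 1.0

    def test_pairing_is_per_dispersal_type(self):
        df = pd.DataFrame([
            self._row("sp1", 1,
                      natal_dispersal_male_km=2.0,
                      natal_dispersal_female_km=np.nan,
                      breeding_dispersal_male_km=5.0,
                      breeding_dispersal_female_km=6.0),
        ])
        out = species_means(df)
        assert math.isnan(out.loc[0, "natal_dispersal_male_km"])
        assert out.loc[0, "breeding_dispersal_male_km"] == 5.0

    def test_invariant_to_population_order(self):
        rows = [
            self._row("sp1", 1, natal_dispersal_male_km=2.0,
                      natal_dispersal_female_km=1.0, epp_proportion=0.1),
            self._row("sp1", 2, natal_dispersal_male_km=6.0,
                      natal_dispersal_female_km=3.0, epp_proportion=0.3),
            self._row("sp2", 1, natal_dispersal_male_km=1.0,
                      natal_dispersal_female_km=1.0, epp_proportion=0.2),
        ]
        a = species_means(pd.DataFrame(rows))
        b = species_means(pd.DataFrame(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_hunted_any_and_asr_method_first(self):
        df = pd.DataFrame([
            self._row("sp1", 1, hunted=False, asr_method=np.nan),
            self._row("sp1", 2, hunted=True, asr_method="census"),
        ])
        out = species_means(df)
        assert out.loc[0, "hunted"]
        assert out.loc[0, "asr_method"] == "census"


class TestDeriveTraits:
    def test_row_per_species_and_missingness_propagation(self):
        df = pd.DataFrame({
            "species": ["a", "b"],
            "natal_dispersal_male_km": [10.0, np.nan],
            "natal_dispersal_female_km": [1.0, 2.0],
            "male_mass_g": [200.0, 100.0],
            "female_mass_g": [100.0, np.nan],
            "asr_proportion_males": [0.5, 0.25],
            "asr_method": ["census", "capture"],
        })
        out = derive_traits(df)
        assert list(out["species"]) == ["a", "b"]
        assert out.loc[0, "natal_bias"] == pytest.approx(1.0)
        assert math.isnan(out.loc[1, "natal_bias"])
        assert out.loc[0, "ssd"] == pytest.approx(0.30103, abs=1e-5)
        assert math.isnan(out.loc[1, "ssd"])
        assert out.loc[1, "asr_arcsine"] == pytest.approx(math.pi / 6)
        # columns with no inputs at all stay missing, not invented
        assert out["mortality_bias"].isna().all()
        assert out["care_bias"].isna().all()

    def test_dichromatism_requires_all_five_regions(self):
        df = pd.DataFrame({
            "species": ["a", "b"],
            "dichromatism_head": [1.0, 1.0],
            "dichromatism_back": [0.0, 0.0],
            "dichromatism_belly": [-1.0, -1.0],
            "dichromatism_tail": [2.0, 2.0],
            "dichromatism_wings": [0.0, np.nan],
        })
        out = derive_traits(df)
        assert out.loc[0, "dichromatism_mean"] == pytest.approx(0.4)
        assert out.loc[0, "dichromatism_sum"] == 2
        assert math.isnan(out.loc[1, "dichromatism_mean"])

    def test_duplicate_species_rejected(self):
        df = pd.DataFrame({"species": ["a", "a"]})
        with pytest.raises(ValueError, match="duplicate"):
            derive_traits(df)

    def test_invalid_scores_rejected(self):
        df = pd.DataFrame({
            "species": ["a"], "polygamy_score_male": [7.0],
            "polygamy_score_female": [0.0],
        })
        with pytest.raises(ValueError, match="polygamy"):
            derive_traits(df)
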