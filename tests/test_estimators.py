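"""Carbon estimators: hand-arithmetic oracles, linearity, method identities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from forcarb.estimators import (
    EstimationError,
    carbon_area_based,
    carbon_bef,
    carbon_continuous_bcf,
    carbon_variable_bef,
    carbon_volume_conversion,
    estimate_all,
    with_density,
)
from forcarb.inventory import (
    AgeGroup,
    InventoryRecord,
    InventoryTable,
    Species,
    VegetationType,
    Zone,
)
from forcarb.registry import (
    ParameterRegistry,
    Stratum,
    VolumeConversionConstants,
)
import pandas as pd


def single_arbor(volume, species=Species.P_YUNNANENSIS, age=AgeGroup.MIDDLE_AGED, area=1.0):
    return InventoryTable(
        (InventoryRecord("a1", "c1", VegetationType.ARBOR, species, age, area, volume, Zone.CORE),)
    )


def test_zero_volume_yields_zero_carbon(registry):
    assert carbon_variable_bef(single_arbor(0.0), registry).total_carbon_tC == 0.0


def test_variable_bef_matches_hand_arithmetic(registry):
    # independent oracle: 1000 × 0.483 × 1.837 × 1.143 × 0.511 computed term by term
    expected = 1000.0 * 0.483 * 1.837 * (1 + 0.143) * 0.511
    got = carbon_variable_bef(single_arbor(1000.0), registry).total_carbon_tC
    assert got == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "species,volume,expected",
    [
        (Species.P_YUNNANENSIS, 1_251_790.89, 588_618.02),
        (Species.QUERCUS_SP, 76_041.34, 47_029.75),
        (Species.C_FUNEBRIS, 462.35, 236.16),
    ],
)
def test_pooled_bef_reproduces_published_species_stocks(registry, species, volume, expected):
    got = carbon_bef(single_arbor(volume, species=species), registry).total_carbon_tC
    assert round(got, 2) == expected


def test_volume_conversion_is_volume_times_0475_under_defaults(registry):
    got = carbon_volume_conversion(single_arbor(1.0)).total_carbon_tC
    assert got == pytest.approx(0.475, rel=1e-12)
    custom = VolumeConversionConstants(delta=2.0, rho=0.5, gamma=0.5)
    assert carbon_volume_conversion(single_arbor(100.0), custom).total_carbon_tC == pytest.approx(50.0)


def test_continuous_bcf_species_aggregate_matches_hand_arithmetic(registry):
    v = 1_251_790.89
    expected = (0.5101 * v + 1.0451) * 0.511
    got = carbon_continuous_bcf(single_arbor(v), registry, "species_aggregate").total_carbon_tC
    assert got == pytest.approx(expected, rel=1e-12)


def test_continuous_bcf_intercept_only_case(registry):
    stock = carbon_continuous_bcf(single_arbor(0.0), registry, "per_record")
    assert stock.total_carbon_tC == pytest.approx(1.0451 * 0.511, rel=1e-12)
    agg = carbon_continuous_bcf(single_arbor(0.0), registry, "species_aggregate")
    assert bool(agg.records["intercept_only"].iloc[0])


def test_continuous_bcf_application_levels_differ_by_one_intercept(registry):
    # two records of one species: per-record pays b·CF twice, aggregate once
    recs = tuple(
        InventoryRecord(f"a{i}", "c1", VegetationType.ARBOR, Species.P_YUNNANENSIS,
                        AgeGroup.YOUNG, 1.0, 10.0, Zone.CORE)
        for i in (1, 2)
    )
    table = InventoryTable(recs)
    agg = carbon_continuous_bcf(table, registry, "species_aggregate").total_carbon_tC
    per = carbon_continuous_bcf(table, registry, "per_record").total_carbon_tC
    assert per - agg == pytest.approx(1.0451 * 0.511, rel=1e-9)


def test_continuous_bcf_requires_explicit_application_level(registry):
    with pytest.raises((EstimationError, TypeError)):
        carbon_continuous_bcf(single_arbor(1.0), registry, "whatever")


@pytest.mark.parametrize(
    "veg,area,expected",
    [(VegetationType.ECONOMIC, 376.33, 4191.94), (VegetationType.SHRUB, 56.37, 523.52)],
)
def test_area_based_reproduces_published_stocks(registry, veg, area, expected):
    sp = Species.ECONOMIC_MIXED if veg is VegetationType.ECONOMIC else Species.SHRUB_MIXED
    table = InventoryTable(
        (InventoryRecord("x1", "c1", veg, sp, AgeGroup.NOT_APPLICABLE, area, 0.0, Zone.CORE),)
    )
    got = carbon_area_based(table, registry).total_carbon_tC
    assert round(got, 2) == expected


def test_area_based_zero_area_gives_zero(registry):
    table = InventoryTable(
        (InventoryRecord("x1", "c1", VegetationType.SHRUB, Species.SHRUB_MIXED,
                         AgeGroup.NOT_APPLICABLE, 0.0, 0.0, Zone.CORE),)
    )
    assert carbon_area_based(table, registry).total_carbon_tC == 0.0


def test_economic_and_shrub_records_never_enter_arbor_methods(registry, zixi):
    for fn in (carbon_variable_bef, carbon_bef):
        stock = fn(zixi, registry)
        assert set(stock.records["vegetation_type"]) == {"arbor"}


class TestProperties:
    @given(k=st.floats(0.1, 10.0))
    def test_homogeneity_volume_scaling_scales_carbon(self, k):
        registry = ParameterRegistry.default()
        base = single_arbor(123.0)
        scaled = single_arbor(123.0 * k)
        for fn in (carbon_variable_bef, carbon_bef):
            assert fn(scaled, registry).total_carbon_tC == pytest.approx(
                k * fn(base, registry).total_carbon_tC, rel=1e-9
            )
        assert carbon_volume_conversion(scaled).total_carbon_tC == pytest.approx(
            k * carbon_volume_conversion(base).total_carbon_tC, rel=1e-9
        )

    def test_additivity_total_is_sum_of_species_totals(self, registry, zixi):
        for name, stock in estimate_all(zixi, registry).items():
            by_species = stock.by("species")["carbon_tC"]
            assert by_species.sum() == pytest.approx(stock.total_carbon_tC, rel=1e-9)

    def test_all_methods_nonnegative_on_fixture(self, registry, zixi):
        for stock in estimate_all(zixi, registry).values():
            assert (stock.records["carbon_tC"] >= 0).all()

    def test_pooled_bef_equals_variable_bef_when_strata_equal_total(self, registry):
        # constructed registry: all age rows overwritten with the total row
        total = registry.species_params(Species.QUERCUS_SP, Stratum.TOTAL)
        rows = [
            {"species": "Quercus_sp", "stratum": s.value,
             "bef": total.bef, "root_shoot": total.root_shoot}
            for s in (Stratum.YOUNG, Stratum.MIDDLE_AGED, Stratum.NEAR_MATURE, Stratum.MATURE)
        ]
        flat = registry.with_overrides({"species_params": rows})
        table = single_arbor(500.0, species=Species.QUERCUS_SP, age=AgeGroup.YOUNG)
        assert carbon_variable_bef(table, flat).total_carbon_tC == pytest.approx(
            carbon_bef(table, flat).total_carbon_tC, rel=1e-12
        )


class TestDensity:
    @pytest.mark.parametrize(
        "carbon,area,expected",
        [(677_315.29, 14_880.28, 45.52), (672_599.83, 14_447.58, 46.55), (0.0, 5.0, 0.0)],
    )
    def test_density_is_carbon_over_area(self, carbon, area, expected):
        df = pd.DataFrame({"carbon_tC": [carbon], "area_hm2": [area]})
        assert round(with_density(df)["density_tC_per_hm2"].iloc[0], 2) == expected

    def test_positive_carbon_on_zero_area_is_inconsistent(self):
        df = pd.DataFrame({"carbon_tC": [1.0], "area_hm2": [0.0]})
        with pytest.raises(EstimationError):
            with_density(df)
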