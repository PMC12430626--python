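"""Volume-to-carbon estimators for the arbor layer plus area-based methods.

Four arbor-layer methods, all driven by standing volume V (m³):

``variable_bef``
    Age-stratified expansion: per record, C = V·D·BEF(species, age)·
    (1+R(species, age))·CF.  Uses the age-group parameter rows.
``bef``
    Species-pooled expansion: C = V·D·BEF_total·(1+R_total)·CF, the
    stratum-pooled ``total`` parameter row, no age differentiation.
``volume_conversion``
    Species-independent C = V·δ·ρ·γ with generic constants.
``continuous_bcf``
    Linear stand biomass model B = a·V + b per species, then C = B·CF.
    The intercept makes the application level matter: applied once per
    species group (``species_aggregate``) or once per record
    (``per_record``).  The caller must choose explicitly.

Economic forests and shrublands carry no volume; their carbon comes from
the area-based mean-biomass method C = S·B̄·CF (``area_based``).

All estimators keep per-record contributions so results can be aggregated
by any inventory dimension afterwards; densities (tC/hm²) are computed at
aggregation time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .inventory import (
    AgeGroup,
    InventoryTable,
    Species,
    VegetationType,
)
from .registry import (
    ParameterRegistry,
    Stratum,
    VolumeConversionConstants,
)

Method = Literal[
    "variable_bef", "bef", "volume_conversion", "continuous_bcf", "area_based"
]

GROUP_KEYS = ("vegetation_type", "species", "age_group", "zone")


class EstimationError(ValueError):
    """An inventory record cannot be estimated with the requested method."""


@dataclass(frozen=True)
class StockTable:
    """Per-record carbon contributions of one method.

    ``records`` columns: record_id, vegetation_type, species, age_group,
    zone, area_hm2, carbon_tC and (for the aggregate-intercept variant of
    the continuous method) intercept_only.
    """

    method: str
    records: pd.DataFrame

    @property
    def total_carbon_tC(self) -> float:
        return float(self.records["carbon_tC"].sum())

    @property
    def total_area_hm2(self) -> float:
        return float(self.records["area_hm2"].sum())

    def by(self, *keys: str) -> pd.DataFrame:
        """Aggregate carbon, area and density over the given dimensions.

        With no keys, returns a single-row frame of grand totals.  Density
        is carbon/area; a group with zero area and positive carbon is an
        inconsistency and raises :class:`EstimationError`.
        """
        for k in keys:
            if k not in GROUP_KEYS:
                raise EstimationError(f"unknown grouping dimension {k!r}; use {GROUP_KEYS}")
        if keys:
            out = self.records.groupby(list(keys))[["carbon_tC", "area_hm2"]].sum()
        else:
            out = pd.DataFrame(
                {"carbon_tC": [self.total_carbon_tC], "area_hm2": [self.total_area_hm2]},
                index=pd.Index(["total"], name="group"),
            )
        return with_density(out)

    def combined_with(self, *others: "StockTable", method: str = "combined") -> "StockTable":
        frames = [self.records] + [o.records for o in others]
        return StockTable(method=method, records=pd.concat(frames, ignore_index=True))


def with_density(grouped: pd.DataFrame) -> pd.DataFrame:
    """Add density_tC_per_hm2 = carbon/area to an aggregated frame."""
    bad = (grouped["area_hm2"] <= 0) & (grouped["carbon_tC"] > 0)
    if bad.any():
        raise EstimationError(
            f"zero area with positive carbon for groups {list(grouped.index[bad])}"
        )
    out = grouped.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = out["carbon_tC"].to_numpy(float) / out["area_hm2"].to_numpy(float)
    out["density_tC_per_hm2"] = np.where(out["area_hm2"].to_numpy(float) > 0, dens, 0.0)
    return out


def carbon_density(stock: StockTable, by: Sequence[str] = ()) -> pd.DataFrame:
    """Carbon stock, area and density aggregated over ``by``."""
    return stock.by(*by)


def _arbor_frame(inventory: InventoryTable) -> pd.DataFrame:
    frame = inventory.to_frame()
    return frame[frame["vegetation_type"] == VegetationType.ARBOR.value].copy()


def _as_stock(method: str, frame: pd.DataFrame) -> StockTable:
    cols = ["record_id", "vegetation_type", "species", "age_group", "zone", "area_hm2", "carbon_tC"]
    if "intercept_only" in frame.columns:
        cols.append("intercept_only")
    return StockTable(method=method, records=frame[cols].reset_index(drop=True))


def carbon_variable_bef(
    inventory: InventoryTable, registry: ParameterRegistry
) -> StockTable:
    """Age-stratified biomass expansion factor method (arbor records only)."""
    frame = _arbor_frame(inventory)
    factors = np.empty(len(frame))
    for i, (sp, ag, rid) in enumerate(
        zip(frame["species"], frame["age_group"], frame["record_id"])
    ):
        age = AgeGroup(ag)
        if age is AgeGroup.NOT_APPLICABLE:
            raise EstimationError(f"record {rid!r}: arbor record without a stand age group")
        factors[i] = registry.species_params(Species(sp), age).carbon_per_m3
    frame["carbon_tC"] = frame["volume_m3"].to_numpy(float) * factors
    return _as_stock("variable_bef", frame)


def carbon_bef(inventory: InventoryTable, registry: ParameterRegistry) -> StockTable:
    """Species-pooled biomass expansion factor method (arbor records only)."""
    frame = _arbor_frame(inventory)
    per_m3 = {
        sp.value: registry.species_params(sp, Stratum.TOTAL).carbon_per_m3
        for sp in set(Species(s) for s in frame["species"])
    }
    frame["carbon_tC"] = frame["volume_m3"].to_numpy(float) * frame["species"].map(per_m3).to_numpy(float)
    return _as_stock("bef", frame)


def carbon_volume_conversion(
    inventory: InventoryTable,
    constants: VolumeConversionConstants | None = None,
) -> StockTable:
    """Generic volume conversion C = V·δ·ρ·γ (arbor records only)."""
    constants = constants or VolumeConversionConstants()
    frame = _arbor_frame(inventory)
    frame["carbon_tC"] = frame["volume_m3"].to_numpy(float) * constants.carbon_per_m3
    return _as_stock("volume_conversion", frame)


def carbon_continuous_bcf(
    inventory: InventoryTable,
    registry: ParameterRegistry,
    application_level: Literal["species_aggregate", "per_record"],
) -> StockTable:
    """Continuous biomass-conversion-factor method B = a·V + b, C = B·CF.

    ``species_aggregate`` applies the equation to each species group's total
    volume, so the intercept b enters once per species; the species carbon is
    then allocated back to records in proportion to volume (volume-less
    groups get an equal split and are flagged ``intercept_only``).
    ``per_record`` applies the equation to every record separately.
    """
    if application_level not in ("species_aggregate", "per_record"):
        raise EstimationError(
            "application_level must be 'species_aggregate' or 'per_record'"
        )
    frame = _arbor_frame(inventory)
    frame["intercept_only"] = False
    carbon = np.zeros(len(frame))
    for sp_value, group in frame.groupby("species"):
        sp = Species(sp_value)
        eq = registry.biomass_equation(sp)
        cf = registry.species_params(sp, Stratum.TOTAL).carbon_fraction
        v = group["volume_m3"].to_numpy(float)
        idx = frame.index.get_indexer(group.index)
        if application_level == "per_record":
            carbon[idx] = (eq.slope * v + eq.intercept) * cf
        else:
            v_total = float(v.sum())
            c_total = eq.biomass_t(v_total) * cf
            if v_total > 0:
                carbon[idx] = eq.slope * v * cf + (eq.intercept * cf) * (v / v_total)
            else:
                carbon[idx] = c_total / len(group)
                frame.loc[group.index, "intercept_only"] = True
    frame["carbon_tC"] = carbon
    return _as_stock("continuous_bcf", frame)


def carbon_area_based(
    inventory: InventoryTable,
    registry: ParameterRegistry,
    vegetation_type: VegetationType | None = None,
) -> StockTable:
    """Mean-biomass area method C = S·B̄·CF for economic and shrub records."""
    wanted = (
        (vegetation_type,)
        if vegetation_type is not None
        else (VegetationType.ECONOMIC, VegetationType.SHRUB)
    )
    frame = inventory.to_frame()
    frame = frame[frame["vegetation_type"].isin(v.value for v in wanted)].copy()
    per_hm2 = {
        vt.value: registry.area_based(vt).mean_biomass_t_per_hm2
        * registry.area_based(vt).carbon_fraction
        for vt in wanted
    }
    frame["carbon_tC"] = frame["area_hm2"].to_numpy(float) * frame["vegetation_type"].map(
        per_hm2
    ).to_numpy(float)
    return _as_stock("area_based", frame)


ARBOR_METHODS = ("variable_bef", "bef", "volume_conversion", "continuous_bcf")


def estimate_all(
    inventory: InventoryTable,
    registry: ParameterRegistry,
    bcf_application_level: Literal["species_aggregate", "per_record"] = "species_aggregate",
) -> dict[str, StockTable]:
    """All four arbor methods plus the area-based method, keyed by name."""
    return {
        "variable_bef": carbon_variable_bef(inventory, registry),
        "bef": carbon_bef(inventory, registry),
        "volume_conversion": carbon_volume_conversion(inventory, registry.constants),
        "continuous_bcf": carbon_continuous_bcf(
            inventory, registry, application_level=bcf_application_level
        ),
        "area_based": carbon_area_based(inventory, registry),
    }
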