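"""Typed lookups over the published volume-to-carbon conversion parameters.

The registry houses three parameter families:

* per-species, per-stratum expansion parameters — biomass expansion factor
  (BEF, aboveground/stem), root-to-shoot ratio (R), basic wood density
  (D, t/m³) and carbon fraction (CF) — as used by the national greenhouse-gas
  inventory style volume expansion methods;
* per-species linear stand biomass equations ``B = a·V + b`` (t, m³) for the
  continuous biomass-conversion-factor method;
* scalar defaults: the generic volume conversion constants (δ=1.90, ρ=0.5,
  γ=0.5) and the area-based mean biomass of economic forests (23.7 t/hm²)
  and shrublands (19.76 t/hm²) with CF 0.47.

Numeric parameters ship as CSV data files inside the package so an audit can
diff one file against the published tables; this module only types, checks
and serves them.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .inventory import ARBOR_SPECIES, AgeGroup, Species, VegetationType


class Stratum(str, Enum):
    """Age stratum of the species parameter table.

    ``total`` is the stratum-pooled row used when age groups are not
    differentiated; the four stand age groups are used otherwise.
    """

    YOUNG = "young"
    MIDDLE_AGED = "middle_aged"
    NEAR_MATURE = "near_mature"
    MATURE = "mature"
    TOTAL = "total"


STRATUM_FOR_AGE: dict[AgeGroup, Stratum] = {
    AgeGroup.YOUNG: Stratum.YOUNG,
    AgeGroup.MIDDLE_AGED: Stratum.MIDDLE_AGED,
    AgeGroup.NEAR_MATURE: Stratum.NEAR_MATURE,
    AgeGroup.MATURE: Stratum.MATURE,
}


class RegistryError(KeyError):
    """Unknown (species, stratum) pair or unsupported species."""


class ValidationError(ValueError):
    """A parameter value violates its physical constraint."""


@dataclass(frozen=True)
class SpeciesParameters:
    species: Species
    stratum: Stratum
    bef: float
    root_shoot: float
    wood_density: float  # t/m3
    carbon_fraction: float

    def __post_init__(self) -> None:
        for name in ("bef", "root_shoot", "wood_density", "carbon_fraction"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0 for {self.species.value}")
        if not 0 < self.carbon_fraction < 1:
            raise ValidationError(
                f"carbon_fraction must lie in (0, 1), got {self.carbon_fraction}"
            )

    @property
    def carbon_per_m3(self) -> float:
        """tC per m³ of standing volume: D·BEF·(1+R)·CF."""
        return (
            self.wood_density * self.bef * (1.0 + self.root_shoot) * self.carbon_fraction
        )


@dataclass(frozen=True)
class BiomassEquation:
    """Stand-level linear biomass–volume relation ``B = a·V + b`` (t, m³)."""

    species: Species
    slope: float  # a, t per m3
    intercept: float  # b, t

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError(f"slope must be > 0 for {self.species.value}")

    def biomass_t(self, volume_m3: float) -> float:
        return self.slope * volume_m3 + self.intercept


@dataclass(frozen=True)
class VolumeConversionConstants:
    """Species-independent volume→carbon constants C = V·δ·ρ·γ."""

    delta: float = 1.90  # volume -> biomass expansion coefficient
    rho: float = 0.5  # biomass -> dry biomass
    gamma: float = 0.5  # dry biomass -> carbon

    def __post_init__(self) -> None:
        for name in ("delta", "rho", "gamma"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def carbon_per_m3(self) -> float:
        return self.delta * self.rho * self.gamma


@dataclass(frozen=True)
class AreaBasedParameters:
    """Mean-biomass area method parameters for volume-less vegetation types."""

    vegetation_type: VegetationType
    mean_biomass_t_per_hm2: float
    carbon_fraction: float = 0.47

    def __post_init__(self) -> None:
        if self.vegetation_type not in (VegetationType.ECONOMIC, VegetationType.SHRUB):
            raise ValidationError("area-based parameters apply to economic/shrub only")
        if self.mean_biomass_t_per_hm2 <= 0:
            raise ValidationError("mean_biomass_t_per_hm2 must be > 0")
        if not 0 < self.carbon_fraction < 1:
            raise ValidationError("carbon_fraction must lie in (0, 1)")


def _read_packaged(name: str) -> str:
    return resources.files("forcarb.data").joinpath(name).read_text()


class ParameterRegistry:
    """Immutable lookup of all conversion parameters; pure by construction."""

    def __init__(
        self,
        species_params: Mapping[tuple[Species, Stratum], SpeciesParameters],
        biomass_equations: Mapping[Species, BiomassEquation],
        constants: VolumeConversionConstants,
        area_based: Mapping[VegetationType, AreaBasedParameters],
    ) -> None:
        self._species_params = dict(species_params)
        self._biomass_equations = dict(biomass_equations)
        self.constants = constants
        self._area_based = dict(area_based)

    # -- construction -------------------------------------------------------

    @classmethod
    def default(cls) -> "ParameterRegistry":
        """Registry loaded from the packaged parameter files."""
        species_params: dict[tuple[Species, Stratum], SpeciesParameters] = {}
        for row in csv.DictReader(io.StringIO(_read_packaged("species_parameters.csv"))):
            p = SpeciesParameters(
                species=Species(row["species"]),
                stratum=Stratum(row["stratum"]),
                bef=float(row["bef"]),
                root_shoot=float(row["root_shoot"]),
                wood_density=float(row["wood_density"]),
                carbon_fraction=float(row["carbon_fraction"]),
            )
            species_params[(p.species, p.stratum)] = p
        equations: dict[Species, BiomassEquation] = {}
        for row in csv.DictReader(io.StringIO(_read_packaged("biomass_equations.csv"))):
            eq = BiomassEquation(
                species=Species(row["species"]),
                slope=float(row["slope"]),
                intercept=float(row["intercept"]),
            )
            equations[eq.species] = eq
        area_based = {
            VegetationType.ECONOMIC: AreaBasedParameters(
                VegetationType.ECONOMIC, mean_biomass_t_per_hm2=23.7, carbon_fraction=0.47
            ),
            VegetationType.SHRUB: AreaBasedParameters(
                VegetationType.SHRUB, mean_biomass_t_per_hm2=19.76, carbon_fraction=0.47
            ),
        }
        return cls(species_params, equations, VolumeConversionConstants(), area_based)

    def with_overrides(self, overrides: Mapping | str | Path) -> "ParameterRegistry":
        """New registry with selected cells replaced; invariants re-checked.

        ``overrides`` is a mapping (or path to a YAML file) with any of the
        keys ``constants``, ``species_params`` (list of rows keyed by
        species+stratum), ``biomass_equations`` (list of rows keyed by
        species) and ``area_based`` (mapping vegetation type -> fields).
        """
        if isinstance(overrides, (str, Path)):
            with open(overrides, "r", encoding="utf-8") as fh:
                overrides = yaml.safe_load(fh) or {}
        overrides = dict(overrides)

        constants = self.constants
        if "constants" in overrides:
            constants = replace(constants, **overrides["constants"])

        species_params = dict(self._species_params)
        for row in overrides.get("species_params", []):
            key = (Species(row["species"]), Stratum(row["stratum"]))
            if key not in species_params:
                raise RegistryError(f"no default row for {key}")
            fields = {k: v for k, v in row.items() if k not in ("species", "stratum")}
            species_params[key] = replace(species_params[key], **fields)

        equations = dict(self._biomass_equations)
        for row in overrides.get("biomass_equations", []):
            sp = Species(row["species"])
            fields = {k: v for k, v in row.items() if k != "species"}
            equations[sp] = replace(equations[sp], **fields)

        area_based = dict(self._area_based)
        for vt_token, fields in overrides.get("area_based", {}).items():
            vt = VegetationType(vt_token)
            area_based[vt] = replace(area_based[vt], **fields)

        return ParameterRegistry(species_params, equations, constants, area_based)

    # -- lookups ------------------------------------------------------------

    def species_params(
        self, species: Species, stratum: Stratum | AgeGroup
    ) -> SpeciesParameters:
        if isinstance(stratum, AgeGroup):
            if stratum not in STRATUM_FOR_AGE:
                raise RegistryError(
                    f"age group {stratum.value!r} has no parameter stratum"
                )
            stratum = STRATUM_FOR_AGE[stratum]
        key = (species, stratum)
        if key not in self._species_params:
            available = sorted(
                s.value for (sp, s) in self._species_params if sp == species
            )
            raise RegistryError(
                f"no parameters for ({species.value}, {stratum.value}); "
                f"available strata for this species: {available or 'none'}"
            )
        return self._species_params[key]

    def biomass_equation(self, species: Species) -> BiomassEquation:
        if species not in self._biomass_equations:
            raise RegistryError(
                f"no biomass equation for {species.value!r}; "
                f"supported species: {sorted(s.value for s in self._biomass_equations)}"
            )
        return self._biomass_equations[species]

    def area_based(self, vegetation_type: VegetationType) -> AreaBasedParameters:
        if vegetation_type not in self._area_based:
            raise RegistryError(
                f"no area-based parameters for {vegetation_type.value!r}"
            )
        return self._area_based[vegetation_type]


def get_species_params(
    species: Species, stratum: Stratum | AgeGroup, registry: ParameterRegistry | None = None
) -> SpeciesParameters:
    return (registry or ParameterRegistry.default()).species_params(species, stratum)


def get_biomass_equation(
    species: Species, registry: ParameterRegistry | None = None
) -> BiomassEquation:
    return (registry or ParameterRegistry.default()).biomass_equation(species)


def load_registry_overrides(config: Mapping | str | Path) -> ParameterRegistry:
    """Default registry with override cells applied (empty config → defaults)."""
    return ParameterRegistry.default().with_overrides(config)
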