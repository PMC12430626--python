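"""Sub-compartment inventory data model and delimited-text I/O.

A *sub-compartment* is the smallest forest-inventory mapping unit with
homogeneous stand attributes.  Each record carries the fields needed for
volume-based carbon accounting: area (hm²), vegetation type, dominant
species (or species group), age group, standing volume (m³) and the
functional zone of the nature reserve the stand falls in.

The canonical exchange format is UTF-8 CSV with a header row.  Arbitrary
source headers are supported through a column mapping, and species / zone /
age tokens are matched case-insensitively against a synonym table (the
species synonyms ship as a data file so they can be audited and extended
without touching code).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import pandas as pd


class VegetationType(str, Enum):
    ARBOR = "arbor"
    ECONOMIC = "economic"
    SHRUB = "shrub"
    NON_STOCKED = "non_stocked"


class Species(str, Enum):
    K_FORTUNEI = "K_fortunei"
    P_ARMANDII = "P_armandii"
    P_YUNNANENSIS = "P_yunnanensis"
    C_FUNEBRIS = "C_funebris"
    QUERCUS_SP = "Quercus_sp"
    E_ROBUSTA = "E_robusta"
    A_CREMASTOGYNE = "A_cremastogyne"
    ECONOMIC_MIXED = "economic_mixed"
    SHRUB_MIXED = "shrub_mixed"
    NONE = "none"


#: The seven dominant arbor species groups of the study system.
ARBOR_SPECIES: tuple[Species, ...] = (
    Species.K_FORTUNEI,
    Species.P_ARMANDII,
    Species.P_YUNNANENSIS,
    Species.C_FUNEBRIS,
    Species.QUERCUS_SP,
    Species.E_ROBUSTA,
    Species.A_CREMASTOGYNE,
)


class AgeGroup(str, Enum):
    YOUNG = "young"
    MIDDLE_AGED = "middle_aged"
    NEAR_MATURE = "near_mature"
    MATURE = "mature"
    NOT_APPLICABLE = "not_applicable"


#: Age groups that carry stand-development meaning (everything but n/a).
STAND_AGE_GROUPS: tuple[AgeGroup, ...] = (
    AgeGroup.YOUNG,
    AgeGroup.MIDDLE_AGED,
    AgeGroup.NEAR_MATURE,
    AgeGroup.MATURE,
)


class Zone(str, Enum):
    CORE = "core"
    BUFFER = "buffer"
    EXPERIMENTAL = "experimental"


class InvalidRecordError(ValueError):
    """A record violates an inventory invariant."""


class SchemaError(ValueError):
    """The source is missing a required column."""


@dataclass(frozen=True)
class RowError:
    """A row that could not be parsed into a valid record."""

    row_index: int  # 0-based data-row index (header excluded)
    message: str


# Canonical column names of the CSV exchange format.
COLUMNS = (
    "record_id",
    "compartment_id",
    "vegetation_type",
    "species",
    "age_group",
    "area_hm2",
    "volume_m3",
    "zone",
)


@dataclass(frozen=True)
class InventoryRecord:
    """One sub-compartment.

    Invariants (checked at construction):

    * ``area_hm2 >= 0`` and ``volume_m3 >= 0``;
    * economic and shrub records have no stand age (``not_applicable``);
    * arbor records carry one of the seven arbor species and a stand age;
    * non-stocked land carries no volume.
    """

    record_id: str
    compartment_id: str
    vegetation_type: VegetationType
    species: Species
    age_group: AgeGroup
    area_hm2: float
    volume_m3: float
    zone: Zone

    def __post_init__(self) -> None:
        if self.area_hm2 < 0:
            raise InvalidRecordError(
                f"record {self.record_id!r}: area_hm2 must be >= 0, got {self.area_hm2}"
            )
        if self.volume_m3 < 0:
            raise InvalidRecordError(
                f"record {self.record_id!r}: volume_m3 must be >= 0, got {self.volume_m3}"
            )
        vt = self.vegetation_type
        if vt in (VegetationType.ECONOMIC, VegetationType.SHRUB):
            if self.age_group is not AgeGroup.NOT_APPLICABLE:
                raise InvalidRecordError(
                    f"record {self.record_id!r}: {vt.value} records take age_group=not_applicable"
                )
        if vt is VegetationType.ARBOR:
            if self.species not in ARBOR_SPECIES:
                raise InvalidRecordError(
                    f"record {self.record_id!r}: arbor record needs an arbor species, "
                    f"got {self.species.value!r}"
                )
            if self.age_group is AgeGroup.NOT_APPLICABLE:
                raise InvalidRecordError(
                    f"record {self.record_id!r}: arbor record needs a stand age group"
                )
        if vt is VegetationType.NON_STOCKED and self.volume_m3 != 0:
            raise InvalidRecordError(
                f"record {self.record_id!r}: non-stocked land cannot carry volume"
            )


@dataclass(frozen=True)
class InventoryTable:
    """Ordered collection of records with unique ids."""

    records: tuple[InventoryRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidRecordError(f"duplicate record_id values: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InventoryRecord]:
        return iter(self.records)

    def filter(self, **field_values) -> "InventoryTable":
        """Records whose named fields equal the given values."""
        kept = tuple(
            r
            for r in self.records
            if all(getattr(r, k) == v for k, v in field_values.items())
        )
        return InventoryTable(kept, provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        """Materialise as a DataFrame with enum values as plain strings."""
        return pd.DataFrame(
            [
                {
                    "record_id": r.record_id,
                    "compartment_id": r.compartment_id,
                    "vegetation_type": r.vegetation_type.value,
                    "species": r.species.value,
                    "age_group": r.age_group.value,
                    "area_hm2": r.area_hm2,
                    "volume_m3": r.volume_m3,
                    "zone": r.zone.value,
                }
                for r in self.records
            ],
            columns=list(COLUMNS),
        )


@dataclass(frozen=True)
class ReadResult:
    table: InventoryTable
    errors: tuple[RowError, ...]


# ---------------------------------------------------------------------------
# token normalisation and synonym tables


def _normalise(token: str) -> str:
    token = token.strip().lower()
    token = re.sub(r"[._\-]", " ", token)
    return re.sub(r"\s+", " ", token).strip()


def _load_species_synonyms() -> dict[str, Species]:
    text = resources.files("forcarb.data").joinpath("species_synonyms.csv").read_text()
    table: dict[str, Species] = {}
    for row in csv.DictReader(io.StringIO(text)):
        table[_normalise(row["token"])] = Species(row["species"])
    # canonical enum values always resolve
    for sp in Species:
        table.setdefault(_normalise(sp.value), sp)
    return table


_VEG_SYNONYMS = {
    "arbor": VegetationType.ARBOR,
    "arbor forest": VegetationType.ARBOR,
    "forest": VegetationType.ARBOR,
    "economic": VegetationType.ECONOMIC,
    "economic forest": VegetationType.ECONOMIC,
    "shrub": VegetationType.SHRUB,
    "shrubland": VegetationType.SHRUB,
    "shrub forest": VegetationType.SHRUB,
    "non stocked": VegetationType.NON_STOCKED,
    "non stocked forest land": VegetationType.NON_STOCKED,
}

_AGE_SYNONYMS = {
    "young": AgeGroup.YOUNG,
    "young forest": AgeGroup.YOUNG,
    "middle aged": AgeGroup.MIDDLE_AGED,
    "middle aged forest": AgeGroup.MIDDLE_AGED,
    "near mature": AgeGroup.NEAR_MATURE,
    "near mature forest": AgeGroup.NEAR_MATURE,
    "mature": AgeGroup.MATURE,
    "mature forest": AgeGroup.MATURE,
    "not applicable": AgeGroup.NOT_APPLICABLE,
    "na": AgeGroup.NOT_APPLICABLE,
    "": AgeGroup.NOT_APPLICABLE,
}

_ZONE_SYNONYMS = {
    "core": Zone.CORE,
    "core zone": Zone.CORE,
    "buffer": Zone.BUFFER,
    "buffer zone": Zone.BUFFER,
    "experimental": Zone.EXPERIMENTAL,
    "experimental zone": Zone.EXPERIMENTAL,
    "experiment": Zone.EXPERIMENTAL,
}


def _parse_enum(token: str, table: Mapping[str, object], what: str):
    key = _normalise(token)
    if key not in table:
        accepted = ", ".join(sorted({str(getattr(v, "value", v)) for v in table.values()}))
        raise ValueError(f"unknown {what} token {token!r}; accepted: {accepted}")
    return table[key]


# ---------------------------------------------------------------------------
# read / write / summarise


def read_inventory(
    source: str | Path | IO[str],
    schema: Mapping[str, str] | None = None,
) -> ReadResult:
    """Parse a delimited inventory file.

    Parameters
    ----------
    source
        Path or open text stream of a CSV file with a header row.
    schema
        Optional mapping from canonical column names (:data:`COLUMNS`) to
        the headers actually present in the source.

    Rows that violate an invariant are reported individually in
    ``ReadResult.errors`` and excluded; the table of valid rows is always
    returned.  A missing required column raises :class:`SchemaError`.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_inventory(fh, schema=schema)

    mapping = {c: c for c in COLUMNS}
    if schema:
        mapping.update(schema)
    reader = csv.DictReader(source)
    header = reader.fieldnames or []
    missing = [actual for actual in mapping.values() if actual not in header]
    if missing:
        raise SchemaError(f"required columns not in header: {missing}")

    synonyms = _load_species_synonyms()
    records: list[InventoryRecord] = []
    errors: list[RowError] = []
    for idx, row in enumerate(reader):
        try:
            area = float(row[mapping["area_hm2"]])
            volume = float(row[mapping["volume_m3"]])
        except ValueError as exc:
            errors.append(RowError(idx, f"unparseable numeric: {exc}"))
            continue
        try:
            records.append(
                InventoryRecord(
                    record_id=row[mapping["record_id"]],
                    compartment_id=row[mapping["compartment_id"]],
                    vegetation_type=_parse_enum(
                        row[mapping["vegetation_type"]], _VEG_SYNONYMS, "vegetation_type"
                    ),
                    species=_parse_enum(row[mapping["species"]], synonyms, "species"),
                    age_group=_parse_enum(row[mapping["age_group"]], _AGE_SYNONYMS, "age_group"),
                    area_hm2=area,
                    volume_m3=volume,
                    zone=_parse_enum(row[mapping["zone"]], _ZONE_SYNONYMS, "zone"),
                )
            )
        except (ValueError, InvalidRecordError) as exc:
            errors.append(RowError(idx, str(exc)))
    name = getattr(source, "name", "<stream>")
    return ReadResult(InventoryTable(tuple(records), provenance=str(name)), tuple(errors))


def write_inventory(table: InventoryTable, sink: str | Path | IO[str]) -> None:
    """Write a table as canonical CSV; ``read_inventory`` round-trips it."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            write_inventory(table, fh)
        return
    writer = csv.writer(sink)
    writer.writerow(COLUMNS)
    for r in table:
        writer.writerow(
            [
                r.record_id,
                r.compartment_id,
                r.vegetation_type.value,
                r.species.value,
                r.age_group.value,
                repr(r.area_hm2),  # repr keeps the float exact across the round trip
                repr(r.volume_m3),
                r.zone.value,
            ]
        )


@dataclass(frozen=True)
class InventorySummary:
    """Area/volume totals of an inventory, overall and per grouping key."""

    total_area_hm2: float
    total_volume_m3: float
    by_vegetation_type: pd.DataFrame
    by_species: pd.DataFrame
    by_age_group: pd.DataFrame
    by_zone: pd.DataFrame


def summarize_inventory(table: InventoryTable) -> InventorySummary:
    """Group sums of area and volume by every inventory dimension."""
    frame = table.to_frame()
    if frame.empty:
        empty = pd.DataFrame(columns=["area_hm2", "volume_m3"])
        return InventorySummary(0.0, 0.0, empty, empty.copy(), empty.copy(), empty.copy())

    def group(key: str) -> pd.DataFrame:
        return frame.groupby(key)[["area_hm2", "volume_m3"]].sum()

    return InventorySummary(
        total_area_hm2=float(frame["area_hm2"].sum()),
        total_volume_m3=float(frame["volume_m3"].sum()),
        by_vegetation_type=group("vegetation_type"),
        by_species=group("species"),
        by_age_group=group("age_group"),
        by_zone=group("zone"),
    )
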