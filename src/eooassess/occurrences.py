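"""Reading, validating, labelling and filtering of occurrence records.

Input files are GBIF-style or literature-style delimited text (comma or tab,
auto-detected). Records keep their full coordinate precision; no
coordinate-precision or basis-of-record filtering is applied. Rows whose
coordinates are blank or unparseable are retained with absent coordinates so
that the species still appears downstream (and can end up Data Deficient).
"""

from __future__ import annotations

import csv
import json
from collections import OrderedDict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from shapely.geometry import Point, Polygon


class Source(str, Enum):
    """Provenance label of an occurrence record."""

    LITERATURE = "LITERATURE"
    GBIF = "GBIF"


@dataclass(frozen=True)
class OccurrenceRecord:
    """One species observation, possibly lacking coordinates.

    ``latitude``/``longitude`` are decimal degrees (WGS84) or ``None``;
    either both are present or both are absent. Longitudes are normalised
    to [-180, 180] on construction of the set, not here.
    """

    species: str
    latitude: float | None
    longitude: float | None
    source: Source
    record_id: str

    def __post_init__(self) -> None:
        if (self.latitude is None) != (self.longitude is None):
            raise ValueError(
                f"record {self.record_id!r}: half-georeferenced record "
                "(exactly one coordinate present)"
            )
        if not self.species.strip():
            raise ValueError(f"record {self.record_id!r}: empty species name")

    @property
    def is_georeferenced(self) -> bool:
        return self.latitude is not None


def canonical_species(name: str) -> str:
    """Trim and case-normalise a binomial; no synonym resolution."""
    return " ".join(name.split()).lower()


def normalise_longitude(lon: float) -> float:
    """Wrap a longitude into [-180, 180]."""
    wrapped = ((lon + 180.0) % 360.0) - 180.0
    # keep +180 as +180 rather than mapping it to -180
    if wrapped == -180.0 and lon > 0:
        return 180.0
    return wrapped


class OccurrenceSet:
    """Mapping species -> list of records, with per-file provenance notes."""

    def __init__(self) -> None:
        self._by_species: "OrderedDict[str, list[OccurrenceRecord]]" = OrderedDict()
        self.provenance: list[str] = []

    def add(self, record: OccurrenceRecord) -> None:
        key = canonical_species(record.species)
        self._by_species.setdefault(key, []).append(record)

    def ensure_species(self, species: str) -> None:
        """Register a species key even with zero records."""
        self._by_species.setdefault(canonical_species(species), [])

    @property
    def species(self) -> list[str]:
        return list(self._by_species)

    def records_for(self, species: str) -> list[OccurrenceRecord]:
        return list(self._by_species.get(canonical_species(species), []))

    def items(self) -> Iterable[tuple[str, list[OccurrenceRecord]]]:
        return ((k, list(v)) for k, v in self._by_species.items())

    def all_records(self) -> list[OccurrenceRecord]:
        return [r for recs in self._by_species.values() for r in recs]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_species.values())

    def __contains__(self, species: str) -> bool:
        return canonical_species(species) in self._by_species


@dataclass
class ColumnProfile:
    """Names of the species / latitude / longitude columns in an input file."""

    species: str = "species"
    latitude: str = "decimalLatitude"
    longitude: str = "decimalLongitude"


GBIF_PROFILE = ColumnProfile()
LITERATURE_PROFILE = ColumnProfile(
    species="species", latitude="latitude", longitude="longitude"
)


@dataclass
class IngestReport:
    """Row accounting for one input file."""

    path: str
    total_rows: int = 0
    parsed_rows: int = 0
    missing_coordinate_rows: int = 0
    malformed_rows: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _parse_coordinate(cell: str | None) -> float | None:
    if cell is None:
        return None
    cell = cell.strip()
    if not cell:
        return None
    try:
        return float(cell)
    except ValueError:
        return None


def _sniff_dialect(path: Path) -> csv.Dialect:
    sample = path.open("r", encoding="utf-8", newline="").read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t")
    except csv.Error:
        return csv.get_dialect("excel")  # type: ignore[return-value]


def read_occurrences(
    path: str | Path,
    source: Source,
    column_profile: ColumnProfile | None = None,
) -> tuple[OccurrenceSet, IngestReport]:
    """Read one delimited occurrence file into an :class:`OccurrenceSet`.

    Rows with blank or unparseable coordinates (in either column) are kept
    with absent coordinates and counted in the report; rows with an empty
    species cell are dropped as malformed. A missing file or a missing
    required column raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if column_profile is None:
        column_profile = GBIF_PROFILE if source is Source.GBIF else LITERATURE_PROFILE

    dialect = _sniff_dialect(path)
    occ = OccurrenceSet()
    occ.provenance.append(f"{path} ({source.value})")
    report = IngestReport(path=str(path))

    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, dialect=dialect)
        header = reader.fieldnames or []
        for col in (column_profile.species, column_profile.latitude, column_profile.longitude):
            if col not in header:
                raise ValueError(f"required column {col!r} absent from {path}")
        for i, row in enumerate(reader):
            report.total_rows += 1
            species = (row.get(column_profile.species) or "").strip()
            if not species:
                report.malformed_rows += 1
                continue
            lat = _parse_coordinate(row.get(column_profile.latitude))
            lon = _parse_coordinate(row.get(column_profile.longitude))
            if lat is not None and not (-90.0 <= lat <= 90.0):
                lat = None
            if lon is not None:
                lon = normalise_longitude(lon)
            if lat is None or lon is None:
                # half-georeferenced rows collapse to non-georeferenced
                lat = lon = None
                report.missing_coordinate_rows += 1
            occ.add(
                OccurrenceRecord(
                    species=species,
                    latitude=lat,
                    longitude=lon,
                    source=source,
                    record_id=f"{path.stem}:{i}",
                )
            )
            report.parsed_rows += 1
    return occ, report


CANONICAL_COLUMNS = ("species", "latitude", "longitude", "source", "record_id")


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    """Write the canonical occurrence CSV (coordinates at full precision)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for species, records in occ.items():
            for r in records:
                writer.writerow(
                    [
                        species,
                        "" if r.latitude is None else repr(r.latitude),
                        "" if r.longitude is None else repr(r.longitude),
                        r.source.value,
                        r.record_id,
                    ]
                )


def write_profile_csv(
    occ: OccurrenceSet,
    path: str | Path,
    profile: ColumnProfile,
    source: Source | None = None,
) -> None:
    """Write records (optionally one source only) using a column profile."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([profile.species, profile.latitude, profile.longitude])
        for species, records in occ.items():
            for r in records:
                if source is not None and r.source is not source:
                    continue
                writer.writerow(
                    [
                        species,
                        "" if r.latitude is None else repr(r.latitude),
                        "" if r.longitude is None else repr(r.longitude),
                    ]
                )


def read_canonical(path: str | Path) -> OccurrenceSet:
    """Read a canonical occurrence CSV written by :func:`write_occurrences`."""
    path = Path(path)
    occ = OccurrenceSet()
    occ.provenance.append(f"{path} (canonical)")
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            lat = _parse_coordinate(row["latitude"])
            lon = _parse_coordinate(row["longitude"])
            if lat is None or lon is None:
                lat = lon = None
            occ.add(
                OccurrenceRecord(
                    species=row["species"],
                    latitude=lat,
                    longitude=lon,
                    source=Source(row["source"]),
                    record_id=row["record_id"],
                )
            )
    return occ


def filter_georeferenced(occ: OccurrenceSet) -> tuple[OccurrenceSet, dict[str, int]]:
    """Keep only records with both coordinates; species keys are retained.

    Returns the filtered set and the per-species dropped count. Species left
    with zero records stay in the set (they classify as DD downstream).
    """
    out = OccurrenceSet()
    out.provenance = list(occ.provenance)
    dropped: dict[str, int] = {}
    for species, records in occ.items():
        out.ensure_species(species)
        dropped[species] = 0
        for r in records:
            if r.is_georeferenced:
                out.add(r)
            else:
                dropped[species] += 1
    return out, dropped


class RegionBoundary:
    """Closed polygon (lon, lat vertices) delimiting a study region."""

    def __init__(self, vertices: Sequence[tuple[float, float]]) -> None:
        if len(vertices) < 3:
            raise ValueError("region boundary needs at least 3 vertices")
        poly = Polygon(vertices)
        if not poly.is_valid or poly.area == 0.0:
            raise ValueError("region boundary is degenerate or self-intersecting")
        self.polygon = poly

    @classmethod
    def from_geojson(cls, path: str | Path) -> "RegionBoundary":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        geom = obj.get("geometry", obj)
        if geom.get("type") == "Feature":
            geom = geom["geometry"]
        if geom.get("type") != "Polygon":
            raise ValueError("region file must contain a GeoJSON Polygon")
        return cls([tuple(v) for v in geom["coordinates"][0]])


def flag_out_of_region(
    occ: OccurrenceSet, region: RegionBoundary
) -> list[tuple[str, bool]]:
    """Inclusive point-in-polygon flags (record_id, inside); nothing deleted.

    Boundary points count as inside. All records must be georeferenced.
    """
    flags: list[tuple[str, bool]] = []
    for r in occ.all_records():
        if not r.is_georeferenced:
            raise ValueError(f"record {r.record_id!r} is not georeferenced")
        inside = region.polygon.covers(Point(r.longitude, r.latitude))
        flags.append((r.record_id, bool(inside)))
    return flags


def merge_sources(a: OccurrenceSet, b: OccurrenceSet) -> OccurrenceSet:
    """Union keyed by species; no cross-source deduplication.

    Duplicate coordinates are harmless downstream: identical points never
    change a convex hull.
    """
    out = OccurrenceSet()
    out.provenance = list(a.provenance) + list(b.provenance)
    for occ in (a, b):
        for species, records in occ.items():
            out.ensure_species(species)
            for r in records:
                out.add(r)
    return out
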