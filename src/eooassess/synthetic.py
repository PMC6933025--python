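"""Synthetic occurrence datasets with known true ranges.

Each species receives a convex elliptical true range (so the true extent of
occurrence equals the true range area), record counts drawn independently
per source, points sampled uniformly inside the range by rejection from its
bounding box, and coordinates blanked at a configurable per-source rate.
Per-species RNG substreams are spawned from the run seed, so adding species
never perturbs earlier ones.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .geometry import AUTHALIC_RADIUS_KM, Ring, geodesic_area
from .occurrences import OccurrenceRecord, OccurrenceSet, Source
from .redlist import Category, ThresholdScheme, DEFAULT_SCHEME, classify

KM_PER_DEGREE = AUTHALIC_RADIUS_KM * math.pi / 180.0


@dataclass(frozen=True)
class RegionBox:
    """Lat/lon box in which synthetic ranges are placed (Iberia-like default)."""

    lat_min: float = 36.0
    lat_max: float = 44.0
    lon_min: float = -10.0
    lon_max: float = 4.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Range areas are log-uniform over ``area_range_km2`` (default spans all
    five EOO categories); per-source record counts are Poisson; ``g_*`` is
    the probability a record carries coordinates.
    """

    n_species: int
    seed: int
    area_range_km2: tuple[float, float] = (1e-1, 10**5.5)
    axis_ratio_range: tuple[float, float] = (0.3, 1.0)
    lambda_lit: float = 8.0
    lambda_gbif: float = 4.0
    g_lit: float = 0.9
    g_gbif: float = 0.9
    region: RegionBox = field(default_factory=RegionBox)
    n_ellipse_vertices: int = 128
    max_placement_retries: int = 200

    def __post_init__(self) -> None:
        if self.n_species < 0:
            raise ValueError("n_species must be non-negative")
        for g in (self.g_lit, self.g_gbif):
            if not 0.0 <= g <= 1.0:
                raise ValueError("georeferencing probabilities must be in [0, 1]")
        if self.lambda_lit < 0 or self.lambda_gbif < 0:
            raise ValueError("record-count means must be non-negative")
        lo, hi = self.area_range_km2
        if not (0 < lo <= hi):
            raise ValueError("area range must be positive and ordered")


@dataclass(frozen=True)
class TruthRecord:
    species: str
    ring: Ring  # lon/lat vertices of the true range polygon
    true_area_km2: float
    true_category: Category


def _ellipse_ring(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    area_km2: float,
) -> Ring:
    """Place an ellipse of the given area inside the region box.

    Rotation and centroid are resampled up to the retry bound when the
    ellipse does not fit; a range larger than the region is fatal.
    """
    region = spec.region
    q = rng.uniform(*spec.axis_ratio_range)
    a = math.sqrt(area_km2 / (math.pi * q))  # semi-major, km
    b = q * a
    t = np.linspace(0.0, 2.0 * math.pi, spec.n_ellipse_vertices, endpoint=False)
    for _ in range(spec.max_placement_retries):
        theta = rng.uniform(0.0, math.pi)
        x = a * np.cos(t) * math.cos(theta) - b * np.sin(t) * math.sin(theta)
        y = a * np.cos(t) * math.sin(theta) + b * np.sin(t) * math.cos(theta)
        dlat = y / KM_PER_DEGREE
        lat_lo = region.lat_min - dlat.min()
        lat_hi = region.lat_max - dlat.max()
        if lat_lo > lat_hi:
            continue
        lat_c = rng.uniform(lat_lo, lat_hi)
        dlon = x / (KM_PER_DEGREE * math.cos(math.radians(lat_c)))
        lon_lo = region.lon_min - dlon.min()
        lon_hi = region.lon_max - dlon.max()
        if lon_lo > lon_hi:
            continue
        lon_c = rng.uniform(lon_lo, lon_hi)
        return [(lon_c + dx, lat_c + dy) for dx, dy in zip(dlon, dlat)]
    raise ValueError(
        f"could not place a range of {area_km2:.1f} km² inside the region "
        f"after {spec.max_placement_retries} retries"
    )


def _sample_in_ring(rng: np.random.Generator, ring: Ring, n: int) -> np.ndarray:
    """Uniform points inside a convex ring via rejection from its bbox."""
    if n == 0:
        return np.empty((0, 2))
    poly = Polygon(ring)
    lon_min, lat_min, lon_max, lat_max = poly.bounds
    out: list[np.ndarray] = []
    remaining = n
    while remaining > 0:
        m = max(64, int(remaining * 1.8))
        lon = rng.uniform(lon_min, lon_max, m)
        lat = rng.uniform(lat_min, lat_max, m)
        keep = shapely.contains_xy(poly, lon, lat)
        pts = np.column_stack([lon[keep], lat[keep]])[:remaining]
        out.append(pts)
        remaining -= len(pts)
    return np.concatenate(out)


def generate(
    spec: SyntheticSpec,
    scheme: ThresholdScheme = DEFAULT_SCHEME,
) -> tuple[OccurrenceSet, list[TruthRecord]]:
    """Generate the occurrence set and per-species truth for ``spec``.

    Identical specs (including seed) reproduce identical output.
    """
    occ = OccurrenceSet()
    occ.provenance.append(f"synthetic seed={spec.seed} n_species={spec.n_species}")
    truths: list[TruthRecord] = []
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_species)
    width = max(4, len(str(max(spec.n_species, 1))))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        species = f"species_{i:0{width}d}"
        occ.ensure_species(species)
        lo, hi = spec.area_range_km2
        area = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        ring = _ellipse_ring(rng, spec, area)
        true_area = geodesic_area(ring)
        truths.append(
            TruthRecord(
                species=species,
                ring=ring,
                true_area_km2=true_area,
                true_category=classify(true_area, scheme),
            )
        )
        for source, lam, g in (
            (Source.LITERATURE, spec.lambda_lit, spec.g_lit),
            (Source.GBIF, spec.lambda_gbif, spec.g_gbif),
        ):
            n = int(rng.poisson(lam))
            pts = _sample_in_ring(rng, ring, n)
            georef = rng.random(n) < g
            for j in range(n):
                lon, lat = (pts[j] if georef[j] else (None, None))
                occ.add(
                    OccurrenceRecord(
                        species=species,
                        latitude=None if lat is None else float(lat),
                        longitude=None if lon is None else float(lon),
                        source=source,
                        record_id=f"{species}:{source.value}:{j}",
                    )
                )
    return occ, truths


def write_truth_csv(truths: Sequence[TruthRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "true_area_km2", "true_category"])
        for t in truths:
            writer.writerow([t.species, repr(float(t.true_area_km2)), t.true_category.value])


def write_ranges_geojson(truths: Sequence[TruthRecord], path: str | Path) -> None:
    features = []
    for t in truths:
        coords = [list(map(float, v)) for v in t.ring]
        if coords:
            coords.append(coords[0])
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "species": t.species,
                    "true_area_km2": t.true_area_km2,
                    "true_category": t.true_category.value,
                },
                "geometry": {"type": "Polygon", "coordinates": [coords]},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=2),
        encoding="utf-8",
    )


@dataclass
class RecoveryReport:
    """Confusion matrix of true vs estimated category with per-class recall."""

    confusion: dict[Category, dict[Category, int]]
    recall: dict[Category, float]
    n_species: int


def recovery_report(assessments, truths: Sequence[TruthRecord]) -> RecoveryReport:
    """Cross-tabulate true categories against estimated ones.

    ``assessments`` is any iterable of objects with ``species`` and
    ``category`` covering exactly the truth species set.
    """
    est = {a.species: a.category for a in assessments}
    true = {t.species: t.true_category for t in truths}
    if set(est) != set(true):
        raise ValueError("assessment and truth species sets differ")
    confusion = {t: {e: 0 for e in Category} for t in Category}
    for species, t_cat in true.items():
        confusion[t_cat][est[species]] += 1
    recall = {}
    for t_cat, row in confusion.items():
        total = sum(row.values())
        recall[t_cat] = row[t_cat] / total if total else float("nan")
    return RecoveryReport(confusion=confusion, recall=recall, n_species=len(true))
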