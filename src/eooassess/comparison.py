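"""Per-species assessment under three source modes and comparison tables.

Every species is assessed three times — literature records only, GBIF
records only, and the combined record set — and the categories are compared
per species. "Shifted" means the literature and combined categories differ,
which decomposes exactly into newly-assessable species (DD -> ranked) and
species whose ranked category changed. A change toward a less-threatened
category is a downgrade of the hypothetical classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping, Sequence

from .geometry import eoo
from .occurrences import OccurrenceSet, Source
from .redlist import CATEGORY_ORDER, Category, ThresholdScheme, DEFAULT_SCHEME, classify


class Mode(str, Enum):
    LITERATURE = "LITERATURE"
    GBIF = "GBIF"
    COMBINED = "COMBINED"


class Direction(str, Enum):
    DOWNGRADE = "DOWNGRADE"
    UPGRADE = "UPGRADE"
    NONE = "NONE"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed-percentage style."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Assessment:
    species: str
    mode: Mode
    n_records: int
    eoo_km2: float | None
    category: Category


def _mode_records(records, mode: Mode):
    if mode is Mode.COMBINED:
        return list(records)
    wanted = Source.LITERATURE if mode is Mode.LITERATURE else Source.GBIF
    return [r for r in records if r.source is wanted]


def assess_all(
    occ: OccurrenceSet,
    mode: Mode,
    scheme: ThresholdScheme = DEFAULT_SCHEME,
    three_point_rule: str = "records",
) -> list[Assessment]:
    """One assessment per species in ``occ`` using only ``mode``'s records.

    ``occ`` must already be filtered to georeferenced records. Species with
    zero records in the mode are assessed DD.
    """
    out: list[Assessment] = []
    for species, records in occ.items():
        selected = _mode_records(records, mode)
        result = eoo(selected, three_point_rule=three_point_rule)
        out.append(
            Assessment(
                species=species,
                mode=mode,
                n_records=result.n_records,
                eoo_km2=result.area_km2,
                category=classify(result, scheme),
            )
        )
    return out


@dataclass(frozen=True)
class ComparisonRow:
    species: str
    cat_lit: Category
    cat_gbif: Category
    cat_combined: Category

    @property
    def newly_assessable(self) -> bool:
        return self.cat_lit is Category.DD and self.cat_combined is not Category.DD

    @property
    def changed_among_assessed(self) -> bool:
        return (
            self.cat_lit.is_ranked
            and self.cat_combined.is_ranked
            and self.cat_lit is not self.cat_combined
        )

    @property
    def shifted(self) -> bool:
        return self.cat_lit is not self.cat_combined

    @property
    def direction(self) -> Direction:
        if not self.changed_among_assessed:
            return Direction.NONE
        if self.cat_combined.threat_rank < self.cat_lit.threat_rank:
            return Direction.DOWNGRADE
        return Direction.UPGRADE


def compare(assessments_by_mode: Mapping[Mode, Sequence[Assessment]]) -> list[ComparisonRow]:
    """Join the three per-mode assessment lists into per-species rows."""
    per_mode: dict[Mode, dict[str, Assessment]] = {}
    for mode in (Mode.LITERATURE, Mode.GBIF, Mode.COMBINED):
        if mode not in assessments_by_mode:
            raise ValueError(f"missing assessments for mode {mode.value}")
        per_mode[mode] = {a.species: a for a in assessments_by_mode[mode]}
    keys = [set(d) for d in per_mode.values()]
    if not (keys[0] == keys[1] == keys[2]):
        offenders = sorted(set.union(*keys) - set.intersection(*keys))
        raise ValueError(f"species sets differ across modes: {offenders}")
    rows = []
    for species in per_mode[Mode.LITERATURE]:  # insertion order of literature list
        rows.append(
            ComparisonRow(
                species=species,
                cat_lit=per_mode[Mode.LITERATURE][species].category,
                cat_gbif=per_mode[Mode.GBIF][species].category,
                cat_combined=per_mode[Mode.COMBINED][species].category,
            )
        )
    return rows


@dataclass
class SummaryTable:
    """Category-by-mode counts plus derived percentages.

    ``counts[mode][category]`` sums to ``n_species`` for every mode. Shift
    counters are absent when the table was built from bare counts rather
    than per-species rows. ``species`` (when known) guards pooling against
    overlapping inputs.
    """

    counts: dict[Mode, dict[Category, int]]
    n_species: int
    n_shifted: int | None = None
    n_newly_assessable: int | None = None
    n_changed_among_assessed: int | None = None
    species: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for mode, col in self.counts.items():
            total = sum(col.values())
            if total != self.n_species:
                raise ValueError(
                    f"{mode.value} column sums to {total}, expected {self.n_species}"
                )

    @classmethod
    def from_counts(
        cls, counts: Mapping[Mode, Mapping[Category, int]], n_species: int
    ) -> "SummaryTable":
        """Build a table from printed/bare per-category counts."""
        full = {
            mode: {cat: int(col.get(cat, 0)) for cat in CATEGORY_ORDER}
            for mode, col in counts.items()
        }
        return cls(counts=full, n_species=n_species)

    def _percent(self, numerator: float) -> float:
        if self.n_species == 0:
            return 0.0
        return round_half_up(100.0 * numerator / self.n_species)

    def percent_classifiable(self, mode: Mode) -> float:
        return self._percent(self.n_species - self.counts[mode][Category.DD])

    def percent_dd(self, mode: Mode) -> float:
        return self._percent(self.counts[mode][Category.DD])

    @property
    def percent_shifted(self) -> float:
        if self.n_shifted is None:
            raise ValueError("shift statistics unavailable for a counts-only table")
        return self._percent(self.n_shifted)

    @property
    def percent_newly_assessable(self) -> float:
        if self.n_newly_assessable is None:
            raise ValueError("shift statistics unavailable for a counts-only table")
        return self._percent(self.n_newly_assessable)

    @property
    def percent_changed_among_assessed(self) -> float:
        if self.n_changed_among_assessed is None:
            raise ValueError("shift statistics unavailable for a counts-only table")
        return self._percent(self.n_changed_among_assessed)


def summarize(
    rows: Sequence[ComparisonRow],
    assessments_by_mode: Mapping[Mode, Sequence[Assessment]] | None = None,
) -> SummaryTable:
    """Tally category-by-mode counts and shift statistics from rows."""
    counts = {mode: {cat: 0 for cat in CATEGORY_ORDER} for mode in Mode}
    for row in rows:
        counts[Mode.LITERATURE][row.cat_lit] += 1
        counts[Mode.GBIF][row.cat_gbif] += 1
        counts[Mode.COMBINED][row.cat_combined] += 1
    return SummaryTable(
        counts=counts,
        n_species=len(rows),
        n_shifted=sum(r.shifted for r in rows),
        n_newly_assessable=sum(r.newly_assessable for r in rows),
        n_changed_among_assessed=sum(r.changed_among_assessed for r in rows),
        species=frozenset(r.species for r in rows),
    )


def pool_summaries(a: SummaryTable, b: SummaryTable) -> SummaryTable:
    """Cell-wise pooling of two tables over disjoint species sets."""
    if a.species is not None and b.species is not None:
        overlap = a.species & b.species
        if overlap:
            raise ValueError(f"overlapping species across pooled tables: {sorted(overlap)}")
    modes = set(a.counts) & set(b.counts)
    counts = {
        mode: {cat: a.counts[mode][cat] + b.counts[mode][cat] for cat in CATEGORY_ORDER}
        for mode in modes
    }

    def _add(x: int | None, y: int | None) -> int | None:
        return None if x is None or y is None else x + y

    species = None
    if a.species is not None and b.species is not None:
        species = a.species | b.species
    return SummaryTable(
        counts=counts,
        n_species=a.n_species + b.n_species,
        n_shifted=_add(a.n_shifted, b.n_shifted),
        n_newly_assessable=_add(a.n_newly_assessable, b.n_newly_assessable),
        n_changed_among_assessed=_add(a.n_changed_among_assessed, b.n_changed_among_assessed),
        species=species,
    )
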