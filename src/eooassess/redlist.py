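"""Strict-threshold hypothetical Red List categorisation from EOO."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union

import yaml

from .geometry import HullResult


class Category(str, Enum):
    """Red List label; ``threat_rank`` orders the ranked labels only."""

    DD = "DD"
    CR = "CR"
    EN = "EN"
    VU = "VU"
    NT = "NT"
    LC = "LC"

    @property
    def threat_rank(self) -> int:
        """CR=4 > EN=3 > VU=2 > NT=1 > LC=0; undefined for DD."""
        ranks = {"CR": 4, "EN": 3, "VU": 2, "NT": 1, "LC": 0}
        if self.value not in ranks:
            raise ValueError("threat rank is undefined for DD")
        return ranks[self.value]

    @property
    def is_ranked(self) -> bool:
        return self is not Category.DD


CATEGORY_ORDER = [Category.DD, Category.CR, Category.EN, Category.VU, Category.NT, Category.LC]


@dataclass(frozen=True)
class ThresholdScheme:
    """Strictly-less-than EOO cutoffs in km² for each threatened category.

    Note the NT cutoff is the scheme used here, not an official criterion-B
    value.
    """

    t_cr: float = 100.0
    t_en: float = 5_000.0
    t_vu: float = 20_000.0
    t_nt: float = 30_000.0

    def __post_init__(self) -> None:
        if not (self.t_cr < self.t_en < self.t_vu < self.t_nt):
            raise ValueError("thresholds must be strictly increasing")

    @classmethod
    def from_file(cls, path: str | Path) -> "ThresholdScheme":
        """Load overrides from a YAML/JSON mapping (keys t_cr..t_nt)."""
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {k: float(v) for k, v in data.items() if k in ("t_cr", "t_en", "t_vu", "t_nt")}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**known)


DEFAULT_SCHEME = ThresholdScheme()


def classify(
    eoo_result: Union[HullResult, float, None],
    scheme: ThresholdScheme = DEFAULT_SCHEME,
) -> Category:
    """Map an EOO value (km², or undefined) to a category.

    Undefined area -> DD. Otherwise the first strict-< threshold wins;
    an area at or above the NT cutoff is LC. Exact-threshold values fall in
    the less-threatened category.
    """
    area = eoo_result.area_km2 if isinstance(eoo_result, HullResult) else eoo_result
    if area is None:
        return Category.DD
    if area < 0:
        raise ValueError(f"negative EOO area {area!r}")
    if area < scheme.t_cr:
        return Category.CR
    if area < scheme.t_en:
        return Category.EN
    if area < scheme.t_vu:
        return Category.VU
    if area < scheme.t_nt:
        return Category.NT
    return Category.LC
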