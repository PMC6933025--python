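from __future__ import annotations

import pytest

from eooassess import OccurrenceRecord, OccurrenceSet, Source


def make_record(
    species: str = "aranea exemplaris",
    lat: float | None = 40.0,
    lon: float | None = -3.0,
    source: Source = Source.LITERATURE,
    record_id: str = "r0",
) -> OccurrenceRecord:
    return OccurrenceRecord(
        species=species, latitude=lat, longitude=lon, source=source, record_id=record_id
    )


def make_set(records) -> OccurrenceSet:
    occ = OccurrenceSet()
    for r in records:
        occ.add(r)
    return occ


@pytest.fixture
def write_csv(tmp_path):
    def _write(name: str, text: str):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path

    return _write
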