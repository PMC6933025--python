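from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eooassess import (
    ColumnProfile,
    OccurrenceRecord,
    OccurrenceSet,
    RegionBoundary,
    Source,
    filter_georeferenced,
    flag_out_of_region,
    merge_sources,
    read_canonical,
    read_occurrences,
    write_occurrences,
)
from eooassess.occurrences import canonical_species, normalise_longitude

from conftest import make_record, make_set


class TestRecord:
    def test_half_georeferenced_is_invalid(self):
        with pytest.raises(ValueError, match="half-georeferenced"):
            OccurrenceRecord("a b", 1.0, None, Source.GBIF, "x")

    def test_empty_species_is_invalid(self):
        with pytest.raises(ValueError, match="species"):
            OccurrenceRecord("   ", 1.0, 2.0, Source.GBIF, "x")

    @pytest.mark.parametrize(
        "lon,expected", [(0.0, 0.0), (190.0, -170.0), (-185.0, 175.0), (180.0, 180.0), (360.0, 0.0)]
    )
    def test_normalise_longitude(self, lon, expected):
        assert normalise_longitude(lon) == pytest.approx(expected)

    def test_canonical_species(self):
        assert canonical_species("  Myrmarachne   bicolor ") == "myrmarachne bicolor"


class TestReadOccurrences:
    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_occurrences(tmp_path / "nope.csv", Source.GBIF)

    def test_missing_column_is_fatal(self, write_csv):
        path = write_csv("bad.csv", "species,decimalLatitude\na b,1\n")
        with pytest.raises(ValueError, match="decimalLongitude"):
            read_occurrences(path, Source.GBIF)

    def test_header_only(self, write_csv):
        path = write_csv("empty.csv", "species,decimalLatitude,decimalLongitude\n")
        occ, report = read_occurrences(path, Source.GBIF)
        assert occ.species == []
        assert report.total_rows == 0

    def test_blank_latitude_retained_as_absent(self, write_csv):
        path = write_csv(
            "m.csv",
            "species,decimalLatitude,decimalLongitude\n"
            "a b,1.0,2.0\na b,,2.0\na b,3.0,4.0\n",
        )
        occ, report = read_occurrences(path, Source.GBIF)
        records = occ.records_for("a b")
        assert len(records) == 3
        assert sum(not r.is_georeferenced for r in records) == 1
        assert report.missing_coordinate_rows == 1
        assert report.parsed_rows == 3

    def test_unparseable_coordinate_counted(self, write_csv):
        path = write_csv(
            "u.csv", "species,decimalLatitude,decimalLongitude\na b,xx,2.0\n"
        )
        occ, report = read_occurrences(path, Source.GBIF)
        assert report.missing_coordinate_rows == 1
        assert not occ.records_for("a b")[0].is_georeferenced

    def test_out_of_range_latitude_becomes_absent(self, write_csv):
        path = write_csv(
            "r.csv", "species,decimalLatitude,decimalLongitude\na b,95.0,2.0\n"
        )
        _, report = read_occurrences(path, Source.GBIF)
        assert report.missing_coordinate_rows == 1

    def test_empty_species_row_dropped(self, write_csv):
        path = write_csv(
            "s.csv", "species,decimalLatitude,decimalLongitude\n ,1.0,2.0\na b,1,2\n"
        )
        occ, report = read_occurrences(path, Source.GBIF)
        assert report.malformed_rows == 1
        assert len(occ) == 1

    def test_tab_delimited_autodetected(self, write_csv):
        path = write_csv(
            "t.tsv", "species\tdecimalLatitude\tdecimalLongitude\na b\t1.0\t2.0\n"
        )
        occ, _ = read_occurrences(path, Source.GBIF)
        assert occ.records_for("a b")[0].latitude == 1.0

    def test_literature_profile_and_custom_columns(self, write_csv):
        path = write_csv("l.csv", "taxon,lat,lon\na b,1.0,2.0\n")
        profile = ColumnProfile(species="taxon", latitude="lat", longitude="lon")
        occ, _ = read_occurrences(path, Source.LITERATURE, profile)
        assert occ.records_for("a b")[0].source is Source.LITERATURE

    def test_per_source_counts_seven_and_sixteen(self, write_csv):
        """One species split 7 literature / 16 GBIF stays split after merge."""
        lit = write_csv(
            "lit.csv",
            "species,latitude,longitude\n"
            + "".join(f"a b,{40 + i * 0.01},-3.0\n" for i in range(7)),
        )
        gbif = write_csv(
            "gbif.csv",
            "species,decimalLatitude,decimalLongitude\n"
            + "".join(f"a b,{40 + i * 0.01},-2.0\n" for i in range(16)),
        )
        occ_lit, _ = read_occurrences(lit, Source.LITERATURE)
        occ_gbif, _ = read_occurrences(gbif, Source.GBIF)
        merged = merge_sources(occ_lit, occ_gbif)
        records = merged.records_for("a b")
        assert len(records) == 23
        assert sum(r.source is Source.LITERATURE for r in records) == 7
        assert sum(r.source is Source.GBIF for r in records) == 16


class TestRoundTrip:
    def test_write_read_preserves_everything(self, tmp_path):
        occ = make_set(
            [
                make_record("a b", 40.123456, -3.654321, Source.LITERATURE, "r1"),
                make_record("a b", None, None, Source.GBIF, "r2"),
                make_record("c d", -10.5, 170.25, Source.GBIF, "r3"),
            ]
        )
        path = tmp_path / "out.csv"
        write_occurrences(occ, path)
        back = read_canonical(path)
        assert back.species == occ.species
        assert len(back) == len(occ)
        for sp in occ.species:
            for orig, rt in zip(occ.records_for(sp), back.records_for(sp)):
                assert rt.source is orig.source
                if orig.latitude is None:
                    assert rt.latitude is None
                else:
                    assert rt.latitude == pytest.approx(orig.latitude, abs=1e-6)
                    assert rt.longitude == pytest.approx(orig.longitude, abs=1e-6)


class TestFilterGeoreferenced:
    def test_identity_when_all_georeferenced(self):
        occ = make_set([make_record(record_id=f"r{i}") for i in range(4)])
        out, dropped = filter_georeferenced(occ)
        assert len(out) == 4
        assert sum(dropped.values()) == 0

    def test_species_with_no_coordinates_retained_empty(self):
        occ = make_set([make_record("a b", None, None)])
        out, dropped = filter_georeferenced(occ)
        assert "a b" in out
        assert out.records_for("a b") == []
        assert dropped["a b"] == 1

    def test_counts(self):
        occ = make_set(
            [make_record(record_id=f"g{i}") for i in range(3)]
            + [make_record(lat=None, lon=None, record_id=f"n{i}") for i in range(2)]
        )
        out, dropped = filter_georeferenced(occ)
        assert len(out) == 3
        assert sum(dropped.values()) == 2

    def test_idempotent(self):
        occ = make_set(
            [make_record(record_id="a"), make_record(lat=None, lon=None, record_id="b")]
        )
        once, _ = filter_georeferenced(occ)
        twice, dropped = filter_georeferenced(once)
        assert [r.record_id for r in twice.all_records()] == [
            r.record_id for r in once.all_records()
        ]
        assert sum(dropped.values()) == 0


class TestRegion:
    square = [(0.0, 0.0), (4.0, 0.0), (4.0, 4.0), (0.0, 4.0)]

    def test_degenerate_region_fatal(self):
        with pytest.raises(ValueError):
            RegionBoundary([(0, 0), (1, 1)])
        with pytest.raises(ValueError):
            RegionBoundary([(0, 0), (1, 1), (2, 2)])

    def test_centroid_inside(self):
        region = RegionBoundary(self.square)
        occ = make_set([make_record(lat=2.0, lon=2.0)])
        assert flag_out_of_region(occ, region) == [("r0", True)]

    def test_far_point_outside(self):
        region = RegionBoundary(self.square)
        occ = make_set([make_record(lat=14.0, lon=2.0)])
        assert flag_out_of_region(occ, region) == [("r0", False)]

    def test_boundary_point_counts_inside(self):
        region = RegionBoundary(self.square)
        occ = make_set([make_record(lat=0.0, lon=2.0)])
        assert flag_out_of_region(occ, region) == [("r0", True)]

    def test_requires_georeferenced(self):
        region = RegionBoundary(self.square)
        occ = make_set([make_record(lat=None, lon=None)])
        with pytest.raises(ValueError, match="georeferenced"):
            flag_out_of_region(occ, region)


class TestMerge:
    def test_merge_with_empty_is_identity(self):
        occ = make_set([make_record(record_id="a"), make_record("c d", record_id="b")])
        merged = merge_sources(occ, OccurrenceSet())
        assert len(merged) == 2
        assert merged.species == occ.species

    def test_species_only_in_second_appears(self):
        a = make_set([make_record("a b")])
        b = make_set([make_record("c d", source=Source.GBIF)])
        merged = merge_sources(a, b)
        assert "c d" in merged

    def test_no_deduplication(self):
        r = make_record()
        merged = merge_sources(make_set([r]), make_set([r]))
        assert len(merged.records_for(r.species)) == 2


@st.composite
def record_lists(draw):
    n = draw(st.integers(0, 8))
    out = []
    for i in range(n):
        sp = draw(st.sampled_from(["a b", "c d", "e f"]))
        geo = draw(st.booleans())
        lat = draw(st.floats(-89, 89)) if geo else None
        lon = draw(st.floats(-179, 179)) if geo else None
        src = draw(st.sampled_from(list(Source)))
        out.append(make_record(sp, lat, lon, src, record_id=f"id{i}"))
    return out


@settings(max_examples=50, deadline=None)
@given(record_lists(), record_lists())
def test_merge_commutative_in_record_multisets(ra, rb):
    a, b = make_set(ra), make_set(rb)
    ab, ba = merge_sources(a, b), merge_sources(b, a)
    key = lambda occ, sp: sorted(
        (r.record_id, r.source.value, repr(r.latitude), repr(r.longitude))
        for r in occ.records_for(sp)
    )
    assert set(ab.species) == set(ba.species)
    for sp in ab.species:
        assert key(ab, sp) == key(ba, sp)


@settings(max_examples=50, deadline=None)
@given(record_lists(), record_lists(), record_lists())
def test_merge_associative_in_record_multisets(ra, rb, rc):
    a, b, c = make_set(ra), make_set(rb), make_set(rc)
    left = merge_sources(merge_sources(a, b), c)
    right = merge_sources(a, merge_sources(b, c))
    key = lambda occ, sp: sorted(
        (r.record_id, r.source.value, repr(r.latitude), repr(r.longitude))
        for r in occ.records_for(sp)
    )
    assert set(left.species) == set(right.species)
    for sp in left.species:
        assert key(left, sp) == key(right, sp)


@settings(max_examples=50, deadline=None)
@given(record_lists())
def test_filter_georeferenced_is_idempotent(records):
    occ = make_set(records)
    once, dropped = filter_georeferenced(occ)
    twice, dropped2 = filter_georeferenced(once)
    assert sum(dropped.values()) == len(occ) - len(once)
    assert sum(dropped2.values()) == 0
    assert [r.record_id for r in twice.all_records()] == [
        r.record_id for r in once.all_records()
    ]
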