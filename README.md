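# eooassess

Extent-of-occurrence (EOO) assessment from multi-source species occurrence
records. The pipeline reads GBIF-style and literature-style occurrence CSVs,
computes each species' minimum convex polygon and its area on the authalic
sphere, maps the area to a hypothetical Red List category with strict
(`<`) thresholds (CR < 100 km², EN < 5,000 km², VU < 20,000 km²,
NT < 30,000 km², otherwise LC; undefined EOO → DD), and compares the
categories obtained from literature records alone, GBIF records alone, and
the combined record set. A synthetic-data generator with known elliptical
true ranges makes every stage testable without downloads.

## Library overview

- `eooassess.occurrences` — CSV ingest (Darwin Core `decimalLatitude` /
  `decimalLongitude` or configurable column maps), georeference filtering,
  region flagging, source merging.
- `eooassess.geometry` — convex hull in planar lon/lat and exact spherical
  area of the chart polygon (R = 6371.0072 km); fewer than three data
  points leave the EOO undefined.
- `eooassess.redlist` — strict-threshold categorisation; thresholds
  overridable from YAML/JSON.
- `eooassess.comparison` — per-mode assessments, per-species shift flags
  (newly assessable, changed among assessed, downgrade/upgrade) and
  category-by-source summary tables with pooling.
- `eooassess.synthetic` — seeded generator of occurrence sets with known
  true range polygons, two source labels, and missing coordinates, plus a
  parameter-recovery confusion matrix.

## CLI

```bash
# generate a synthetic dataset (writes occurrences, per-source CSVs, truth)
eooassess synth --n-species 100 --seed 42 --out runs/synth

# assess and compare literature / GBIF / combined modes
eooassess assess --literature runs/synth/literature.csv \
                 --gbif runs/synth/gbif.csv --out runs/assess

# confusion matrix of true vs estimated categories
eooassess recover --occurrences runs/synth/occurrences.csv \
                  --truth runs/synth/truth.csv --out runs/recover
```

`assess` writes `assessments.csv`, `comparison.csv`, a `summary.csv` shaped
as category rows × source-mode columns, optional `hulls.geojson`, and a
`manifest.json` with per-stage record accounting and derived percentages.
Options may also be given in a YAML file via `--config`; flags win.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes brute-force hull oracles, closed-form and Monte-Carlo
area oracles, property tests (hypothesis) for merge/filter/hull/classifier
invariants, and an acceptance suite (`tests/test_acceptance.py`).

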