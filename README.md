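# fairtables

Structural metadata, validation, identifier-driven merging, datapackage
export and a read-only query API for **multi-table experimental data**.

## The problem

A designed experiment — say, several hundred greenhouse plants under a
treatment × developmental-stage factorial — produces a family of flat data
tables acquired at different times: a plants table, a samples table, and
assay tables (biochemistry, metabolomics, ...) that arrive weeks later,
keyed by sample identifiers. In practice these live in spreadsheets, and
linking an assay row back to its sample and plant is done by hand —
repeatedly, and error-prone.

`fairtables` replaces that manual handling with a small amount of
*structural metadata* captured as the data are produced:

- one TSV data table per observational entity (each variable a column,
  each observation a row);
- a **subsets** file: each table's key concept, its identifier column, and
  the table it *is obtained from* (a sample is obtained from a plant) —
  these parent links form a lineage forest;
- an **attributes** file: every column annotated with a category from a
  closed four-value vocabulary — `identifier`, `factor`, `quantitative`,
  `qualitative` — plus description, unit, data type, and an optional
  controlled-vocabulary term (IRI/CURIE, carried verbatim).

With the categories and links machine-readable, the library can validate
referential integrity, join any subset with its ancestors or siblings on
identifier columns, export the whole collection as a
[Frictionless-style datapackage](https://frictionlessdata.io/) descriptor
(extended with a per-field `category` property), and serve filtered,
merged views over HTTP — all without touching the data by hand.

## Worked example

Generate a seeded synthetic collection (12 plants × 2 treatments ×
3 stages, two assay tables), validate it, and pull a merged slice:

```sh
$ fairtables generate --seed 42 --out demo
generated 4 subsets in demo

$ fairtables validate --collection demo
no issues

$ fairtables report --collection demo
{
  "n_subsets": 4,
  "n_attributes": 22,
  "pct_attributes_with_cv_term": 100.0,
  "pct_subsets_with_cv_term": 100.0,
  "has_license": true,
  "has_title": true,
  "n_errors": 0,
  "n_warnings": 0
}

$ fairtables merge --collection demo --subset biochemistry \
    --filter Treatment=control --filter biochemistry_v01.min=2 | head -4
AssayID	SampleID	biochemistry_v01	biochemistry_v02	biochemistry_v03	biochemistry_v04	biochemistry_v05	PlantID	Stage	Treatment
B0_0003	S0003	2.409449	2.176661	1.06826	3.087128	1.596014	P001	S3	control
B0_0007	S0007	8.513453	0.666034	0.59915	0.443183	1.851469	P003	S1	control
B0_0008	S0008	3.092477	0.892305	0.431643	0.438462	1.916677	P003	S2	control
```

The merge walked the lineage (biochemistry → samples → plants), so each
assay row carries its sample's `Stage` and its plant's `Treatment` without
any manual joining; rows were then filtered to control plants with
`biochemistry_v01 ≥ 2`. The readiness report summarizes annotation
coverage (CV terms on every column and subset), the presence of a title
and license, and the validator's error/warning counts.

`fairtables export-datapackage --collection demo` writes
`datapackage.json`; `fairtables serve --collection demo` exposes
`/api/{collection}/metadata`, `/api/{collection}/data/{subset}` and
`/api/{collection}/merged?subsets=a,b` (described by
`/api/openapi.json`), returning TSV or JSON.

The same operations are available as library calls:

```python
from fairtables import load_collection, validate_collection, lineage_merge

collection = load_collection("demo")
assert not validate_collection(collection)
table = lineage_merge(collection, "metabolomics")
```

## Validation rules

Errors V01–V08 break the machine contract (missing tables, dictionary
mismatches, bad identifiers, duplicate keys, referential orphans,
out-of-vocabulary categories, cast failures, lineage defects); warnings
V09–V12 flag reuse-readiness gaps (missing identifier cells, missing CV
terms or units, multiple lineage roots). The `validate` command exits 0
when only warnings remain, 1 on errors — stable for CI use.

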