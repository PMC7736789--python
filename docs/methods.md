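# Methods

## The data model

A *collection* is a set of flat, typed tables — one per observational
entity — tied together by two kinds of structural metadata:

1. **Subset definitions.** Each table (subset) has a short name, a file
   name, an entity label (its key concept: plant, sample, assay result),
   the name of its identifier column, and at most one *parent*: the
   subset it is obtained from. Parent links therefore form a **forest**
   (each node has at most one outgoing edge, no cycles). We deliberately
   model a single parent rather than a general DAG: experimental tables
   are acquired sequentially, and each one derives from exactly one
   earlier table. Multiple roots are allowed but flagged with a warning
   (V11), since most designs have a single origin table.

2. **Attribute definitions.** Every column carries a category from the
   closed vocabulary {`identifier`, `factor`, `quantitative`,
   `qualitative`}, a free-text description, a unit, a declared data type
   ({`string`, `integer`, `float`, `date`}), and an optional CV term.
   Quantitative columns must be numeric (integer/float). CV terms are
   opaque text (IRI or CURIE): they are stored and exported verbatim and
   never resolved — semantic lookup is out of scope by design.

Exactly one identifier attribute per subset is assumed; compound keys are
not modelled (no multi-column key appears in the motivating designs, and
single keys keep merge semantics unambiguous).

## File dialect and numeric choices

Tables and metadata are TSV: UTF-8, TAB delimiter, no quoting — a cell
may not contain a TAB or newline, and a violation is a parse error rather
than something to guess around. Missing cells are written `NA`; `NA` and
the empty string both parse as missing. Dates must be ISO-8601
(`YYYY-MM-DD`); anything else is a cast failure. Floats are serialized
with Python `repr`, the shortest round-trippable form, which is what
makes write→parse→write a byte-level fixed point.

Cast failures are **collected, not raised**: the offending cell becomes
missing and the failure is carried on the collection so the validator can
report every problem in one pass (code V07) instead of stopping at the
first bad cell.

The canonical serialization orders subsets topologically (parents first,
lexicographic tie-break) and attributes in declaration order within each
subset; categories are lowercased. This makes repeated writes
byte-identical, which in turn makes file-level diffing and the
determinism tests meaningful.

### Strict and lenient parsing

Parsers are strict by default: an out-of-vocabulary category, a table
header that disagrees with the dictionary, or a defective parent link
raises immediately. Loading a collection from disk, however, uses the
lenient path: the raw category label is kept, mismatched columns are read
as text, a defective lineage edge is dropped, and each tolerated problem
is recorded on the collection for the validator to report (V06, V02,
V08). The reasoning: a validator that can only be run on already-valid
input is useless; the loader must carry broken collections far enough for
the diagnostics to locate the break.

## Validation

Twelve fixed rules, each with a fixed severity (the mapping is not
configurable so exit codes stay stable in scripts and CI). Errors V01–V08
are exactly the conditions under which identifier-driven merging cannot
be trusted; this equivalence is tested directly — collections with zero
errors always merge, and every seeded single-violation injection is
detected at its injected location.

Two rules deserve a note:

- **V04 (duplicate identifier)** applies only to a subset's *own*
  identifier column. A parent identifier appearing in a child table (a
  foreign key) legitimately repeats — many samples per plant — so it is
  excluded. Missing-cell checks (V09) do apply to every
  identifier-category column, foreign keys included.
- **V05 vs V09.** A non-missing parent key that names no parent row is a
  referential error (V05). A *missing* parent key is only a warning
  (V09): tables are captured progressively, and early rows may not have
  their links filled in yet. Matching is exact, case-sensitive string
  comparison on the canonical cell text after whitespace trimming —
  silent case-folding would mask genuine data errors.
- **V07** is emitted for every collected cast failure, whatever the
  column's category: a malformed date or integer is as much a defect as a
  malformed measurement.

The FAIR-readiness report is a deliberately lightweight local summary
(annotation coverage, title/license presence, issue counts). It is not an
implementation of any published FAIR assessment grid, which require
repository-level and human context this library does not have.

## Merging

Lineage merges are **many-to-one left joins** from the most-derived
subset up its ancestor chain, keyed on each ancestor's identifier. Left,
not inner: a merge must never invent or drop observations, so the output
has exactly the starting subset's rows in their original order, with
missing parent keys yielding missing ancestor columns. Cross-subset
merges first lineage-merge each target through the ancestors strictly
below the lowest common ancestor (so each partial result carries the LCA's
identifier column), then **inner-join** the partials pairwise left to
right on that identifier — cross-assay analysis naturally restricts to
commonly measured units. The LCA's own columns enter only when the LCA is
itself one of the targets.

Column collisions across the joined tables are disambiguated with a
`subsetname.` prefix; join-key identifier columns are kept once,
unprefixed. Renames are injective, so the mapping is reversible.

Join-key comparison uses the same canonical-text equality as the
validator. The implementation builds object-dtype pandas frames and
performs the key lookups explicitly (hash map for left joins, grouped
scan for inner joins) so that row order, cell types and missing-value
behavior are exactly specified; the tests compare its output byte-for-byte
against an independent brute-force nested-loop join oracle.

Filters are equality on canonical cell text or closed numeric intervals
(unbounded sides allowed); missing cells never satisfy any predicate, and
interval predicates on non-numeric columns are rejected.

## Datapackage export

The descriptor follows the Tabular Data Package v1 layout: one resource
per subset (topological order) with `path`, an ordered field schema,
`primaryKey`, and `foreignKeys` encoding the parent links. The
four-value column vocabulary rides on a single custom field property,
`category`; CV terms map to the standard `rdfType` slot rather than a
second custom key. Descriptive metadata (title, license, contributors)
pass through untouched in both directions — the descriptor's job is
interoperability and reusability of the structure, findability is the
repository's.

Export refuses a collection with validation errors (a `--force` override
exists): broken structure should not be disseminated.

`check_descriptor` implements the profile constraints as an explicit,
self-contained rule set (required keys, admissible field types, category
vocabulary, primaryKey/foreignKey referential soundness) and returns a
list of located violations. The same approach is used for the OpenAPI
3.0 document served by the query API: a structural checker for the
constraints the document can actually violate. Both checkers are
intentionally small and readable rather than schema-engine-driven.

## Query service

A pure-view WSGI application (served with the standard library's
`wsgiref` server from the CLI): three GET routes over loaded collections,
plus the OpenAPI description. `data/{subset}` returns the lineage-merged
table with filters applied in request order; `merged` returns the
cross-subset join. Filters arrive as query parameters (`attr=value`,
`attr.min=`/`attr.max=`). Responses are TSV (the same dialect the loader
reads — self-consumability is tested) or JSON arrays of objects. No
endpoint mutates state; identical requests return byte-identical bodies.
Authentication and write endpoints are out of scope: the service exists
to disseminate.

## Synthetic collections

The generator emulates the shape of a multifactorial greenhouse study:

| parameter | default | meaning |
|---|---|---|
| `n_plants` | 12 | rows of the root table |
| `treatments` | control, stressed | plant-level factor, assigned round-robin |
| `stages` | S1, S2, S3 | sample-level factor |
| `samples_per_plant_stage` | 1 | replicates per plant × stage |
| `assays` | 2 (5 and 8 variables) | leaf tables, one row per sample |
| lognormal (meanlog, sdlog) | (0, 1) and (1, 0.5) | assay value distributions |
| `missing_rate` | 0.05 | per-cell masking probability in assay variables |
| `cv_annotation_rate` | 1.0 | probability an attribute gets a placeholder CURIE |

Round-robin treatment assignment (rather than random) makes factor
balance exact and testable. Lognormal values give metabolite-like
positive, right-skewed data. Placeholder CURIEs (`EX:0000001`, ...) stand
in for ontology terms because terms are carried verbatim — realism would
add nothing the code path can see. Everything derives from one seeded
`numpy` generator, so identical spec + seed means byte-identical
directories.

What the generator does **not** emulate: measurement-error structure,
batch effects, realistic metabolite ranges, unbalanced or nested designs,
or messy real-world spreadsheet quirks (merged cells, locale decimal
commas, encoding drift). Passing tests therefore demonstrate the
machinery's correctness on well-formed and minimally corrupted
collections, not robustness to arbitrary spreadsheet abuse.

The violation injector applies the smallest edit that produces one
specific rule violation (delete a data file for V01, rewrite one foreign
key to an unseen value for V05, one category label to `covariate` for
V06, ...), choosing the edit site pseudo-randomly from a seed and
returning the expected diagnostic. Injections target leaf tables where a
single edit could otherwise cascade (duplicating a plant identifier would
orphan its samples), keeping each injected collection a clean test of
exactly one rule.

## Problem sizes

Tests and the acceptance script run on small instances — typically 3–12
plants, 9–36 samples, two assays — chosen so that the brute-force oracles
(nested-loop joins, exhaustive path enumeration) remain the obviously
correct reference and the full suite stays fast. The properties being
checked (round-trip identity, oracle equivalence, injection detection)
are size-independent structural guarantees, so small instances lose no
generality.

## Known limitations

- Single-column identifiers only; no compound keys.
- One parent per subset; genuinely multi-parent derivations (a pooled
  sample drawn from several plants) cannot be expressed.
- The lineage-merge direction is fixed (child-preserving left joins);
  there is no full-outer cross merge yet.
- The datapackage and OpenAPI checkers cover the constraints this model
  emits, not the full breadth of either specification.
- No streaming: tables are loaded whole, which is fine for the intended
  scale (thousands of rows) and wrong for millions.
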