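"""Seeded generator of realistic multi-table study collections.

The generator emulates the shape of a greenhouse multifactorial experiment:
plants grown under a set of treatments, sampled at several developmental
stages, with downstream assay tables (biochemical / metabolomic variables)
keyed by sample identifiers.  It produces:

* ``plants`` — one row per plant; ``Treatment`` factor assigned round-robin
  so factor balance is exact and testable;
* ``samples`` — one row per plant × stage × replicate; ``Stage`` factor and
  the ``PlantID`` foreign key;
* one subset per assay — one row per sample, with quantitative variables
  drawn from a lognormal (metabolite-like positive, right-skewed values)
  and cells masked to missing with a fixed probability.

CV terms are placeholder CURIEs (``EX:0000001`` ...): terms are carried
verbatim and never resolved, so ontological realism is unnecessary.
Everything is deterministic given the seed — the same spec written twice
yields byte-identical directories.

A companion *violation injector* applies the minimal edit that produces
exactly one validation rule violation (V01–V12), returning the expected
diagnostic, so the validator can be exercised in a closed loop.
"""

from __future__ import annotations

import random
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .datamodel import (
    AttributeDef,
    Category,
    DataTable,
    DatasetCollection,
    SubsetDef,
    build_linkage_graph,
)
from .errors import InvalidSpecError, UnsupportedCodeError
from .metadata_io import load_collection, write_collection
from .validator import SEVERITY, ValidationIssue

__all__ = ["AssaySpec", "GeneratorSpec", "generate_collection", "inject_violation"]


@dataclass(frozen=True)
class AssaySpec:
    """One downstream assay table: quantitative variables with lognormal
    (meanlog, sdlog) values."""

    name: str
    n_variables: int
    meanlog: float = 0.0
    sdlog: float = 1.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic collection.

    Defaults mirror a desk-scale version of a two-treatment, three-stage
    greenhouse design with two assay tables.
    """

    seed: int = 0
    n_plants: int = 12
    treatments: tuple[str, ...] = ("control", "stressed")
    stages: tuple[str, ...] = ("S1", "S2", "S3")
    samples_per_plant_stage: int = 1
    assays: tuple[AssaySpec, ...] = (
        AssaySpec("biochemistry", 5, meanlog=0.0, sdlog=1.0),
        AssaySpec("metabolomics", 8, meanlog=1.0, sdlog=0.5),
    )
    missing_rate: float = 0.05
    cv_annotation_rate: float = 1.0
    license_present: bool = True

    def __post_init__(self):
        if self.n_plants < 1:
            raise InvalidSpecError("n_plants must be >= 1")
        if not self.treatments or not self.stages:
            raise InvalidSpecError("need at least 1 treatment and 1 stage")
        if self.samples_per_plant_stage < 1:
            raise InvalidSpecError("samples_per_plant_stage must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidSpecError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.cv_annotation_rate <= 1.0:
            raise InvalidSpecError("cv_annotation_rate must be in [0, 1]")
        if any(a.n_variables < 1 for a in self.assays):
            raise InvalidSpecError("assay n_variables must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_plants * len(self.stages) * self.samples_per_plant_stage


def generate_collection(
    spec: GeneratorSpec, out_dir: str | Path | None = None
) -> DatasetCollection:
    """Generate a collection (optionally written to ``out_dir``).

    The result always passes validation with zero errors; with the default
    annotation/unit settings it is warning-free as well.
    """
    rng = np.random.default_rng(spec.seed)

    plant_ids = [f"P{i + 1:03d}" for i in range(spec.n_plants)]
    plants = DataTable(
        column_names=["PlantID", "Treatment"],
        rows=[
            [pid, spec.treatments[i % len(spec.treatments)]]
            for i, pid in enumerate(plant_ids)
        ],
    )

    sample_rows = []
    n = 0
    for pid in plant_ids:
        for stage in spec.stages:
            for _ in range(spec.samples_per_plant_stage):
                n += 1
                sample_rows.append([f"S{n:04d}", pid, stage])
    samples = DataTable(column_names=["SampleID", "PlantID", "Stage"],
                        rows=sample_rows)
    sample_ids = [row[0] for row in sample_rows]

    tables: dict[str, DataTable] = {"plants": plants, "samples": samples}
    subsets = [
        SubsetDef("plants", "plants.txt", "plant", "PlantID", ""),
        SubsetDef("samples", "samples.txt", "sample", "SampleID", "plants"),
    ]
    attributes: list[AttributeDef] = [
        AttributeDef("plants", "PlantID", Category.IDENTIFIER,
                     "plant identifier", "", "string"),
        AttributeDef("plants", "Treatment", Category.FACTOR,
                     "treatment applied to the plant", "", "string"),
        AttributeDef("samples", "SampleID", Category.IDENTIFIER,
                     "sample identifier", "", "string"),
        AttributeDef("samples", "PlantID", Category.IDENTIFIER,
                     "plant the sample was taken from", "", "string"),
        AttributeDef("samples", "Stage", Category.FACTOR,
                     "developmental stage at sampling", "", "string"),
    ]

    for a_idx, assay in enumerate(spec.assays):
        prefix = assay.name[:1].upper()
        var_names = [f"{assay.name}_v{j + 1:02d}" for j in range(assay.n_variables)]
        values = rng.lognormal(assay.meanlog, assay.sdlog,
                               size=(len(sample_ids), assay.n_variables))
        mask = rng.random(values.shape) < spec.missing_rate
        rows = []
        for i, sid in enumerate(sample_ids):
            row: list = [f"{prefix}{a_idx}_{i + 1:04d}", sid]
            for j in range(assay.n_variables):
                row.append(None if mask[i, j] else float(round(values[i, j], 6)))
            rows.append(row)
        tables[assay.name] = DataTable(
            column_names=["AssayID", "SampleID"] + var_names, rows=rows)
        subsets.append(SubsetDef(assay.name, f"{assay.name}.txt",
                                 "assay result", "AssayID", "samples"))
        attributes.append(AttributeDef(assay.name, "AssayID",
                                       Category.IDENTIFIER,
                                       "assay result identifier", "", "string"))
        attributes.append(AttributeDef(assay.name, "SampleID",
                                       Category.IDENTIFIER,
                                       "sample the measurement was made on",
                                       "", "string"))
        for v in var_names:
            attributes.append(AttributeDef(
                assay.name, v, Category.QUANTITATIVE,
                f"{assay.name} variable {v}", "a.u.", "float"))

    # CV-term annotation (placeholder CURIEs), deterministic draw order
    annotated: list[AttributeDef] = []
    term = 0
    for a in attributes:
        term += 1
        if rng.random() < spec.cv_annotation_rate:
            annotated.append(replace(a, cv_term=f"EX:{term:07d}"))
        else:
            annotated.append(a)
    attributes = annotated
    subsets = [replace(s, cv_term=f"EX:S{i + 1:06d}")
               for i, s in enumerate(subsets)]

    descriptive = {
        "name": f"synthetic-study-seed{spec.seed}",
        "title": "Synthetic multifactorial greenhouse study",
        "contributors": [{"title": "fairtables synthetic generator"}],
    }
    if spec.license_present:
        descriptive["license"] = "CC-BY-4.0"

    collection = DatasetCollection(
        subsets=subsets,
        attributes=attributes,
        tables=tables,
        graph=build_linkage_graph(subsets),
        descriptive=descriptive,
    )
    if out_dir is not None:
        write_collection(collection, out_dir)
    return collection


# ---------------------------------------------------------------- injector
def inject_violation(
    src_dir: str | Path, code: str, seed: int, dst_dir: str | Path
) -> tuple[Path, ValidationIssue]:
    """Copy a clean on-disk collection and apply the minimal edit that
    produces exactly one violation of ``code``.

    Returns the corrupted copy's path and the expected diagnostic (code +
    location).  The edit site is chosen pseudo-randomly from ``seed``.
    Raises :class:`UnsupportedCodeError` for unknown codes.
    """
    if code not in SEVERITY:
        raise UnsupportedCodeError(f"unknown rule code {code!r}")
    src, dst = Path(src_dir), Path(dst_dir)
    if dst.exists():
        shutil.rmtree(dst)
    shutil.copytree(src, dst)
    rnd = random.Random(seed)
    collection = load_collection(src)
    injector = _INJECTORS.get(code)
    if injector is None:
        raise UnsupportedCodeError(f"no injector for rule code {code!r}")
    expected = injector(collection, dst, rnd)
    return dst, expected


def _expected(code: str, subset: str = "", attribute: str = "",
              row: int | None = None) -> ValidationIssue:
    return ValidationIssue(code=code, severity=SEVERITY[code], subset=subset,
                           attribute=attribute, row=row,
                           message=f"injected {code}")


def _leaf_assay(collection: DatasetCollection, rnd: random.Random) -> SubsetDef:
    leaves = [s for s in collection.subsets
              if not collection.graph.children(s.subset_name)]
    return rnd.choice(sorted(leaves, key=lambda s: s.subset_name))


def _table_lines(dst: Path, file_name: str) -> list[str]:
    return (dst / file_name).read_text("utf-8").splitlines()


def _write_lines(dst: Path, file_name: str, lines: list[str]) -> None:
    (dst / file_name).write_text("\n".join(lines) + "\n", "utf-8")


def _edit_cell(dst: Path, file_name: str, row: int, col: int, value: str) -> None:
    """row is the 1-based data-row number (header excluded)."""
    lines = _table_lines(dst, file_name)
    cells = lines[row].split("\t")
    cells[col] = value
    lines[row] = "\t".join(cells)
    _write_lines(dst, file_name, lines)


def _inject_v01(collection, dst, rnd):
    s = _leaf_assay(collection, rnd)
    (dst / s.file_name).unlink()
    return _expected("V01", subset=s.subset_name)


def _inject_v02(collection, dst, rnd):
    s = _leaf_assay(collection, rnd)
    lines = _table_lines(dst, s.file_name)
    lines = [line + "\tUndeclared" for line in lines]
    _write_lines(dst, s.file_name, lines)
    return _expected("V02", subset=s.subset_name, attribute="Undeclared")


def _inject_v03(collection, dst, rnd):
    s = _leaf_assay(collection, rnd)
    _rewrite_attribute_row(dst, s.subset_name, s.identifier_attribute,
                           category="qualitative")
    return _expected("V03", subset=s.subset_name,
                     attribute=s.identifier_attribute)


def _inject_v04(collection, dst, rnd):
    s = _leaf_assay(collection, rnd)
    table = collection.tables[s.subset_name]
    col = table.column_index(s.identifier_attribute)
    r = rnd.randrange(1, table.n_rows)  # 1-based row to overwrite (not row 1)
    first = table.rows[0][col]
    _edit_cell(dst, s.file_name, r + 1, col, str(first))
    return _expected("V04", subset=s.subset_name,
                     attribute=s.identifier_attribute, row=r + 1)


def _inject_v05(collection, dst, rnd):
    table = collection.tables["samples"]
    col = table.column_index("PlantID")
    r = rnd.randrange(table.n_rows)
    _edit_cell(dst, "samples.txt", r + 1, col, "Pzzz999")
    return _expected("V05", subset="samples", attribute="PlantID", row=r + 1)


def _inject_v06(collection, dst, rnd):
    s = _leaf_assay(collection, rnd)
    quant = [a for a in collection.attributes_for(s.subset_name)
             if a.category == Category.QUANTITATIVE]
    a = rnd.choice(quant)
    _rewrite_attribute_row(dst, a.subset_name, a.attribute_name,
                           category="covariate")
    return _expected("V06", subset=a.subset_name, attribute=a.attribute_name)


def _inject_v07(collection, dst, rnd):
    s = _leaf_assay(collection, rnd)
    table = collection.tables[s.subset_name]
    quant_cols = [i for i, c in enumerate(table.column_names)
                  if collection.attribute(s.subset_name, c).category
                  == Category.QUANTITATIVE]
    col = rnd.choice(quant_cols)
    r = rnd.randrange(table.n_rows)
    _edit_cell(dst, s.file_name, r + 1, col, "not-a-number")
    return _expected("V07", subset=s.subset_name,
                     attribute=table.column_names[col], row=r + 1)


def _inject_v08(collection, dst, rnd):
    s = _leaf_assay(collection, rnd)
    _rewrite_subset_row(dst, s.subset_name, parent="no_such_subset")
    return _expected("V08", subset=s.subset_name)


def _inject_v09(collection, dst, rnd):
    s = _leaf_assay(collection, rnd)
    table = collection.tables[s.subset_name]
    col = table.column_index(s.identifier_attribute)
    r = rnd.randrange(table.n_rows)
    _edit_cell(dst, s.file_name, r + 1, col, "NA")
    return _expected("V09", subset=s.subset_name,
                     attribute=s.identifier_attribute, row=r + 1)


def _inject_v10(collection, dst, rnd):
    s = _leaf_assay(collection, rnd)
    attrs = collection.attributes_for(s.subset_name)
    a = rnd.choice(attrs)
    _rewrite_attribute_row(dst, a.subset_name, a.attribute_name, cv_term="")
    return _expected("V10", subset=a.subset_name, attribute=a.attribute_name)


def _inject_v11(collection, dst, rnd):
    _rewrite_subset_row(dst, "samples", parent="")
    return _expected("V11")


def _inject_v12(collection, dst, rnd):
    s = _leaf_assay(collection, rnd)
    quant = [a for a in collection.attributes_for(s.subset_name)
             if a.category == Category.QUANTITATIVE]
    a = rnd.choice(quant)
    _rewrite_attribute_row(dst, a.subset_name, a.attribute_name, unit="")
    return _expected("V12", subset=a.subset_name, attribute=a.attribute_name)


_INJECTORS = {
    "V01": _inject_v01, "V02": _inject_v02, "V03": _inject_v03,
    "V04": _inject_v04, "V05": _inject_v05, "V06": _inject_v06,
    "V07": _inject_v07, "V08": _inject_v08, "V09": _inject_v09,
    "V10": _inject_v10, "V11": _inject_v11, "V12": _inject_v12,
}


def _rewrite_attribute_row(dst: Path, subset: str, attribute: str, **fields):
    from .metadata_io import ATTRIBUTE_COLUMNS

    lines = _table_lines(dst, "attributes.tsv")
    header = lines[0].split("\t")
    idx = {c: header.index(c) for c in ATTRIBUTE_COLUMNS}
    for i, line in enumerate(lines[1:], start=1):
        cells = line.split("\t")
        if cells[idx["subset"]] == subset and cells[idx["attribute"]] == attribute:
            for key, value in fields.items():
                cells[idx[key]] = value
            lines[i] = "\t".join(cells)
            break
    else:
        raise AssertionError(f"attribute row {subset}/{attribute} not found")
    _write_lines(dst, "attributes.tsv", lines)


def _rewrite_subset_row(dst: Path, subset: str, **fields):
    from .metadata_io import SUBSET_COLUMNS

    lines = _table_lines(dst, "subsets.tsv")
    header = lines[0].split("\t")
    idx = {c: header.index(c) for c in SUBSET_COLUMNS}
    for i, line in enumerate(lines[1:], start=1):
        cells = line.split("\t")
        if cells[idx["subset"]] == subset:
            for key, value in fields.items():
                cells[idx[key]] = value
            lines[i] = "\t".join(cells)
            break
    else:
        raise AssertionError(f"subset row {subset} not found")
    _write_lines(dst, "subsets.tsv", lines)
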