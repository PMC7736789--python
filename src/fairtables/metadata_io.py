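"""Reading and writing collections on disk.

A collection directory holds one TSV data table per entity plus two
structural-metadata files: a *subsets* file (one row per table: name, file,
key concept, identifier column, parent link, CV term) and an *attributes*
file (one row per column: category, description, unit, data type, CV term).
An optional ``descriptive.json`` carries the descriptive block (title,
license, authors) that exports pass through.

Dialect: UTF-8, TAB delimiter, no quoting — a cell may not contain a TAB or
newline.  Missing values are written as ``NA``; both ``NA`` and the empty
string parse as missing.  Dates must be ISO-8601 (``YYYY-MM-DD``).
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

from .datamodel import (
    AttributeDef,
    CastFailure,
    Category,
    Cell,
    DataTable,
    DatasetCollection,
    LinkageGraph,
    SubsetDef,
    build_linkage_graph,
    topological_order,
)
from .errors import (
    CycleDetectedError,
    DuplicateAttributeError,
    DuplicateSubsetError,
    EmptyDocumentError,
    FairTablesError,
    FileNotFoundCollectionError,
    MissingHeaderColumnError,
    SelfParentError,
    UnknownCategoryError,
    UnknownParentError,
)

__all__ = [
    "CollectionLayout",
    "parse_subsets_metadata",
    "parse_attributes_metadata",
    "read_data_table",
    "load_collection",
    "write_structural_metadata",
    "write_collection",
    "format_cell",
    "format_data_table",
    "subsets_to_text",
    "attributes_to_text",
]

SUBSET_COLUMNS = ("subset", "file", "entity", "identifier", "parent", "cv_term")
ATTRIBUTE_COLUMNS = (
    "subset",
    "attribute",
    "category",
    "description",
    "unit",
    "type",
    "cv_term",
)
DESCRIPTIVE_FILE = "descriptive.json"


@dataclass(frozen=True)
class CollectionLayout:
    """File-naming and dialect conventions of a collection directory."""

    subsets_file: str = "subsets.tsv"
    attributes_file: str = "attributes.tsv"
    encoding: str = "utf-8"
    missing_tokens: tuple[str, ...] = ("", "NA")


DEFAULT_LAYOUT = CollectionLayout()


# ---------------------------------------------------------------- TSV core
def _split_rows(document: str) -> list[list[str]]:
    return [line.split("\t") for line in document.splitlines()]


def _header_index(header: list[str], required: tuple[str, ...]) -> dict[str, int]:
    index = {}
    for col in required:
        if col not in header:
            raise MissingHeaderColumnError(col)
        index[col] = header.index(col)
    return index


def _cell(row: list[str], idx: int) -> str:
    return row[idx].strip() if idx < len(row) else ""


# ---------------------------------------------------------------- metadata
def parse_subsets_metadata(document: str) -> list[SubsetDef]:
    """Parse the subsets metadata file.

    Required header columns: ``subset file entity identifier parent
    cv_term``; extra columns are preserved verbatim in ``SubsetDef.extras``.
    An empty parent cell marks a root.  Row order is preserved.
    """
    rows = _split_rows(document)
    if not rows:
        raise EmptyDocumentError("subsets metadata document is empty")
    header = [h.strip() for h in rows[0]]
    idx = _header_index(header, SUBSET_COLUMNS)
    extra_cols = [(h, i) for i, h in enumerate(header) if h not in SUBSET_COLUMNS]
    data_rows = [r for r in rows[1:] if any(c.strip() for c in r)]
    if not data_rows:
        raise EmptyDocumentError("subsets metadata document has no data rows")

    defs: list[SubsetDef] = []
    seen: set[str] = set()
    for row in data_rows:
        name = _cell(row, idx["subset"])
        if name in seen:
            raise DuplicateSubsetError(f"subset {name!r} declared twice")
        seen.add(name)
        defs.append(
            SubsetDef(
                subset_name=name,
                file_name=_cell(row, idx["file"]),
                entity_label=_cell(row, idx["entity"]),
                identifier_attribute=_cell(row, idx["identifier"]),
                parent_subset=_cell(row, idx["parent"]),
                cv_term=_cell(row, idx["cv_term"]),
                extras=tuple(sorted((h, _cell(row, i)) for h, i in extra_cols)),
            )
        )
    return defs


def parse_attributes_metadata(document: str, strict: bool = True) -> list[AttributeDef]:
    """Parse the attributes metadata file.

    Category labels are matched case-insensitively and canonicalized to
    lowercase.  With ``strict=True`` an out-of-vocabulary category raises
    :class:`UnknownCategoryError`; with ``strict=False`` the raw label is
    kept so the validator can report it (rule V06).
    """
    rows = _split_rows(document)
    if not rows:
        raise EmptyDocumentError("attributes metadata document is empty")
    header = [h.strip() for h in rows[0]]
    idx = _header_index(header, ATTRIBUTE_COLUMNS)
    data_rows = [r for r in rows[1:] if any(c.strip() for c in r)]
    if not data_rows:
        raise EmptyDocumentError("attributes metadata document has no data rows")

    defs: list[AttributeDef] = []
    seen: set[tuple[str, str]] = set()
    for row in data_rows:
        subset = _cell(row, idx["subset"])
        attr = _cell(row, idx["attribute"])
        if (subset, attr) in seen:
            raise DuplicateAttributeError(
                f"attribute {attr!r} declared twice for subset {subset!r}"
            )
        seen.add((subset, attr))
        label = _cell(row, idx["category"])
        try:
            category: Category | str = Category.parse(label)
        except UnknownCategoryError:
            if strict:
                raise
            category = label
        defs.append(
            AttributeDef(
                subset_name=subset,
                attribute_name=attr,
                category=category,
                description=_cell(row, idx["description"]),
                unit=_cell(row, idx["unit"]),
                data_type=_cell(row, idx["type"]) or "string",
                cv_term=_cell(row, idx["cv_term"]),
            )
        )
    return defs


# ---------------------------------------------------------------- tables
def _cast(text: str, data_type: str) -> Cell:
    if data_type == "integer":
        return int(text)
    if data_type == "float":
        return float(text)
    if data_type == "date":
        return datetime.date.fromisoformat(text)
    return text


def read_data_table(
    document: str,
    attrs: list[AttributeDef],
    subset_name: str = "",
    missing_tokens: tuple[str, ...] = DEFAULT_LAYOUT.missing_tokens,
    strict: bool = True,
) -> tuple[DataTable, list[CastFailure]]:
    """Read one TSV data table, casting cells per the attribute dictionary.

    The first row is the header; ``attrs`` must cover its column set
    exactly (:class:`ColumnMismatchError` otherwise, reporting both
    differences).  With ``strict=False`` a mismatched table still loads —
    undeclared columns are read as text — so the validator can report the
    discrepancy (rule V02).  Cast failures are always collected, not
    raised: the offending cell becomes missing and the failure is returned
    for the validator (rule V07).
    """
    from .errors import ColumnMismatchError

    rows = _split_rows(document)
    if not rows:
        raise EmptyDocumentError(f"data table {subset_name!r} is empty")
    header = [h.strip() for h in rows[0]]
    by_name = {a.attribute_name: a for a in attrs}
    missing_in_dict = set(header) - set(by_name)
    missing_in_table = set(by_name) - set(header)
    if strict and (missing_in_dict or missing_in_table):
        raise ColumnMismatchError(missing_in_dict, missing_in_table)

    types = [
        by_name[h].data_type if h in by_name else "string" for h in header
    ]
    failures: list[CastFailure] = []
    out_rows: list[list[Cell]] = []
    for r, raw in enumerate(rows[1:], start=1):
        cells: list[Cell] = []
        for c, dtype in enumerate(types):
            text = _cell(raw, c)
            if text in missing_tokens:
                cells.append(None)
                continue
            try:
                cells.append(_cast(text, dtype))
            except (ValueError, TypeError):
                failures.append(CastFailure(subset_name, header[c], r, text))
                cells.append(None)
        out_rows.append(cells)
    return DataTable(column_names=header, rows=out_rows), failures


def format_cell(cell: Cell) -> str:
    """Canonical text form of a cell (``NA`` for missing)."""
    if cell is None:
        return "NA"
    if isinstance(cell, bool):  # bool is an int subclass; be explicit
        return str(cell)
    if isinstance(cell, float):
        return repr(cell)
    if isinstance(cell, datetime.date):
        return cell.isoformat()
    return str(cell)


def format_data_table(table: DataTable) -> str:
    lines = ["\t".join(table.column_names)]
    for row in table.rows:
        lines.append("\t".join(format_cell(c) for c in row))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------- writing
def _category_text(category) -> str:
    return category.value if isinstance(category, Category) else str(category)


def subsets_to_text(collection: DatasetCollection) -> str:
    """Canonical subsets file: documented column order, rows in
    topological-then-declaration order, extras sorted after cv_term."""
    order = _canonical_subset_order(collection)
    extra_keys = sorted({k for s in collection.subsets for k, _ in s.extras})
    header = list(SUBSET_COLUMNS) + extra_keys
    lines = ["\t".join(header)]
    for name in order:
        s = collection.subset(name)
        extras = dict(s.extras)
        row = [
            s.subset_name,
            s.file_name,
            s.entity_label,
            s.identifier_attribute,
            s.parent_subset,
            s.cv_term,
        ] + [extras.get(k, "") for k in extra_keys]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def attributes_to_text(collection: DatasetCollection) -> str:
    order = _canonical_subset_order(collection)
    lines = ["\t".join(ATTRIBUTE_COLUMNS)]
    for name in order:
        for a in collection.attributes_for(name):
            lines.append(
                "\t".join(
                    [
                        a.subset_name,
                        a.attribute_name,
                        _category_text(a.category).lower(),
                        a.description,
                        a.unit,
                        a.data_type,
                        a.cv_term,
                    ]
                )
            )
    # attributes for subsets absent from the subsets list (defective input)
    known = set(order)
    for a in collection.attributes:
        if a.subset_name not in known:
            lines.append(
                "\t".join(
                    [
                        a.subset_name,
                        a.attribute_name,
                        _category_text(a.category).lower(),
                        a.description,
                        a.unit,
                        a.data_type,
                        a.cv_term,
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def _canonical_subset_order(collection: DatasetCollection) -> list[str]:
    try:
        return topological_order(collection.graph)
    except Exception:  # defective lineage: fall back to declaration order
        return collection.subset_names()


def write_structural_metadata(
    collection: DatasetCollection, root_dir: str | Path
) -> list[str]:
    """Write the two structural-metadata files; byte-stable across calls.

    Returns the written file names (always exactly two).
    """
    root = Path(root_dir)
    root.mkdir(parents=True, exist_ok=True)
    layout = DEFAULT_LAYOUT
    (root / layout.subsets_file).write_text(
        subsets_to_text(collection), encoding=layout.encoding
    )
    (root / layout.attributes_file).write_text(
        attributes_to_text(collection), encoding=layout.encoding
    )
    return [layout.subsets_file, layout.attributes_file]


def write_collection(collection: DatasetCollection, root_dir: str | Path) -> list[str]:
    """Write a full collection directory: structural metadata, every data
    table, and (when present) the descriptive block."""
    root = Path(root_dir)
    written = write_structural_metadata(collection, root)
    for s in collection.subsets:
        table = collection.tables.get(s.subset_name)
        if table is None:
            continue
        (root / s.file_name).write_text(
            format_data_table(table), encoding=DEFAULT_LAYOUT.encoding
        )
        written.append(s.file_name)
    if collection.descriptive:
        (root / DESCRIPTIVE_FILE).write_text(
            json.dumps(collection.descriptive, indent=2, sort_keys=True) + "\n",
            encoding=DEFAULT_LAYOUT.encoding,
        )
        written.append(DESCRIPTIVE_FILE)
    return written


# ---------------------------------------------------------------- loading
def load_collection(
    root_dir: str | Path, layout: CollectionLayout = DEFAULT_LAYOUT
) -> DatasetCollection:
    """Load a collection directory.

    Structural parse errors (bad headers, duplicates) are raised; semantic
    problems are tolerated and left for the validator: unknown categories
    (V06), defective lineage links (V08, the offending edge is dropped),
    missing data files (V01) and cast failures (V07) are all recorded on
    the returned collection.
    """
    root = Path(root_dir)
    subsets_path = root / layout.subsets_file
    attributes_path = root / layout.attributes_file
    for p in (subsets_path, attributes_path):
        if not p.exists():
            raise FileNotFoundCollectionError(str(p))

    subsets = parse_subsets_metadata(subsets_path.read_text(layout.encoding))
    attributes = parse_attributes_metadata(
        attributes_path.read_text(layout.encoding), strict=False
    )

    load_defects: list[tuple[str, str, str]] = []
    graph = _build_graph_lenient(subsets, load_defects)

    tables: dict[str, DataTable] = {}
    cast_failures: list[CastFailure] = []
    for s in subsets:
        path = root / s.file_name
        if not path.exists():
            continue  # validator reports V01
        table, failures = read_data_table(
            path.read_text(layout.encoding),
            [a for a in attributes if a.subset_name == s.subset_name],
            subset_name=s.subset_name,
            missing_tokens=layout.missing_tokens,
            strict=False,
        )
        tables[s.subset_name] = table
        cast_failures.extend(failures)

    descriptive: dict = {}
    desc_path = root / DESCRIPTIVE_FILE
    if desc_path.exists():
        descriptive = json.loads(desc_path.read_text(layout.encoding))

    return DatasetCollection(
        subsets=subsets,
        attributes=attributes,
        tables=tables,
        graph=graph,
        descriptive=descriptive,
        cast_failures=cast_failures,
        load_defects=load_defects,
    )


def _build_graph_lenient(
    subsets: list[SubsetDef], load_defects: list[tuple[str, str, str]]
) -> LinkageGraph:
    """Build the lineage graph, dropping defective parent links (recorded
    as V08 defects) so a broken collection still loads for validation."""
    current = list(subsets)
    while True:
        try:
            return build_linkage_graph(current)
        except (UnknownParentError, SelfParentError) as exc:
            bad = _first_bad_parent(current)
            load_defects.append(("V08", bad.subset_name, str(exc)))
            current = [
                s if s is not bad else _without_parent(s) for s in current
            ]
        except CycleDetectedError as exc:
            # break the cycle at the lexicographically first member
            cyclic = _first_cycle_member(current)
            load_defects.append(("V08", cyclic.subset_name, str(exc)))
            current = [
                s if s is not cyclic else _without_parent(s) for s in current
            ]


def _without_parent(s: SubsetDef) -> SubsetDef:
    return SubsetDef(
        subset_name=s.subset_name,
        file_name=s.file_name,
        entity_label=s.entity_label,
        identifier_attribute=s.identifier_attribute,
        parent_subset="",
        cv_term=s.cv_term,
        extras=s.extras,
    )


def _first_bad_parent(subsets: list[SubsetDef]) -> SubsetDef:
    names = {s.subset_name for s in subsets}
    for s in subsets:
        if s.parent_subset and (
            s.parent_subset not in names or s.parent_subset == s.subset_name
        ):
            return s
    raise AssertionError("no defective parent link found")


def _first_cycle_member(subsets: list[SubsetDef]) -> SubsetDef:
    parent = {s.subset_name: s.parent_subset for s in subsets}
    in_cycle: set[str] = set()
    for start in parent:
        seen: list[str] = []
        node = start
        while node and node not in seen:
            seen.append(node)
            node = parent.get(node, "")
        if node:  # revisited: nodes from first occurrence onward are cyclic
            in_cycle.update(seen[seen.index(node):])
    name = min(in_cycle)
    return next(s for s in subsets if s.subset_name == name)
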