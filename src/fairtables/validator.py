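"""Semantic validation of a loaded collection.

Twelve fixed rules guard the model's invariants.  Errors (V01–V08) break
the machine contract — merging, export and reuse cannot be trusted until
they are fixed; warnings (V09–V12) flag reuse-readiness gaps (missing
identifier cells, missing CV terms or units, multiple lineage roots).

    V01 error    data table missing for a subset, or table without a subset
    V02 error    table column absent from the dictionary, or vice versa
    V03 error    declared identifier attribute missing or not category=identifier
    V04 error    duplicate value in a subset's own identifier column
    V05 error    referential break: child row names no parent row, or the
                 child table lacks the parent's identifier column entirely
    V06 error    attribute category outside the 4-value vocabulary
    V07 error    cell could not be cast to its declared data type
    V08 error    lineage defect (unknown parent, self-parent, cycle)
    V09 warning  missing cell in an identifier column
    V10 warning  attribute lacks a CV term
    V11 warning  multiple roots in the lineage forest
    V12 warning  quantitative attribute with no unit

Missing parent-key cells are a warning (V09), not a referential error:
tables are acquired progressively, and early tables must stay usable
before every link is filled in.  Identifier matching is exact,
case-sensitive string comparison after whitespace trimming — silent
case-folding would hide real data errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

from .datamodel import Category, DataTable, DatasetCollection
from .errors import UnknownColumnError
from .metadata_io import format_cell

__all__ = [
    "ValidationIssue",
    "FairReadinessReport",
    "SEVERITY",
    "validate_collection",
    "referential_orphans",
    "fair_readiness",
    "render_issues_text",
    "render_issues_json",
]

#: Fixed code → severity mapping (not configurable: stable CI exit codes).
SEVERITY = {
    **{f"V{i:02d}": "error" for i in range(1, 9)},
    **{f"V{i:02d}": "warning" for i in range(9, 13)},
}


@dataclass(frozen=True)
class ValidationIssue:
    """One coded, located diagnostic."""

    code: str
    severity: str
    subset: str = ""
    attribute: str = ""
    row: int | None = None  # 1-based data-row number
    message: str = ""

    def __post_init__(self):
        assert self.code in SEVERITY and self.severity == SEVERITY[self.code]
        assert self.message


def _issue(code: str, message: str, subset: str = "", attribute: str = "",
           row: int | None = None) -> ValidationIssue:
    return ValidationIssue(
        code=code, severity=SEVERITY[code], subset=subset,
        attribute=attribute, row=row, message=message,
    )


def referential_orphans(
    child: DataTable, parent: DataTable, key_column: str
) -> list[tuple[int, str]]:
    """Child rows whose non-missing key value names no parent row.

    Returns ``(1-based row number, canonical key text)`` in row order.
    Raises :class:`UnknownColumnError` if either table lacks the column.
    """
    if key_column not in child.column_names:
        raise UnknownColumnError(f"child table lacks column {key_column!r}")
    if key_column not in parent.column_names:
        raise UnknownColumnError(f"parent table lacks column {key_column!r}")
    parent_keys = {
        format_cell(v) for v in parent.column(key_column) if v is not None
    }
    out = []
    for r, v in enumerate(child.column(key_column), start=1):
        if v is not None and format_cell(v) not in parent_keys:
            out.append((r, format_cell(v)))
    return out


def validate_collection(collection: DatasetCollection) -> list[ValidationIssue]:
    """Apply every rule; issues are sorted by (subset, code, row)."""
    issues: list[ValidationIssue] = []
    subset_names = set(collection.subset_names())

    # V08 — lineage defects tolerated at load time
    for code, subset, message in collection.load_defects:
        issues.append(_issue(code, message, subset=subset))

    # V01 — subset/table pairing
    for name in sorted(subset_names):
        if name not in collection.tables:
            issues.append(_issue(
                "V01", f"no data table for subset {name!r}", subset=name))
    for name in sorted(set(collection.tables) - subset_names):
        issues.append(_issue(
            "V01", f"data table {name!r} has no subset definition", subset=name))

    # V06 — category vocabulary (redundant guard over the parser)
    for a in collection.attributes:
        if not isinstance(a.category, Category):
            issues.append(_issue(
                "V06",
                f"category {str(a.category)!r} is outside the vocabulary "
                "{identifier, factor, quantitative, qualitative}",
                subset=a.subset_name, attribute=a.attribute_name))

    # V07 — collected cast failures
    for f in collection.cast_failures:
        issues.append(_issue(
            "V07",
            f"cell {f.text!r} cannot be cast to the declared data type",
            subset=f.subset, attribute=f.column, row=f.row))

    # V10 / V12 — per-attribute reuse-readiness warnings
    for a in collection.attributes:
        if not a.cv_term:
            issues.append(_issue(
                "V10", "attribute lacks a CV term",
                subset=a.subset_name, attribute=a.attribute_name))
        if a.category == Category.QUANTITATIVE and not a.unit:
            issues.append(_issue(
                "V12", "quantitative attribute has no unit",
                subset=a.subset_name, attribute=a.attribute_name))

    for s in collection.subsets:
        name = s.subset_name
        attrs = collection.attributes_for(name)
        by_name = {a.attribute_name: a for a in attrs}
        table = collection.tables.get(name)

        # V03 — declared identifier attribute
        ident = by_name.get(s.identifier_attribute)
        if ident is None:
            issues.append(_issue(
                "V03",
                f"declared identifier {s.identifier_attribute!r} is not in "
                "the attribute dictionary",
                subset=name, attribute=s.identifier_attribute))
        elif ident.category != Category.IDENTIFIER:
            issues.append(_issue(
                "V03",
                f"declared identifier {s.identifier_attribute!r} has "
                f"category {str(ident.category)!r}, not 'identifier'",
                subset=name, attribute=s.identifier_attribute))

        if table is None:
            continue

        # V02 — table columns vs dictionary (load raises on mismatch for
        # loadable tables; this guards in-memory collections)
        for col in table.column_names:
            if col not in by_name:
                issues.append(_issue(
                    "V02", f"column {col!r} is not in the attribute dictionary",
                    subset=name, attribute=col))
        for attr_name in by_name:
            if attr_name not in table.column_names:
                issues.append(_issue(
                    "V02", f"dictionary attribute {attr_name!r} is not a "
                    "table column", subset=name, attribute=attr_name))

        # V04 — duplicates in the subset's own identifier column
        if s.identifier_attribute in table.column_names:
            seen: dict[str, int] = {}
            for r, v in enumerate(table.column(s.identifier_attribute), start=1):
                if v is None:
                    continue
                key = format_cell(v)
                if key in seen:
                    issues.append(_issue(
                        "V04",
                        f"identifier {key!r} already used in row {seen[key]}",
                        subset=name, attribute=s.identifier_attribute, row=r))
                else:
                    seen[key] = r

        # V09 — missing cells in any identifier-category column
        for a in attrs:
            if a.category != Category.IDENTIFIER:
                continue
            if a.attribute_name not in table.column_names:
                continue
            for r, v in enumerate(table.column(a.attribute_name), start=1):
                if v is None:
                    issues.append(_issue(
                        "V09", "missing identifier cell",
                        subset=name, attribute=a.attribute_name, row=r))

        # V05 — referential integrity against the parent table
        if s.parent_subset and s.parent_subset in subset_names:
            parent_def = collection.subset(s.parent_subset)
            parent_table = collection.tables.get(s.parent_subset)
            key = parent_def.identifier_attribute
            if key not in table.column_names:
                issues.append(_issue(
                    "V05",
                    f"child table lacks the parent identifier column {key!r}",
                    subset=name, attribute=key))
            elif parent_table is not None and key in parent_table.column_names:
                for r, value in referential_orphans(table, parent_table, key):
                    issues.append(_issue(
                        "V05",
                        f"value {value!r} names no row in parent "
                        f"{s.parent_subset!r}",
                        subset=name, attribute=key, row=r))

    # V11 — multiple roots
    roots = collection.graph.roots()
    if len(roots) > 1:
        issues.append(_issue(
            "V11", f"lineage forest has {len(roots)} roots: {roots}"))

    issues.sort(key=lambda i: (i.subset, i.code, i.row or 0, i.attribute))
    return issues


# ---------------------------------------------------------------- reporting
@dataclass(frozen=True)
class FairReadinessReport:
    """Lightweight local reuse-readiness summary (not a published FAIR grid)."""

    n_subsets: int
    n_attributes: int
    pct_attributes_with_cv_term: float
    pct_subsets_with_cv_term: float
    has_license: bool
    has_title: bool
    n_errors: int
    n_warnings: int


def fair_readiness(
    collection: DatasetCollection, issues: list[ValidationIssue]
) -> FairReadinessReport:
    n_attr = len(collection.attributes)
    n_sub = len(collection.subsets)
    return FairReadinessReport(
        n_subsets=n_sub,
        n_attributes=n_attr,
        pct_attributes_with_cv_term=(
            100.0 * sum(1 for a in collection.attributes if a.cv_term) / n_attr
            if n_attr else 0.0
        ),
        pct_subsets_with_cv_term=(
            100.0 * sum(1 for s in collection.subsets if s.cv_term) / n_sub
            if n_sub else 0.0
        ),
        has_license=bool(collection.descriptive.get("license")),
        has_title=bool(collection.descriptive.get("title")),
        n_errors=sum(1 for i in issues if i.severity == "error"),
        n_warnings=sum(1 for i in issues if i.severity == "warning"),
    )


def render_issues_text(issues: list[ValidationIssue]) -> str:
    if not issues:
        return "no issues\n"
    lines = []
    for i in issues:
        loc = i.subset or "-"
        if i.attribute:
            loc += f".{i.attribute}"
        if i.row is not None:
            loc += f":{i.row}"
        lines.append(f"{i.code} {i.severity:<7} {loc:<30} {i.message}")
    return "\n".join(lines) + "\n"


def render_issues_json(issues: list[ValidationIssue]) -> str:
    return json.dumps([asdict(i) for i in issues], indent=2) + "\n"
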