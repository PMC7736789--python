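"""Export/import of a collection as a tabular datapackage descriptor.

The descriptor follows the Frictionless Tabular Data Package v1 layout —
one resource per subset with path, ordered field schema, ``primaryKey``
(the identifier attribute) and ``foreignKeys`` (child key → parent
resource/key) — extended with one custom field property, ``category``,
carrying the four-value column vocabulary.  A column's CV term maps to the
standard ``rdfType`` field property (the spec's own semantic slot) rather
than a second custom key; a subset's entity label and CV term live on the
resource as ``entity`` and ``rdfType``.

Descriptive metadata (title, license, contributors, ...) pass through
untouched: they are the repository's concern, while the descriptor carries
the structural metadata that makes the tables interoperable and reusable.

Serialization is canonical: UTF-8, 2-space indentation, lexicographically
sorted keys, resources in topological order, fields in table-column order
— identical collections yield byte-identical descriptors.

``check_descriptor`` validates a descriptor document against the profile
constraints this model relies on (required keys, admissible field types,
the category vocabulary, primaryKey/foreignKey referential soundness);
the rule set is written out explicitly in ``_check_parsed``.
"""

from __future__ import annotations

import json
from pathlib import Path

from .datamodel import (
    AttributeDef,
    Category,
    DatasetCollection,
    SubsetDef,
    build_linkage_graph,
    topological_order,
)
from .errors import (
    DanglingForeignKeyError,
    MalformedJSONError,
    SchemaViolationError,
    UnknownCategoryPropertyError,
    ValidationRequiredError,
)
from .metadata_io import read_data_table

__all__ = [
    "to_datapackage",
    "from_datapackage",
    "check_descriptor",
    "descriptor_to_json",
    "write_datapackage",
    "PROFILE",
    "FIELD_TYPES",
    "TYPE_TO_FIELD",
    "FIELD_TO_TYPE",
]

PROFILE = "tabular-data-package"
RESOURCE_PROFILE = "tabular-data-resource"

#: declared data type -> datapackage field type
TYPE_TO_FIELD = {"string": "string", "integer": "integer", "float": "number",
                 "date": "date"}
FIELD_TO_TYPE = {v: k for k, v in TYPE_TO_FIELD.items()}
FIELD_TYPES = tuple(sorted(FIELD_TO_TYPE))

CATEGORY_VALUES = tuple(c.value for c in Category)


def to_datapackage(collection: DatasetCollection, validate: bool = True) -> dict:
    """Build the descriptor for a validated collection.

    Refuses (``ValidationRequiredError``) when the collection still has
    validation errors: broken structure must not be disseminated.
    ``validate=False`` bypasses the gate (the CLI's ``--force``).
    """
    from .validator import validate_collection

    if validate:
        errors = [
            i for i in validate_collection(collection) if i.severity == "error"
        ]
        if errors:
            raise ValidationRequiredError(
                f"collection has {len(errors)} validation errors; fix them "
                "before export"
            )

    resources = []
    for name in topological_order(collection.graph):
        s = collection.subset(name)
        fields = []
        for a in collection.attributes_for(name):
            f = {
                "name": a.attribute_name,
                "type": TYPE_TO_FIELD[a.data_type],
                "category": a.category.value
                if isinstance(a.category, Category) else str(a.category),
            }
            if a.description:
                f["description"] = a.description
            if a.unit:
                f["unit"] = a.unit
            if a.cv_term:
                f["rdfType"] = a.cv_term
            fields.append(f)
        schema: dict = {"fields": fields, "primaryKey": [s.identifier_attribute]}
        if s.parent_subset:
            parent = collection.subset(s.parent_subset)
            schema["foreignKeys"] = [
                {
                    "fields": [parent.identifier_attribute],
                    "reference": {
                        "resource": parent.subset_name,
                        "fields": [parent.identifier_attribute],
                    },
                }
            ]
        resource = {
            "name": s.subset_name,
            "path": s.file_name,
            "profile": RESOURCE_PROFILE,
            "entity": s.entity_label,
            "schema": schema,
        }
        if s.cv_term:
            resource["rdfType"] = s.cv_term
        resources.append(resource)

    descriptor = {"profile": PROFILE, "resources": resources}
    for k, v in collection.descriptive.items():
        descriptor.setdefault(k, v)
    descriptor.setdefault("name", "collection")
    return descriptor


def descriptor_to_json(descriptor: dict) -> str:
    return json.dumps(descriptor, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def write_datapackage(collection: DatasetCollection, root_dir: str | Path) -> str:
    """Write ``datapackage.json`` next to the TSV resources."""
    root = Path(root_dir)
    root.mkdir(parents=True, exist_ok=True)
    path = root / "datapackage.json"
    path.write_text(descriptor_to_json(to_datapackage(collection)),
                    encoding="utf-8")
    return path.name


def from_datapackage(
    descriptor: dict, resource_documents: dict[str, str]
) -> DatasetCollection:
    """Reconstruct a collection from a descriptor and its TSV documents.

    ``resource_documents`` maps each resource path to the table text.
    Raises ``SchemaViolationError`` subclasses when the descriptor breaks
    the profile.
    """
    violations = _check_parsed(descriptor)
    if violations:
        first = violations[0]
        if "category" in first:
            raise UnknownCategoryPropertyError(first)
        if "foreignKey" in first:
            raise DanglingForeignKeyError(first)
        raise SchemaViolationError(first)

    reserved = {"profile", "resources"}
    descriptive = {k: v for k, v in descriptor.items() if k not in reserved}

    subsets: list[SubsetDef] = []
    attributes: list[AttributeDef] = []
    for res in descriptor["resources"]:
        schema = res["schema"]
        parent = ""
        for fk in schema.get("foreignKeys", []):
            parent = fk["reference"]["resource"]
        subsets.append(
            SubsetDef(
                subset_name=res["name"],
                file_name=res["path"],
                entity_label=res.get("entity", ""),
                identifier_attribute=schema["primaryKey"][0],
                parent_subset=parent,
                cv_term=res.get("rdfType", ""),
            )
        )
        for f in schema["fields"]:
            attributes.append(
                AttributeDef(
                    subset_name=res["name"],
                    attribute_name=f["name"],
                    category=Category.parse(f["category"]),
                    description=f.get("description", ""),
                    unit=f.get("unit", ""),
                    data_type=FIELD_TO_TYPE[f["type"]],
                    cv_term=f.get("rdfType", ""),
                )
            )

    tables = {}
    cast_failures = []
    for res in descriptor["resources"]:
        doc = resource_documents.get(res["path"])
        if doc is None:
            continue
        table, failures = read_data_table(
            doc,
            [a for a in attributes if a.subset_name == res["name"]],
            subset_name=res["name"],
        )
        tables[res["name"]] = table
        cast_failures.extend(failures)

    return DatasetCollection(
        subsets=subsets,
        attributes=attributes,
        tables=tables,
        graph=build_linkage_graph(subsets),
        descriptive=descriptive,
        cast_failures=cast_failures,
    )


# ---------------------------------------------------------------- checking
def check_descriptor(document: str) -> list[str]:
    """Validate a descriptor JSON document; empty list ⇔ acceptable.

    Raises :class:`MalformedJSONError` when the document is not JSON.
    """
    try:
        descriptor = json.loads(document)
    except json.JSONDecodeError as exc:
        raise MalformedJSONError(str(exc)) from None
    return _check_parsed(descriptor)


def _check_parsed(descriptor) -> list[str]:
    v: list[str] = []
    if not isinstance(descriptor, dict):
        return ["descriptor must be a JSON object"]
    resources = descriptor.get("resources")
    if not isinstance(resources, list) or not resources:
        return ["descriptor must declare a non-empty 'resources' array"]

    names: set[str] = set()
    primary: dict[str, list[str]] = {}
    for i, res in enumerate(resources):
        where = f"resources[{i}]"
        if not isinstance(res, dict):
            v.append(f"{where}: resource must be an object")
            continue
        name = res.get("name")
        if not isinstance(name, str) or not name:
            v.append(f"{where}: missing resource 'name'")
            name = f"#{i}"
        elif name in names:
            v.append(f"{where}: duplicate resource name {name!r}")
        names.add(name)
        if not isinstance(res.get("path"), str) or not res["path"]:
            v.append(f"{where}: missing resource 'path'")
        schema = res.get("schema")
        if not isinstance(schema, dict):
            v.append(f"{where}: missing 'schema' object")
            continue
        fields = schema.get("fields")
        if not isinstance(fields, list) or not fields:
            v.append(f"{where}: schema must declare a non-empty 'fields' array")
            fields = []
        field_names = []
        for j, f in enumerate(fields):
            fwhere = f"{where}.schema.fields[{j}]"
            if not isinstance(f, dict):
                v.append(f"{fwhere}: field must be an object")
                continue
            fname = f.get("name")
            if not isinstance(fname, str) or not fname:
                v.append(f"{fwhere}: missing field 'name'")
                fname = f"#{j}"
            field_names.append(fname)
            ftype = f.get("type")
            if ftype not in FIELD_TYPES:
                v.append(
                    f"{fwhere}: field {fname!r} has type {ftype!r}; "
                    f"admissible types: {list(FIELD_TYPES)}"
                )
            cat = f.get("category")
            if cat is None:
                v.append(f"{fwhere}: field {fname!r} lacks the category property")
            elif cat not in CATEGORY_VALUES:
                v.append(
                    f"{fwhere}: field {fname!r} category {cat!r} is outside "
                    f"{list(CATEGORY_VALUES)}"
                )
        pk = schema.get("primaryKey")
        if not isinstance(pk, list) or not pk:
            v.append(f"{where}: schema must declare a 'primaryKey' list")
            pk = []
        for key in pk:
            if key not in field_names:
                v.append(f"{where}: primaryKey {key!r} is not a declared field")
        primary[name] = pk

    for i, res in enumerate(resources):
        if not isinstance(res, dict) or not isinstance(res.get("schema"), dict):
            continue
        name = res.get("name", f"#{i}")
        for j, fk in enumerate(res["schema"].get("foreignKeys", [])):
            where = f"resources[{i}].schema.foreignKeys[{j}]"
            if not isinstance(fk, dict) or "reference" not in fk:
                v.append(f"{where}: foreignKey must carry a 'reference'")
                continue
            ref = fk["reference"]
            target = ref.get("resource")
            if target not in names:
                v.append(
                    f"{where}: foreignKey references unknown resource {target!r}"
                )
                continue
            ref_fields = ref.get("fields", [])
            if ref_fields != primary.get(target, []):
                v.append(
                    f"{where}: foreignKey reference fields {ref_fields!r} do "
                    f"not match resource {target!r} primaryKey"
                )
            own = fk.get("fields", [])
            own_fields = [
                f.get("name") for f in res["schema"].get("fields", [])
                if isinstance(f, dict)
            ]
            for key in own:
                if key not in own_fields:
                    v.append(
                        f"{where}: foreignKey field {key!r} is not a declared "
                        f"field of {name!r}"
                    )
    return v
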