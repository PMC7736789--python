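"""Read-only HTTP query layer over loaded collections.

A thin WSGI application exposing structural metadata, lineage-merged
subset data with filters, and cross-subset merged views — so external
tools (R, Python, notebooks) can pull exactly the slice they need without
touching the files.  The service is a pure view: no endpoint mutates a
collection and identical requests return byte-identical bodies.

Routes (described by the served OpenAPI 3.0 document):

    GET /api/openapi.json
    GET /api/{collection}/metadata
    GET /api/{collection}/data/{subset}?Treatment=control&var.min=0&format=tsv
    GET /api/{collection}/merged?subsets=a,b&format=json

Filters are query parameters: ``attribute=value`` for equality,
``attribute.min`` / ``attribute.max`` for closed numeric intervals;
missing cells never match.  ``limit`` caps the returned rows.  TSV bodies
use the collection dialect and re-parse under the collection reader.
"""

from __future__ import annotations

import datetime
import json
from typing import Callable, Mapping
from urllib.parse import parse_qsl

from .datamodel import DataTable, DatasetCollection, topological_order
from .errors import (
    FairTablesError,
    NoCommonAncestorError,
    PredicateTypeMismatchError,
    UnknownColumnError,
    UnknownSubsetError,
)
from .merge import Equals, Interval, filter_rows, lineage_merge, merge_across
from .metadata_io import format_data_table

__all__ = [
    "create_app",
    "openapi_document",
    "check_openapi_document",
    "wsgi_get",
    "serve",
]

TSV_TYPE = "text/tab-separated-values; charset=utf-8"
JSON_TYPE = "application/json; charset=utf-8"


# ---------------------------------------------------------------- helpers
def _json_cell(v):
    if isinstance(v, datetime.date):
        return v.isoformat()
    return v


def _table_body(table: DataTable, fmt: str) -> tuple[bytes, str]:
    if fmt == "json":
        records = [
            {c: _json_cell(v) for c, v in zip(table.column_names, row)}
            for row in table.rows
        ]
        return (json.dumps(records, indent=2).encode() + b"\n", JSON_TYPE)
    return format_data_table(table).encode(), TSV_TYPE


def _parse_filters(params: list[tuple[str, str]]):
    """Turn query parameters into (attribute, predicate) pairs, preserving
    parameter order; ``.min``/``.max`` pairs coalesce into one interval."""
    reserved = {"format", "limit", "subsets"}
    filters: list[tuple[str, object]] = []
    intervals: dict[str, dict] = {}
    for key, value in params:
        if key in reserved:
            continue
        if key.endswith(".min") or key.endswith(".max"):
            attr, bound = key.rsplit(".", 1)
            try:
                number = float(value)
            except ValueError:
                raise PredicateTypeMismatchError(
                    f"bound {key}={value!r} is not numeric"
                )
            if attr not in intervals:
                intervals[attr] = {}
                filters.append((attr, intervals[attr]))  # placeholder
            intervals[attr][bound] = number
        else:
            filters.append((key, Equals(value)))
    return [
        (attr, Interval(lo=p.get("min"), hi=p.get("max")))
        if isinstance(p, dict) else (attr, p)
        for attr, p in filters
    ]


def _apply_filters(table: DataTable, filters) -> DataTable:
    for attribute, predicate in filters:
        table = filter_rows(table, attribute, predicate)
    return table


# ---------------------------------------------------------------- endpoints
def endpoint_metadata(collection: DatasetCollection) -> dict:
    """Structural metadata, field-for-field, in topological-then-declaration
    order (mirrors the canonical metadata files)."""
    order = topological_order(collection.graph)
    return {
        "subsets": [
            {
                "subset": s.subset_name,
                "file": s.file_name,
                "entity": s.entity_label,
                "identifier": s.identifier_attribute,
                "parent": s.parent_subset,
                "cv_term": s.cv_term,
            }
            for s in (collection.subset(n) for n in order)
        ],
        "attributes": [
            {
                "subset": a.subset_name,
                "attribute": a.attribute_name,
                "category": a.category.value
                if hasattr(a.category, "value") else str(a.category),
                "description": a.description,
                "unit": a.unit,
                "type": a.data_type,
                "cv_term": a.cv_term,
            }
            for n in order
            for a in collection.attributes_for(n)
        ],
    }


def endpoint_data(collection: DatasetCollection, subset: str, filters,
                  fmt: str, limit: int | None = None) -> tuple[bytes, str]:
    """Lineage-merged table for one subset, filters applied in order."""
    table = _apply_filters(lineage_merge(collection, subset), filters)
    if limit is not None:
        table = DataTable(table.column_names, table.rows[:limit])
    return _table_body(table, fmt)


def endpoint_merged(collection: DatasetCollection, subsets: list[str],
                    filters, fmt: str, limit: int | None = None
                    ) -> tuple[bytes, str]:
    """Cross-subset merged view through the lowest common ancestor."""
    table = _apply_filters(merge_across(collection, subsets), filters)
    if limit is not None:
        table = DataTable(table.column_names, table.rows[:limit])
    return _table_body(table, fmt)


# ---------------------------------------------------------------- openapi
def openapi_document(collection_ids: list[str]) -> dict:
    """OpenAPI 3.0 description of the service routes."""
    tsv = {"schema": {"type": "string"}}
    table_responses = {
        "200": {
            "description": "merged, filtered table",
            "content": {
                "text/tab-separated-values": tsv,
                "application/json": {
                    "schema": {"type": "array", "items": {"type": "object"}}
                },
            },
        },
        "400": {"description": "bad filter or merge request"},
        "404": {"description": "unknown collection or subset"},
    }
    common_params = [
        {
            "name": "format",
            "in": "query",
            "schema": {"type": "string", "enum": ["tsv", "json"]},
            "description": "response body format (default tsv)",
        },
        {
            "name": "limit",
            "in": "query",
            "schema": {"type": "integer", "minimum": 0},
            "description": "maximum number of rows returned",
        },
    ]
    return {
        "openapi": "3.0.3",
        "info": {
            "title": "fairtables query service",
            "description": (
                "Read-only access to structural metadata, lineage-merged "
                "subset data and cross-subset merged views of experimental "
                f"data collections. Loaded collections: {sorted(collection_ids)}."
            ),
            "version": "1.0.0",
        },
        "paths": {
            "/api/{collection}/metadata": {
                "get": {
                    "operationId": "getMetadata",
                    "parameters": [_path_param("collection")],
                    "responses": {
                        "200": {
                            "description": "structural metadata document",
                            "content": {"application/json": {
                                "schema": {"type": "object"}}},
                        },
                        "404": {"description": "unknown collection"},
                    },
                }
            },
            "/api/{collection}/data/{subset}": {
                "get": {
                    "operationId": "getData",
                    "parameters": [
                        _path_param("collection"),
                        _path_param("subset"),
                        *common_params,
                    ],
                    "responses": table_responses,
                }
            },
            "/api/{collection}/merged": {
                "get": {
                    "operationId": "getMerged",
                    "parameters": [
                        _path_param("collection"),
                        {
                            "name": "subsets",
                            "in": "query",
                            "required": True,
                            "schema": {"type": "string"},
                            "description": "comma-separated subset names",
                        },
                        *common_params,
                    ],
                    "responses": table_responses,
                }
            },
        },
    }


def _path_param(name: str) -> dict:
    return {
        "name": name,
        "in": "path",
        "required": True,
        "schema": {"type": "string"},
    }


def check_openapi_document(doc) -> list[str]:
    """Structural validation of an OpenAPI 3.0 document.

    Checks the constraints the 3.0 schema imposes on the parts this
    service emits: version string, info block, per-operation responses,
    and parameter object shape.  Empty list ⇔ acceptable.
    """
    v: list[str] = []
    if not isinstance(doc, dict):
        return ["document must be a JSON object"]
    version = doc.get("openapi", "")
    if not isinstance(version, str) or not version.startswith("3.0"):
        v.append(f"openapi version must be 3.0.x, got {version!r}")
    info = doc.get("info")
    if not isinstance(info, dict):
        v.append("missing 'info' object")
    else:
        for key in ("title", "version"):
            if not isinstance(info.get(key), str) or not info[key]:
                v.append(f"info.{key} is required")
    paths = doc.get("paths")
    if not isinstance(paths, dict) or not paths:
        v.append("missing non-empty 'paths' object")
        return v
    for path, item in paths.items():
        if not path.startswith("/"):
            v.append(f"path {path!r} must start with '/'")
        if not isinstance(item, dict):
            v.append(f"path item {path!r} must be an object")
            continue
        for method, op in item.items():
            where = f"{method.upper()} {path}"
            if method not in ("get", "put", "post", "delete", "options",
                              "head", "patch", "trace"):
                v.append(f"{path}: unknown method {method!r}")
                continue
            responses = op.get("responses")
            if not isinstance(responses, dict) or not responses:
                v.append(f"{where}: operation must declare responses")
                continue
            for status, resp in responses.items():
                if not (status == "default" or status.isdigit()):
                    v.append(f"{where}: bad response status {status!r}")
                if not isinstance(resp, dict) or "description" not in resp:
                    v.append(f"{where}: response {status} needs a description")
            for p in op.get("parameters", []):
                if not isinstance(p, dict) or "name" not in p or "in" not in p:
                    v.append(f"{where}: parameter objects need name and in")
                elif p["in"] == "path" and not p.get("required"):
                    v.append(f"{where}: path parameter {p['name']!r} must be "
                             "required")
    return v


# ---------------------------------------------------------------- wsgi app
def create_app(collections: Mapping[str, DatasetCollection]) -> Callable:
    """Build the WSGI application serving the given collections."""
    openapi_bytes = (
        json.dumps(openapi_document(list(collections)), indent=2,
                   sort_keys=True).encode() + b"\n"
    )

    def app(environ, start_response):
        method = environ.get("REQUEST_METHOD", "GET")
        path = environ.get("PATH_INFO", "/")
        params = parse_qsl(environ.get("QUERY_STRING", ""),
                           keep_blank_values=True)
        if method != "GET":
            return _respond(start_response, 405, b'{"error": "GET only"}\n',
                            JSON_TYPE)
        try:
            return _route(start_response, path, params)
        except (UnknownSubsetError,) as exc:
            return _error(start_response, 404, exc)
        except (UnknownColumnError, PredicateTypeMismatchError,
                NoCommonAncestorError) as exc:
            return _error(start_response, 400, exc)
        except FairTablesError as exc:
            return _error(start_response, 400, exc)

    def _route(start_response, path: str, params):
        if path == "/api/openapi.json":
            return _respond(start_response, 200, openapi_bytes, JSON_TYPE)
        parts = [p for p in path.split("/") if p]
        if len(parts) < 2 or parts[0] != "api":
            return _respond(start_response, 404,
                            b'{"error": "not found"}\n', JSON_TYPE)
        collection = collections.get(parts[1])
        if collection is None:
            return _respond(
                start_response, 404,
                json.dumps({"error": f"unknown collection {parts[1]!r}"}
                           ).encode() + b"\n", JSON_TYPE)
        qp = dict(params)
        fmt = qp.get("format", "tsv")
        limit = int(qp["limit"]) if "limit" in qp else None

        if parts[2:] == ["metadata"]:
            body = json.dumps(endpoint_metadata(collection),
                              indent=2).encode() + b"\n"
            return _respond(start_response, 200, body, JSON_TYPE)
        if len(parts) == 4 and parts[2] == "data":
            body, ctype = endpoint_data(
                collection, parts[3], _parse_filters(params), fmt, limit)
            return _respond(start_response, 200, body, ctype)
        if parts[2:] == ["merged"]:
            names = [s for s in qp.get("subsets", "").split(",") if s]
            if not names:
                raise UnknownSubsetError(
                    "the 'subsets' query parameter is required")
            body, ctype = endpoint_merged(
                collection, names, _parse_filters(params), fmt, limit)
            return _respond(start_response, 200, body, ctype)
        return _respond(start_response, 404, b'{"error": "not found"}\n',
                        JSON_TYPE)

    return app


def _respond(start_response, status: int, body: bytes, ctype: str):
    reasons = {200: "OK", 400: "Bad Request", 404: "Not Found",
               405: "Method Not Allowed"}
    start_response(
        f"{status} {reasons[status]}",
        [("Content-Type", ctype), ("Content-Length", str(len(body)))],
    )
    return [body]


def _error(start_response, status: int, exc: Exception):
    body = json.dumps(
        {"error": type(exc).__name__, "message": str(exc)}
    ).encode() + b"\n"
    return _respond(start_response, status, body, JSON_TYPE)


# ---------------------------------------------------------------- clients
def wsgi_get(app: Callable, path: str) -> tuple[int, str, bytes]:
    """Call the app in-process: returns (status, content type, body)."""
    path, _, query = path.partition("?")
    captured: dict = {}

    def start_response(status, headers):
        captured["status"] = int(status.split()[0])
        captured["headers"] = dict(headers)

    environ = {
        "REQUEST_METHOD": "GET",
        "PATH_INFO": path,
        "QUERY_STRING": query,
        "SERVER_NAME": "localhost",
        "SERVER_PORT": "80",
        "wsgi.url_scheme": "http",
    }
    body = b"".join(app(environ, start_response))
    return captured["status"], captured["headers"].get("Content-Type", ""), body


def serve(collections: Mapping[str, DatasetCollection],
          host: str = "127.0.0.1", port: int = 8080) -> None:
    """Run the service with the standard library's WSGI server."""
    from wsgiref.simple_server import make_server

    with make_server(host, port, create_app(collections)) as httpd:
        httpd.serve_forever()
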