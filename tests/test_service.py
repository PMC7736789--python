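"""Query service behavior exercised through the WSGI callable."""

import json

import pytest

from fairtables.metadata_io import (
    parse_attributes_metadata,
    read_data_table,
)
from fairtables.merge import lineage_merge, merge_across
from fairtables.service import (
    check_openapi_document,
    create_app,
    openapi_document,
    wsgi_get,
)
from fairtables.synthetic import GeneratorSpec, generate_collection
from conftest import make_plants_samples


@pytest.fixture(scope="module")
def demo():
    return generate_collection(GeneratorSpec(seed=17, n_plants=4))


@pytest.fixture(scope="module")
def app(demo):
    return create_app({"demo": demo, "tiny": make_plants_samples()})


# --------------------------------------------------------------- metadata
def test_metadata_mirrors_structural_metadata(app, demo):
    status, ctype, body = wsgi_get(app, "/api/demo/metadata")
    assert status == 200 and ctype.startswith("application/json")
    doc = json.loads(body)
    assert [s["subset"] for s in doc["subsets"]] == [
        "plants", "samples", "biochemistry", "metabolomics"
    ]
    samples = next(s for s in doc["subsets"] if s["subset"] == "samples")
    assert samples["parent"] == "plants"
    assert len(doc["attributes"]) == len(demo.attributes)
    for entry in doc["attributes"]:
        a = demo.attribute(entry["subset"], entry["attribute"])
        assert entry["category"] == a.category.value
        assert entry["unit"] == a.unit and entry["cv_term"] == a.cv_term


def test_unknown_collection_is_404(app):
    status, _, _ = wsgi_get(app, "/api/ghost/metadata")
    assert status == 404


# ------------------------------------------------------------------- data
def test_data_returns_lineage_merged_tsv(app, demo):
    status, ctype, body = wsgi_get(app, "/api/demo/data/samples")
    assert status == 200 and ctype.startswith("text/tab-separated-values")
    lines = body.decode().splitlines()
    merged = lineage_merge(demo, "samples")
    assert lines[0].split("\t") == merged.column_names
    assert len(lines) - 1 == merged.n_rows


def test_data_filter_matches_library_result(app):
    status, _, body = wsgi_get(app, "/api/tiny/data/samples?Treatment=control")
    assert status == 200
    assert len(body.decode().splitlines()) - 1 == 2  # s1, s2


def test_data_filter_unknown_attribute_is_400(app):
    status, _, body = wsgi_get(app, "/api/tiny/data/samples?Ghost=1")
    assert status == 400 and b"Ghost" in body


def test_data_unknown_subset_is_404(app):
    status, _, _ = wsgi_get(app, "/api/demo/data/ghost")
    assert status == 404


def test_interval_filter_and_limit(app, demo):
    status, _, body = wsgi_get(
        app, "/api/demo/data/biochemistry?biochemistry_v01.min=0&limit=3"
    )
    assert status == 200
    assert len(body.decode().splitlines()) - 1 <= 3


# ----------------------------------------------------------------- merged
def test_merged_row_count_matches_merge_across(app, demo):
    status, _, body = wsgi_get(
        app, "/api/demo/merged?subsets=biochemistry,metabolomics"
    )
    assert status == 200
    expected = merge_across(demo, ["biochemistry", "metabolomics"])
    assert len(body.decode().splitlines()) - 1 == expected.n_rows


def test_merged_single_subset_equals_data_endpoint(app):
    a = wsgi_get(app, "/api/demo/merged?subsets=samples")
    b = wsgi_get(app, "/api/demo/data/samples")
    assert a[2] == b[2]


def test_merged_different_roots_is_400(app):
    # plants and samples share a root; construct the failure with two trees
    from fairtables.datamodel import (
        AttributeDef, Category, DataTable, SubsetDef, build_linkage_graph,
    )

    c = make_plants_samples()
    c.subsets.append(SubsetDef("soil", "soil.txt", "soil", "SoilID", ""))
    c.attributes.append(
        AttributeDef("soil", "SoilID", Category.IDENTIFIER, "soil id")
    )
    c.tables["soil"] = DataTable(["SoilID"], [["z1"]])
    c.graph = build_linkage_graph(c.subsets)
    app2 = create_app({"c": c})
    status, _, body = wsgi_get(app2, "/api/c/merged?subsets=samples,soil")
    assert status == 400 and b"NoCommonAncestor" in body


# ------------------------------------------------------------- contracts
def test_service_is_a_pure_view(app):
    first = wsgi_get(app, "/api/demo/data/metabolomics?format=json")
    second = wsgi_get(app, "/api/demo/data/metabolomics?format=json")
    assert first == second


def test_every_tsv_body_reparses_under_the_collection_reader(app, demo):
    paths = [
        "/api/demo/data/plants",
        "/api/demo/data/samples",
        "/api/demo/data/biochemistry",
        "/api/demo/merged?subsets=biochemistry,metabolomics",
    ]
    # a permissive dictionary for the merged/disambiguated headers
    for path in paths:
        status, _, body = wsgi_get(app, path)
        assert status == 200
        text = body.decode()
        header = text.splitlines()[0].split("\t")
        attrs_doc = "subset\tattribute\tcategory\tdescription\tunit\ttype\tcv_term\n"
        attrs_doc += "".join(
            f"x\t{col}\tqualitative\t\t\tstring\t\n" for col in header
        )
        attrs = parse_attributes_metadata(attrs_doc)
        table, failures = read_data_table(text, attrs, subset_name="x")
        assert failures == []
        assert len(table.rows) == len(text.splitlines()) - 1


def test_json_format_round_trips_values(app, demo):
    status, ctype, body = wsgi_get(app, "/api/demo/data/plants?format=json")
    assert status == 200 and ctype.startswith("application/json")
    records = json.loads(body)
    assert [r["PlantID"] for r in records] == demo.tables["plants"].column(
        "PlantID"
    )


# -------------------------------------------------------------- openapi
def test_served_openapi_document_is_valid(app):
    status, _, body = wsgi_get(app, "/api/openapi.json")
    assert status == 200
    doc = json.loads(body)
    assert check_openapi_document(doc) == []
    assert set(doc["paths"]) == {
        "/api/{collection}/metadata",
        "/api/{collection}/data/{subset}",
        "/api/{collection}/merged",
    }


def test_openapi_checker_flags_defects():
    doc = openapi_document(["x"])
    assert check_openapi_document(doc) == []
    broken = json.loads(json.dumps(doc))
    del broken["info"]["title"]
    broken["paths"]["/api/{collection}/metadata"]["get"].pop("responses")
    violations = check_openapi_document(broken)
    assert any("info.title" in v for v in violations)
    assert any("responses" in v for v in violations)
    assert check_openapi_document({"openapi": "2.0"})  # wrong major version
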