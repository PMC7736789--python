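"""Parsing, casting and canonical serialization of collections."""

import datetime

import pytest

from fairtables.datamodel import AttributeDef, Category
from fairtables.errors import (
    ColumnMismatchError,
    DuplicateAttributeError,
    DuplicateSubsetError,
    EmptyDocumentError,
    FileNotFoundCollectionError,
    MissingHeaderColumnError,
    UnknownCategoryError,
)
from fairtables.metadata_io import (
    attributes_to_text,
    format_data_table,
    load_collection,
    parse_attributes_metadata,
    parse_subsets_metadata,
    read_data_table,
    subsets_to_text,
    write_collection,
    write_structural_metadata,
)
from fairtables.synthetic import GeneratorSpec, generate_collection

SUBSETS_DOC = (
    "subset\tfile\tentity\tidentifier\tparent\tcv_term\n"
    "plants\tplants.txt\tplant\tPlantID\t\t\n"
    "samples\tsamples.txt\tsample\tSampleID\tplants\t\n"
)


# ---------------------------------------------------------------- subsets
def test_parse_subsets_worked_example():
    defs = parse_subsets_metadata(SUBSETS_DOC)
    assert [d.subset_name for d in defs] == ["plants", "samples"]
    assert defs[0].parent_subset == "" and defs[1].parent_subset == "plants"
    assert defs[1].identifier_attribute == "SampleID"


def test_parse_subsets_header_only_is_empty():
    with pytest.raises(EmptyDocumentError):
        parse_subsets_metadata("subset\tfile\tentity\tidentifier\tparent\tcv_term\n")


def test_parse_subsets_missing_column_named():
    with pytest.raises(MissingHeaderColumnError) as err:
        parse_subsets_metadata("subset\tfile\tentity\tidentifier\tparent\nx\ty\tz\ti\t\n")
    assert err.value.column == "cv_term"


def test_parse_subsets_duplicate_name():
    doc = SUBSETS_DOC + "plants\tother.txt\tplant\tPlantID\t\t\n"
    with pytest.raises(DuplicateSubsetError):
        parse_subsets_metadata(doc)


def test_parse_subsets_insensitive_to_extra_column_order():
    base = ["subset", "file", "entity", "identifier", "parent", "cv_term"]
    rows = [
        dict(zip(base, ["plants", "plants.txt", "plant", "PlantID", "", ""])),
        dict(zip(base, ["samples", "samples.txt", "sample", "SampleID",
                        "plants", ""])),
    ]
    for r in rows:
        r["note"] = f"note-{r['subset']}"
        r["owner"] = "lab"

    def doc(columns):
        lines = ["\t".join(columns)]
        for r in rows:
            lines.append("\t".join(r[c] for c in columns))
        return "\n".join(lines) + "\n"

    a = parse_subsets_metadata(doc(base + ["note", "owner"]))
    b = parse_subsets_metadata(doc(["owner"] + base + ["note"]))
    assert a == b
    assert dict(a[0].extras) == {"note": "note-plants", "owner": "lab"}


# -------------------------------------------------------------- attributes
def test_parse_attributes_worked_example_and_case_insensitivity():
    doc = (
        "subset\tattribute\tcategory\tdescription\tunit\ttype\tcv_term\n"
        "samples\tSampleID\tIdentifier\tsample code\t\tstring\t\n"
    )
    (a,) = parse_attributes_metadata(doc)
    assert a.category is Category.IDENTIFIER and a.data_type == "string"


def test_parse_attributes_rejects_out_of_vocabulary_category():
    doc = (
        "subset\tattribute\tcategory\tdescription\tunit\ttype\tcv_term\n"
        "samples\tX\tcovariate\t\t\tstring\t\n"
    )
    with pytest.raises(UnknownCategoryError) as err:
        parse_attributes_metadata(doc)
    assert err.value.label == "covariate"
    # lenient mode keeps the raw label for the validator
    (a,) = parse_attributes_metadata(doc, strict=False)
    assert a.category == "covariate"


def test_parse_attributes_duplicate_pair():
    doc = (
        "subset\tattribute\tcategory\tdescription\tunit\ttype\tcv_term\n"
        "s\tX\tfactor\t\t\tstring\t\n"
        "s\tX\tfactor\t\t\tstring\t\n"
    )
    with pytest.raises(DuplicateAttributeError):
        parse_attributes_metadata(doc)


def test_attributes_roundtrip_one_per_category(plants_samples):
    collection = plants_samples
    collection.attributes.append(
        AttributeDef("plants", "Mass", Category.QUANTITATIVE, "mass", "g",
                     "float")
    )
    collection.attributes.append(
        AttributeDef("plants", "Color", Category.QUALITATIVE, "color")
    )
    collection.tables["plants"].column_names.extend(["Mass", "Color"])
    for row in collection.tables["plants"].rows:
        row.extend([1.0, "red"])
    text = attributes_to_text(collection)
    assert parse_attributes_metadata(text) == sorted(
        collection.attributes, key=lambda a: a.subset_name
    )


# ----------------------------------------------------------------- tables
def attr(subset, name, category, data_type="string", unit=""):
    return AttributeDef(subset, name, category, "", unit, data_type)


def test_read_table_worked_example():
    attrs = [
        attr("plants", "PlantID", Category.IDENTIFIER),
        attr("plants", "Treatment", Category.FACTOR),
    ]
    table, failures = read_data_table("PlantID\tTreatment\np1\tcontrol\n", attrs)
    assert table.rows == [["p1", "control"]] and failures == []


def test_missing_tokens_become_missing_marker():
    attrs = [attr("s", "x", Category.QUANTITATIVE, "float")]
    table, failures = read_data_table("x\nNA\n\n3.5\n", attrs)
    assert table.column("x") == [None, None, 3.5] and failures == []


@pytest.mark.parametrize(
    "text,value",
    [
        ("3.2e1", 32.0), ("0.5", 0.5), ("-7", -7.0), ("1e-3", 0.001),
        ("inf", float("inf")), ("2.5E2", 250.0), ("+4", 4.0), (".5", 0.5),
        ("5.", 5.0), ("0", 0.0),
    ],
)
def test_float_casting_matches_python_float(text, value):
    attrs = [attr("s", "x", Category.QUANTITATIVE, "float")]
    table, failures = read_data_table(f"x\n{text}\n", attrs)
    assert failures == [] and table.rows[0][0] == float(text) == value


@pytest.mark.parametrize(
    "text", ["abc", "1,5", "12a", "--3", "3.2.1", "1/2", "l.5", "NaNx",
             "2e", "0x1f"],
)
def test_uncastable_cell_recorded_and_set_missing(text):
    attrs = [attr("s", "x", Category.QUANTITATIVE, "float")]
    table, failures = read_data_table(f"x\n{text}\n", attrs, subset_name="s")
    assert table.rows[0][0] is None
    assert [(f.subset, f.column, f.row, f.text) for f in failures] == [
        ("s", "x", 1, text)
    ]


def test_integer_and_date_casting():
    attrs = [
        attr("s", "n", Category.QUANTITATIVE, "integer"),
        attr("s", "d", Category.QUALITATIVE, "date"),
    ]
    table, failures = read_data_table("n\td\n42\t2020-12-15\n3.5\t15/12/2020\n",
                                      attrs, subset_name="s")
    assert table.rows[0] == [42, datetime.date(2020, 12, 15)]
    assert table.rows[1] == [None, None]  # both uncastable
    assert {f.text for f in failures} == {"3.5", "15/12/2020"}


def test_column_mismatch_reports_both_sides():
    attrs = [attr("s", "x", Category.FACTOR)]
    with pytest.raises(ColumnMismatchError) as err:
        read_data_table("y\nv\n", attrs)
    assert err.value.missing_in_dict == ["y"]
    assert err.value.missing_in_table == ["x"]


def test_read_table_conserves_rows_and_cells(generated):
    for name, table in generated.tables.items():
        text = format_data_table(table)
        reread, _ = read_data_table(text, generated.attributes_for(name))
        assert reread.column_names == table.column_names
        assert reread.n_rows == table.n_rows
        assert sum(len(r) for r in reread.rows) == sum(
            len(r) for r in table.rows
        )


# ------------------------------------------------------------- collection
def test_load_collection_counts(tmp_path):
    out = tmp_path / "c"
    generate_collection(GeneratorSpec(seed=2), out)
    c = load_collection(out)
    assert len(c.tables) == 4
    assert len(c.graph.edges) == 3


def test_load_missing_attributes_file(tmp_path, generated_dir):
    (generated_dir / "attributes.tsv").unlink()
    with pytest.raises(FileNotFoundCollectionError) as err:
        load_collection(generated_dir)
    assert "attributes.tsv" in err.value.file_name


def test_write_load_roundtrip(tmp_path, generated):
    out = tmp_path / "rt"
    write_collection(generated, out)
    assert load_collection(out).structurally_equal(generated)


def test_write_structural_metadata_exactly_two_files(tmp_path, generated):
    written = write_structural_metadata(generated, tmp_path / "w")
    assert sorted(written) == ["attributes.tsv", "subsets.tsv"]


def test_write_is_byte_stable_and_a_fixed_point(tmp_path, generated):
    a, b = tmp_path / "a", tmp_path / "b"
    write_collection(generated, a)
    write_collection(generated, b)
    for f in ("subsets.tsv", "attributes.tsv"):
        assert (a / f).read_bytes() == (b / f).read_bytes()
    # write -> parse -> write is the identity on bytes (canonical form)
    reloaded = load_collection(a)
    c = tmp_path / "c"
    write_collection(reloaded, c)
    for f in ("subsets.tsv", "attributes.tsv"):
        assert (a / f).read_bytes() == (c / f).read_bytes()


@pytest.mark.parametrize("seed", range(0, 100, 7))
def test_parse_write_roundtrip_over_seeds(tmp_path, seed):
    spec = GeneratorSpec(seed=seed, n_plants=3, samples_per_plant_stage=1)
    out = tmp_path / f"s{seed}"
    original = generate_collection(spec, out)
    assert load_collection(out).structurally_equal(original)
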