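"""Merge semantics against a brute-force nested-loop join oracle."""

import pytest

from fairtables.datamodel import DataTable
from fairtables.errors import (
    NoCommonAncestorError,
    PredicateTypeMismatchError,
    UnknownColumnError,
    UnknownSubsetError,
)
from fairtables.merge import (
    Equals,
    Interval,
    execute_merge,
    filter_rows,
    lineage_merge,
    merge_across,
    plan_lineage_merge,
)
from fairtables.metadata_io import format_data_table
from fairtables.synthetic import AssaySpec, GeneratorSpec, generate_collection
from conftest import make_plants_samples


# ------------------------------------------------------------- oracle
def nested_loop_left_join(child: DataTable, parent: DataTable,
                          key: str) -> DataTable:
    """Reference semantics: for every child row, scan the parent for the
    single matching key; keep missing when no match."""
    ci, pi = child.column_index(key), parent.column_index(key)
    extra = [c for c in parent.column_names if c != key]
    rows = []
    for crow in child.rows:
        match = None
        for prow in parent.rows:
            if crow[ci] is not None and prow[pi] == crow[ci]:
                match = prow
                break
        rows.append(
            list(crow)
            + [match[parent.column_index(c)] if match else None for c in extra]
        )
    return DataTable(child.column_names + extra, rows)


def nested_loop_inner_join(left: DataTable, right: DataTable,
                           key: str) -> DataTable:
    li, ri = left.column_index(key), right.column_index(key)
    extra = [c for c in right.column_names if c != key]
    rows = []
    for lrow in left.rows:
        if lrow[li] is None:
            continue
        for rrow in right.rows:
            if rrow[ri] == lrow[li]:
                rows.append(
                    list(lrow) + [rrow[right.column_index(c)] for c in extra]
                )
    return DataTable(left.column_names + extra, rows)


# ------------------------------------------------------------- planning
def test_plan_for_worked_example(plants_samples):
    plan = plan_lineage_merge(plants_samples, "samples")
    assert [(s.left, s.right, s.key) for s in plan.join_steps] == [
        ("samples", "plants", "PlantID")
    ]


def test_plan_for_root_is_empty(plants_samples):
    plan = plan_lineage_merge(plants_samples, "plants")
    assert plan.join_steps == ()
    merged = execute_merge(plants_samples, plan)
    assert merged.rows == plants_samples.tables["plants"].rows


def test_plan_follows_ancestor_chain(generated):
    plan = plan_lineage_merge(generated, "biochemistry")
    assert [s.right for s in plan.join_steps] == ["samples", "plants"]


def test_plan_unknown_subset(plants_samples):
    with pytest.raises(UnknownSubsetError):
        plan_lineage_merge(plants_samples, "ghost")


# ------------------------------------------------------------ execution
def test_samples_inherit_plant_treatment(plants_samples):
    merged = lineage_merge(plants_samples, "samples")
    assert merged.n_rows == 3
    treatments = dict(zip(merged.column("SampleID"), merged.column("Treatment")))
    assert treatments == {"s1": "control", "s2": "control", "s3": "treated"}


def test_missing_parent_key_keeps_missing_values():
    c = make_plants_samples(sample_links=(("s1", "p1"), ("s2", None)))
    merged = lineage_merge(c, "samples")
    assert merged.n_rows == 2
    assert merged.column("Treatment") == ["control", None]


@pytest.mark.parametrize("seed", range(10))
def test_lineage_merge_equals_nested_loop_oracle(seed):
    c = generate_collection(GeneratorSpec(seed=seed, n_plants=5))
    for name in c.subset_names():
        merged = lineage_merge(c, name)
        expected = c.tables[name]
        node = name
        while (parent := c.graph.parent(node)) is not None:
            expected = nested_loop_left_join(
                expected, c.tables[parent], c.identifier_of(parent)
            )
            node = parent
        assert format_data_table(merged) == format_data_table(expected)
        assert merged.n_rows == c.tables[name].n_rows


# ---------------------------------------------------------------- cross
def test_cross_merge_counts_overlap(tmp_path):
    # two assays over 10 shared samples, thinned to a 7-row overlap
    c = generate_collection(
        GeneratorSpec(seed=4, n_plants=10, stages=("S1",), missing_rate=0.0)
    )
    c.tables["biochemistry"].rows = c.tables["biochemistry"].rows[:8]
    c.tables["metabolomics"].rows = c.tables["metabolomics"].rows[1:]
    merged = merge_across(c, ["biochemistry", "metabolomics"])
    assert merged.n_rows == 7  # samples measured by both assays


@pytest.mark.parametrize("seed", range(6))
def test_cross_merge_equals_nested_loop_oracle(seed):
    c = generate_collection(GeneratorSpec(seed=seed, n_plants=4))
    merged = merge_across(c, ["biochemistry", "metabolomics"])

    def renamed(name):
        t = c.tables[name]
        cols = [
            f"{name}.{col}" if col == "AssayID" else col
            for col in t.column_names
        ]
        return DataTable(cols, [list(r) for r in t.rows])

    expected = nested_loop_inner_join(
        renamed("biochemistry"), renamed("metabolomics"), "SampleID"
    )
    assert format_data_table(merged) == format_data_table(expected)


def test_cross_merge_singleton_equals_lineage(generated):
    a = merge_across(generated, ["biochemistry"])
    b = lineage_merge(generated, "biochemistry")
    assert format_data_table(a) == format_data_table(b)


def test_cross_merge_requires_common_ancestor(plants_samples):
    from fairtables.datamodel import (
        AttributeDef, Category, SubsetDef, build_linkage_graph,
    )

    c = plants_samples
    c.subsets.append(SubsetDef("soil", "soil.txt", "soil", "SoilID", ""))
    c.attributes.append(
        AttributeDef("soil", "SoilID", Category.IDENTIFIER, "soil id")
    )
    c.tables["soil"] = DataTable(["SoilID"], [["z1"]])
    c.graph = build_linkage_graph(c.subsets)
    with pytest.raises(NoCommonAncestorError):
        merge_across(c, ["samples", "soil"])


def test_cross_merge_inner_stage_is_associative():
    c = generate_collection(
        GeneratorSpec(
            seed=8,
            n_plants=3,
            assays=(AssaySpec("a1", 2), AssaySpec("a2", 2), AssaySpec("a3", 2)),
        )
    )
    left = merge_across(c, ["a1", "a2", "a3"])
    ab = merge_across(c, ["a1", "a2"])
    # row multiset must agree with joining (a1⋈a2)⋈a3 key-wise
    key_rows = sorted(map(str, left.column("SampleID")))
    ab_then = sorted(
        k for k in map(str, ab.column("SampleID"))
        if k in set(map(str, c.tables["a3"].column("SampleID")))
    )
    assert key_rows == ab_then


# --------------------------------------------------------------- filters
def test_filter_equality_on_merged_fixture(plants_samples):
    merged = lineage_merge(plants_samples, "samples")
    kept = filter_rows(merged, "Treatment", Equals("control"))
    assert kept.column("SampleID") == ["s1", "s2"]


def test_filter_unbounded_interval_drops_only_missing():
    t = DataTable(["x"], [[1.0], [None], [-3.5]])
    kept = filter_rows(t, "x", Interval())
    assert kept.column("x") == [1.0, -3.5]


def test_filter_equality_absent_value(plants_samples):
    merged = lineage_merge(plants_samples, "samples")
    assert filter_rows(merged, "Treatment", Equals("ghost")).n_rows == 0


def test_filter_interval_on_text_column_rejected(plants_samples):
    merged = lineage_merge(plants_samples, "samples")
    with pytest.raises(PredicateTypeMismatchError):
        filter_rows(merged, "Treatment", Interval(lo=0.0))
    with pytest.raises(UnknownColumnError):
        filter_rows(merged, "ghost", Equals("x"))


def test_filtering_is_monotone_and_idempotent(generated):
    merged = lineage_merge(generated, "biochemistry")
    pred = Interval(lo=0.5)
    once = filter_rows(merged, "biochemistry_v01", pred)
    twice = filter_rows(once, "biochemistry_v01", pred)
    assert once.n_rows <= merged.n_rows
    assert once.rows == twice.rows
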