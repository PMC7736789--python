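import pytest

from fairtables.datamodel import (
    AttributeDef,
    Category,
    DataTable,
    DatasetCollection,
    SubsetDef,
    build_linkage_graph,
)
from fairtables.synthetic import GeneratorSpec, generate_collection


def make_plants_samples(sample_links=(("s1", "p1"), ("s2", "p1"), ("s3", "p2"))):
    """The canonical two-table worked example: plants under two treatments,
    samples each linked to the plant it was taken from."""
    subsets = [
        SubsetDef("plants", "plants.txt", "plant", "PlantID", ""),
        SubsetDef("samples", "samples.txt", "sample", "SampleID", "plants"),
    ]
    attributes = [
        AttributeDef("plants", "PlantID", Category.IDENTIFIER, "plant id"),
        AttributeDef("plants", "Treatment", Category.FACTOR, "treatment"),
        AttributeDef("samples", "SampleID", Category.IDENTIFIER, "sample id"),
        AttributeDef("samples", "PlantID", Category.IDENTIFIER, "source plant"),
    ]
    tables = {
        "plants": DataTable(
            ["PlantID", "Treatment"], [["p1", "control"], ["p2", "treated"]]
        ),
        "samples": DataTable(
            ["SampleID", "PlantID"], [list(link) for link in sample_links]
        ),
    }
    return DatasetCollection(
        subsets=subsets,
        attributes=attributes,
        tables=tables,
        graph=build_linkage_graph(subsets),
        descriptive={"title": "worked example", "license": "CC-BY-4.0"},
    )


@pytest.fixture
def plants_samples():
    return make_plants_samples()


@pytest.fixture
def small_spec():
    return GeneratorSpec(seed=11, n_plants=4, samples_per_plant_stage=1)


@pytest.fixture
def generated(small_spec):
    return generate_collection(small_spec)


@pytest.fixture
def generated_dir(tmp_path, small_spec):
    out = tmp_path / "collection"
    generate_collection(small_spec, out)
    return out
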