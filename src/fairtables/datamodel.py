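"""Core types of the linked-table data model.

An experimental study is recorded as a *collection*: one tab-separated data
table per observational entity (plants, samples, assay results, ...), plus a
dictionary describing every table (its key concept and the table it is
obtained from) and every column (category, description, unit, data type,
controlled-vocabulary term).  The "is obtained from" links between tables
form a lineage forest: each table has at most one parent, reflecting the
order in which data were acquired as the experiment progressed.

Columns are classified with a closed four-value vocabulary — ``identifier``,
``factor``, ``quantitative``, ``qualitative`` — which is what makes the
collection machine-actionable: identifiers are join keys, factors are the
controlled independent variables of the design, and quantitative/qualitative
mark the dependent variables.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field
from typing import Union

import networkx as nx

from .errors import (
    CycleDetectedError,
    SelfParentError,
    UnknownParentError,
    UnknownSubsetError,
)

__all__ = [
    "Category",
    "DATA_TYPES",
    "AttributeDef",
    "SubsetDef",
    "DataTable",
    "LinkageGraph",
    "DatasetCollection",
    "CastFailure",
    "Cell",
    "build_linkage_graph",
    "topological_order",
    "ancestor_chain",
]


class Category(str, enum.Enum):
    """Closed vocabulary classifying each column of a data table."""

    IDENTIFIER = "identifier"
    FACTOR = "factor"
    QUANTITATIVE = "quantitative"
    QUALITATIVE = "qualitative"

    @classmethod
    def parse(cls, label: str) -> "Category":
        """Parse a category label, case-insensitively.

        Raises :class:`~fairtables.errors.UnknownCategoryError` for any
        label outside the four-value vocabulary.
        """
        from .errors import UnknownCategoryError

        try:
            return cls(label.strip().lower())
        except ValueError:
            raise UnknownCategoryError(label) from None


#: Admissible declared data types for a column.
DATA_TYPES = ("string", "integer", "float", "date")

#: A table cell: text, integer, float, date, or the missing marker (None).
Cell = Union[str, int, float, datetime.date, None]


@dataclass(frozen=True)
class AttributeDef:
    """Dictionary entry for one column of one subset's table.

    ``category`` is normally a :class:`Category`; a plain string survives
    only on the lenient loading path so the validator can report the
    out-of-vocabulary label (rule V06) instead of refusing to load.
    ``cv_term`` is carried verbatim (IRI or CURIE); no resolution is ever
    attempted.
    """

    subset_name: str
    attribute_name: str
    category: Union[Category, str]
    description: str = ""
    unit: str = ""
    data_type: str = "string"
    cv_term: str = ""

    def __post_init__(self):
        if not self.attribute_name:
            raise ValueError("attribute_name must be non-empty")
        if self.data_type not in DATA_TYPES:
            raise ValueError(
                f"data_type must be one of {DATA_TYPES}, got {self.data_type!r}"
            )
        if self.category == Category.QUANTITATIVE and self.data_type not in (
            "integer",
            "float",
        ):
            raise ValueError(
                f"quantitative attribute {self.attribute_name!r} must have an "
                f"integer or float data type, got {self.data_type!r}"
            )


@dataclass(frozen=True)
class SubsetDef:
    """One entity/table of the collection.

    ``parent_subset`` is empty for a root table; otherwise it names the
    table this one is obtained from (a sample is obtained from a plant).
    ``extras`` holds unrecognized metadata columns verbatim.
    """

    subset_name: str
    file_name: str
    entity_label: str
    identifier_attribute: str
    parent_subset: str = ""
    cv_term: str = ""
    extras: tuple = ()  # tuple of (key, value) pairs, order preserved

    def __post_init__(self):
        if not self.subset_name:
            raise ValueError("subset_name must be non-empty")
        if not self.identifier_attribute:
            raise ValueError(
                f"subset {self.subset_name!r} must declare an identifier attribute"
            )


@dataclass
class DataTable:
    """An ordered, typed rectangular table.

    Rows and columns preserve file order.  Cells are Python values
    (str/int/float/date) or ``None`` for missing.
    """

    column_names: list[str]
    rows: list[list[Cell]]

    def __post_init__(self):
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("column names must be unique within a table")
        for i, row in enumerate(self.rows):
            if len(row) != len(self.column_names):
                raise ValueError(
                    f"row {i + 1} has {len(row)} cells, expected "
                    f"{len(self.column_names)}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column_index(self, name: str) -> int:
        from .errors import UnknownColumnError

        try:
            return self.column_names.index(name)
        except ValueError:
            raise UnknownColumnError(f"no column named {name!r}") from None

    def column(self, name: str) -> list[Cell]:
        i = self.column_index(name)
        return [row[i] for row in self.rows]

    def to_pandas(self):
        """Object-dtype DataFrame (cells kept as Python values, None for missing)."""
        import pandas as pd

        df = pd.DataFrame(
            {
                name: pd.Series(self.column(name), dtype=object)
                for name in self.column_names
            },
            columns=self.column_names,
        )
        if not self.rows:  # keep the column structure even when empty
            df = pd.DataFrame(columns=self.column_names, dtype=object)
        return df


@dataclass(frozen=True)
class CastFailure:
    """One cell that could not be cast to its declared data type.

    Collected (not raised) so the validator can report every problem in
    one pass; the offending cell is set to missing.
    """

    subset: str
    column: str
    row: int  # 1-based data-row number
    text: str


class LinkageGraph:
    """The "is obtained from" forest over subsets.

    Wraps a directed graph with child→parent edges.  Invariants (enforced
    by :func:`build_linkage_graph`): at most one outgoing edge per node,
    no cycles.
    """

    def __init__(self, graph: nx.DiGraph):
        self._g = graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Sorted (child, parent) pairs."""
        return sorted(self._g.edges)

    def __contains__(self, subset: str) -> bool:
        return subset in self._g

    def parent(self, subset: str) -> str | None:
        if subset not in self._g:
            raise UnknownSubsetError(f"unknown subset {subset!r}")
        succ = list(self._g.successors(subset))
        return succ[0] if succ else None

    def roots(self) -> list[str]:
        return sorted(n for n in self._g.nodes if self._g.out_degree(n) == 0)

    def children(self, subset: str) -> list[str]:
        if subset not in self._g:
            raise UnknownSubsetError(f"unknown subset {subset!r}")
        return sorted(self._g.predecessors(subset))


def build_linkage_graph(subsets: list[SubsetDef]) -> LinkageGraph:
    """Build the lineage forest from subset parent links.

    Raises ``SelfParentError``, ``UnknownParentError`` or
    ``CycleDetectedError`` when the links do not form a forest.
    """
    names = [s.subset_name for s in subsets]
    name_set = set(names)
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for s in subsets:
        if not s.parent_subset:
            continue
        if s.parent_subset == s.subset_name:
            raise SelfParentError(f"subset {s.subset_name!r} is its own parent")
        if s.parent_subset not in name_set:
            raise UnknownParentError(
                f"subset {s.subset_name!r} is obtained from unknown subset "
                f"{s.parent_subset!r}"
            )
        g.add_edge(s.subset_name, s.parent_subset)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise CycleDetectedError(f"lineage links form a cycle: {cycle}")
    return LinkageGraph(g)


def topological_order(graph: LinkageGraph) -> list[str]:
    """Subset names with every parent before all of its children.

    Deterministic: ties are broken by lexicographic subset name.
    """
    # Edges run child -> parent, so sort on the reversed graph.
    return list(nx.lexicographical_topological_sort(graph._g.reverse(copy=False)))


def ancestor_chain(graph: LinkageGraph, subset: str) -> list[str]:
    """[parent, grandparent, ..., root] for a subset; empty for a root."""
    if subset not in graph:
        raise UnknownSubsetError(f"unknown subset {subset!r}")
    chain: list[str] = []
    node = graph.parent(subset)
    while node is not None:
        chain.append(node)
        node = graph.parent(node)
    return chain


@dataclass
class DatasetCollection:
    """A whole experiment: definitions, dictionary, typed tables, lineage.

    ``descriptive`` is an open key/value block (title, license, authors)
    passed through to exports untouched — the repository's concern, not
    structural metadata.  ``cast_failures`` and ``load_defects`` hold
    problems tolerated at load time for the validator to report.
    """

    subsets: list[SubsetDef]
    attributes: list[AttributeDef]
    tables: dict[str, DataTable]
    graph: LinkageGraph
    descriptive: dict = field(default_factory=dict)
    cast_failures: list[CastFailure] = field(default_factory=list)
    load_defects: list[tuple[str, str, str]] = field(default_factory=list)
    # load_defects entries: (rule_code, subset, message)

    # -------------------------------------------------------- accessors
    def subset(self, name: str) -> SubsetDef:
        for s in self.subsets:
            if s.subset_name == name:
                return s
        raise UnknownSubsetError(f"unknown subset {name!r}")

    def subset_names(self) -> list[str]:
        return [s.subset_name for s in self.subsets]

    def attributes_for(self, subset_name: str) -> list[AttributeDef]:
        """Attribute dictionary entries for one subset, declaration order."""
        return [a for a in self.attributes if a.subset_name == subset_name]

    def attribute(self, subset_name: str, attribute_name: str) -> AttributeDef:
        for a in self.attributes:
            if a.subset_name == subset_name and a.attribute_name == attribute_name:
                return a
        from .errors import UnknownColumnError

        raise UnknownColumnError(
            f"no attribute {attribute_name!r} in subset {subset_name!r}"
        )

    def identifier_of(self, subset_name: str) -> str:
        return self.subset(subset_name).identifier_attribute

    # -------------------------------------------------------- equality
    def structurally_equal(self, other: "DatasetCollection") -> bool:
        """Field-for-field equality of definitions, dictionary, cells and
        descriptive block (load/export round-trip check).

        Declaration order of subsets/attribute lists is not significant
        (canonical serialization reorders rows topologically); row and
        column order inside data tables is strict.
        """
        def _skey(s):
            return s.subset_name

        def _akey(a):
            # stable sort: within-subset declaration order stays significant
            return a.subset_name

        return (
            sorted(self.subsets, key=_skey) == sorted(other.subsets, key=_skey)
            and sorted(self.attributes, key=_akey)
            == sorted(other.attributes, key=_akey)
            and set(self.tables) == set(other.tables)
            and all(
                self.tables[k].column_names == other.tables[k].column_names
                and self.tables[k].rows == other.tables[k].rows
                for k in self.tables
            )
            and self.descriptive == other.descriptive
        )
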