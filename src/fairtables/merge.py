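"""Identifier-driven combination of subsets.

Two operations cover the analyst's needs without hand manipulation of the
tables: a *lineage merge* joins a subset with all of its ancestors (each
assay row pulls in its sample's and plant's columns), and a *cross merge*
joins sibling subsets through their lowest common ancestor's identifier
(two assays compared on the samples measured by both).

Join semantics: lineage joins are many-to-one LEFT joins from child onto
parent — the most-derived subset's rows are never invented or dropped, and
rows with a missing parent key keep missing values in the parent-derived
columns.  Cross-subset joins are INNER — cross-assay analysis naturally
restricts to commonly measured units.  Key comparison is exact string
equality on the canonical cell text, the same rule as the validator.

Column collisions are disambiguated with a ``subsetname.`` prefix (join
identifier columns are kept once, unprefixed); renames are injective and
reversible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .datamodel import (
    Category,
    Cell,
    DataTable,
    DatasetCollection,
    ancestor_chain,
)
from .errors import (
    KeyColumnAbsentError,
    NoCommonAncestorError,
    PredicateTypeMismatchError,
    UnknownColumnError,
    UnknownSubsetError,
    UnmergeableLineageError,
)
from .metadata_io import format_cell

__all__ = [
    "JoinStep",
    "MergePlan",
    "Equals",
    "Interval",
    "plan_lineage_merge",
    "execute_merge",
    "merge_across",
    "filter_rows",
    "lineage_merge",
]


@dataclass(frozen=True)
class JoinStep:
    """One left join: ``left``'s accumulated frame onto ``right`` keyed on
    ``right``'s identifier column (carried by ``left`` as a foreign key)."""

    left: str
    right: str
    key: str


@dataclass(frozen=True)
class MergePlan:
    target_subsets: tuple[str, ...]
    join_steps: tuple[JoinStep, ...]
    column_renames: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        renamed = list(self.column_renames.values())
        if len(set(renamed)) != len(renamed):
            raise ValueError("column renames must be injective")


def _collision_renames(
    collection: DatasetCollection, members: list[str], join_keys: set[str]
) -> dict[str, str]:
    """Map ``subset.column`` qualified names for columns whose bare name
    appears in more than one member subset (join keys excluded)."""
    owners: dict[str, list[str]] = {}
    for name in members:
        table = collection.tables.get(name)
        cols = table.column_names if table else [
            a.attribute_name for a in collection.attributes_for(name)
        ]
        for col in cols:
            if col in join_keys:
                continue
            owners.setdefault(col, []).append(name)
    renames: dict[str, str] = {}
    for col, subs in owners.items():
        if len(subs) > 1:
            for sub in subs:
                renames[f"{sub}\x00{col}"] = f"{sub}.{col}"
    return renames


def plan_lineage_merge(collection: DatasetCollection, subset: str) -> MergePlan:
    """Plan the join of a subset with its whole ancestor chain.

    Each step is keyed on the respective parent's identifier attribute;
    a step's key must exist in both tables with identifier category, else
    the lineage is declared unmergeable.
    """
    if subset not in set(collection.subset_names()):
        raise UnknownSubsetError(f"unknown subset {subset!r}")
    chain = ancestor_chain(collection.graph, subset)
    steps: list[JoinStep] = []
    child = subset
    for parent in chain:
        key = collection.identifier_of(parent)
        _check_key(collection, child, parent, key)
        steps.append(JoinStep(left=child, right=parent, key=key))
        child = parent
    members = [subset, *chain]
    join_keys = {s.key for s in steps}
    renames = _collision_renames(collection, members, join_keys)
    return MergePlan(
        target_subsets=tuple(members),
        join_steps=tuple(steps),
        column_renames=renames,
    )


def _check_key(collection, child: str, parent: str, key: str) -> None:
    for name in (child, parent):
        table = collection.tables.get(name)
        if table is None:
            raise UnmergeableLineageError(f"subset {name!r} has no data table")
        if key not in table.column_names:
            raise UnmergeableLineageError(
                f"table {name!r} lacks the join key column {key!r}"
            )


# ---------------------------------------------------------------- frames
def _frame(collection: DatasetCollection, subset: str,
           renames: dict[str, str], drop: set[str] = frozenset()) -> pd.DataFrame:
    """Object-dtype frame of a subset with canonical-text join keys and
    collision renames applied."""
    table = collection.tables[subset]
    df = table.to_pandas()
    mapping = {}
    for col in df.columns:
        new = renames.get(f"{subset}\x00{col}")
        if new:
            mapping[col] = new
    if mapping:
        df = df.rename(columns=mapping)
    if drop:
        df = df.drop(columns=[c for c in df.columns if c in drop])
    return df


def _canonical_key(series: pd.Series) -> pd.Series:
    return series.map(lambda v: None if v is None else format_cell(v))


def _left_join(left: pd.DataFrame, right: pd.DataFrame, key: str) -> pd.DataFrame:
    """Order-preserving left join on canonical key text; the right side
    must be unique on the key (many-to-one)."""
    rk = _canonical_key(right[key])
    if rk.dropna().duplicated().any():
        raise UnmergeableLineageError(
            f"join key {key!r} is not unique in the parent table"
        )
    lookup = {
        k: row for k, row in zip(rk, right.drop(columns=[key]).itertuples(index=False))
    }
    extra_cols = [c for c in right.columns if c != key]
    lk = _canonical_key(left[key])
    extras = {c: [] for c in extra_cols}
    for k in lk:
        row = lookup.get(k) if k is not None else None
        for i, c in enumerate(extra_cols):
            extras[c].append(row[i] if row is not None else None)
    out = left.copy()
    for c in extra_cols:
        out[c] = pd.Series(extras[c], dtype=object, index=out.index)
    return out


def execute_merge(collection: DatasetCollection, plan: MergePlan) -> DataTable:
    """Execute a lineage merge plan.

    The output has exactly the starting subset's rows, in order; columns
    are the starting subset's, then each ancestor's non-key columns in
    step order.
    """
    start = plan.target_subsets[0]
    if start not in collection.tables:
        raise UnmergeableLineageError(f"subset {start!r} has no data table")
    df = _frame(collection, start, plan.column_renames)
    for step in plan.join_steps:
        if step.key not in df.columns:
            raise KeyColumnAbsentError(
                f"join key {step.key!r} absent from the accumulated table"
            )
        right = _frame(collection, step.right, plan.column_renames)
        df = _left_join(df, right, step.key)
    return _to_table(df)


def lineage_merge(collection: DatasetCollection, subset: str) -> DataTable:
    """Convenience: plan and execute the lineage merge of one subset."""
    return execute_merge(collection, plan_lineage_merge(collection, subset))


def _to_table(df: pd.DataFrame) -> DataTable:
    rows = [
        [None if _is_na(v) else v for v in row]
        for row in df.itertuples(index=False, name=None)
    ]
    return DataTable(column_names=list(df.columns), rows=rows)


def _is_na(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


# ---------------------------------------------------------------- cross
def _lowest_common_ancestor(collection: DatasetCollection,
                            subsets: list[str]) -> str:
    chains = []
    for s in subsets:
        if s not in set(collection.subset_names()):
            raise UnknownSubsetError(f"unknown subset {s!r}")
        chains.append([s, *ancestor_chain(collection.graph, s)])
    common = set(chains[0])
    for c in chains[1:]:
        common &= set(c)
    if not common:
        raise NoCommonAncestorError(
            f"subsets {subsets} share no common ancestor"
        )
    # the LCA is the common node nearest the targets = first hit walking
    # up from any one target
    return next(n for n in chains[0] if n in common)


def merge_across(collection: DatasetCollection, subsets: list[str]) -> DataTable:
    """Join several subsets through their lowest common ancestor (LCA).

    Each subset is lineage-merged through the ancestors strictly below the
    LCA — so every partial result carries the LCA's identifier column —
    then the partial results are inner-joined pairwise on that identifier,
    left to right in the given order.
    """
    if len(subsets) == 1:
        return lineage_merge(collection, subsets[0])
    lca = _lowest_common_ancestor(collection, subsets)
    key = collection.identifier_of(lca)

    # collision bookkeeping over every member subset involved
    members: list[str] = []
    partial_chains: list[list[str]] = []
    for s in subsets:
        chain = [s] if s == lca else [s, *_chain_below(collection, s, lca)]
        partial_chains.append(chain)
        for m in chain:
            if m not in members:
                members.append(m)
    join_keys = {key}
    for chain in partial_chains:
        for m in chain:
            if m != lca:
                parent = collection.graph.parent(m)
                if parent is not None and parent in members:
                    join_keys.add(collection.identifier_of(parent))
    renames = _collision_renames(collection, members, join_keys)

    partials: list[pd.DataFrame] = []
    for s, chain in zip(subsets, partial_chains):
        _require_table(collection, s)
        df = _frame(collection, s, renames)
        child = s
        for parent in chain[1:]:
            pkey = collection.identifier_of(parent)
            _check_key(collection, child, parent, pkey)
            df = _left_join(df, _frame(collection, parent, renames), pkey)
            child = parent
        if key not in df.columns:
            raise UnmergeableLineageError(
                f"subset {s!r} does not carry the common key {key!r}"
            )
        partials.append(df)

    out = partials[0]
    for df in partials[1:]:
        out = _inner_join(out, df, key)
    return _to_table(out)


def _chain_below(collection: DatasetCollection, subset: str, lca: str) -> list[str]:
    chain = ancestor_chain(collection.graph, subset)
    return chain[: chain.index(lca)] if lca in chain else chain


def _require_table(collection: DatasetCollection, subset: str) -> None:
    if subset not in collection.tables:
        raise UnmergeableLineageError(f"subset {subset!r} has no data table")


def _inner_join(left: pd.DataFrame, right: pd.DataFrame, key: str) -> pd.DataFrame:
    """Inner join preserving left order, then right order within a key."""
    rk = _canonical_key(right[key])
    groups: dict[str, list] = {}
    rcols = [c for c in right.columns if c != key]
    for k, row in zip(rk, right[rcols].itertuples(index=False, name=None)):
        if k is not None:
            groups.setdefault(k, []).append(row)
    lk = _canonical_key(left[key])
    out_rows = []
    for k, lrow in zip(lk, left.itertuples(index=False, name=None)):
        if k is None:
            continue
        for rrow in groups.get(k, ()):
            out_rows.append(lrow + rrow)
    cols = list(left.columns) + rcols
    return pd.DataFrame(out_rows, columns=cols, dtype=object)


# ---------------------------------------------------------------- filters
@dataclass(frozen=True)
class Equals:
    """Equality predicate on the canonical cell text."""

    value: object

    def matches(self, cell: Cell) -> bool:
        if cell is None:
            return False
        return format_cell(cell) == (
            self.value if isinstance(self.value, str) else format_cell(self.value)
        )


@dataclass(frozen=True)
class Interval:
    """Closed numeric interval; ``None`` bounds are unbounded."""

    lo: float | None = None
    hi: float | None = None

    def matches(self, cell: Cell) -> bool:
        if not isinstance(cell, (int, float)) or isinstance(cell, bool):
            return False
        lo = -math.inf if self.lo is None else self.lo
        hi = math.inf if self.hi is None else self.hi
        return lo <= cell <= hi


def filter_rows(table: DataTable, attribute: str, predicate) -> DataTable:
    """Row-order-preserving selection; missing cells never match.

    Interval predicates are only admissible on numeric (quantitative)
    columns; applying one to a column with non-numeric cells raises
    :class:`PredicateTypeMismatchError`.
    """
    idx = table.column_index(attribute)  # raises UnknownColumnError
    if isinstance(predicate, Interval):
        for v in table.column(attribute):
            if v is not None and (
                not isinstance(v, (int, float)) or isinstance(v, bool)
            ):
                raise PredicateTypeMismatchError(
                    f"interval predicate on non-numeric column {attribute!r}"
                )
    rows = [row for row in table.rows if predicate.matches(row[idx])]
    return DataTable(column_names=list(table.column_names), rows=rows)
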