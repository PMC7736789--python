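"""Exception hierarchy.

Every error raised by the library derives from :class:`FairTablesError`
so callers (and the CLI) can distinguish library failures from bugs.
"""


class FairTablesError(Exception):
    """Base class for all errors raised by fairtables."""


# ---------------------------------------------------------------- lineage
class UnknownParentError(FairTablesError):
    """A subset's parent link names no known subset."""


class SelfParentError(FairTablesError):
    """A subset declares itself as its own parent."""


class CycleDetectedError(FairTablesError):
    """Following parent links revisits a subset."""


class UnknownSubsetError(FairTablesError):
    """A subset name is not part of the collection/graph."""


# ---------------------------------------------------------------- parsing
class MissingHeaderColumnError(FairTablesError):
    """A required metadata header column is absent."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"missing required header column: {column!r}")


class EmptyDocumentError(FairTablesError):
    """A metadata document contains no data rows."""


class DuplicateSubsetError(FairTablesError):
    """The same subset name is declared twice."""


class DuplicateAttributeError(FairTablesError):
    """The same (subset, attribute) pair is declared twice."""


class UnknownCategoryError(FairTablesError):
    """An attribute category is outside the 4-value vocabulary."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(
            f"unknown category {label!r}; admissible values are "
            "identifier, factor, quantitative, qualitative"
        )


class ColumnMismatchError(FairTablesError):
    """A data table's header disagrees with its attribute dictionary."""

    def __init__(self, missing_in_dict, missing_in_table):
        self.missing_in_dict = sorted(missing_in_dict)
        self.missing_in_table = sorted(missing_in_table)
        super().__init__(
            f"columns absent from dictionary: {self.missing_in_dict}; "
            f"dictionary attributes absent from table: {self.missing_in_table}"
        )


class FileNotFoundCollectionError(FairTablesError):
    """A required collection file is missing on disk."""

    def __init__(self, file_name: str):
        self.file_name = file_name
        super().__init__(f"required collection file not found: {file_name}")


# ---------------------------------------------------------------- merging
class MergeError(FairTablesError):
    """Base class for merge failures."""


class UnmergeableLineageError(MergeError):
    """A structural defect (missing/duplicated key) prevents a lineage merge."""


class KeyColumnAbsentError(MergeError):
    """A join key column is absent from a table (defensive check)."""


class NoCommonAncestorError(MergeError):
    """The requested subsets share no common ancestor in the lineage forest."""


class UnknownColumnError(FairTablesError):
    """A referenced column does not exist in the table."""


class PredicateTypeMismatchError(FairTablesError):
    """An interval predicate was applied to a non-numeric column."""


# ---------------------------------------------------------------- datapackage
class MalformedJSONError(FairTablesError):
    """A descriptor document is not valid JSON."""


class SchemaViolationError(FairTablesError):
    """A descriptor violates the datapackage profile."""


class UnknownCategoryPropertyError(SchemaViolationError):
    """A descriptor field lacks the category property or uses a bad value."""


class DanglingForeignKeyError(SchemaViolationError):
    """A foreignKey references a resource or key that does not exist."""


class ValidationRequiredError(FairTablesError):
    """Export refused because the collection has validation errors."""


# ---------------------------------------------------------------- generator
class InvalidSpecError(FairTablesError):
    """A generator specification violates its invariants."""


class UnsupportedCodeError(FairTablesError):
    """The violation injector does not support the requested rule code."""
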