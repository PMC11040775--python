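"""Exception hierarchy.

Mutating operations raise eagerly on malformed input; ``validate_study`` never
raises — it reports (see :mod:`omicrate.model`).
"""


class OmicrateError(Exception):
    """Base class for all package errors."""


class InvalidNameError(OmicrateError, ValueError):
    """Identifier empty, or contains path separators / reserved components."""


class InvalidTableError(OmicrateError, ValueError):
    """A results/feature/mapping table violates a structural invariant."""


class UnknownTargetError(OmicrateError, KeyError):
    """Requested study/model/test/column/database does not exist."""


class UnknownTestError(UnknownTargetError):
    """Enrichment references a test absent from the model's differential tests."""


class UnknownTermError(UnknownTargetError):
    """Enrichment references a term absent from its annotation database."""


class UnknownColumnError(UnknownTargetError):
    """A query, clause or linkout references a column not in the table."""


class NonNumericColumnError(OmicrateError, TypeError):
    """A threshold clause or statistic ranking targets a non-numeric column."""


class ValidationFailedError(OmicrateError):
    """Install refused because validation produced errors (report attached)."""

    def __init__(self, report):
        self.report = report
        summary = "; ".join(f"{i.code}@{i.location}" for i in report.errors)
        super().__init__(f"study failed validation: {summary}")


class RegistryError(OmicrateError):
    """Registry-level failure (permissions, missing root)."""


class StudyNotFoundError(OmicrateError, KeyError):
    """No installed container with the requested name."""


class ChecksumMismatchError(OmicrateError):
    """Container file content disagrees with its manifest checksum."""


class SchemaVersionError(OmicrateError):
    """Container schema major version is newer than this reader supports."""


class UnsupportedFormatError(OmicrateError, ValueError):
    """Serialization format outside {tsv, csv, json, feather}."""


class EmptySetError(OmicrateError, ValueError):
    """Similarity coefficients are undefined for empty feature sets."""


class TermNotTestedError(OmicrateError):
    """Term's feature set is disjoint from the features present in the test."""
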