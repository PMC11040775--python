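"""The study -> model -> test data model.

Every omic analysis fits a natural hierarchy: a *study* holds one or more
statistical *models* of the data (e.g. the same counts modelled with and
without a batch covariate, or one model per omic layer in a multi-omic
study), and each model holds one or more hypothesis *tests*.  The container
archives analyst-supplied results under that hierarchy without re-running any
statistics: the minimal payload is a single per-test results table (feature
identifier plus at least one numeric column).  Everything else — assay
matrices, feature metadata, annotation databases, enrichment results, a
cross-model feature-ID mapping, linkouts, a report — is optional and
incremental.

Mutating helpers validate eagerly and raise; :func:`validate_study` is total:
it never raises on well-typed input and returns a :class:`ValidationReport`
listing errors (installation blockers) and warnings.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidNameError,
    InvalidTableError,
    UnknownTargetError,
    UnknownTermError,
    UnknownTestError,
)

__all__ = [
    "ColumnMeta",
    "ResultsTable",
    "Test",
    "Assay",
    "AnnotationDatabase",
    "EnrichmentResults",
    "LinkoutSpec",
    "PlotHook",
    "Model",
    "Study",
    "Issue",
    "ValidationReport",
    "create_study",
    "add_results",
    "add_assays",
    "add_enrichments",
    "add_mapping",
    "attach_metadata",
    "validate_study",
    "infer_column_roles",
]

ROLES = {"feature_id", "effect_size", "statistic", "p_value", "adjusted_p_value", "other"}

# Case-insensitive column-name tokens used when the analyst supplies no roles.
_ROLE_TOKENS = {
    "p_value": {"p_value", "pval", "p.value", "pvalue", "p", "nominal"},
    "adjusted_p_value": {
        "adj_p_val", "adj.p.val", "adj_p_value", "adj_p", "padj", "fdr",
        "q_value", "qval", "qvalue", "adjusted",
    },
    "effect_size": {"logfc", "log2fc", "log2foldchange", "lfc", "effect", "effect_size", "beta"},
    "statistic": {"t", "stat", "statistic", "t_statistic", "tstat", "z", "lr"},
}

_BAD_NAME = re.compile(r"[/\\\x00]")


def check_identifier(name: str, what: str = "identifier") -> str:
    """Reject names unusable as registry/container path components."""
    if not isinstance(name, str) or not name.strip():
        raise InvalidNameError(f"{what} must be a non-empty string, got {name!r}")
    if _BAD_NAME.search(name) or name in {".", ".."}:
        raise InvalidNameError(f"{what} {name!r} contains path separators or is reserved")
    return name


def infer_column_roles(columns: Sequence[str]) -> dict[str, str]:
    """Guess column roles from conventional names; the first column is the key."""
    roles: dict[str, str] = {}
    for i, col in enumerate(columns):
        if i == 0:
            roles[col] = "feature_id"
            continue
        low = col.lower()
        for role, tokens in _ROLE_TOKENS.items():
            if low in tokens:
                roles[col] = role
                break
        else:
            roles[col] = "other"
    return roles


@dataclass
class ColumnMeta:
    role: str = "other"
    tooltip: str = ""
    display_name: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise InvalidTableError(f"unknown column role {self.role!r}")

    def to_dict(self) -> dict:
        return {"role": self.role, "tooltip": self.tooltip, "display_name": self.display_name}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColumnMeta":
        return cls(role=d.get("role", "other"), tooltip=d.get("tooltip", ""),
                   display_name=d.get("display_name", ""))


class ResultsTable:
    """Per-test feature-level statistics: the minimal required payload.

    Wraps a :class:`pandas.DataFrame` whose first column (by convention, or
    whichever column carries ``role="feature_id"``) holds opaque string
    feature identifiers; the remaining columns are the analyst's statistics
    (effect size, test statistic, nominal and adjusted p-values, ...).

    The frame may be supplied lazily via ``loader`` — container loading uses
    this so large tables are parsed only on first access.
    """

    def __init__(
        self,
        df: Optional[pd.DataFrame] = None,
        column_meta: Optional[Mapping[str, ColumnMeta | Mapping]] = None,
        loader: Optional[Callable[[], pd.DataFrame]] = None,
    ):
        if df is None and loader is None:
            raise InvalidTableError("ResultsTable needs a DataFrame or a loader")
        self._df: Optional[pd.DataFrame] = None
        self._loader = loader
        self._column_meta: dict[str, ColumnMeta] = {}
        if column_meta:
            for col, meta in column_meta.items():
                self._column_meta[col] = (
                    meta if isinstance(meta, ColumnMeta) else ColumnMeta.from_dict(meta)
                )
        if df is not None:
            self._df = self._normalize(df)

    # -- frame access -----------------------------------------------------

    @property
    def is_loaded(self) -> bool:
        return self._df is not None

    @property
    def df(self) -> pd.DataFrame:
        if self._df is None:
            self._df = self._normalize(self._loader())
        return self._df

    def _normalize(self, df: pd.DataFrame) -> pd.DataFrame:
        if df.shape[1] == 0:
            raise InvalidTableError("results table has no columns")
        df = df.copy()
        key = self.feature_column(df.columns)
        cols = [key] + [c for c in df.columns if c != key]
        df = df[cols]
        df[key] = df[key].astype(str)
        return df.reset_index(drop=True)

    def feature_column(self, columns: Optional[Sequence[str]] = None) -> str:
        cols = list(columns if columns is not None else self.df.columns)
        flagged = [c for c, m in self._column_meta.items()
                   if m.role == "feature_id" and c in cols]
        if len(flagged) > 1:
            raise InvalidTableError(f"multiple columns flagged feature_id: {flagged}")
        return flagged[0] if flagged else cols[0]

    @property
    def column_meta(self) -> dict[str, ColumnMeta]:
        """Explicit metadata completed with inferred roles for plain columns."""
        inferred = infer_column_roles(list(self.df.columns))
        out: dict[str, ColumnMeta] = {}
        for col in self.df.columns:
            if col in self._column_meta:
                out[col] = self._column_meta[col]
            else:
                out[col] = ColumnMeta(role=inferred[col])
        return out

    def set_column_meta(self, column: str, **kwargs) -> None:
        if column not in self.df.columns:
            raise UnknownTargetError(f"no column {column!r} in results table")
        meta = self.column_meta[column]
        for k, v in kwargs.items():
            setattr(meta, k, v)
        self._column_meta[column] = meta

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c, m in self.column_meta.items() if m.role == role]

    @property
    def feature_ids(self) -> pd.Series:
        return self.df[self.feature_column()]

    def __len__(self) -> int:
        return len(self.df)

    # -- validation & equality --------------------------------------------

    def problems(self, location: str = "results") -> list["Issue"]:
        issues: list[Issue] = []
        df = self.df
        key = self.feature_column()
        if df[key].duplicated().any():
            dups = df.loc[df[key].duplicated(), key].unique()[:5].tolist()
            issues.append(Issue("error", "DUPLICATE_FEATURE_ID",
                                f"duplicate feature ids (e.g. {dups})", location))
        if df.shape[1] < 2:
            issues.append(Issue("error", "NO_VALUE_COLUMNS",
                                "results table needs at least one column besides the feature id",
                                location))
        for col, meta in self.column_meta.items():
            if meta.role in ("p_value", "adjusted_p_value"):
                vals = pd.to_numeric(df[col], errors="coerce")
                bad = vals.dropna()
                if ((bad < 0) | (bad > 1)).any():
                    issues.append(Issue("error", "P_OUT_OF_RANGE",
                                        f"column {col!r} has p-values outside [0, 1]", location))
        return issues

    def validate(self, location: str = "results") -> None:
        errs = [i for i in self.problems(location) if i.level == "error"]
        if errs:
            raise InvalidTableError("; ".join(f"{i.code}: {i.message}" for i in errs))

    def equals(self, other: "ResultsTable") -> bool:
        if not isinstance(other, ResultsTable):
            return False
        if not self.df.equals(other.df):
            return False
        return {c: m.to_dict() for c, m in self.column_meta.items()} == {
            c: m.to_dict() for c, m in other.column_meta.items()
        }


@dataclass
class Test:
    name: str
    results: ResultsTable
    description: str = ""
    metadata: dict = field(default_factory=dict)

    def equals(self, other: "Test") -> bool:
        return (self.name == other.name and self.description == other.description
                and self.metadata == other.metadata and self.results.equals(other.results))


class Assay:
    """Numeric features x samples matrix with optional per-sample metadata."""

    def __init__(self, matrix: pd.DataFrame, sample_meta: Optional[pd.DataFrame] = None):
        if matrix.index.duplicated().any():
            raise InvalidTableError("assay has duplicate feature ids in its row index")
        if matrix.columns.duplicated().any():
            raise InvalidTableError("assay has repeated sample ids")
        self.matrix = matrix.copy()
        self.matrix.index = self.matrix.index.astype(str)
        self.matrix.columns = self.matrix.columns.astype(str)
        if sample_meta is not None:
            sample_meta = sample_meta.copy()
            sample_meta.index = sample_meta.index.astype(str)
            unknown = set(sample_meta.index) - set(self.matrix.columns)
            if unknown:
                raise InvalidTableError(f"sample_meta keys not in assay samples: {sorted(unknown)}")
        self.sample_meta = sample_meta

    def equals(self, other: "Assay") -> bool:
        if not isinstance(other, Assay):
            return False
        if not self.matrix.equals(other.matrix):
            return False
        if (self.sample_meta is None) != (other.sample_meta is None):
            return False
        return self.sample_meta is None or self.sample_meta.equals(other.sample_meta)


@dataclass
class AnnotationTerm:
    description: str
    features: frozenset

    def to_dict(self) -> dict:
        return {"description": self.description, "features": sorted(self.features)}


class AnnotationDatabase:
    """Named map term_id -> (description, feature-id set), e.g. a GO slice."""

    def __init__(self, name: str, terms: Mapping[str, AnnotationTerm | Mapping | Iterable]):
        self.name = check_identifier(name, "database name")
        self.terms: dict[str, AnnotationTerm] = {}
        for term_id, payload in terms.items():
            if isinstance(payload, AnnotationTerm):
                term = payload
            elif isinstance(payload, Mapping):
                term = AnnotationTerm(payload.get("description", ""),
                                      frozenset(map(str, payload["features"])))
            else:
                term = AnnotationTerm("", frozenset(map(str, payload)))
            if not term.features:
                raise InvalidTableError(f"term {term_id!r} has an empty feature set")
            self.terms[str(term_id)] = term

    def feature_set(self, term_id: str) -> frozenset:
        if term_id not in self.terms:
            raise UnknownTermError(f"term {term_id!r} not in database {self.name!r}")
        return self.terms[term_id].features

    def equals(self, other: "AnnotationDatabase") -> bool:
        return (isinstance(other, AnnotationDatabase) and self.name == other.name
                and {k: (v.description, v.features) for k, v in self.terms.items()}
                == {k: (v.description, v.features) for k, v in other.terms.items()})


class EnrichmentResults:
    """Long table of per-(term, test) enrichment p-values for one database."""

    COLUMNS = ["term_id", "test", "nominal", "adjusted"]

    def __init__(self, database: str, table: pd.DataFrame):
        self.database = check_identifier(database, "database name")
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise InvalidTableError(f"enrichment table missing columns {missing}")
        table = table[self.COLUMNS].copy()
        table["term_id"] = table["term_id"].astype(str)
        table["test"] = table["test"].astype(str)
        if table.duplicated(["term_id", "test"]).any():
            raise InvalidTableError("duplicate (term_id, test) rows in enrichment table")
        for col in ("nominal", "adjusted"):
            vals = pd.to_numeric(table[col], errors="coerce").dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise InvalidTableError(f"enrichment {col} p-values outside [0, 1]")
        self.table = table.reset_index(drop=True)

    @property
    def tests(self) -> list[str]:
        return sorted(self.table["test"].unique())

    @property
    def term_ids(self) -> list[str]:
        return sorted(self.table["term_id"].unique())

    def equals(self, other: "EnrichmentResults") -> bool:
        return (isinstance(other, EnrichmentResults) and self.database == other.database
                and self.table.equals(other.table))


_SLOT = re.compile(r"\{[^{}]*\}")


@dataclass
class LinkoutSpec:
    """URL pattern with exactly one substitution slot for a cell value."""

    column: str
    pattern: str
    label: str = ""

    def __post_init__(self):
        if len(_SLOT.findall(self.pattern)) != 1:
            raise InvalidTableError(
                f"linkout pattern must contain exactly one {{slot}}: {self.pattern!r}")

    def to_dict(self) -> dict:
        return {"column": self.column, "pattern": self.pattern, "label": self.label}


@dataclass
class PlotHook:
    """Registered custom plot callable; storage and dispatch only, no rendering."""

    name: str
    scope: str  # single_feature | multi_feature | multi_test
    func: Optional[Callable] = None
    ref: str = ""  # dotted "module:function" reference, survives serialization
    models: tuple = ()  # () = applies to all models

    def __post_init__(self):
        if self.scope not in {"single_feature", "multi_feature", "multi_test"}:
            raise InvalidTableError(f"unknown plot scope {self.scope!r}")

    def applicable(self, model: str) -> bool:
        return not self.models or model in self.models

    def dispatch(self, *args, **kwargs):
        if self.func is None:
            raise UnknownTargetError(f"plot hook {self.name!r} has no live callable")
        return self.func(*args, **kwargs)

    def to_dict(self) -> dict:
        return {"name": self.name, "scope": self.scope, "ref": self.ref,
                "models": list(self.models)}


class Model:
    """Named grouping of tests plus optional assay, feature metadata, enrichments."""

    def __init__(self, name: str, description: str = ""):
        self.name = check_identifier(name, "model name")
        self.description = description
        self.metadata: dict = {}
        self.tests: dict[str, Test] = {}
        self.assays: Optional[Assay] = None
        self.features: Optional[pd.DataFrame] = None
        self.enrichments: dict[str, EnrichmentResults] = {}

    @property
    def test_names(self) -> list[str]:
        return list(self.tests)

    def feature_universe(self, rule: str = "union_of_tests") -> set[str]:
        """Feature ids across this model's tests (union by default)."""
        sets = [set(t.results.feature_ids) for t in self.tests.values()]
        if not sets:
            return set()
        if rule == "union_of_tests":
            return set.union(*sets)
        if rule == "intersection_of_tests":
            return set.intersection(*sets)
        raise ValueError(f"unknown universe rule {rule!r}")

    def equals(self, other: "Model") -> bool:
        if not isinstance(other, Model):
            return False
        if (self.name, self.description, self.metadata) != (
                other.name, other.description, other.metadata):
            return False
        if list(self.tests) != list(other.tests):
            return False
        if any(not self.tests[k].equals(other.tests[k]) for k in self.tests):
            return False
        if (self.assays is None) != (other.assays is None):
            return False
        if self.assays is not None and not self.assays.equals(other.assays):
            return False
        if (self.features is None) != (other.features is None):
            return False
        if self.features is not None and not self.features.equals(other.features):
            return False
        if set(self.enrichments) != set(other.enrichments):
            return False
        return all(self.enrichments[k].equals(other.enrichments[k]) for k in self.enrichments)


class Study:
    """Root container: metadata plus an ordered collection of models."""

    def __init__(self, name: str, description: str = "", version: str = "0.1.0",
                 maintainer: str = "", metadata: Optional[Mapping] = None):
        self.name = check_identifier(name, "study name")
        self.description = description
        self.version = version
        self.maintainer = maintainer
        self.metadata: dict = dict(metadata or {})
        self.models: dict[str, Model] = {}
        self.mapping: Optional[pd.DataFrame] = None
        self.report: Optional[str] = None
        self.linkouts: dict[str, list[LinkoutSpec]] = {}
        self.plot_registry: dict[str, PlotHook] = {}
        self.annotations: dict[str, AnnotationDatabase] = {}

    # -- incremental construction -----------------------------------------

    def model(self, name: str, create: bool = False, description: str = "") -> Model:
        if name not in self.models:
            if not create:
                raise UnknownTargetError(f"no model {name!r} in study {self.name!r}")
            self.models[name] = Model(name, description)
        return self.models[name]

    def add_results(self, model: str, test: str, table: pd.DataFrame | ResultsTable,
                    column_meta: Optional[Mapping] = None, description: str = "") -> "Study":
        """Attach (replacing, if present) one test's results table."""
        check_identifier(test, "test name")
        rt = table if isinstance(table, ResultsTable) else ResultsTable(table, column_meta)
        if column_meta and isinstance(table, ResultsTable):
            for col, meta in column_meta.items():
                rt.set_column_meta(col, **(meta.to_dict() if isinstance(meta, ColumnMeta) else meta))
        rt.validate(f"{model}/{test}")
        m = self.model(model, create=True)
        m.tests[test] = Test(name=test, results=rt, description=description)
        return self

    def add_assays(self, model: str, assay: Assay | pd.DataFrame,
                   sample_meta: Optional[pd.DataFrame] = None) -> "Study":
        if not isinstance(assay, Assay):
            assay = Assay(assay, sample_meta)
        m = self.model(model, create=True)
        m.assays = assay
        universe = m.feature_universe()
        if universe:
            overlap = len(set(assay.matrix.index) & universe) / len(universe)
            if overlap < 1.0:
                warnings.warn(
                    f"assay features cover {overlap:.2f} of {model!r} result features",
                    stacklevel=2)
        return self

    def add_features(self, model: str, features: pd.DataFrame) -> "Study":
        features = features.copy()
        key = features.columns[0]
        features[key] = features[key].astype(str)
        if features[key].duplicated().any():
            raise InvalidTableError("feature table has duplicate feature ids")
        self.model(model, create=True).features = features.reset_index(drop=True)
        return self

    def add_annotations(self, database: AnnotationDatabase) -> "Study":
        self.annotations[database.name] = database
        return self

    def add_enrichments(self, model: str, database: AnnotationDatabase | str,
                        results: EnrichmentResults | pd.DataFrame) -> "Study":
        """Attach per-term-per-test enrichment p-values for one database.

        Enrichment tests must match or be a subset of the model's differential
        tests, and every term must exist in the named annotation database.
        """
        m = self.model(model)
        if not m.tests:
            raise UnknownTestError(f"model {model!r} has no differential tests yet")
        if isinstance(database, AnnotationDatabase):
            self.add_annotations(database)
            db = database
        else:
            if database not in self.annotations:
                raise UnknownTargetError(f"no annotation database {database!r}")
            db = self.annotations[database]
        if not isinstance(results, EnrichmentResults):
            results = EnrichmentResults(db.name, results)
        extra_tests = set(results.tests) - set(m.test_names)
        if extra_tests:
            raise UnknownTestError(
                f"enrichment tests {sorted(extra_tests)} are not differential tests of {model!r}")
        extra_terms = set(results.term_ids) - set(db.terms)
        if extra_terms:
            raise UnknownTermError(
                f"terms {sorted(extra_terms)[:5]} absent from database {db.name!r}")
        m.enrichments[db.name] = results
        return self

    def add_mapping(self, mapping: pd.DataFrame) -> "Study":
        """Attach the cross-model feature-ID mapping table (one column per model).

        Rows align corresponding ids across models; many-to-many is allowed
        and missing cells mark ids with no counterpart.  All-missing rows are
        dropped with a warning.  Ids are stored as strings.
        """
        mapping = mapping.copy()
        all_missing = mapping.isna().all(axis=1)
        if all_missing.any():
            warnings.warn(f"dropping {int(all_missing.sum())} all-missing mapping rows",
                          stacklevel=2)
            mapping = mapping.loc[~all_missing]
        # canonical storage: object dtype, str ids, NaN for missing
        mapping = mapping.astype(object).where(mapping.notna(), np.nan)
        for col in mapping.columns:
            mask = mapping[col].notna()
            mapping.loc[mask, col] = mapping.loc[mask, col].astype(str)
        self.mapping = mapping.reset_index(drop=True)
        return self

    def map_features(self, from_model: str, to_model: str, feature_id: str) -> list[str]:
        """All counterpart ids of ``feature_id`` in another model (many-to-many)."""
        if self.mapping is None:
            return []
        for col in (from_model, to_model):
            if col not in self.mapping.columns:
                raise UnknownTargetError(f"mapping table has no column {col!r}")
        hits = self.mapping.loc[self.mapping[from_model] == feature_id, to_model]
        return sorted(set(hits.dropna().astype(str)))

    def set_report(self, path_or_url: str) -> "Study":
        self.report = str(path_or_url)
        return self

    def add_linkout(self, column: str, pattern: str, label: str = "") -> "Study":
        spec = LinkoutSpec(column=column, pattern=pattern, label=label)
        self.linkouts.setdefault(column, []).append(spec)
        return self

    def add_plot(self, hook: PlotHook) -> "Study":
        self.plot_registry[hook.name] = hook
        return self

    def attach_metadata(self, target: str, payload: Mapping, model: Optional[str] = None,
                        test: Optional[str] = None, column: Optional[str] = None) -> "Study":
        """Attach open key->value metadata to the study, a model, a test, or a column.

        Column payloads set tooltip / display_name / role on that column's
        metadata.  A study payload may carry the special key ``report``.
        """
        if target == "study":
            payload = dict(payload)
            if "report" in payload:
                self.set_report(payload.pop("report"))
            self.metadata.update(payload)
        elif target == "model":
            self.model(model).metadata.update(payload)
        elif target == "test":
            m = self.model(model)
            if test not in m.tests:
                raise UnknownTargetError(f"no test {test!r} in model {model!r}")
            m.tests[test].metadata.update(payload)
        elif target == "column":
            m = self.model(model)
            if test not in m.tests:
                raise UnknownTargetError(f"no test {test!r} in model {model!r}")
            m.tests[test].results.set_column_meta(column, **payload)
        else:
            raise UnknownTargetError(f"unknown metadata target {target!r}")
        return self

    # -- summaries ----------------------------------------------------------

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_tests(self) -> int:
        return sum(len(m.tests) for m in self.models.values())

    def summary(self) -> dict:
        return {"name": self.name, "version": self.version,
                "n_models": self.n_models, "n_tests": self.n_tests,
                "description": self.description}

    def equals(self, other: "Study") -> bool:
        if not isinstance(other, Study):
            return False
        if (self.name, self.description, self.version, self.maintainer,
                self.metadata, self.report) != (
                other.name, other.description, other.version, other.maintainer,
                other.metadata, other.report):
            return False
        if list(self.models) != list(other.models):
            return False
        if any(not self.models[k].equals(other.models[k]) for k in self.models):
            return False
        if (self.mapping is None) != (other.mapping is None):
            return False
        if self.mapping is not None and not self.mapping.equals(other.mapping):
            return False
        if {c: [s.to_dict() for s in v] for c, v in self.linkouts.items()} != {
                c: [s.to_dict() for s in v] for c, v in other.linkouts.items()}:
            return False
        if set(self.annotations) != set(other.annotations):
            return False
        if any(not self.annotations[k].equals(other.annotations[k]) for k in self.annotations):
            return False
        return {k: h.to_dict() for k, h in self.plot_registry.items()} == {
            k: h.to_dict() for k, h in other.plot_registry.items()}


# -- validation -------------------------------------------------------------


@dataclass
class Issue:
    level: str  # error | warning
    code: str
    message: str
    location: str

    def to_dict(self) -> dict:
        return {"level": self.level, "code": self.code,
                "message": self.message, "location": self.location}


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.level == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.level == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, level: str, code: str, message: str, location: str) -> None:
        self.issues.append(Issue(level, code, message, location))

    def __str__(self) -> str:
        if not self.issues:
            return "OK: no issues"
        return "\n".join(f"[{i.level.upper()}] {i.code} at {i.location}: {i.message}"
                         for i in self.issues)


def validate_study(study: Study) -> ValidationReport:
    """Check every container invariant; report, never raise.

    An empty error list means the study is minimally complete (at least one
    results table) and installable; warnings never block installation.
    """
    rep = ValidationReport()
    try:
        check_identifier(study.name, "study name")
    except InvalidNameError as exc:
        rep.add("error", "BAD_IDENTIFIER", str(exc), "study")

    if study.n_tests == 0:
        rep.add("error", "NO_RESULTS",
                "minimal input rule unmet: at least one results table is required", "study")

    schemas_seen: dict[str, list[tuple[str, str]]] = {}
    for mname, model in study.models.items():
        loc = f"model:{mname}"
        for tname, test in model.tests.items():
            tloc = f"{loc}/test:{tname}"
            try:
                rep.issues.extend(test.results.problems(tloc))
                schemas_seen.setdefault(tname, []).append(
                    (mname, ",".join(test.results.df.columns)))
            except Exception as exc:  # total: report, don't raise
                rep.add("error", "INTERNAL", f"could not inspect results: {exc}", tloc)
        if model.assays is not None:
            universe = model.feature_universe()
            if universe:
                overlap = len(set(model.assays.matrix.index) & universe) / len(universe)
                if overlap < 1.0:
                    rep.add("warning", "ASSAY_OVERLAP",
                            f"assay covers {overlap:.3f} of result features", loc)
        for dbname, enr in model.enrichments.items():
            eloc = f"{loc}/enrichment:{dbname}"
            extra = set(enr.tests) - set(model.test_names)
            if extra:
                rep.add("error", "SUBSET_VIOLATION",
                        f"enrichment tests {sorted(extra)} not among differential tests", eloc)
            if dbname not in study.annotations:
                rep.add("error", "UNKNOWN_DATABASE",
                        f"no annotation database {dbname!r} attached to the study", eloc)
            else:
                missing = set(enr.term_ids) - set(study.annotations[dbname].terms)
                if missing:
                    rep.add("error", "UNKNOWN_TERM",
                            f"terms {sorted(missing)[:5]} absent from database", eloc)

    # a test name reused across models with different column schemas is legal
    # (schemas are per-test) but worth flagging
    for tname, entries in schemas_seen.items():
        if len({schema for _, schema in entries}) > 1:
            rep.add("warning", "SCHEMA_HETEROGENEITY",
                    f"test {tname!r} has different column schemas across models "
                    f"{[m for m, _ in entries]}", f"test:{tname}")

    if study.mapping is not None:
        unknown = set(study.mapping.columns) - set(study.models)
        if unknown:
            rep.add("error", "UNKNOWN_MODEL_COLUMN",
                    f"mapping columns {sorted(unknown)} match no model", "mapping")
        if study.mapping.isna().all(axis=1).any():
            rep.add("warning", "EMPTY_MAPPING_ROW", "mapping contains all-missing rows",
                    "mapping")

    for col, specs in study.linkouts.items():
        for spec in specs:
            if len(_SLOT.findall(spec.pattern)) != 1:
                rep.add("error", "LINKOUT_PATTERN",
                        f"pattern {spec.pattern!r} must have exactly one slot",
                        f"linkout:{col}")

    return rep


# -- functional facade (mirrors the incremental-construction call style) ----


def create_study(name: str, description: str = "", metadata: Optional[Mapping] = None,
                 **kwargs) -> Study:
    """Start an empty study; everything else is added incrementally."""
    return Study(name, description=description, metadata=metadata, **kwargs)


def add_results(study: Study, model: str, test: str, table, column_meta=None, **kw) -> Study:
    return study.add_results(model, test, table, column_meta, **kw)


def add_assays(study: Study, model: str, assay, sample_meta=None) -> Study:
    return study.add_assays(model, assay, sample_meta)


def add_enrichments(study: Study, model: str, database, results) -> Study:
    return study.add_enrichments(model, database, results)


def add_mapping(study: Study, mapping: pd.DataFrame) -> Study:
    return study.add_mapping(mapping)


def attach_metadata(study: Study, target: str, payload, **kw) -> Study:
    return study.attach_metadata(target, payload, **kw)
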