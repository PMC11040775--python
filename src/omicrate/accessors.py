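"""FAIR-style accessor layer: query stored tables, serialize to many formats.

Filters on a query combine with AND; sorting is stable with feature-id
ascending as the tie-break so pagination is reproducible; the same table can
be exported as TSV, CSV, records-oriented JSON or Arrow/feather, and each
serialization parses back to the original values.
"""

from __future__ import annotations

import io
import json
import math
import operator
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union
from urllib.parse import quote

import numpy as np
import pandas as pd

from .errors import UnknownColumnError, UnknownTargetError, UnsupportedFormatError
from .model import Study

__all__ = ["Filter", "TableQuery", "get_results", "get_enrichments",
           "export_table", "parse_table", "resolve_linkouts"]

_OPS = {
    "<": operator.lt, "<=": operator.le, ">": operator.gt, ">=": operator.ge,
    "==": operator.eq,
}


@dataclass
class Filter:
    column: str
    op: str  # < <= > >= == contains in
    value: object


@dataclass
class TableQuery:
    """Declarative slice of one stored table.

    ``study`` is informational (used by the CLI to resolve a registry entry);
    the in-process API receives the Study object directly.
    """

    study: str = ""
    model: str = ""
    test: str = ""
    database: str = ""
    filters: list[Filter] = field(default_factory=list)
    features: Optional[Sequence[str]] = None      # exact id list ("in")
    feature_contains: Optional[str] = None        # substring search
    sort: Optional[tuple[str, str]] = None        # (column, "asc"|"desc")
    offset: int = 0
    limit: Optional[int] = None


def _apply_filter(df: pd.DataFrame, f: Filter) -> pd.Series:
    if f.column not in df.columns:
        raise UnknownColumnError(f"no column {f.column!r}")
    col = df[f.column]
    if f.op in _OPS:
        with np.errstate(invalid="ignore"):
            mask = _OPS[f.op](col, f.value)
        # missing values never satisfy a comparison
        return pd.Series(mask, index=df.index).fillna(False).astype(bool) & col.notna()
    if f.op == "contains":
        return col.astype(str).str.contains(str(f.value), regex=False).fillna(False)
    if f.op == "in":
        values = set(map(str, f.value)) if not isinstance(f.value, str) else {f.value}
        return col.astype(str).isin(values)
    raise UnknownColumnError(f"unknown filter op {f.op!r}")


def _slice(df: pd.DataFrame, key: str, query: TableQuery) -> tuple[pd.DataFrame, int]:
    mask = pd.Series(True, index=df.index)
    for f in query.filters:
        mask &= _apply_filter(df, f).astype(bool)
    if query.features is not None:
        mask &= df[key].isin(set(map(str, query.features)))
    if query.feature_contains:
        mask &= df[key].str.contains(query.feature_contains, regex=False)
    out = df.loc[mask]

    if query.sort is not None:
        col, direction = query.sort
        if col not in out.columns:
            raise UnknownColumnError(f"no sort column {col!r}")
        out = out.sort_values([col, key], ascending=[direction != "desc", True],
                              kind="mergesort")
    else:
        out = out.sort_values(key, kind="mergesort")
    total = len(out)
    if query.offset:
        out = out.iloc[query.offset:]
    if query.limit is not None:
        if query.limit < 0:
            raise ValueError("limit must be >= 0")
        out = out.iloc[: query.limit]
    return out.reset_index(drop=True), total


def get_results(study: Study, query: TableQuery) -> tuple[pd.DataFrame, int]:
    """Filtered / sorted / paginated slice of one test's results table.

    Returns ``(slice, total)`` where *total* is the row count after filtering
    but before pagination.
    """
    model = study.model(query.model)
    if query.test not in model.tests:
        raise UnknownTargetError(f"no test {query.test!r} in model {query.model!r}")
    rt = model.tests[query.test].results
    return _slice(rt.df, rt.feature_column(), query)


def get_enrichments(study: Study, model: str, database: str,
                    test: Optional[str] = None) -> pd.DataFrame:
    """Long (term_id, test, nominal, adjusted) table; stored combinations only."""
    m = study.model(model)
    if database not in m.enrichments:
        raise UnknownTargetError(f"no enrichment database {database!r} under model {model!r}")
    table = m.enrichments[database].table
    if test is not None:
        if test not in m.tests:
            raise UnknownTargetError(f"no test {test!r} in model {model!r}")
        table = table.loc[table["test"] == test]
    return table.reset_index(drop=True)


# -- serialization ----------------------------------------------------------

_NA = "NA"


def _jsonable(v):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        v = float(v)
    if isinstance(v, float) and math.isnan(v):
        return None
    if isinstance(v, np.bool_):
        return bool(v)
    return v


def export_table(table: pd.DataFrame, format: str = "tsv") -> bytes:
    """Serialize a table to tsv / csv / json (records) / feather bytes."""
    fmt = format.lower()
    if fmt in ("tsv", "txt"):
        return table.to_csv(sep="\t", index=False, na_rep=_NA).encode("utf-8")
    if fmt == "csv":
        return table.to_csv(index=False, na_rep=_NA).encode("utf-8")
    if fmt == "json":
        records = [
            {col: _jsonable(v) for col, v in zip(table.columns, row)}
            for row in table.itertuples(index=False, name=None)
        ]
        return json.dumps(records).encode("utf-8")
    if fmt == "feather":
        import pyarrow.feather as feather

        buf = io.BytesIO()
        feather.write_feather(table.reset_index(drop=True), buf)
        return buf.getvalue()
    raise UnsupportedFormatError(f"format {format!r} not supported (tsv, csv, json, feather)")


def parse_table(data: bytes, format: str = "tsv",
                key: Optional[str] = None) -> pd.DataFrame:
    """Inverse of :func:`export_table` (column order and values preserved)."""
    fmt = format.lower()
    if fmt in ("tsv", "txt", "csv"):
        sep = "\t" if fmt in ("tsv", "txt") else ","
        df = pd.read_csv(io.BytesIO(data), sep=sep, keep_default_na=False,
                         na_values=[_NA], float_precision="round_trip")
    elif fmt == "json":
        records = json.loads(data.decode("utf-8"))
        df = pd.DataFrame.from_records(records)
    elif fmt == "feather":
        import pyarrow.feather as feather

        df = feather.read_feather(io.BytesIO(data))
    else:
        raise UnsupportedFormatError(f"format {format!r} not supported")
    if key is not None and key in df.columns:
        df[key] = df[key].astype(str)
    return df


def resolve_linkouts(study: Study, column: str, value: str) -> list[str]:
    """Substitute ``value`` (percent-encoded) into every linkout pattern of a column."""
    urls = []
    for spec in study.linkouts.get(column, []):
        slot_start = spec.pattern.index("{")
        slot_end = spec.pattern.index("}", slot_start)
        urls.append(spec.pattern[:slot_start] + quote(str(value), safe="")
                    + spec.pattern[slot_end + 1:])
    return urls
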