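"""Multi-set filtering across hypothesis tests, with UpSet-style summaries.

Interesting biology often sits in intersections, unions and complements of
per-test feature sets — e.g. genes differential in disease cell type A versus
control (set 1) but *not* differential between the two disease cell types
(set 2).  A :class:`SetDefinition` turns one test's results table into a
feature set via AND-ed threshold clauses (optionally on the absolute value of
a signed column, optionally complemented against a universe); sets combine by
intersection or union; :func:`upset_summary` enumerates the exclusive
intersection regions across all sets, ranked for display.

The same machinery applies unchanged to the enrichment term-test table with
terms as the elements.

Semantics to note: a missing value fails every clause, so negation *includes*
features whose value is missing — complement is taken against the universe,
not against "features with a value".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import NonNumericColumnError, UnknownColumnError, UnknownTargetError
from .model import Model

__all__ = ["Clause", "SetDefinition", "Universe", "UpSetSummary",
           "build_universe", "evaluate_set", "combine_sets", "upset_summary",
           "apply_set_filter"]

_OPS = {"<": np.less, "<=": np.less_equal, ">": np.greater, ">=": np.greater_equal}


@dataclass
class Clause:
    """One numeric threshold, e.g. ``padj <= 0.05`` or ``|logFC| >= 1``."""

    column: str
    op: str
    threshold: float
    absolute: bool = False

    def __post_init__(self):
        if self.op not in _OPS:
            raise UnknownColumnError(f"clause op must be one of {sorted(_OPS)}, got {self.op!r}")


@dataclass
class SetDefinition:
    """AND of clauses over one test's table; ``negate`` complements vs the universe."""

    test: str
    clauses: list[Clause] = field(default_factory=list)
    negate: bool = False

    def __post_init__(self):
        if not self.clauses:
            raise UnknownColumnError("a set definition needs at least one clause")
        self.clauses = [c if isinstance(c, Clause) else Clause(**c) for c in self.clauses]


@dataclass
class Universe:
    """Reference feature set for complements."""

    features: frozenset
    rule: str = "union_of_tests"

    @property
    def size(self) -> int:
        return len(self.features)


def build_universe(model: Model, rule: str = "union_of_tests") -> Universe:
    return Universe(frozenset(model.feature_universe(rule)), rule)


def evaluate_set(model: Model, definition: SetDefinition,
                 universe: Optional[Universe] = None) -> set[str]:
    """Feature ids of the definition's test satisfying all clauses.

    Missing values fail clauses.  With ``negate`` the complement is taken
    against ``universe`` (default: union of features across the model's tests).
    """
    if definition.test not in model.tests:
        raise UnknownTargetError(f"no test {definition.test!r} in model {model.name!r}")
    rt = model.tests[definition.test].results
    df = rt.df
    key = rt.feature_column()
    mask = np.ones(len(df), dtype=bool)
    for clause in definition.clauses:
        if clause.column not in df.columns:
            raise UnknownColumnError(f"no column {clause.column!r} in test {definition.test!r}")
        col = df[clause.column]
        if not pd.api.types.is_numeric_dtype(col):
            raise NonNumericColumnError(f"column {clause.column!r} is not numeric")
        vals = col.to_numpy(dtype=float)
        if clause.absolute:
            vals = np.abs(vals)
        with np.errstate(invalid="ignore"):
            ok = _OPS[clause.op](vals, clause.threshold)
        mask &= ok & ~np.isnan(vals)
    selected = set(df.loc[mask, key])
    if definition.negate:
        uni = universe if universe is not None else build_universe(model)
        return set(uni.features) - selected
    return selected


def combine_sets(model: Model, definitions: Iterable[SetDefinition],
                 mode: str = "intersection",
                 universe: Optional[Universe] = None) -> set[str]:
    """Fold evaluated sets under intersection or union."""
    definitions = list(definitions)
    if not definitions:
        raise UnknownTargetError("combine_sets needs at least one definition")
    if mode not in ("intersection", "union"):
        raise ValueError(f"mode must be intersection|union, got {mode!r}")
    uni = universe if universe is not None else build_universe(model)
    sets = [evaluate_set(model, d, uni) for d in definitions]
    out = sets[0].copy()
    for s in sets[1:]:
        out = out & s if mode == "intersection" else out | s
    return out


@dataclass
class UpSetSummary:
    """Exclusive-intersection summary across named sets.

    ``regions`` holds the displayed (top_n) patterns; ``all_regions`` every
    non-empty pattern, so that region sizes always partition the union.
    """

    set_names: list[str]
    set_sizes: dict[str, int]
    regions: list[tuple[tuple[str, ...], int]]
    all_regions: list[tuple[tuple[str, ...], int]]
    order_by: str = "size"
    exclusive: bool = True

    @property
    def union_size(self) -> int:
        if not self.exclusive:
            raise ValueError("union partition only holds for exclusive regions")
        return sum(size for _, size in self.all_regions)


def _region_sort_key(order_by: str):
    # ties: degree ascending, then membership pattern lexicographic
    if order_by == "size":
        return lambda item: (-item[1], len(item[0]), item[0])
    if order_by == "degree":
        return lambda item: (-len(item[0]), -item[1], item[0])
    raise ValueError(f"order_by must be size|degree, got {order_by!r}")


def upset_summary(per_test_sets: Mapping[str, Iterable], top_n: int = 10,
                  order_by: str = "size", exclusive: bool = True) -> UpSetSummary:
    """Enumerate intersection regions across sets, ranked for display.

    Exclusive mode (default, matching the usual UpSet convention) assigns each
    element of the union to exactly one membership pattern, so region sizes
    sum to the union size.  Inclusive mode reports, for each of the
    ``2^T - 1`` candidate patterns, the size of the plain intersection of the
    named sets ("at least these").
    """
    if top_n < 0:
        raise ValueError("top_n must be >= 0")
    names = list(per_test_sets)
    sets = {name: set(per_test_sets[name]) for name in names}
    sizes = {name: len(sets[name]) for name in names}

    if exclusive:
        counts: dict[tuple[str, ...], int] = {}
        for element in set().union(*sets.values()) if sets else set():
            pattern = tuple(n for n in names if element in sets[n])
            counts[pattern] = counts.get(pattern, 0) + 1
        all_regions = sorted(counts.items(), key=_region_sort_key(order_by))
    else:
        all_regions = []
        for r in range(1, len(names) + 1):
            for combo in itertools.combinations(names, r):
                inter = set.intersection(*(sets[n] for n in combo))
                if inter:
                    all_regions.append((combo, len(inter)))
        all_regions.sort(key=_region_sort_key(order_by))

    return UpSetSummary(set_names=names, set_sizes=sizes,
                        regions=all_regions[:top_n], all_regions=all_regions,
                        order_by=order_by, exclusive=exclusive)


def apply_set_filter(table: pd.DataFrame, surviving: Iterable, key: Optional[str] = None
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Restrict a table to surviving features.

    Returns the filtered table plus a per-row boolean flag aligned with the
    *original* table (downstream views use it to dim rather than drop rows).
    """
    key = key or table.columns[0]
    if key not in table.columns:
        raise UnknownColumnError(f"no feature column {key!r}")
    surviving = set(map(str, surviving))
    flags = table[key].astype(str).isin(surviving)
    flags.name = "passes_filter"
    return table.loc[flags].reset_index(drop=True), flags
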