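"""Data behind the enrichment visualizations.

Four computations, all returning plain data (rendering is a client concern):

* :func:`barcode_data` — features of one term ranked by a test statistic
  (default |t|), with a box summary, the classic barcode view of within-term
  variability.
* :func:`term_similarity` / :func:`build_network` — an EnrichmentMap-style
  term network: nodes are significant terms sized by tested-feature count and
  carrying one wedge per test; edges are Jaccard / overlap / combined
  similarities above a cutoff; clusters are connected components.
* :func:`tiled_layout` — deterministic tile ordering of clusters (largest or
  most significant first, read top-to-bottom then left-to-right).
* :func:`hexbin_aggregate` — hexagonal binning of 2-D scatter points for
  large-dataset plotting (two offset rectangular lattices, nearest-centre
  rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    EmptySetError,
    NonNumericColumnError,
    TermNotTestedError,
    UnknownColumnError,
    UnknownTargetError,
)
from .model import Study

__all__ = ["BarcodeData", "TermNode", "TermEdge", "TermNetwork", "TileLayout",
           "HexBinGrid", "barcode_data", "term_similarity", "build_network",
           "tiled_layout", "hexbin_aggregate"]


# -- barcode ----------------------------------------------------------------


@dataclass
class BarcodeData:
    term_id: str
    test: str
    statistic_column: str
    entries: pd.DataFrame          # feature_id, statistic, rank (1 = largest)
    box: dict                      # min, q1, median, q3, max
    universe_range: tuple[float, float]
    n_excluded: int                # term features absent from the test's results

    def ranks(self) -> list[int]:
        return self.entries["rank"].tolist()


def barcode_data(study: Study, model: str, database: str, term: str, test: str,
                 statistic_column: Optional[str] = None, absolute: bool = True
                 ) -> BarcodeData:
    """Rank a term's tested features by (absolute) test statistic.

    Only features present in *both* the term and the test's results table are
    included; the count of untested term members is reported, not imputed.
    Box quartiles use linear interpolation.
    """
    m = study.model(model)
    if database not in study.annotations:
        raise UnknownTargetError(f"no annotation database {database!r}")
    if test not in m.tests:
        raise UnknownTargetError(f"no test {test!r} in model {model!r}")
    term_features = study.annotations[database].feature_set(term)

    rt = m.tests[test].results
    df = rt.df
    key = rt.feature_column()
    if statistic_column is None:
        stat_cols = rt.columns_with_role("statistic")
        if not stat_cols:
            raise UnknownColumnError(
                f"test {test!r} has no column with role=statistic; pass statistic_column")
        statistic_column = stat_cols[0]
    if statistic_column not in df.columns:
        raise UnknownColumnError(f"no column {statistic_column!r} in test {test!r}")
    if not pd.api.types.is_numeric_dtype(df[statistic_column]):
        raise NonNumericColumnError(f"column {statistic_column!r} is not numeric")

    values = df[statistic_column].astype(float)
    if absolute:
        values = values.abs()
    tested = pd.DataFrame({"feature_id": df[key], "statistic": values})

    hits = tested.loc[tested["feature_id"].isin(term_features)].dropna(subset=["statistic"])
    if hits.empty:
        raise TermNotTestedError(
            f"term {term!r} shares no tested features with test {test!r}")
    hits = hits.sort_values(["statistic", "feature_id"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
    hits["rank"] = np.arange(1, len(hits) + 1)

    q = np.percentile(hits["statistic"].to_numpy(), [0, 25, 50, 75, 100])
    box = {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}
    finite = tested["statistic"].dropna()
    uni_range = (float(finite.min()), float(finite.max())) if len(finite) else (math.nan,) * 2

    return BarcodeData(term_id=term, test=test, statistic_column=statistic_column,
                       entries=hits, box=box, universe_range=uni_range,
                       n_excluded=len(term_features) - hits["feature_id"].isin(term_features).sum())


# -- term similarity & network ---------------------------------------------


def term_similarity(set_a: Iterable, set_b: Iterable, metric: str = "jaccard",
                    k: float = 0.5) -> float:
    """Similarity of two feature sets in [0, 1].

    jaccard  J = |A∩B| / |A∪B|
    overlap  O = |A∩B| / min(|A|, |B|)   (always >= J)
    combined C = k·O + (1−k)·J  with k in [0, 1]
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise EmptySetError("similarity is undefined for empty sets")
    inter = len(a & b)
    jac = inter / len(a | b)
    ovl = inter / min(len(a), len(b))
    if metric == "jaccard":
        return jac
    if metric == "overlap":
        return ovl
    if metric == "combined":
        if not 0.0 <= k <= 1.0:
            raise ValueError(f"k must be in [0, 1], got {k}")
        return k * ovl + (1.0 - k) * jac
    raise ValueError(f"metric must be jaccard|overlap|combined, got {metric!r}")


@dataclass
class TermNode:
    term_id: str
    label: str
    size: int                       # |term ∩ tested-feature universe|
    wedges: list[dict]              # {test, nominal, adjusted} per stored test

    def min_adjusted(self) -> float:
        ps = [w["adjusted"] for w in self.wedges if w["adjusted"] is not None
              and not math.isnan(w["adjusted"])]
        return min(ps) if ps else math.inf


@dataclass
class TermEdge:
    source: str
    target: str
    jaccard: float
    overlap: float
    combined: float
    weight: float                   # value of the selected metric


@dataclass
class TermNetwork:
    nodes: dict[str, TermNode]
    edges: list[TermEdge]
    clusters: list[list[str]]       # connected components, each sorted
    metric: str
    edge_cutoff: float
    node_cutoff: float
    warning: str = ""

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_edges(self, members: Sequence[str]) -> int:
        s = set(members)
        return sum(1 for e in self.edges if e.source in s and e.target in s)

    def to_dict(self) -> dict:
        return {
            "nodes": [{"id": n.term_id, "label": n.label, "size": n.size,
                       "wedges": n.wedges} for n in self.nodes.values()],
            "edges": [{"source": e.source, "target": e.target, "jaccard": e.jaccard,
                       "overlap": e.overlap, "combined": e.combined} for e in self.edges],
            "clusters": self.clusters,
        }


def build_network(study: Study, model: str, database: str, node_cutoff: float = 0.05,
                  metric: str = "jaccard", edge_cutoff: float = 0.25, k: float = 0.5,
                  use_adjusted: bool = True, allow_empty: bool = True) -> TermNetwork:
    """EnrichmentMap-style term network for one (model, database).

    Nodes are terms significant (adjusted p by default) at ``node_cutoff`` in
    at least one test; each node carries one wedge per stored test and its
    size is the count of term features that were actually tested in the
    model, never the raw database term size.  Edges join term pairs whose
    similarity (computed on the tested feature sets) reaches ``edge_cutoff``;
    clusters are the connected components of the thresholded graph.
    """
    m = study.model(model)
    if database not in m.enrichments:
        raise UnknownTargetError(f"no enrichment results for {database!r} under {model!r}")
    if database not in study.annotations:
        raise UnknownTargetError(f"no annotation database {database!r}")
    db = study.annotations[database]
    table = m.enrichments[database].table
    universe = m.feature_universe()
    pcol = "adjusted" if use_adjusted else "nominal"

    passing = table.loc[table[pcol] <= node_cutoff, "term_id"].unique()
    if len(passing) == 0:
        if allow_empty:
            return TermNetwork({}, [], [], metric, edge_cutoff, node_cutoff,
                               warning=f"no term passes {pcol} <= {node_cutoff}")
        raise UnknownTargetError(f"no term passes {pcol} <= {node_cutoff}")

    nodes: dict[str, TermNode] = {}
    tested_sets: dict[str, set] = {}
    for term in sorted(passing):
        rows = table.loc[table["term_id"] == term].sort_values("test")
        wedges = [{"test": r.test,
                   "nominal": None if pd.isna(r.nominal) else float(r.nominal),
                   "adjusted": None if pd.isna(r.adjusted) else float(r.adjusted)}
                  for r in rows.itertuples()]
        tested = set(db.feature_set(term)) & universe
        tested_sets[term] = tested
        nodes[term] = TermNode(term_id=term, label=db.terms[term].description or term,
                               size=len(tested), wedges=wedges)

    edges: list[TermEdge] = []
    term_ids = sorted(nodes)
    for i, a in enumerate(term_ids):
        for b in term_ids[i + 1:]:
            if not tested_sets[a] or not tested_sets[b]:
                continue
            jac = term_similarity(tested_sets[a], tested_sets[b], "jaccard")
            ovl = term_similarity(tested_sets[a], tested_sets[b], "overlap")
            comb = k * ovl + (1.0 - k) * jac
            weight = {"jaccard": jac, "overlap": ovl, "combined": comb}[metric]
            if weight >= edge_cutoff:
                edges.append(TermEdge(a, b, jac, ovl, comb, weight))

    g = nx.Graph()
    g.add_nodes_from(term_ids)
    g.add_edges_from((e.source, e.target) for e in edges)
    clusters = sorted((sorted(c) for c in nx.connected_components(g)),
                      key=lambda c: (-len(c), c[0]))
    return TermNetwork(nodes, edges, clusters, metric, edge_cutoff, node_cutoff)


# -- tiled layout -----------------------------------------------------------


@dataclass
class TileLayout:
    """Ordered clusters with grid tile positions, read top→bottom then left→right."""

    cluster_order: list[list[str]]          # node order within each cluster
    tiles: list[tuple[int, int]]            # (row, col) per cluster, column-major
    sort_key: str
    n_rows: int
    n_cols: int


def tiled_layout(network: TermNetwork, sort_key: str = "node_count") -> TileLayout:
    """Deterministic tile ordering of network clusters.

    ``node_count`` / ``edge_count`` sort descending (largest first);
    ``min_p`` sorts by smallest adjusted p ascending (most significant
    first).  Ties break on the secondary statistic then the lexicographically
    smallest member term.  Within a cluster, nodes order by (min adjusted p,
    term_id).  Tiles fill a near-square grid column-major so the trend reads
    top-to-bottom then left-to-right.
    """
    if sort_key not in ("node_count", "edge_count", "min_p"):
        raise ValueError(f"unknown sort key {sort_key!r}")

    def stats(members: list[str]) -> dict:
        return {
            "node_count": len(members),
            "edge_count": network.cluster_edges(members),
            "min_p": min((network.nodes[t].min_adjusted() for t in members),
                         default=math.inf),
            "first": min(members),
        }

    infos = [(members, stats(members)) for members in network.clusters]
    keys = {
        "node_count": lambda s: (-s["node_count"], s["min_p"], s["first"]),
        "edge_count": lambda s: (-s["edge_count"], -s["node_count"], s["first"]),
        "min_p": lambda s: (s["min_p"], -s["node_count"], s["first"]),
    }[sort_key]
    infos.sort(key=lambda item: keys(item[1]))

    ordered = [sorted(members, key=lambda t: (network.nodes[t].min_adjusted(), t))
               for members, _ in infos]
    n = len(ordered)
    n_rows = max(1, math.ceil(math.sqrt(n))) if n else 1
    n_cols = math.ceil(n / n_rows) if n else 0
    tiles = [(i % n_rows, i // n_rows) for i in range(n)]
    return TileLayout(cluster_order=ordered, tiles=tiles, sort_key=sort_key,
                      n_rows=n_rows, n_cols=n_cols)


# -- hexagonal binning ------------------------------------------------------


@dataclass
class HexBinGrid:
    gridsize: int
    cells: np.ndarray               # (n_cells, 3) keys (lattice, i, j)
    centers: np.ndarray             # (n_cells, 2) data coordinates
    counts: np.ndarray              # (n_cells,) point counts
    members: Optional[list[list[int]]]  # input indices per cell (optional)
    n_dropped: int                  # non-finite points excluded
    extent: tuple[float, float, float, float]
    cell_width: float
    cell_height: float

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _nearest_index(u: np.ndarray, n: int) -> np.ndarray:
    """Nearest integer in [0, n]; exact halves resolve to the smaller index."""
    lo = np.clip(np.floor(u), 0, n)
    hi = np.clip(lo + 1, 0, n)
    pick_hi = (u - lo) > (hi - u)  # strict: ties stay on lo
    return np.where(pick_hi, hi, lo).astype(np.int64)


def hexbin_aggregate(points: Sequence, gridsize: int,
                     extent: Optional[tuple[float, float, float, float]] = None,
                     keep_members: bool = False) -> HexBinGrid:
    """Aggregate 2-D points into hexagonal cells.

    Standard two-lattice construction: centres sit on a rectangular lattice
    of pitch (dx, dy) plus a second lattice offset by (dx/2, dy/2), with
    dx = x-span / gridsize.  Each finite point goes to the nearest centre
    under the anisotropic metric (Δx/dx)² + 3·(Δy/dy)², which makes the cell
    boundaries regular hexagons; between-lattice ties go to the first
    lattice, within-lattice ties to the smaller index.  Non-finite points are
    dropped and counted.
    """
    if gridsize < 1:
        raise ValueError("gridsize must be >= 1")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    finite = np.isfinite(pts).all(axis=1)
    n_dropped = int((~finite).sum())
    pts = pts[finite]
    if len(pts) == 0:
        return HexBinGrid(gridsize, np.empty((0, 3), dtype=int), np.empty((0, 2)),
                          np.empty(0, dtype=int), [] if keep_members else None,
                          n_dropped, (0.0, 0.0, 0.0, 0.0), 1.0, 1.0)

    if extent is None:
        xmin, xmax = float(pts[:, 0].min()), float(pts[:, 0].max())
        ymin, ymax = float(pts[:, 1].min()), float(pts[:, 1].max())
    else:
        xmin, xmax, ymin, ymax = map(float, extent)
    xspan = (xmax - xmin) or 1.0
    yspan = (ymax - ymin) or 1.0
    nx_ = gridsize
    ny_ = max(1, round(gridsize / math.sqrt(3)))
    dx = xspan / nx_
    dy = yspan / ny_

    u = (pts[:, 0] - xmin) / dx
    v = (pts[:, 1] - ymin) / dy

    # lattice A centres at integer (i, j), i in [0, nx], j in [0, ny]
    ia, ja = _nearest_index(u, nx_), _nearest_index(v, ny_)
    d_a = (u - ia) ** 2 + 3.0 * (v - ja) ** 2
    # lattice B centres at (i + 1/2, j + 1/2), i in [0, nx-1], j in [0, ny-1]
    ib = _nearest_index(u - 0.5, nx_ - 1)
    jb = _nearest_index(v - 0.5, ny_ - 1)
    d_b = (u - ib - 0.5) ** 2 + 3.0 * (v - jb - 0.5) ** 2

    use_b = d_b < d_a  # strict: ties go to lattice A
    lattice = use_b.astype(np.int64)
    ii = np.where(use_b, ib, ia)
    jj = np.where(use_b, jb, ja)

    cells: dict[tuple[int, int, int], int] = {}
    members: dict[tuple[int, int, int], list[int]] = {}
    assign = np.stack([lattice, ii, jj], axis=1)
    for idx, cell in enumerate(map(tuple, assign)):
        cells[cell] = cells.get(cell, 0) + 1
        if keep_members:
            members.setdefault(cell, []).append(idx)

    ordered = sorted(cells)
    centers = np.array([[xmin + (i + 0.5 * lat) * dx, ymin + (j + 0.5 * lat) * dy]
                        for lat, i, j in ordered])
    counts = np.array([cells[c] for c in ordered], dtype=int)
    mem = [members[c] for c in ordered] if keep_members else None
    return HexBinGrid(gridsize, np.array(ordered, dtype=int), centers, counts, mem,
                      n_dropped,
                      (xmin - dx / 2, xmax + dx / 2, ymin - dy / 2, ymax + dy / 2),
                      dx, dy)
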