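"""Pair enumeration, measure tables, thresholding and network assembly.

Candidate pairs are enumerated per unordered group pair, measures are
computed with a deterministic parallel map, strict directional thresholds
select edges, and the resulting undirected network keeps isolated nodes
with group/annotation attributes on nodes and measure values plus shared
miRNA symbols on edges.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from cernanet.io_harmonize import (
    AnnotationTable,
    ExpressionMatrix,
    InteractionTable,
)
from cernanet.pair_measures import (
    MEASURES,
    DiscretizeMethod,
    compute_pair_record,
)
from cernanet.preprocessing import GeneGrouping

logger = logging.getLogger(__name__)


def group_pair_label(group1: str, group2: str) -> str:
    """Canonical unordered group-pair label, e.g. ``Coding|Noncoding``."""
    a, b = sorted((group1, group2))
    return f"{a}|{b}"


def enumerate_pairs(
    grouping: GeneGrouping,
    selected_group_pairs: Iterable[tuple[str, str]] | None = None,
) -> list[tuple[str, str, str]]:
    """All canonical gene pairs whose group-pair label is selected.

    Returns (gene1, gene2, group_pair) triples, gene1 < gene2, in
    deterministic lexicographic order.  ``None`` selects every group pair.
    """
    labels = set(grouping.groups)
    if selected_group_pairs is None:
        wanted = {group_pair_label(a, b) for a in labels for b in labels}
    else:
        selected = list(selected_group_pairs)
        if not selected:
            raise ValueError("empty group-pair selection")
        for a, b in selected:
            for g in (a, b):
                if g not in labels:
                    raise ValueError(f"unknown group label {g!r}")
        wanted = {group_pair_label(a, b) for a, b in selected}
    out = []
    for g1, g2 in combinations(sorted(grouping.group_of), 2):
        label = group_pair_label(grouping.group_of[g1], grouping.group_of[g2])
        if label in wanted:
            out.append((g1, g2, label))
    return out


def _compute_chunk(args):
    (pairs, cerna, mirna, interactions, universe, measures, n_bins, method) = args
    return [
        compute_pair_record(
            g1, g2, label, cerna, mirna, interactions, universe,
            measures=measures, n_bins=n_bins, discretize_method=method,
        )
        for g1, g2, label in pairs
    ]


def compute_measures(
    pairs: Sequence[tuple[str, str, str]],
    cerna_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    interactions: InteractionTable,
    universe,
    measures: Sequence[str] = MEASURES,
    workers: int = 1,
    n_bins: int | None = None,
    discretize_method: DiscretizeMethod = "equal-frequency",
    custom=None,
) -> pd.DataFrame:
    """One PairMeasureRecord row per candidate pair.

    Results are bit-identical for any worker count: each pair's computation
    is pure and the output rows follow the input pair order.  Columns:
    gene1, gene2, group_pair, t, shared_mirnas (semicolon-joined, sorted)
    and one column per measure (NaN = undefined/absent).
    """
    for name in measures:
        if name not in MEASURES and not (custom and name in custom):
            raise ValueError(f"unknown measure {name!r}")
    pairs = list(pairs)
    if workers <= 1 or custom or len(pairs) < 2 * workers:
        records = _compute_chunk(
            (pairs, cerna_expr, mirna_expr, interactions, universe,
             tuple(measures), n_bins, discretize_method)
        )
    else:
        chunks = [pairs[i::workers] for i in range(workers)]
        args = [
            (chunk, cerna_expr, mirna_expr, interactions, universe,
             tuple(measures), n_bins, discretize_method)
            for chunk in chunks
        ]
        with ProcessPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(_compute_chunk, args))
        # stitch round-robin chunks back into the original pair order
        records = [None] * len(pairs)
        for w, chunk_records in enumerate(results):
            records[w::workers] = chunk_records
    rows = []
    for rec in records:
        row = {
            "gene1": rec.gene1,
            "gene2": rec.gene2,
            "group_pair": rec.group_pair,
            "t": rec.t,
            "shared_mirnas": ";".join(sorted(rec.shared_mirnas)),
        }
        for name in measures:
            v = rec.values.get(name)
            row[name] = np.nan if v is None else v
        rows.append(row)
    cols = ["gene1", "gene2", "group_pair", "t", "shared_mirnas", *measures]
    return pd.DataFrame(rows, columns=cols)


def measure_density(
    table: pd.DataFrame, measure: str, bins: int = 50
) -> pd.DataFrame:
    """Per-group-pair histogram of a measure's non-absent values.

    Returns rows (group_pair, bin_left, bin_right, count, density); all
    group pairs share one bin grid so densities are comparable.
    """
    if measure not in table.columns:
        raise ValueError(f"measure {measure!r} not in table")
    vals = table[measure].dropna()
    if vals.empty:
        return pd.DataFrame(
            columns=["group_pair", "bin_left", "bin_right", "count", "density"]
        )
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:  # single spike bin
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, bins + 1)
    out = []
    for label, sub in table.groupby("group_pair"):
        v = sub[measure].dropna().to_numpy(dtype=float)
        counts, _ = np.histogram(v, bins=edges)
        width = np.diff(edges)
        dens = counts / counts.sum() / width if counts.sum() else counts * 0.0
        for i in range(bins):
            out.append(
                {
                    "group_pair": label,
                    "bin_left": edges[i],
                    "bin_right": edges[i + 1],
                    "count": int(counts[i]),
                    "density": dens[i],
                }
            )
    return pd.DataFrame(out)


@dataclass(frozen=True)
class ThresholdSpec:
    """Strict directional cutoff for one measure and group pair ('all' = any)."""

    measure: str
    direction: str  # "less-than" | "greater-than"
    cutoff: float
    group_pair: str = "all"

    def __post_init__(self) -> None:
        if self.direction not in ("less-than", "greater-than"):
            raise ValueError(f"direction must be less-than/greater-than")

    def passes(self, value: float) -> bool:
        if np.isnan(value):
            return False
        if self.direction == "less-than":
            return value < self.cutoff
        return value > self.cutoff


def apply_thresholds(
    table: pd.DataFrame, specs: Sequence[ThresholdSpec]
) -> pd.DataFrame:
    """Rows surviving EVERY matching spec (strict inequalities).

    A per-group-pair spec overrides an ``all`` spec for the same measure.
    Absent (NaN) values fail any threshold on their measure.  Duplicate
    (measure, group_pair) specs are an error, as is a spec on an
    uncomputed measure.
    """
    seen = set()
    for spec in specs:
        if spec.measure not in table.columns:
            raise ValueError(f"threshold on uncomputed measure {spec.measure!r}")
        key = (spec.measure, spec.group_pair)
        if key in seen:
            raise ValueError(f"duplicate threshold spec for {key}")
        seen.add(key)
    if not specs:
        return table.copy()
    mask = pd.Series(True, index=table.index)
    for label, sub in table.groupby("group_pair"):
        by_measure: dict[str, ThresholdSpec] = {}
        for spec in specs:
            if spec.group_pair == "all" and spec.measure not in by_measure:
                by_measure[spec.measure] = spec
        for spec in specs:
            if spec.group_pair == label:
                by_measure[spec.measure] = spec
        for spec in by_measure.values():
            vals = sub[spec.measure]
            ok = vals.apply(lambda v: spec.passes(v))
            mask.loc[sub.index] &= ok
    surviving = table[mask].copy()
    logger.info(
        "apply_thresholds: %d of %d pairs became edges", len(surviving), len(table)
    )
    return surviving


def build_network(
    edges: pd.DataFrame,
    all_nodes: Iterable[str],
    grouping: GeneGrouping | None = None,
    annotation: AnnotationTable | None = None,
) -> nx.Graph:
    """Assemble the undirected ceRNA network, retaining isolated nodes.

    ``edges`` is a (surviving) measure table; duplicate pair rows collapse
    to a single edge (logged).  Edge attributes: the measure values, t and
    the shared miRNA symbols; node attributes: group and annotation fields.
    """
    g = nx.Graph()
    for node in sorted(set(all_nodes)):
        attrs = {}
        if grouping is not None:
            attrs["group"] = grouping.group_of.get(node, "")
        if annotation is not None and node in set(annotation.gene_symbols):
            attrs.update(
                {k: str(v) for k, v in annotation.data.loc[node].items()}
            )
        g.add_node(node, **attrs)
    n_dup = 0
    measure_cols = [c for c in edges.columns if c in MEASURES]
    for row in edges.itertuples(index=False):
        u, v = sorted((row.gene1, row.gene2))
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        if g.has_edge(u, v):
            n_dup += 1
            continue
        attrs = {
            "group_pair": row.group_pair,
            "t": int(row.t),
            "shared_mirnas": row.shared_mirnas,
        }
        for c in measure_cols:
            val = getattr(row, c)
            if not (isinstance(val, float) and np.isnan(val)):
                attrs[c] = float(val)
        g.add_edge(u, v, **attrs)
    if n_dup:
        logger.info("build_network: collapsed %d duplicate edge rows", n_dup)
    return g


@dataclass(frozen=True)
class NetworkSummary:
    """Connected/isolated node, edge and component counts."""

    n_connected_nodes: int
    n_isolated_nodes: int
    n_edges: int
    n_components: int

    def to_dict(self) -> dict[str, int]:
        return {
            "n_connected_nodes": self.n_connected_nodes,
            "n_isolated_nodes": self.n_isolated_nodes,
            "n_edges": self.n_edges,
            "n_components": self.n_components,
        }


def summarize(network: nx.Graph) -> NetworkSummary:
    """Counts per the convention: components are counted among connected
    nodes only — isolated nodes are not singleton components."""
    connected = [n for n, d in network.degree() if d > 0]
    sub = network.subgraph(connected)
    return NetworkSummary(
        n_connected_nodes=len(connected),
        n_isolated_nodes=network.number_of_nodes() - len(connected),
        n_edges=network.number_of_edges(),
        n_components=nx.number_connected_components(sub) if connected else 0,
    )


def write_edge_table(network: nx.Graph, path, delimiter: str = "\t") -> None:
    measure_cols = sorted(
        {k for _, _, d in network.edges(data=True) for k in d if k in MEASURES}
    )
    rows = []
    for u, v, d in sorted(network.edges(data=True)):
        row = {
            "gene1": u,
            "gene2": v,
            "group_pair": d.get("group_pair", ""),
            "t": d.get("t", ""),
            "shared_mirnas": d.get("shared_mirnas", ""),
        }
        for c in measure_cols:
            row[c] = d.get(c, "")
        rows.append(row)
    cols = ["gene1", "gene2", "group_pair", "t", "shared_mirnas", *measure_cols]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=delimiter, index=False)


def write_node_table(network: nx.Graph, path, delimiter: str = "\t") -> None:
    rows = []
    for n, d in sorted(network.nodes(data=True)):
        rows.append({"node": n, "degree": network.degree(n), **d})
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)
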