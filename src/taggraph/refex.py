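"""Recursive structural feature extraction (ReFeX-style) over snapshots.

Every node in every monthly snapshot gets six base structural features —
degree, weighted degree, egonet internal/external edge counts, PageRank and
per-component eigenvector centrality — which are then aggregated recursively
over same-snapshot neighborhoods with sum and mean. Redundant columns are
pruned by absolute Pearson correlation on the matrix stacked over all
snapshots, and the surviving columns are min-max normalized to [0, 1]
globally, so that the whole time series shares a single feature space for
the role factorization.

Aggregation paths are named the conventional way: ``degree(sum)(mean)`` is
the mean over neighbors of the sum over their neighbors of degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cooccurrence import SnapshotSeries, TemporalSnapshot

logger = logging.getLogger(__name__)

__all__ = [
    "BASE_FEATURES",
    "AGGREGATORS",
    "FeatureSpec",
    "FeatureTensor",
    "base_features",
    "compute_features",
    "recursive_aggregate",
    "prune_features",
    "normalize_features",
]

BASE_FEATURES = (
    "degree",
    "weighted_degree",
    "egonet_internal_edges",
    "egonet_external_edges",
    "pagerank",
    "eigenvector_centrality",
)
AGGREGATORS = ("sum", "mean")

DEFAULT_DEPTH = 2
DEFAULT_PRUNE_THRESHOLD = 0.95

_PAGERANK_DAMPING = 0.85


@dataclass(frozen=True)
class FeatureSpec:
    """A base feature plus an ordered aggregation path (empty = base)."""

    base: str
    path: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.base not in BASE_FEATURES:
            raise ValueError(f"unknown base feature {self.base!r}")
        if any(a not in AGGREGATORS for a in self.path):
            raise ValueError(f"unknown aggregator in path {self.path!r}")

    @property
    def name(self) -> str:
        return self.base + "".join(f"({a})" for a in self.path)

    @property
    def sort_key(self) -> tuple:
        return (
            len(self.path),
            BASE_FEATURES.index(self.base),
            tuple(AGGREGATORS.index(a) for a in self.path),
        )


def _eigenvector_centrality(g: nx.Graph) -> dict[str, float]:
    """Per-component eigenvector centrality, L2-normalized within component.

    The Perron vector of each component's unweighted adjacency matrix, from
    a dense symmetric eigensolver (deterministic, no convergence tuning).
    Isolates score 0.
    """
    values: dict[str, float] = {}
    for component in nx.connected_components(g):
        nodes = sorted(component)
        if len(nodes) == 1:
            values[nodes[0]] = 0.0
            continue
        idx = {v: i for i, v in enumerate(nodes)}
        a = np.zeros((len(nodes), len(nodes)))
        for u, v in g.subgraph(nodes).edges():
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
        _, vecs = np.linalg.eigh(a)
        vec = np.abs(vecs[:, -1])  # Perron vector is nonnegative on a
        vec /= np.linalg.norm(vec)  # connected component; abs fixes sign
        for v, i in idx.items():
            values[v] = float(vec[i])
    return values


def base_features(snapshot: TemporalSnapshot) -> pd.DataFrame:
    """Six structural base features for every node of one snapshot.

    Egonet counts use the closed neighborhood N[v]: internal edges have both
    endpoints in N[v], external edges exactly one. PageRank (damping 0.85,
    weighted) sums to 1 over the snapshot's nodes; with no edges it is
    uniform. Isolates score 0 on everything except their PageRank share.
    """
    nodes = snapshot.nodes
    if not nodes:
        return pd.DataFrame(columns=list(BASE_FEATURES), dtype=float)
    g = snapshot.to_networkx()
    degree = {v: g.degree(v) for v in nodes}
    wdegree = {v: g.degree(v, weight="weight") for v in nodes}
    internal: dict[str, float] = {}
    external: dict[str, float] = {}
    for v in nodes:
        ego = set(g.neighbors(v)) | {v}
        inside = outside = 0
        for u in ego:
            for w in g.neighbors(u):
                if w in ego:
                    inside += 1
                else:
                    outside += 1
        internal[v] = inside // 2
        external[v] = outside
    pagerank = nx.pagerank(g, alpha=_PAGERANK_DAMPING, weight="weight", tol=1e-12, max_iter=1000)
    eigen = _eigenvector_centrality(g)
    data = {
        "degree": [float(degree[v]) for v in nodes],
        "weighted_degree": [float(wdegree[v]) for v in nodes],
        "egonet_internal_edges": [float(internal[v]) for v in nodes],
        "egonet_external_edges": [float(external[v]) for v in nodes],
        "pagerank": [float(pagerank[v]) for v in nodes],
        "eigenvector_centrality": [eigen[v] for v in nodes],
    }
    return pd.DataFrame(data, index=pd.Index(nodes, name="tag"), dtype=float)


@dataclass
class FeatureTensor:
    """Stacked node-time feature matrix.

    Rows are (month, tag) pairs covering exactly the union of snapshot node
    sets; columns follow ``specs``. ``months`` lists every month of the
    source series, including empty ones, preserving snapshot indexing.
    """

    values: pd.DataFrame
    specs: list[FeatureSpec]
    months: list[str]
    normalized: bool = False
    pruned_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.values.columns) != [s.name for s in self.specs]:
            raise ValueError("columns do not match specs")

    @property
    def n_rows(self) -> int:
        return len(self.values)

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready frame with explicit tag and month columns."""
        out = self.values.reset_index()
        return out[["tag", "month"] + self.feature_names]


def _neighbor_indices(snapshot: TemporalSnapshot) -> list[np.ndarray]:
    nodes = snapshot.nodes
    idx = {v: i for i, v in enumerate(nodes)}
    neigh: list[list[int]] = [[] for _ in nodes]
    for a, b in snapshot.edges:
        neigh[idx[a]].append(idx[b])
        neigh[idx[b]].append(idx[a])
    return [np.asarray(sorted(n), dtype=int) for n in neigh]


def _stack_base(series: SnapshotSeries) -> pd.DataFrame:
    blocks = []
    for snap in series:
        block = base_features(snap)
        if block.empty:
            continue
        block = block.copy()
        block["month"] = snap.month
        blocks.append(block.reset_index())
    if not blocks:
        raise ValueError("series has no nodes in any snapshot")
    stacked = pd.concat(blocks, ignore_index=True)
    return stacked.set_index(["month", "tag"]).sort_index()


def recursive_aggregate(
    tensor: FeatureTensor, series: SnapshotSeries, depth: int
) -> FeatureTensor:
    """Expand features by neighbor aggregation, without pruning.

    For each feature ``f`` retained at the previous level and each
    aggregator, the new value at (v, t) aggregates ``f(u, t)`` over the
    same-snapshot neighbors ``u`` of ``v``; a mean over an empty neighbor
    set is 0. Neighbor sets are unweighted — edge weights influence features
    only through ``weighted_degree``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    values = tensor.values.copy()
    specs = list(tensor.specs)
    for _ in range(depth):
        existing = {s.name for s in specs}
        frontier = [
            (parent, FeatureSpec(parent.base, parent.path + (agg,)))
            for parent in specs
            for agg in AGGREGATORS
            if FeatureSpec(parent.base, parent.path + (agg,)).name not in existing
        ]
        if not frontier:
            break
        new_cols = _aggregate_level(values, frontier, series)
        for _, spec in frontier:
            values[spec.name] = new_cols[spec.name]
        specs.extend(spec for _, spec in frontier)
    return FeatureTensor(values=values, specs=specs, months=tensor.months)


def _aggregate_level(
    values: pd.DataFrame,
    frontier: list[tuple[FeatureSpec, FeatureSpec]],
    series: SnapshotSeries,
) -> dict[str, np.ndarray]:
    out = {child.name: np.zeros(len(values)) for _, child in frontier}
    for snap in series:
        nodes = snap.nodes
        if not nodes:
            continue
        neigh = _neighbor_indices(snap)
        locs = values.index.get_indexer([(snap.month, v) for v in nodes])
        cache: dict[str, np.ndarray] = {}
        for parent, child in frontier:
            col = cache.get(parent.name)
            if col is None:
                col = values[parent.name].to_numpy()[locs]
                cache[parent.name] = col
            agg = child.path[-1]
            if agg == "sum":
                vals = np.array([col[n].sum() if len(n) else 0.0 for n in neigh])
            else:
                vals = np.array([col[n].mean() if len(n) else 0.0 for n in neigh])
            out[child.name][locs] = vals
    return out


def prune_features(
    tensor: FeatureTensor, correlation_threshold: float = DEFAULT_PRUNE_THRESHOLD
) -> FeatureTensor:
    """Drop constant and near-duplicate columns on the stacked matrix.

    Columns are scanned in canonical order (shorter aggregation path first,
    then base-feature order, then sum before mean); a column is dropped when
    it is constant or when its absolute Pearson correlation with any
    already-retained column exceeds the threshold over all rows.
    """
    ordered = sorted(tensor.specs, key=lambda s: s.sort_key)
    retained: list[FeatureSpec] = []
    kept_cols: list[np.ndarray] = []
    dropped: list[tuple[str, str]] = []
    for spec in ordered:
        col = tensor.values[spec.name].to_numpy(dtype=float)
        std = col.std()
        if std == 0 or col.max() == col.min():
            dropped.append((spec.name, "constant"))
            continue
        redundant = None
        centered = col - col.mean()
        for other, other_col in zip(retained, kept_cols):
            r = float(np.dot(centered, other_col - other_col.mean()) / (len(col) * std * other_col.std()))
            if abs(r) > correlation_threshold:
                redundant = (other.name, r)
                break
        if redundant is not None:
            dropped.append((spec.name, f"|r|={abs(redundant[1]):.4f} with {redundant[0]}"))
            continue
        retained.append(spec)
        kept_cols.append(col)
    for name, reason in dropped:
        logger.debug("pruned feature %s: %s", name, reason)
    logger.info("pruned %d of %d features, %d retained", len(dropped), len(ordered), len(retained))
    return FeatureTensor(
        values=tensor.values[[s.name for s in retained]],
        specs=retained,
        months=tensor.months,
        normalized=tensor.normalized,
        pruned_log=tensor.pruned_log + dropped,
    )


def normalize_features(tensor: FeatureTensor) -> FeatureTensor:
    """Min-max normalize each column to [0, 1] over all rows jointly."""
    values = tensor.values.copy()
    for name in values.columns:
        col = values[name].to_numpy(dtype=float)
        lo, hi = col.min(), col.max()
        if hi == lo:
            raise RuntimeError(f"constant column {name!r} reached normalization; prune first")
        values[name] = (col - lo) / (hi - lo)
    return FeatureTensor(
        values=values,
        specs=list(tensor.specs),
        months=tensor.months,
        normalized=True,
        pruned_log=list(tensor.pruned_log),
    )


def compute_features(
    series: SnapshotSeries,
    depth: int = DEFAULT_DEPTH,
    prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
) -> FeatureTensor:
    """Full feature stage: base features, recursion with per-level pruning,
    then global min-max normalization.

    Pruning runs after the base level and again after each recursion level,
    so redundant columns never spawn further aggregates; the recursion
    expands only features retained at the previous level.
    """
    stacked = _stack_base(series)
    specs = [FeatureSpec(b) for b in BASE_FEATURES]
    tensor = FeatureTensor(values=stacked[[s.name for s in specs]], specs=specs, months=series.months)
    tensor = prune_features(tensor, prune_threshold)
    for _ in range(depth):
        frontier_before = set(tensor.feature_names)
        tensor = recursive_aggregate(tensor, series, depth=1)
        # recursion level: expand retained frontier by one, then prune
        tensor = prune_features(tensor, prune_threshold)
        if set(tensor.feature_names) == frontier_before:
            break
    tensor = normalize_features(tensor)
    logger.info("feature tensor: %d rows x %d features", tensor.n_rows, len(tensor.specs))
    return tensor
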