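"""Structural features: hand-computed examples plus a brute-force oracle
over exhaustive small graphs."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from taggraph.cooccurrence import SnapshotSeries
from taggraph.refex import (
    FeatureSpec,
    FeatureTensor,
    base_features,
    compute_features,
    normalize_features,
    prune_features,
    recursive_aggregate,
)

from conftest import series_from_graph, snapshot_from_graph


def tensor_from_columns(columns: dict[str, list[float]]) -> FeatureTensor:
    """Small tensor with arbitrary column data under valid feature names."""
    names = list(columns)
    n = len(next(iter(columns.values())))
    idx = pd.MultiIndex.from_tuples(
        [("2020-01", f"t{i}") for i in range(n)], names=["month", "tag"]
    )
    from taggraph.io import _parse_spec

    specs = [_parse_spec(name) for name in names]
    return FeatureTensor(
        values=pd.DataFrame(columns, index=idx), specs=specs, months=["2020-01"]
    )


class TestBaseFeatures:
    def test_triangle(self):
        snap = snapshot_from_graph(nx.cycle_graph(3))
        feats = base_features(snap)
        assert (feats["degree"] == 2).all()
        assert (feats["egonet_internal_edges"] == 3).all()
        assert (feats["egonet_external_edges"] == 0).all()
        assert feats["pagerank"].to_numpy() == pytest.approx([1 / 3] * 3)

    def test_star_center_and_leaf(self):
        snap = snapshot_from_graph(nx.star_graph(3))  # center n0, leaves n1..n3
        feats = base_features(snap)
        assert feats.loc["n0", "degree"] == 3
        assert feats.loc["n0", "egonet_internal_edges"] == 3
        assert feats.loc["n0", "egonet_external_edges"] == 0
        assert feats.loc["n1", "degree"] == 1
        assert feats.loc["n1", "egonet_internal_edges"] == 1
        assert feats.loc["n1", "egonet_external_edges"] == 2

    def test_isolate_all_zero_except_pagerank(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_node(2)
        snap = snapshot_from_graph(g)
        feats = base_features(snap)
        iso = feats.loc["n2"]
        assert iso["degree"] == 0
        assert iso["weighted_degree"] == 0
        assert iso["egonet_internal_edges"] == 0
        assert iso["egonet_external_edges"] == 0
        assert iso["eigenvector_centrality"] == 0
        assert iso["pagerank"] > 0

    def test_pagerank_sums_to_one(self):
        for g in (nx.path_graph(5), nx.empty_graph(4), nx.star_graph(3)):
            feats = base_features(snapshot_from_graph(g))
            assert feats["pagerank"].sum() == pytest.approx(1.0, abs=1e-8)


class TestRecursion:
    def base_tensor(self, g):
        series = series_from_graph(g)
        snap = series[0]
        block = base_features(snap)
        block["month"] = snap.month
        values = block.reset_index().set_index(["month", "tag"]).sort_index()
        from taggraph.refex import BASE_FEATURES

        specs = [FeatureSpec(b) for b in BASE_FEATURES]
        tensor = FeatureTensor(
            values=values[[s.name for s in specs]], specs=specs, months=series.months
        )
        return tensor, series

    def test_triangle_degree_aggregates(self):
        tensor, series = self.base_tensor(nx.cycle_graph(3))
        expanded = recursive_aggregate(tensor, series, depth=1)
        assert (expanded.values["degree(sum)"] == 4).all()
        assert (expanded.values["degree(mean)"] == 2).all()

    def test_star_center_aggregates(self):
        tensor, series = self.base_tensor(nx.star_graph(3))
        expanded = recursive_aggregate(tensor, series, depth=1)
        assert expanded.values.loc[("2020-01", "n0"), "degree(sum)"] == 3
        assert expanded.values.loc[("2020-01", "n0"), "degree(mean)"] == 1

    def test_isolate_aggregates_are_zero(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_node(2)
        tensor, series = self.base_tensor(g)
        expanded = recursive_aggregate(tensor, series, depth=2)
        row = expanded.values.loc[("2020-01", "n2")]
        for name in expanded.feature_names:
            if "(" in name:
                assert row[name] == 0.0


class TestPruning:
    def test_duplicate_column_dropped(self):
        tensor = tensor_from_columns(
            {"degree": [1.0, 2.0, 3.0], "weighted_degree": [1.0, 2.0, 3.0]}
        )
        pruned = prune_features(tensor, 0.95)
        assert pruned.feature_names == ["degree"]

    def test_affine_duplicate_dropped(self):
        tensor = tensor_from_columns(
            {"degree": [1.0, 2.0, 3.0], "pagerank": [2.0, 4.0, 6.0]}
        )
        pruned = prune_features(tensor, 0.95)
        assert pruned.feature_names == ["degree"]

    def test_independent_columns_retained(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(200), rng.random(200)
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 0.95
        tensor = tensor_from_columns({"degree": list(a), "pagerank": list(b)})
        assert prune_features(tensor, 0.95).feature_names == ["degree", "pagerank"]

    def test_constant_column_dropped(self):
        tensor = tensor_from_columns({"degree": [1.0, 2.0, 3.0], "pagerank": [7.0] * 3})
        assert prune_features(tensor, 0.95).feature_names == ["degree"]


class TestNormalization:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([0.0, 5.0, 10.0], [0.0, 0.5, 1.0]),
            ([0.0, 0.5, 1.0], [0.0, 0.5, 1.0]),
            ([-2.0, 0.0, 2.0], [0.0, 0.5, 1.0]),
        ],
    )
    def test_min_max(self, column, expected):
        tensor = tensor_from_columns({"degree": column})
        normalized = normalize_features(tensor)
        assert list(normalized.values["degree"]) == expected
        assert normalized.normalized

    def test_constant_column_is_internal_error(self):
        tensor = tensor_from_columns({"degree": [1.0, 1.0]})
        with pytest.raises(RuntimeError):
            normalize_features(tensor)


def oracle_features(snap, depth):
    """Direct recomputation from neighbor lists, independent of the
    implementation: dense PageRank by power iteration, eigenvector via
    numpy eigh per component, explicit egonet edge counting, and literal
    sum/mean recursion."""
    nodes = snap.nodes
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = {v: set() for v in nodes}
    weights = {}
    for (a, b), (c, w) in snap.edges.items():
        adj[a].add(b)
        adj[b].add(a)
        weights[(a, b)] = weights[(b, a)] = w

    feats = {}
    feats["degree"] = {v: float(len(adj[v])) for v in nodes}
    feats["weighted_degree"] = {v: sum(weights[(v, u)] for u in adj[v]) for v in nodes}
    internal, external = {}, {}
    for v in nodes:
        ego = adj[v] | {v}
        inside = sum(1 for (a, b) in snap.edges if a in ego and b in ego)
        outside = sum(1 for (a, b) in snap.edges if (a in ego) != (b in ego))
        internal[v], external[v] = float(inside), float(outside)
    feats["egonet_internal_edges"] = internal
    feats["egonet_external_edges"] = external

    # weighted PageRank: dense iteration with dangling redistribution
    pr = np.full(n, 1.0 / n)
    out_weight = np.array([sum(weights[(v, u)] for u in adj[v]) for v in nodes])
    for _ in range(500):
        nxt = np.zeros(n)
        for v in nodes:
            i = index[v]
            if out_weight[i] > 0:
                for u in adj[v]:
                    nxt[index[u]] += 0.85 * pr[i] * weights[(v, u)] / out_weight[i]
            else:
                nxt += 0.85 * pr[i] / n
        nxt += 0.15 / n
        if np.abs(nxt - pr).sum() < 1e-14:
            pr = nxt
            break
        pr = nxt
    feats["pagerank"] = {v: float(pr[index[v]]) for v in nodes}

    # eigenvector centrality per component via shifted power iteration
    # (A + I guarantees convergence on bipartite components)
    eig = {}
    seen = set()
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            v = frontier.pop()
            for u in adj[v]:
                if u not in comp:
                    comp.add(u)
                    frontier.append(u)
        seen |= comp
        comp_nodes = sorted(comp)
        if len(comp_nodes) == 1:
            eig[comp_nodes[0]] = 0.0
            continue
        a = np.eye(len(comp_nodes))
        ci = {v: i for i, v in enumerate(comp_nodes)}
        for v in comp_nodes:
            for u in adj[v]:
                a[ci[v], ci[u]] = 1.0
        x = np.full(len(comp_nodes), 1.0 / np.sqrt(len(comp_nodes)))
        for _ in range(100000):
            nxt = a @ x
            nxt /= np.linalg.norm(nxt)
            if np.linalg.norm(nxt - x) < 1e-14:
                x = nxt
                break
            x = nxt
        for v in comp_nodes:
            eig[v] = float(abs(x[ci[v]]))
    feats["eigenvector_centrality"] = eig

    frontier_names = list(feats)
    for _ in range(depth):
        new = {}
        for name in frontier_names:
            col = feats[name]
            new[f"{name}(sum)"] = {v: sum(col[u] for u in adj[v]) for v in nodes}
            new[f"{name}(mean)"] = {
                v: (sum(col[u] for u in adj[v]) / len(adj[v])) if adj[v] else 0.0
                for v in nodes
            }
        feats.update(new)
        frontier_names = list(new)
    return feats


def assert_matches_oracle(g, depth=2):
    snap = snapshot_from_graph(g)
    series = series_from_graph(g)
    block = base_features(snap)
    block["month"] = snap.month
    values = block.reset_index().set_index(["month", "tag"]).sort_index()
    from taggraph.refex import BASE_FEATURES

    specs = [FeatureSpec(b) for b in BASE_FEATURES]
    tensor = FeatureTensor(
        values=values[[s.name for s in specs]], specs=specs, months=series.months
    )
    expanded = recursive_aggregate(tensor, series, depth=depth)
    oracle = oracle_features(snap, depth)
    for name in expanded.feature_names:
        for v in snap.nodes:
            got = expanded.values.loc[(snap.month, v), name]
            want = oracle[name][v]
            assert got == pytest.approx(want, abs=1e-6), (name, v)


def test_all_connected_graphs_up_to_six_nodes_match_oracle():
    graphs = [g for g in nx.graph_atlas_g()[1:] if len(g) <= 6 and nx.is_connected(g)]
    assert len(graphs) > 100
    for g in graphs:
        assert_matches_oracle(g, depth=1)


def test_random_graphs_up_to_eight_nodes_match_oracle():
    rng = np.random.default_rng(17)
    for _ in range(40):
        n = int(rng.integers(2, 9))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.8)), seed=int(rng.integers(2**31)))
        assert_matches_oracle(g, depth=2)


def test_compute_features_end_to_end_is_normalized():
    g = nx.barbell_graph(4, 2)
    tensor = compute_features(series_from_graph(g), depth=2)
    assert tensor.normalized
    vals = tensor.values.to_numpy()
    assert vals.min() >= 0.0 and vals.max() <= 1.0
    assert tensor.n_rows == len(g)
    # every retained column spans the full [0, 1] range after min-max
    assert np.allclose(vals.min(axis=0), 0.0)
    assert np.allclose(vals.max(axis=0), 1.0)
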