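"""Role interpretation: centralities, correlations, rankings, trajectories."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from taggraph.analysis import (
    MEASURES,
    centrality_measures,
    dominant_role,
    neighbor_frequency,
    node_relevance,
    role_measure_correlations,
    role_trajectory,
    role_transition_tags,
    top_k_neighbors,
)
from taggraph.cooccurrence import SnapshotSeries, TemporalSnapshot
from taggraph.rolx import MissingRowError, RoleModel

from conftest import series_from_graph


def model_from_w(W: np.ndarray, rows: list[tuple[str, str]], months: list[str]) -> RoleModel:
    """Hand-planted role model: H is irrelevant for these queries."""
    r = W.shape[1]
    return RoleModel(
        r=r,
        W=W,
        H=np.ones((r, 3)),
        rows=pd.MultiIndex.from_tuples(rows, names=["month", "tag"]),
        feature_names=["degree", "pagerank", "eigenvector_centrality"],
        months=months,
        fit_error=0.0,
    )


def snapshot(month, t, freqs, edges):
    """Edges given as {(a, b): c}; weights derived from the closed form."""
    full = {
        tuple(sorted(k)): (c, c / (freqs[k[0]] * freqs[k[1]])) for k, c in edges.items()
    }
    return TemporalSnapshot(t=t, month=month, tag_frequencies=freqs, edges=full)


class TestCentralities:
    def test_path_graph_betweenness(self):
        series = series_from_graph(nx.path_graph(3))  # n0 - n1 - n2
        table = centrality_measures(series)
        month = series[0].month
        assert table.loc[(month, "n1"), "betweenness_centrality"] == 1.0
        assert table.loc[(month, "n0"), "betweenness_centrality"] == 0.0
        assert table.loc[(month, "n2"), "betweenness_centrality"] == 0.0

    def test_triangle_clustering_is_one(self):
        series = series_from_graph(nx.complete_graph(3))
        table = centrality_measures(series)
        assert (table["local_clustering_coefficient"] == 1.0).all()

    def test_isolate_conventions(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_node(2)
        table = centrality_measures(series_from_graph(g))
        month = "2020-01"
        iso = table.loc[(month, "n2")]
        assert iso["closeness_centrality"] == 0.0
        assert iso["local_clustering_coefficient"] == 0.0
        assert iso["degree"] == 0.0

    def test_closeness_within_component(self):
        series = series_from_graph(nx.path_graph(3))
        table = centrality_measures(series)
        # center: 2 reachable at distances 1+1 -> 2/2 = 1
        assert table.loc[("2020-01", "n1"), "closeness_centrality"] == 1.0
        # ends: (3-1-... ) 2 reachable at distances 1+2 -> 2/3
        assert table.loc[("2020-01", "n0"), "closeness_centrality"] == pytest.approx(2 / 3)


def textbook_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


class TestCorrelations:
    def centrality_and_model(self, w_cols):
        rng = np.random.default_rng(0)
        n = len(next(iter(w_cols.values())) if isinstance(w_cols, dict) else w_cols)
        rows = [("2020-01", f"t{i:04d}") for i in range(n)]
        idx = pd.MultiIndex.from_tuples(rows, names=["month", "tag"])
        degree = np.arange(n, dtype=float)
        centrality = pd.DataFrame(
            {m: rng.random(n) for m in MEASURES}, index=idx
        )
        centrality["degree"] = degree
        return centrality, rows, degree

    def test_role_equal_to_degree_has_correlation_one(self):
        centrality, rows, degree = self.centrality_and_model([0.0] * 50)
        W = np.column_stack([degree, 50.0 - degree])
        model = model_from_w(W, rows, ["2020-01"])
        table = role_measure_correlations(model, centrality)
        assert table.loc[0, "degree"] == pytest.approx(1.0)
        assert table.loc[1, "degree"] == pytest.approx(-1.0)

    def test_random_role_uncorrelated_with_degree(self):
        centrality, rows, _ = self.centrality_and_model([0.0] * 1000)
        W = np.random.default_rng(99).random((1000, 1))
        model = model_from_w(W, rows, ["2020-01"])
        table = role_measure_correlations(model, centrality)
        assert abs(table.loc[0, "degree"]) < 0.1

    def test_constant_column_is_undefined_not_zero(self):
        centrality, rows, _ = self.centrality_and_model([0.0] * 20)
        W = np.full((20, 1), 0.7)
        model = model_from_w(W, rows, ["2020-01"])
        table = role_measure_correlations(model, centrality)
        assert table.loc[0].isna().all()

    def test_agrees_with_textbook_pearson(self):
        centrality, rows, _ = self.centrality_and_model([0.0] * 200)
        W = np.random.default_rng(5).random((200, 2))
        model = model_from_w(W, rows, ["2020-01"])
        table = role_measure_correlations(model, centrality)
        for role in range(2):
            for measure in MEASURES:
                expected = textbook_pearson(
                    list(W[:, role]), list(centrality[measure])
                )
                assert table.loc[role, measure] == pytest.approx(expected, abs=1e-12)


def two_node_setup(weight_c=1, s_a=2, s_b=1):
    snap = snapshot("2020-01", 0, {"a": s_a, "b": s_b}, {("a", "b"): weight_c})
    series = SnapshotSeries([snap])
    W = np.array([[0.4, 0.0], [0.8, 0.1]])  # rows: (2020-01, a), (2020-01, b)
    model = model_from_w(W, [("2020-01", "a"), ("2020-01", "b")], ["2020-01"])
    return series, model


class TestNodeRelevance:
    def test_product_form(self):
        series, model = two_node_setup()
        # weight(a,b) = 1/2, role_relevance(b, 0) = 0.8
        assert node_relevance(series, model, "a", "b", 0, 0) == 0.5 * 0.8

    def test_zero_relevance_annihilates(self):
        series, model = two_node_setup()
        assert node_relevance(series, model, "b", "a", 1, 0) == 0.0

    def test_non_neighbor_is_error_not_zero(self):
        snap = snapshot("2020-01", 0, {"a": 1, "b": 1, "c": 1}, {("a", "b"): 1})
        series = SnapshotSeries([snap])
        model = model_from_w(
            np.ones((3, 1)), [("2020-01", x) for x in "abc"], ["2020-01"]
        )
        with pytest.raises(ValueError):
            node_relevance(series, model, "a", "c", 0, 0)


class TestTopK:
    def star_setup(self):
        freqs = {"hub": 4, "x": 2, "y": 2, "z": 2}
        snap = snapshot(
            "2020-01", 0, freqs, {("hub", "x"): 2, ("hub", "y"): 2, ("hub", "z"): 1}
        )
        series = SnapshotSeries([snap])
        rows = [("2020-01", t) for t in sorted(freqs)]
        W = np.array([[0.0], [0.5], [0.5], [0.9]])  # hub, x, y, z
        model = model_from_w(W, rows, ["2020-01"])
        return series, model

    def test_truncation_below_k(self):
        series, model = self.star_setup()
        ranking = top_k_neighbors(series, model, "hub", 0, 0, k=20)
        assert len(ranking.ranked) == 3

    def test_descending_with_lexicographic_ties(self):
        series, model = self.star_setup()
        ranking = top_k_neighbors(series, model, "hub", 0, 0, k=20)
        # weights: x,y -> 2/8=0.25, z -> 1/8; relevance: x=y=0.125, z=0.1125
        assert ranking.tags() == ["x", "y", "z"]
        values = [v for _, v in ranking.ranked]
        assert values == sorted(values, reverse=True)
        assert values[0] == values[1]  # tie broken by name

    def test_missing_start_tag_signals(self):
        series, model = self.star_setup()
        with pytest.raises(MissingRowError):
            top_k_neighbors(series, model, "nope", 0, 0)


class TestNeighborFrequency:
    def three_snapshot_setup(self):
        snaps = []
        rows = []
        for t, month in enumerate(["2020-01", "2020-02", "2020-03"]):
            freqs = {"hub": 2, "a": 1, "b": 1}
            edges = {("hub", "a"): 1} if t < 2 else {("hub", "a"): 1, ("hub", "b"): 1}
            snaps.append(snapshot(month, t, freqs, edges))
            rows += [(month, tag) for tag in sorted(freqs)]
        W = np.ones((len(rows), 1))
        model = model_from_w(W, rows, [s.month for s in snaps])
        return SnapshotSeries(snaps), model

    def test_counts_match_enumeration(self):
        series, model = self.three_snapshot_setup()
        counts = neighbor_frequency(series, model, "hub", 0, k=20)
        assert counts == {"a": 3, "b": 1}

    def test_never_neighbor_absent_from_map(self):
        series, model = self.three_snapshot_setup()
        counts = neighbor_frequency(series, model, "hub", 0, k=20)
        assert "hub" not in counts


class TestDominantRole:
    def model(self):
        W = np.array([[0.7, 0.2, 0.1], [0.5, 0.5, 0.0], [0.0, 0.0, 0.0]])
        rows = [("2020-01", "a"), ("2020-01", "b"), ("2020-01", "c")]
        return model_from_w(W, rows, ["2020-01"])

    def test_argmax(self):
        assert dominant_role(self.model(), "a", "2020-01") == 0

    def test_tie_takes_lowest_index(self):
        assert dominant_role(self.model(), "b", "2020-01") == 0

    def test_all_zero_row_has_no_role(self):
        assert dominant_role(self.model(), "c", "2020-01") is None

    def test_missing_row_signals(self):
        with pytest.raises(MissingRowError):
            dominant_role(self.model(), "a", "2020-02")


class TestTransitionRule:
    def setup_series(self):
        """6 candidate tags with engineered top-k frequencies.

        Start tag 'hub' present in 5 snapshots. Role 0 relevance picks a
        different neighbor subset than role 1 via planted W.
        """
        months = [f"2020-{m:02d}" for m in range(1, 6)]
        tags = ["hub", "p", "q", "r", "s", "u", "v"]
        snaps = []
        rows = []
        for t, month in enumerate(months):
            freqs = {tag: 1 for tag in tags}
            freqs["hub"] = 1
            edges = {("hub", x): 1 for x in tags if x != "hub"}
            snaps.append(snapshot(month, t, freqs, edges))
            rows += [(month, tag) for tag in sorted(tags)]
        # roles: role0 high for p,q,r; role1 high for p,u
        w_by_tag = {
            "hub": (0.0, 0.0),
            "p": (1.0, 1.0),
            "q": (1.0, 0.0),
            "r": (1.0, 0.0),
            "s": (0.2, 0.0),
            "u": (0.0, 1.0),
            "v": (0.1, 0.0),
        }
        W = np.array([w_by_tag[tag] for month, tag in rows])
        model = model_from_w(W, rows, months)
        return SnapshotSeries(snaps), model

    def test_rule_selects_expected_subset(self):
        series, model = self.setup_series()
        # k=3 keeps {p, q, r} for role 0 every month (s, u, v fall below),
        # and {p, u, + lexicographic third} for role 1
        # role-1 top-3 is p, u, plus q (zero relevance, lexicographic tie
        # among q/r/s/v), so both p and q satisfy the rule
        hits = role_transition_tags(series, model, "hub", 0, [1], min_freq=2, k=3)
        assert [tag for tag, _ in hits] == ["p", "q"]
        assert hits[0][1] == 5  # p in role-0 top-k in all 5 snapshots

    def test_min_freq_strictly_exceeded(self):
        series, model = self.setup_series()
        hits = role_transition_tags(series, model, "hub", 0, [1], min_freq=5, k=3)
        assert hits == []  # freq == min_freq does not qualify


class TestTrajectory:
    def model_over_months(self):
        months = ["2020-01", "2020-02", "2020-03", "2020-04"]
        rows = [("2020-01", "a"), ("2020-02", "a"), ("2020-03", "a"), ("2020-04", "a"),
                ("2020-03", "b")]
        W = np.array([[1.0, 0.0]] * 4 + [[0.2, 0.6]])
        return model_from_w(W, rows, months), months

    def test_full_presence_has_no_missing(self):
        model, months = self.model_over_months()
        traj = role_trajectory(model, "a")
        assert len(traj) == len(months)
        assert traj.notna().all().all()
        assert (traj.sum(axis=1) == 1.0).all()

    def test_single_month_tag_has_one_entry(self):
        model, months = self.model_over_months()
        traj = role_trajectory(model, "b")
        assert traj.notna().all(axis=1).sum() == 1
        assert traj.loc["2020-03"].tolist() == pytest.approx([0.25, 0.75])

    def test_never_seen_tag_signals(self):
        model, _ = self.model_over_months()
        with pytest.raises(MissingRowError):
            role_trajectory(model, "zzz")


def test_trajectory_plot_writes_figure(tmp_path):
    W = np.array([[1.0, 0.0], [0.3, 0.3], [0.0, 1.0]])
    rows = [("2020-01", "a"), ("2020-02", "a"), ("2020-03", "a")]
    model = model_from_w(W, rows, ["2020-01", "2020-02", "2020-03"])
    from taggraph.analysis import plot_role_trajectory

    traj = role_trajectory(model, "a")
    out = tmp_path / "traj.png"
    plot_role_trajectory(traj, out, title="a")
    assert out.stat().st_size > 0
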