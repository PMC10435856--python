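import datetime as dt

import networkx as nx
import pytest

from taggraph.corpus import Corpus, PaperRecord
from taggraph.cooccurrence import SnapshotSeries, TemporalSnapshot, snapshot_from_papers


def record(pid: str, date: str, tags) -> PaperRecord:
    return PaperRecord(pid, dt.date.fromisoformat(date), tuple(tags))


@pytest.fixture
def worked_corpus() -> Corpus:
    """Four papers in one month: P1{A,B}, P2{A,B}, P3{A,C}, P4{A}.

    Known counts: s_A=4, s_B=2, s_C=1; c_AB=2, c_AC=1;
    SA(A,B)=2/8=0.25, SA(A,C)=1/4=0.25.
    """
    return Corpus(
        [
            record("P1", "2020-03-02", ["A", "B"]),
            record("P2", "2020-03-10", ["A", "B"]),
            record("P3", "2020-03-15", ["A", "C"]),
            record("P4", "2020-03-20", ["A"]),
        ]
    )


def snapshot_from_graph(g: nx.Graph, month: str = "2020-01", t: int = 0) -> TemporalSnapshot:
    """Realize an arbitrary graph as a co-occurrence snapshot.

    One paper per edge (both endpoint tags) and one single-tag paper per
    isolated node, so s_i = max(degree, 1) and c_ij = 1 on every edge.
    """
    g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes()})
    papers = []
    idx = 0
    for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
        papers.append(record(f"E{idx:04d}", f"{month}-01", [u, v]))
        idx += 1
    for v in sorted(g.nodes()):
        if g.degree(v) == 0:
            papers.append(record(f"I{idx:04d}", f"{month}-01", [v]))
            idx += 1
    return snapshot_from_papers(t, month, papers)


def series_from_graph(g: nx.Graph, month: str = "2020-01") -> SnapshotSeries:
    return SnapshotSeries([snapshot_from_graph(g, month)])
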