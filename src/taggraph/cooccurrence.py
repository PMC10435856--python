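"""Monthly co-occurrence snapshots of the tag graph.

A snapshot for month *t* is the undirected graph G_t = (V_t, E_t): V_t is the
set of tags appearing in papers published that month, and an edge {i, j}
exists when at least one paper carries both tags. Edge weights use the
association strength SA = c_ij / (s_i * s_j), where c_ij counts papers with
both tags and s_i, s_j count papers with each tag individually, all within
the month. Weights are within-month only; nothing is accumulated over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Sequence

import networkx as nx

from .corpus import Corpus, PaperRecord

__all__ = [
    "TemporalSnapshot",
    "SnapshotSeries",
    "association_strength",
    "count_cooccurrences",
    "slice_by_month",
    "build_taggraph",
    "month_range",
]


class DomainError(ValueError):
    """Argument outside the formula's domain."""


def association_strength(c_ij: int, s_i: int, s_j: int) -> float:
    """Association strength SA = c_ij / (s_i * s_j).

    Normalizes the pair count by the individual tag frequencies, so a pair of
    rare tags that always co-occur scores higher than a pair of ubiquitous
    tags that co-occur incidentally. Symmetric in (s_i, s_j); maximum 1.0 for
    co-singletons (c=1, s_i=s_j=1).
    """
    if s_i < 1 or s_j < 1:
        raise DomainError(f"tag frequencies must be >= 1, got s_i={s_i}, s_j={s_j}")
    if not 1 <= c_ij <= min(s_i, s_j):
        raise DomainError(f"need 1 <= c_ij <= min(s_i, s_j), got c_ij={c_ij}")
    return c_ij / (s_i * s_j)


def count_cooccurrences(
    papers: Sequence[PaperRecord],
) -> tuple[dict[str, int], dict[tuple[str, str], int]]:
    """Per-month tag frequencies s_i and pair counts c_ij.

    Precondition: every paper's tag list is already deduplicated (normalized
    corpora satisfy this); a repeated tag within one paper is rejected rather
    than silently collapsed, since it signals an unnormalized corpus.
    """
    freqs: dict[str, int] = {}
    pairs: dict[tuple[str, str], int] = {}
    for paper in papers:
        tags = sorted(paper.raw_tags)
        if len(set(tags)) != len(tags):
            raise DomainError(f"paper {paper.paper_id!r} has duplicate tags; normalize first")
        for tag in tags:
            freqs[tag] = freqs.get(tag, 0) + 1
        for a, b in combinations(tags, 2):
            pairs[(a, b)] = pairs.get((a, b), 0) + 1
    return freqs, pairs


@dataclass
class TemporalSnapshot:
    """One month's weighted co-occurrence graph.

    ``edges`` maps a sorted tag pair to ``(c_ij, weight)`` with
    ``weight = c_ij / (s_i * s_j)`` exactly; no self-loops, single storage
    per unordered pair. Tags with s_i >= 1 but no co-occurrence remain as
    isolated nodes.
    """

    t: int
    month: str
    tag_frequencies: dict[str, int] = field(default_factory=dict)
    edges: dict[tuple[str, str], tuple[int, float]] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.tag_frequencies)

    @property
    def n_nodes(self) -> int:
        return len(self.tag_frequencies)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, tag: str) -> list[str]:
        out = []
        for (a, b) in self.edges:
            if a == tag:
                out.append(b)
            elif b == tag:
                out.append(a)
        return sorted(out)

    def weight(self, tag_a: str, tag_b: str) -> float:
        key = (tag_a, tag_b) if tag_a <= tag_b else (tag_b, tag_a)
        return self.edges[key][1]

    def validate(self) -> None:
        for (a, b), (c, w) in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a > b:
                raise ValueError(f"edge key not sorted: {(a, b)}")
            s_a, s_b = self.tag_frequencies[a], self.tag_frequencies[b]
            if not 1 <= c <= min(s_a, s_b):
                raise ValueError(f"inconsistent counts on {(a, b)}: c={c}, s=({s_a},{s_b})")
            if w != c / (s_a * s_b):
                raise ValueError(f"weight mismatch on {(a, b)}")

    def to_networkx(self) -> nx.Graph:
        """Weighted undirected graph; node attribute ``s`` is the frequency."""
        g = nx.Graph()
        for tag in self.nodes:
            g.add_node(tag, s=self.tag_frequencies[tag])
        for (a, b), (c, w) in sorted(self.edges.items()):
            g.add_edge(a, b, c=c, weight=w)
        return g


@dataclass
class SnapshotSeries:
    """Gap-free, month-indexed sequence of snapshots (empty months included)."""

    snapshots: list[TemporalSnapshot]

    def __post_init__(self) -> None:
        months = [s.month for s in self.snapshots]
        if months and months != month_range(months[0], months[-1]):
            raise ValueError("snapshots must cover consecutive months")
        for i, snap in enumerate(self.snapshots):
            if snap.t != i:
                raise ValueError("snapshot indices must be 0-based and consecutive")

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self) -> Iterator[TemporalSnapshot]:
        return iter(self.snapshots)

    def __getitem__(self, t: int) -> TemporalSnapshot:
        return self.snapshots[t]

    @property
    def months(self) -> list[str]:
        return [s.month for s in self.snapshots]

    def by_month(self, month: str) -> TemporalSnapshot:
        for snap in self.snapshots:
            if snap.month == month:
                return snap
        raise KeyError(month)


def _month_tuple(month: str) -> tuple[int, int]:
    year, mon = month.split("-")
    y, m = int(year), int(mon)
    if not 1 <= m <= 12:
        raise ValueError(f"bad month label {month!r}")
    return y, m


def month_range(start: str, end: str) -> list[str]:
    """Inclusive list of YYYY-MM labels from start to end."""
    y0, m0 = _month_tuple(start)
    y1, m1 = _month_tuple(end)
    if (y0, m0) > (y1, m1):
        raise ValueError(f"start {start!r} after end {end!r}")
    out = []
    y, m = y0, m0
    while (y, m) <= (y1, m1):
        out.append(f"{y:04d}-{m:02d}")
        m += 1
        if m > 12:
            y, m = y + 1, 1
    return out


def slice_by_month(
    corpus: Corpus, start: str, end: str
) -> tuple[dict[str, list[PaperRecord]], int]:
    """Bucket records by calendar month over the inclusive [start, end] window.

    Every month in the window is present as a key, possibly with an empty
    list. Returns the buckets and the count of records outside the window.
    """
    months = month_range(start, end)
    buckets: dict[str, list[PaperRecord]] = {m: [] for m in months}
    excluded = 0
    for rec in corpus.records:
        if rec.month in buckets:
            buckets[rec.month].append(rec)
        else:
            excluded += 1
    return buckets, excluded


def snapshot_from_papers(t: int, month: str, papers: Sequence[PaperRecord]) -> TemporalSnapshot:
    freqs, pair_counts = count_cooccurrences(papers)
    edges = {
        pair: (c, association_strength(c, freqs[pair[0]], freqs[pair[1]]))
        for pair, c in sorted(pair_counts.items())
    }
    return TemporalSnapshot(t=t, month=month, tag_frequencies=freqs, edges=edges)


def build_taggraph(
    corpus: Corpus,
    tag_map=None,
    start: str | None = None,
    end: str | None = None,
) -> SnapshotSeries:
    """Normalize (optionally), slice by month and build all snapshots.

    ``start``/``end`` default to the corpus's own span. When a ``TagMap`` is
    given the corpus is canonicalized first (see ``taggraph.normalize``).
    """
    if tag_map is not None:
        from .normalize import apply_tag_map

        corpus = apply_tag_map(corpus, tag_map)
    span = corpus.date_span
    if span is None:
        raise ValueError("empty corpus")
    start = start or f"{span[0].year:04d}-{span[0].month:02d}"
    end = end or f"{span[1].year:04d}-{span[1].month:02d}"
    buckets, _ = slice_by_month(corpus, start, end)
    snapshots = [
        snapshot_from_papers(t, month, papers)
        for t, (month, papers) in enumerate(buckets.items())
    ]
    return SnapshotSeries(snapshots)
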