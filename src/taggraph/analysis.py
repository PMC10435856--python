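"""Role interpretation and temporal queries over a fitted role model.

Three families of questions:

* what a role *means* — Pearson correlation of each role's relevance column
  against classic per-snapshot centrality measures (PageRank, betweenness,
  closeness, degree, local clustering), over all node-snapshot rows;
* how a tag *evolves* — its role-mixture trajectory month by month, and the
  dominant role per month;
* what surrounds a tag — neighbors ranked by
  ``node_relevance = edge association strength x neighbor's role relevance``,
  top-k per snapshot, with cross-snapshot frequency counts and a transition
  rule that flags tags consistently seen in one role that also surface in
  another (e.g. peripheral terms that migrate toward the core).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .cooccurrence import SnapshotSeries
from .rolx import MissingRowError, RoleModel

logger = logging.getLogger(__name__)

__all__ = [
    "MEASURES",
    "RelevanceRanking",
    "centrality_measures",
    "role_measure_correlations",
    "node_relevance",
    "top_k_neighbors",
    "neighbor_frequency",
    "dominant_role",
    "role_transition_tags",
    "role_trajectory",
    "plot_role_trajectory",
]

MEASURES = (
    "pagerank",
    "betweenness_centrality",
    "closeness_centrality",
    "degree",
    "local_clustering_coefficient",
)

DEFAULT_K = 20
DEFAULT_MIN_FREQ = 2


def centrality_measures(series: SnapshotSeries) -> pd.DataFrame:
    """Five classic measures for every node in every snapshot.

    PageRank uses damping 0.85 on the weighted graph. Betweenness and
    closeness use unweighted shortest paths: association-strength weights are
    similarities, not distances, so no distance transform is applied.
    Closeness is the within-component form (reachable-1)/sum(distances);
    isolates score 0 on everything but their PageRank share.
    """
    blocks = []
    for snap in series:
        nodes = snap.nodes
        if not nodes:
            continue
        g = snap.to_networkx()
        pagerank = nx.pagerank(g, alpha=0.85, weight="weight", tol=1e-12, max_iter=1000)
        betweenness = nx.betweenness_centrality(g, normalized=True, weight=None)
        closeness = nx.closeness_centrality(g, wf_improved=False)
        clustering = nx.clustering(g, weight=None)
        block = pd.DataFrame(
            {
                "pagerank": [pagerank[v] for v in nodes],
                "betweenness_centrality": [betweenness[v] for v in nodes],
                "closeness_centrality": [closeness[v] for v in nodes],
                "degree": [float(g.degree(v)) for v in nodes],
                "local_clustering_coefficient": [clustering[v] for v in nodes],
            },
            index=pd.Index(nodes, name="tag"),
        )
        block["month"] = snap.month
        blocks.append(block.reset_index())
    if not blocks:
        return pd.DataFrame(columns=["tag", "month", *MEASURES]).set_index(["month", "tag"])
    out = pd.concat(blocks, ignore_index=True).set_index(["month", "tag"]).sort_index()
    return out[list(MEASURES)]


def role_measure_correlations(model: RoleModel, centrality: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each role's raw relevance with each measure.

    Rows must align exactly with the model's (month, tag) index. A constant
    column (no variance on either side) yields an undefined correlation,
    reported as NaN — deliberately distinct from 0 — and logged.
    """
    if not centrality.index.equals(model.rows):
        centrality = centrality.reindex(model.rows)
        if centrality.isna().any().any():
            raise ValueError("centrality rows do not align with the role model")
    out = pd.DataFrame(
        index=pd.Index(range(model.r), name="role"), columns=list(MEASURES), dtype=float
    )
    for role in range(model.r):
        w = model.W[:, role]
        for measure in MEASURES:
            m = centrality[measure].to_numpy(dtype=float)
            if w.min() == w.max() or m.min() == m.max():
                out.loc[role, measure] = np.nan
                logger.info("correlation undefined for role %d vs %s (constant)", role, measure)
            else:
                out.loc[role, measure] = float(np.corrcoef(w, m)[0, 1])
    return out


def node_relevance(
    series: SnapshotSeries,
    model: RoleModel,
    start_tag: str,
    end_tag: str,
    role: int,
    t: int,
) -> float:
    """Relevance of a neighbor: edge weight times the neighbor's role relevance.

    ``end_tag`` must be a direct neighbor of ``start_tag`` in snapshot ``t``;
    for non-neighbors the quantity is undefined and a ValueError is raised
    rather than returning 0.
    """
    snap = series[t]
    if start_tag not in snap.tag_frequencies:
        raise MissingRowError(f"start tag {start_tag!r} absent in {snap.month}")
    if end_tag not in snap.neighbors(start_tag):
        raise ValueError(f"{end_tag!r} is not a neighbor of {start_tag!r} in {snap.month}")
    weight = snap.weight(start_tag, end_tag)
    return weight * model.role_relevance(end_tag, role, snap.month)


@dataclass
class RelevanceRanking:
    """Descending neighbor ranking for one (start tag, role, snapshot)."""

    start_tag: str
    role: int
    t: int
    month: str
    ranked: list[tuple[str, float]]

    def tags(self) -> list[str]:
        return [tag for tag, _ in self.ranked]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_tag": self.start_tag,
                "role": self.role,
                "month": self.month,
                "rank": range(1, len(self.ranked) + 1),
                "neighbor": [t for t, _ in self.ranked],
                "relevance": [v for _, v in self.ranked],
            }
        )


def top_k_neighbors(
    series: SnapshotSeries,
    model: RoleModel,
    start_tag: str,
    role: int,
    t: int,
    k: int = DEFAULT_K,
) -> RelevanceRanking:
    """Rank all direct neighbors of a tag by node relevance, truncated at k.

    Descending by relevance; ties break lexicographically by neighbor name,
    so rankings are deterministic.
    """
    snap = series[t]
    if start_tag not in snap.tag_frequencies:
        raise MissingRowError(f"start tag {start_tag!r} absent in {snap.month}")
    scored = [
        (n, node_relevance(series, model, start_tag, n, role, t))
        for n in snap.neighbors(start_tag)
    ]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return RelevanceRanking(start_tag, role, t, snap.month, scored[:k])


def neighbor_frequency(
    series: SnapshotSeries,
    model: RoleModel,
    start_tag: str,
    role: int,
    k: int = DEFAULT_K,
) -> dict[str, int]:
    """How many snapshots each tag spends in the start tag's top-k ranking.

    Months where the start tag is absent contribute nothing. The result maps
    tag -> count; iterate ``sorted(out.items(), key=lambda kv: (-kv[1], kv[0]))``
    for the frequency-table ordering.
    """
    counts: dict[str, int] = {}
    for t in range(len(series)):
        if start_tag not in series[t].tag_frequencies:
            continue
        for tag in top_k_neighbors(series, model, start_tag, role, t, k).tags():
            counts[tag] = counts.get(tag, 0) + 1
    return counts


def dominant_role(model: RoleModel, tag: str, month: str) -> int | None:
    """Argmax of the role mixture; ties take the lowest role index.

    Returns None (an explicit no-role marker) for an all-zero row.
    """
    mix = model.mixture(tag, month)
    if mix.sum() == 0:
        return None
    return int(np.argmax(mix))


def role_transition_tags(
    series: SnapshotSeries,
    model: RoleModel,
    start_tag: str,
    from_role: int,
    to_roles: list[int],
    min_freq: int = DEFAULT_MIN_FREQ,
    k: int = DEFAULT_K,
) -> list[tuple[str, int]]:
    """Tags consistently ranked in one role that also surface in another.

    A tag qualifies when its top-k ranking frequency for ``from_role``
    strictly exceeds ``min_freq`` and it appears at least once in the
    ranking of some role in ``to_roles``. Sorted by from-role frequency
    descending, then name. Returns (tag, from_role_frequency) pairs.
    """
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    from_freq = neighbor_frequency(series, model, start_tag, from_role, k)
    to_freqs = [neighbor_frequency(series, model, start_tag, r, k) for r in to_roles]
    out = [
        (tag, freq)
        for tag, freq in from_freq.items()
        if freq > min_freq and any(f.get(tag, 0) >= 1 for f in to_freqs)
    ]
    out.sort(key=lambda item: (-item[1], item[0]))
    return out


def role_trajectory(model: RoleModel, tag: str) -> pd.DataFrame:
    """Month-by-month role mixture of one tag, NaN rows where absent.

    Rows cover every month of the model's series (including months with no
    papers); columns role_0..role_{r-1}. Raises MissingRowError for a tag
    never seen in any snapshot.
    """
    cols = [f"role_{k}" for k in range(model.r)]
    out = pd.DataFrame(np.nan, index=pd.Index(model.months, name="month"), columns=cols)
    seen = False
    for month in model.months:
        try:
            out.loc[month] = model.mixture(tag, month)
            seen = True
        except MissingRowError:
            continue
    if not seen:
        raise MissingRowError(f"tag {tag!r} never appears in the series")
    return out


def plot_role_trajectory(trajectory: pd.DataFrame, path, title: str | None = None) -> None:
    """Stacked-bar chart of a tag's role mixture per month.

    ``trajectory`` is the frame returned by :func:`role_trajectory`; months
    where the tag is absent are left blank. Writes the figure to ``path``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    months = list(trajectory.index)
    fig, ax = plt.subplots(figsize=(max(6, len(months) * 0.4), 3.5))
    bottom = np.zeros(len(months))
    for col in trajectory.columns:
        vals = trajectory[col].fillna(0.0).to_numpy()
        ax.bar(range(len(months)), vals, bottom=bottom, label=col)
        bottom += vals
    ax.set_xticks(range(len(months)))
    ax.set_xticklabels(months, rotation=90, fontsize=7)
    ax.set_ylabel("role mixture")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, ncol=min(len(trajectory.columns), 5))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
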