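"""Writers and readers for snapshots, feature tensors, role models and tables.

All artifacts are plain text (GraphML, CSV, JSON). Numeric round-trips are
lossless: floats are serialized with Python's shortest repr, which parses
back to the identical double, so a written graph re-reads exactly.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .analysis import RelevanceRanking
from .cooccurrence import SnapshotSeries, TemporalSnapshot, month_range
from .refex import FeatureSpec, FeatureTensor
from .rolx import RoleModel

__all__ = [
    "write_snapshot_graph",
    "read_snapshot_graph",
    "write_series_edges",
    "read_series_edges",
    "write_correlations",
    "write_rankings",
    "write_frequency",
    "write_features",
    "read_features",
    "write_role_model",
    "read_role_model",
]

GRAPH_FORMATS = ("graphml", "edge_csv")

_EDGE_HEADER = ["month", "tag_i", "tag_j", "c_ij", "s_i", "s_j", "weight"]


def write_snapshot_graph(snapshot: TemporalSnapshot, path: str | Path, format: str = "graphml") -> None:
    """Write one snapshot as GraphML or an edge CSV.

    GraphML carries node labels and frequencies plus edge counts and
    weights. The edge CSV lists one row per edge; isolated nodes are kept as
    rows with an empty ``tag_j`` so the node set survives the round trip.
    """
    path = Path(path)
    if format == "graphml":
        g = snapshot.to_networkx()
        for v in g.nodes:
            g.nodes[v]["label"] = v
        g.graph["month"] = snapshot.month
        g.graph["t"] = snapshot.t
        nx.write_graphml(g, path)
    elif format == "edge_csv":
        with path.open("w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(_EDGE_HEADER)
            writer.writerows(_edge_rows(snapshot))
    else:
        raise ValueError(f"unknown graph format {format!r}; expected one of {GRAPH_FORMATS}")


def _edge_rows(snapshot: TemporalSnapshot) -> Iterable[list]:
    linked: set[str] = set()
    for (a, b), (c, w) in sorted(snapshot.edges.items()):
        linked.update((a, b))
        yield [snapshot.month, a, b, c,
               snapshot.tag_frequencies[a], snapshot.tag_frequencies[b], repr(w)]
    for tag in snapshot.nodes:
        if tag not in linked:
            yield [snapshot.month, tag, "", 0, snapshot.tag_frequencies[tag], 0, repr(0.0)]


def read_snapshot_graph(path: str | Path, format: str = "graphml") -> TemporalSnapshot:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        freqs = {str(g.nodes[v]["label"]): int(g.nodes[v]["s"]) for v in g.nodes}
        edges = {}
        for u, v, data in g.edges(data=True):
            a, b = sorted((str(g.nodes[u]["label"]), str(g.nodes[v]["label"])))
            edges[(a, b)] = (int(data["c"]), float(data["weight"]))
        return TemporalSnapshot(
            t=int(g.graph.get("t", 0)),
            month=str(g.graph.get("month", "")),
            tag_frequencies=freqs,
            edges=edges,
        )
    if format == "edge_csv":
        snapshots = _snapshots_from_rows(_read_edge_rows(path), t0=0)
        if len(snapshots) != 1:
            raise ValueError(f"expected a single month in {path}, found {len(snapshots)}")
        return snapshots[0]
    raise ValueError(f"unknown graph format {format!r}; expected one of {GRAPH_FORMATS}")


def _read_edge_rows(path: Path) -> list[dict]:
    with path.open("r", newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames != _EDGE_HEADER:
            raise ValueError(f"unexpected edge CSV header in {path}: {reader.fieldnames}")
        return list(reader)


def _snapshots_from_rows(rows: Sequence[Mapping[str, str]], t0: int = 0) -> list[TemporalSnapshot]:
    by_month: dict[str, tuple[dict, dict]] = {}
    for row in rows:
        freqs, edges = by_month.setdefault(row["month"], ({}, {}))
        a = row["tag_i"]
        freqs[a] = int(row["s_i"])
        if row["tag_j"]:
            b = row["tag_j"]
            freqs[b] = int(row["s_j"])
            key = (a, b) if a <= b else (b, a)
            edges[key] = (int(row["c_ij"]), float(row["weight"]))
    return [
        TemporalSnapshot(t=t0 + i, month=month, tag_frequencies=freqs, edges=edges)
        for i, (month, (freqs, edges)) in enumerate(sorted(by_month.items()))
    ]


def write_series_edges(series: SnapshotSeries, path: str | Path) -> None:
    """All snapshots of a series in one edge CSV (empty months yield no rows)."""
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_EDGE_HEADER)
        for snap in series:
            writer.writerows(_edge_rows(snap))


def read_series_edges(path: str | Path, start: str, end: str) -> SnapshotSeries:
    """Rebuild a series from an edge CSV; the window restores empty months."""
    months = month_range(start, end)
    by_month = {s.month: s for s in _snapshots_from_rows(_read_edge_rows(Path(path)))}
    snapshots = []
    for t, month in enumerate(months):
        snap = by_month.get(month, TemporalSnapshot(t=t, month=month))
        snap.t = t
        snapshots.append(snap)
    return SnapshotSeries(snapshots)


def write_correlations(correlations: pd.DataFrame, path: str | Path) -> None:
    """Long-format CSV: one row per (role, measure); NaN marks undefined."""
    long = correlations.reset_index().melt(
        id_vars="role", var_name="measure", value_name="correlation"
    )
    long = long.sort_values(["role", "measure"], kind="mergesort").reset_index(drop=True)
    long.to_csv(path, index=False)


def write_rankings(rankings: Sequence[RelevanceRanking], path: str | Path) -> None:
    """One row per (start_tag, role, month, rank, neighbor, relevance)."""
    frames = [r.to_frame() for r in rankings]
    cols = ["start_tag", "role", "month", "rank", "neighbor", "relevance"]
    if frames:
        out = pd.concat(frames, ignore_index=True)
        out = out.sort_values(["start_tag", "role", "month", "rank"], kind="mergesort")
    else:
        out = pd.DataFrame(columns=cols)
    out[cols].to_csv(path, index=False)


def write_frequency(counts: Mapping[str, int], path: str | Path, start_tag: str, role: int) -> None:
    """Frequency table sorted by count descending, then tag."""
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["start_tag", "role", "tag", "snapshot_count"])
        for tag, count in rows:
            writer.writerow([start_tag, role, tag, count])


_SPEC_RE = re.compile(r"^([a-z_]+)((?:\((?:sum|mean)\))*)$")


def _parse_spec(name: str) -> FeatureSpec:
    m = _SPEC_RE.match(name)
    if not m:
        raise ValueError(f"unparseable feature name {name!r}")
    path = tuple(re.findall(r"\((sum|mean)\)", m.group(2)))
    return FeatureSpec(m.group(1), path)


def write_features(tensor: FeatureTensor, path: str | Path) -> None:
    """Feature CSV (tag, month, one column per feature) plus a meta JSON."""
    path = Path(path)
    tensor.to_frame().to_csv(path, index=False)
    meta = {"months": tensor.months, "normalized": tensor.normalized}
    path.with_suffix(".meta.json").write_text(json.dumps(meta, sort_keys=True))


def read_features(path: str | Path) -> FeatureTensor:
    path = Path(path)
    frame = pd.read_csv(path, dtype={"tag": str, "month": str})
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    feature_cols = [c for c in frame.columns if c not in ("tag", "month")]
    values = frame.set_index(["month", "tag"]).sort_index()[feature_cols]
    return FeatureTensor(
        values=values,
        specs=[_parse_spec(c) for c in feature_cols],
        months=list(meta["months"]),
        normalized=bool(meta["normalized"]),
    )


def write_role_model(model: RoleModel, w_path: str | Path, h_path: str | Path) -> None:
    """W as (tag, month, role_*) CSV, H as (role, feature) CSV, plus meta."""
    model.w_frame().to_csv(w_path, index=False)
    model.h_frame().to_csv(h_path, index=False)
    meta = {
        "r": model.r,
        "fit_error": model.fit_error,
        "seed": model.seed,
        "restarts": model.restarts,
        "months": model.months,
    }
    Path(w_path).with_suffix(".meta.json").write_text(json.dumps(meta, sort_keys=True))


def read_role_model(w_path: str | Path, h_path: str | Path) -> RoleModel:
    meta = json.loads(Path(w_path).with_suffix(".meta.json").read_text())
    r = int(meta["r"])
    cols = [f"role_{k}" for k in range(r)]
    w_frame = pd.read_csv(w_path, dtype={"tag": str, "month": str}).set_index(["month", "tag"]).sort_index()
    h_frame = pd.read_csv(h_path)
    return RoleModel(
        r=r,
        W=w_frame[cols].to_numpy(),
        H=h_frame.drop(columns="role").to_numpy(),
        rows=w_frame.index,
        feature_names=[c for c in h_frame.columns if c != "role"],
        months=list(meta["months"]),
        fit_error=float(meta["fit_error"]),
        seed=int(meta["seed"]),
        restarts=int(meta["restarts"]),
    )
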