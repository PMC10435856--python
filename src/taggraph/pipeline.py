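"""End-to-end orchestration: ingest -> normalize -> graph -> features ->
roles -> interpret -> report.

Every stage reads its input from the previous stage's serialized artifact in
the output directory and writes its own, so any stage can be rerun in
isolation. All outputs are deterministic functions of (input, config, seed);
rerunning with the same config reproduces them byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import analysis as ana
from . import io as tio
from .config import PipelineConfig
from .cooccurrence import SnapshotSeries, build_taggraph
from .corpus import Corpus, read_corpus, write_corpus_jsonl
from .normalize import TrigramEmbedder, normalize_corpus
from .refex import compute_features
from .rolx import factorize, select_num_roles

logger = logging.getLogger(__name__)

__all__ = [
    "run_pipeline",
    "stage_ingest",
    "stage_normalize",
    "stage_build_graph",
    "stage_features",
    "stage_roles",
    "stage_interpret",
    "stage_report",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_ingest(config: PipelineConfig) -> Corpus:
    out = _outdir(config)
    corpus = read_corpus(config.input, config.dialect, config.keywords_column)
    write_corpus_jsonl(corpus, out / "corpus.jsonl")
    logger.info("[ingest] %d records, %d skipped", len(corpus), corpus.skipped_count)
    return corpus


def stage_normalize(config: PipelineConfig) -> Corpus:
    out = _outdir(config)
    corpus = read_corpus(out / "corpus.jsonl", "jsonl")
    provider = TrigramEmbedder(dim=config.embedding_dim, hash_seed=config.embedding_hash_seed)
    normalized, tag_map = normalize_corpus(
        corpus, provider, eps=config.dbscan_eps, min_samples=config.dbscan_min_samples
    )
    write_corpus_jsonl(normalized, out / "corpus_normalized.jsonl")
    rows = sorted(tag_map.assignment.items())
    with (out / "tagmap.csv").open("w") as handle:
        handle.write("surface_tag,cluster_id,canonical_label,member_count\n")
        for tag, cid in rows:
            handle.write(f"{tag},{cid},{tag_map.labels[cid]},{tag_map.member_counts[cid]}\n")
    logger.info("[normalize] %d surface tags -> %d clusters", len(rows), len(tag_map.labels))
    return normalized


def _window(config: PipelineConfig, corpus: Corpus) -> tuple[str, str]:
    if config.window_start is not None:
        return config.window_start, config.window_end
    span = corpus.date_span
    if span is None:
        raise StageError("build-graph: empty corpus")
    return (f"{span[0].year:04d}-{span[0].month:02d}", f"{span[1].year:04d}-{span[1].month:02d}")


def stage_build_graph(config: PipelineConfig) -> SnapshotSeries:
    out = _outdir(config)
    corpus = read_corpus(out / "corpus_normalized.jsonl", "jsonl")
    start, end = _window(config, corpus)
    series = build_taggraph(corpus, None, start, end)
    snapdir = out / "snapshots"
    snapdir.mkdir(exist_ok=True)
    for snap in series:
        tio.write_snapshot_graph(snap, snapdir / f"{snap.month}.csv", "edge_csv")
    (out / "window.json").write_text(json.dumps({"start": start, "end": end}))
    n_nodes = sum(s.n_nodes for s in series)
    n_edges = sum(s.n_edges for s in series)
    logger.info("[build-graph] %d snapshots, %d node-months, %d edges", len(series), n_nodes, n_edges)
    return series


def _load_series(out: Path) -> SnapshotSeries:
    from .cooccurrence import TemporalSnapshot, month_range

    window = json.loads((out / "window.json").read_text())
    snapshots = []
    for t, month in enumerate(month_range(window["start"], window["end"])):
        path = out / "snapshots" / f"{month}.csv"
        snap = TemporalSnapshot(t=t, month=month)
        if path.exists():
            loaded = tio._snapshots_from_rows(tio._read_edge_rows(path), t0=t)
            if loaded:
                snap = loaded[0]
                snap.t = t
        snapshots.append(snap)
    return SnapshotSeries(snapshots)


def stage_features(config: PipelineConfig):
    out = _outdir(config)
    series = _load_series(out)
    tensor = compute_features(series, depth=config.refex_depth,
                              prune_threshold=config.refex_prune_threshold)
    tio.write_features(tensor, out / "features.csv")
    logger.info("[features] %d rows x %d features", tensor.n_rows, len(tensor.specs))
    return tensor


def stage_roles(config: PipelineConfig):
    out = _outdir(config)
    tensor = tio.read_features(out / "features.csv")
    if config.rolx_r is not None:
        r = config.rolx_r
        selection = []
    else:
        r, selection = select_num_roles(
            tensor, config.rolx_r_min, config.rolx_r_max,
            seed=config.seed, restarts=config.rolx_restarts, return_scores=True,
        )
    model = factorize(tensor, r, seed=config.seed, restarts=config.rolx_restarts)
    tio.write_role_model(model, out / "roles_W.csv", out / "roles_H.csv")
    with (out / "role_selection.csv").open("w") as handle:
        handle.write("r,fit_error,mdl_bits\n")
        for row in selection:
            handle.write(f"{row[0]},{row[1]!r},{row[2]!r}\n")
    logger.info("[roles] r=%d fit_error=%.6g", model.r, model.fit_error)
    return model


def _start_tags(config: PipelineConfig, series: SnapshotSeries) -> list[str]:
    if config.analysis_start_tags:
        return list(config.analysis_start_tags)
    totals: dict[str, int] = {}
    for snap in series:
        for tag, s in snap.tag_frequencies.items():
            totals[tag] = totals.get(tag, 0) + s
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return [tag for tag, _ in ranked[:3]]


def stage_interpret(config: PipelineConfig) -> None:
    out = _outdir(config)
    series = _load_series(out)
    model = tio.read_role_model(out / "roles_W.csv", out / "roles_H.csv")
    centrality = ana.centrality_measures(series)
    correlations = ana.role_measure_correlations(model, centrality)
    tio.write_correlations(correlations, out / "correlations.csv")
    start_tags = _start_tags(config, series)
    rankings = []
    freq_rows = []
    for tag in start_tags:
        for role in range(model.r):
            for t in range(len(series)):
                if tag in series[t].tag_frequencies:
                    rankings.append(
                        ana.top_k_neighbors(series, model, tag, role, t, config.analysis_k)
                    )
            counts = ana.neighbor_frequency(series, model, tag, role, config.analysis_k)
            for neighbor, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
                freq_rows.append((tag, role, neighbor, count))
    tio.write_rankings(rankings, out / "rankings.csv")
    with (out / "frequencies.csv").open("w") as handle:
        handle.write("start_tag,role,tag,snapshot_count\n")
        for row in freq_rows:
            handle.write(",".join(str(x) for x in row) + "\n")
    if config.analysis_from_role is not None and config.analysis_to_roles:
        with (out / "transitions.csv").open("w") as handle:
            handle.write("start_tag,tag,from_role_frequency\n")
            for tag in start_tags:
                hits = ana.role_transition_tags(
                    series, model, tag,
                    config.analysis_from_role, config.analysis_to_roles,
                    config.analysis_min_freq, config.analysis_k,
                )
                for hit, freq in hits:
                    handle.write(f"{tag},{hit},{freq}\n")
    logger.info("[interpret] %d rankings for start tags %s", len(rankings), start_tags)


def stage_report(config: PipelineConfig) -> dict:
    out = _outdir(config)
    series = _load_series(out)
    model = tio.read_role_model(out / "roles_W.csv", out / "roles_H.csv")
    summary = {
        "months": len(series),
        "node_months": sum(s.n_nodes for s in series),
        "edges": sum(s.n_edges for s in series),
        "features": len(model.feature_names),
        "roles": model.r,
        "fit_error": model.fit_error,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    logger.info("[report] %s", summary)
    return summary


_STAGES = [
    ("ingest", stage_ingest),
    ("normalize", stage_normalize),
    ("build-graph", stage_build_graph),
    ("features", stage_features),
    ("roles", stage_roles),
    ("interpret", stage_interpret),
    ("report", stage_report),
]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order; returns the output directory.

    The validated config is copied next to the outputs. A stage failure
    aborts the run with the stage name attached.
    """
    config.validate()
    out = _outdir(config)
    config.to_yaml(out / "config_used.yaml")
    for name, stage in _STAGES:
        try:
            stage(config)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
    return out
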