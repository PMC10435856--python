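"""Merge surface variants of author keywords into canonical tag clusters.

Authors spell the same concept many ways (typos, case, acronym mixing), which
fragments the co-occurrence graph. The fix is density clustering in an
embedding space: every distinct surface tag is embedded as a unit vector, a
DBSCAN pass in cosine distance groups near-duplicates, and each cluster is
labelled by its most frequent member. The downstream graph is built at the
cluster level, so a "tag" thereafter means a cluster of surface forms.

The built-in embedder is a deterministic character-trigram bag hashed into a
fixed-dimension space — no model download, fully reproducible. Any sentence
embedder (e.g. a transformer) can be plugged in behind the same callable
contract; it receives a list of strings and must return unit-norm rows.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .corpus import Corpus, PaperRecord, normalize_tag_text

logger = logging.getLogger(__name__)

__all__ = [
    "TagEmbedding",
    "TagMap",
    "TrigramEmbedder",
    "preprocess_tag",
    "embed_tags",
    "cluster_tags",
    "build_tag_map",
    "apply_tag_map",
    "normalize_corpus",
    "partition_precision_recall",
]

DEFAULT_EPS = 0.35
DEFAULT_MIN_SAMPLES = 2
DEFAULT_DIM = 1024


class EmbeddingError(RuntimeError):
    """The embedding provider failed on a batch of tags."""


def preprocess_tag(tag: str) -> str:
    """Trim, collapse whitespace, NFC-normalize and case-fold a surface tag."""
    return normalize_tag_text(tag).casefold()


@dataclass(frozen=True)
class TagEmbedding:
    tag: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.vector))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"embedding for {self.tag!r} not unit norm ({norm})")


class TrigramEmbedder:
    """Character-trigram term-frequency embedding, hashed and L2-normalized.

    Tags are padded with boundary markers so that edits near the ends of the
    string also perturb three trigrams, like interior edits. The hash is a
    keyed blake2b digest, so vectors are identical across processes and runs.
    """

    def __init__(self, dim: int = DEFAULT_DIM, hash_seed: int = 0) -> None:
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = dim
        self._key = hash_seed.to_bytes(8, "little")

    def _bucket(self, trigram: str) -> int:
        digest = hashlib.blake2b(trigram.encode("utf-8"), digest_size=8, key=self._key)
        return int.from_bytes(digest.digest(), "little") % self.dim

    def __call__(self, tags: Sequence[str]) -> np.ndarray:
        vectors = np.zeros((len(tags), self.dim))
        for i, tag in enumerate(tags):
            padded = f"\x02\x02{tag}\x03\x03"
            for j in range(len(padded) - 2):
                vectors[i, self._bucket(padded[j : j + 2 + 1])] += 1.0
        norms = np.linalg.norm(vectors, axis=1, keepdims=True)
        if np.any(norms == 0):
            empty = [tags[i] for i in np.flatnonzero(norms[:, 0] == 0)]
            raise EmbeddingError(f"zero embedding for tags {empty!r}")
        return vectors / norms


def embed_tags(
    tags: Sequence[str],
    provider: Callable[[Sequence[str]], np.ndarray] | None = None,
) -> list[TagEmbedding]:
    """Embed deduplicated tags as unit vectors.

    ``provider`` maps a list of strings to an array of unit-norm rows;
    defaults to the built-in :class:`TrigramEmbedder`.
    """
    if not tags:
        return []
    if len(set(tags)) != len(tags):
        raise ValueError("tags must be deduplicated before embedding")
    if any(not t for t in tags):
        raise ValueError("tags must be non-empty")
    provider = provider or TrigramEmbedder()
    try:
        matrix = np.asarray(provider(tags), dtype=float)
    except EmbeddingError:
        raise
    except Exception as exc:  # noqa: BLE001 - provider contract violation
        raise EmbeddingError(f"provider failed on batch of {len(tags)} tags") from exc
    if matrix.shape != (len(tags), matrix.shape[1]):
        raise EmbeddingError("provider returned a misshapen matrix")
    return [TagEmbedding(tag, matrix[i]) for i, tag in enumerate(tags)]


def cluster_tags(
    embeddings: Sequence[TagEmbedding],
    eps: float = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> dict[str, int]:
    """Density-cluster tag embeddings in cosine distance.

    A tag is a core point when at least ``min_samples`` tags (itself
    included) lie within ``eps``; clusters are maximal density-connected
    sets; unreachable tags are noise and become singleton clusters rather
    than being dropped, so rare misfit tags survive into the graph.

    The partition is invariant under input permutation: tags are sorted
    before clustering, which pins down border-point assignment.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if not embeddings:
        return {}
    ordered = sorted(embeddings, key=lambda e: e.tag)
    matrix = np.stack([e.vector for e in ordered])
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric="cosine").fit_predict(matrix)
    assignment: dict[str, int] = {}
    next_id = int(labels.max()) + 1 if len(labels) else 0
    for emb, label in zip(ordered, labels):
        if label == -1:
            assignment[emb.tag] = next_id
            next_id += 1
        else:
            assignment[emb.tag] = int(label)
    return assignment


@dataclass
class TagMap:
    """Total map from surface tag to cluster, with canonical labels.

    ``assignment`` covers every corpus tag (preprocessed form); each
    cluster's label is its highest-frequency member (ties broken
    lexicographically), so applying the map twice equals applying it once.
    """

    assignment: dict[str, int]
    labels: dict[int, str]
    member_counts: dict[int, int] = field(default_factory=dict)

    def canonical(self, tag: str) -> str:
        return self.labels[self.assignment[preprocess_tag(tag)]]

    def validate(self) -> None:
        for cluster_id, label in self.labels.items():
            if self.assignment.get(label) != cluster_id:
                raise ValueError(f"label {label!r} does not map to its own cluster")


def build_tag_map(
    corpus: Corpus,
    clustering: Mapping[str, int],
    tag_frequencies: Mapping[str, int] | None = None,
) -> TagMap:
    """Label each cluster by its most frequent member tag.

    ``tag_frequencies`` counts papers per preprocessed tag; recomputed from
    the corpus when omitted. Every corpus tag (after preprocessing) must be
    covered by ``clustering``.
    """
    if tag_frequencies is None:
        tag_frequencies = {}
        for rec in corpus.records:
            for tag in {preprocess_tag(t) for t in rec.raw_tags}:
                tag_frequencies[tag] = tag_frequencies.get(tag, 0) + 1
    uncovered = sorted(set(tag_frequencies) - set(clustering))
    if uncovered:
        raise ValueError(f"clustering does not cover corpus tags: {uncovered[:5]!r}")
    members: dict[int, list[str]] = {}
    for tag, cluster_id in clustering.items():
        members.setdefault(cluster_id, []).append(tag)
    labels: dict[int, str] = {}
    counts: dict[int, int] = {}
    for cluster_id, tags in members.items():
        tags.sort()
        best = min(tags, key=lambda t: (-tag_frequencies.get(t, 0), t))
        labels[cluster_id] = best
        counts[cluster_id] = sum(tag_frequencies.get(t, 0) for t in tags)
    tag_map = TagMap(assignment=dict(clustering), labels=labels, member_counts=counts)
    tag_map.validate()
    return tag_map


def apply_tag_map(corpus: Corpus, tag_map: TagMap) -> Corpus:
    """Replace every record's tags by canonical labels, deduplicated per paper.

    Idempotent: canonical labels map to themselves.
    """
    records = []
    for rec in corpus.records:
        canon = sorted({tag_map.canonical(t) for t in rec.raw_tags})
        records.append(PaperRecord(rec.paper_id, rec.publication_date, tuple(canon)))
    return Corpus(records, skipped_count=corpus.skipped_count)


def normalize_corpus(
    corpus: Corpus,
    provider: Callable[[Sequence[str]], np.ndarray] | None = None,
    eps: float = DEFAULT_EPS,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> tuple[Corpus, TagMap]:
    """End-to-end normalization: embed, cluster, label, apply."""
    surface = sorted({preprocess_tag(t) for rec in corpus.records for t in rec.raw_tags})
    embeddings = embed_tags(surface, provider)
    clustering = cluster_tags(embeddings, eps=eps, min_samples=min_samples)
    tag_map = build_tag_map(corpus, clustering)
    merged = sum(1 for t in surface if tag_map.canonical(t) != t)
    logger.info(
        "normalized %d surface tags into %d clusters (%d merged away)",
        len(surface), len(tag_map.labels), merged,
    )
    return apply_tag_map(corpus, tag_map), tag_map


def partition_precision_recall(
    predicted: Mapping[str, object], truth: Mapping[str, object]
) -> tuple[float, float]:
    """Pairwise precision/recall of a predicted partition against ground truth.

    Both maps send an item to a group key; only items present in both are
    scored. Precision: fraction of predicted same-group pairs that are truly
    together; recall: fraction of true same-group pairs recovered. Perfect
    partitions score (1.0, 1.0); with no same-group pairs on either side the
    undefined ratio is reported as 1.0.
    """
    items = sorted(set(predicted) & set(truth))
    tp = fp = fn = 0
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            same_pred = predicted[a] == predicted[b]
            same_true = truth[a] == truth[b]
            tp += same_pred and same_true
            fp += same_pred and not same_true
            fn += same_true and not same_pred
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return precision, recall
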