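"""Synthetic dated corpora with planted structural ground truth.

The generator emulates a monthly stream of papers carrying author keywords,
with a vocabulary split into structural archetypes chosen to exercise every
downstream stage:

* **hub** — appears in a large fraction of papers, co-occurring with
  everything: high degree and centrality every month;
* **theme** — tags grouped into topics; each paper samples one topic and a
  few of its tags jointly, giving dense intra-theme co-occurrence;
* **noise** — a large pool of rare tags attached to otherwise ordinary
  papers: low degree, random attachment;
* **emerging** — rare before a changepoint month, frequent after it, so
  their structural role shifts over the series;
* **peninsula** — internally dense groups whose papers contain only group
  members plus one designated bridge tag; the bridge also appears in
  ordinary papers, so the group hangs off the core through that single
  tag (every shortest path from a member to a hub passes the bridge).

Surface-form noise is optional: with ``typo_rate`` > 0 each tag occurrence
is replaced by an edit-distance-1 variant with that probability, exercising
the normalization stage against a known variant table.

Everything is driven by one seed; identical configs produce byte-identical
corpora.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .corpus import Corpus, PaperRecord
from .cooccurrence import month_range

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate_corpus", "make_variants"]

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Defaults produce 24 months of ~100 papers each over a ~300-tag
    vocabulary, a scale at which planted archetypes are recoverable on a
    single CPU in minutes.
    """

    n_months: int = 24
    papers_per_month: float = 100.0  # Poisson mean
    start_month: str = "2020-03"
    n_hubs: int = 4
    n_themes: int = 6
    theme_size: int = 8
    n_noise: int = 220
    n_emerging: int = 10
    n_peninsulas: int = 3
    peninsula_size: int = 6  # including the bridge tag
    p_hub: float = 0.35  # per-hub inclusion probability in a core paper
    p_bridge_in_core: float = 0.08
    p_emerging_low: float = 0.02
    p_emerging_high: float = 0.30
    changepoint: int = 12  # month index at which emerging tags switch rate
    p_peninsula_paper: float = 0.15
    p_noise_paper: float = 0.20  # papers carrying only rare noise tags
    theme_tags_range: tuple[int, int] = (2, 4)
    tags_per_paper: tuple[int, int] = (3, 8)
    typo_rate: float = 0.0
    variants_per_tag: int = 2
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_hub", "p_bridge_in_core", "p_emerging_low", "p_emerging_high",
                     "p_peninsula_paper", "p_noise_paper", "typo_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.changepoint < self.n_months:
            raise ValueError("changepoint must lie inside the month range")
        lo, hi = self.tags_per_paper
        if not 1 <= lo <= hi:
            raise ValueError("tags_per_paper range must be positive and ordered")
        if self.peninsula_size < 3:
            raise ValueError("peninsula groups need at least 3 tags (bridge + 2)")
        pool = self.n_hubs + self.n_themes * self.theme_size + self.n_noise + self.n_emerging
        if pool < hi:
            raise ValueError("core vocabulary smaller than tags_per_paper maximum")
        if lo > self.peninsula_size:
            raise ValueError("tags_per_paper minimum exceeds peninsula group size")
        if self.n_months < 1 or self.papers_per_month <= 0:
            raise ValueError("need at least one month and a positive paper rate")


@dataclass
class SyntheticTruth:
    """Ground truth shipped beside a generated corpus."""

    archetypes: dict[str, str]  # canonical tag -> hub|theme|noise|emerging|peninsula
    variant_map: dict[str, str]  # surface variant -> canonical tag
    theme_groups: list[list[str]]
    peninsula_groups: list[dict]  # {"bridge": tag, "members": [...]}
    emerging_tags: list[str]
    hub_tags: list[str]
    noise_tags: list[str]
    changepoint_month: str
    months: list[str]

    def canonical_partition(self) -> dict[str, str]:
        """Surface tag -> canonical tag (canonicals map to themselves)."""
        out = {tag: tag for tag in self.archetypes}
        out.update(self.variant_map)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def make_variants(tag: str, n: int, seed: int = 0) -> list[str]:
    """n distinct strings at edit distance exactly 1 from ``tag``.

    Candidates enumerate every single-character substitution, insertion and
    deletion over a-z; a seeded permutation picks n of them, so the output
    is deterministic.
    """
    if len(tag) < 2:
        raise ValueError("tag must have length >= 2")
    if n < 1:
        raise ValueError("n must be >= 1")
    candidates: set[str] = set()
    for i in range(len(tag)):
        candidates.add(tag[:i] + tag[i + 1 :])  # deletion
        for ch in _ALPHABET:
            if ch != tag[i]:
                candidates.add(tag[:i] + ch + tag[i + 1 :])  # substitution
    for i in range(len(tag) + 1):
        for ch in _ALPHABET:
            candidates.add(tag[:i] + ch + tag[i:])  # insertion
    candidates.discard(tag)
    ordered = sorted(candidates)
    if n > len(ordered):
        raise ValueError(f"only {len(ordered)} distinct variants exist for {tag!r}")
    rng = np.random.default_rng(seed)
    picks = rng.permutation(len(ordered))[:n]
    return [ordered[i] for i in picks]


def _pseudo_word(rng: np.random.Generator) -> str:
    n_syll = int(rng.integers(4, 7))
    return "".join(
        _CONSONANTS[int(rng.integers(len(_CONSONANTS)))] + _VOWELS[int(rng.integers(len(_VOWELS)))]
        for _ in range(n_syll)
    )


def _make_vocabulary(config: GeneratorConfig, rng: np.random.Generator) -> dict:
    total = (
        config.n_hubs
        + config.n_themes * config.theme_size
        + config.n_noise
        + config.n_emerging
        + config.n_peninsulas * config.peninsula_size
    )
    words: list[str] = []
    used: set[str] = set()
    while len(words) < total:
        w = _pseudo_word(rng)
        if w not in used:
            used.add(w)
            words.append(w)
    pos = 0

    def take(k: int) -> list[str]:
        nonlocal pos
        out = words[pos : pos + k]
        pos += k
        return out

    hubs = take(config.n_hubs)
    themes = [take(config.theme_size) for _ in range(config.n_themes)]
    noise = take(config.n_noise)
    emerging = take(config.n_emerging)
    peninsulas = []
    for _ in range(config.n_peninsulas):
        group = take(config.peninsula_size)
        peninsulas.append({"bridge": group[0], "members": group[1:]})
    return {"hubs": hubs, "themes": themes, "noise": noise, "emerging": emerging,
            "peninsulas": peninsulas}


def _variant_table(
    vocab: dict, config: GeneratorConfig, rng: np.random.Generator
) -> dict[str, list[str]]:
    """Per-canonical-tag variant lists, globally collision-free."""
    all_tags = (
        vocab["hubs"]
        + [t for g in vocab["themes"] for t in g]
        + vocab["noise"]
        + vocab["emerging"]
        + [g["bridge"] for g in vocab["peninsulas"]]
        + [m for g in vocab["peninsulas"] for m in g["members"]]
    )
    taken = set(all_tags)
    table: dict[str, list[str]] = {}
    for tag in all_tags:
        pool = make_variants(tag, min(12, config.variants_per_tag + 10), seed=int(rng.integers(2**31)))
        chosen = []
        for cand in pool:
            if cand not in taken:
                taken.add(cand)
                chosen.append(cand)
            if len(chosen) == config.variants_per_tag:
                break
        if len(chosen) < config.variants_per_tag:
            raise ValueError(f"could not find collision-free variants for {tag!r}")
        table[tag] = chosen
    return table


def _core_paper_tags(
    vocab: dict, config: GeneratorConfig, rng: np.random.Generator, after_changepoint: bool
) -> list[str]:
    lo, hi = config.tags_per_paper
    k = int(rng.integers(lo, hi + 1))
    tags: list[str] = [h for h in vocab["hubs"] if rng.random() < config.p_hub]
    for group in vocab["peninsulas"]:
        if rng.random() < config.p_bridge_in_core:
            tags.append(group["bridge"])
    theme = vocab["themes"][int(rng.integers(len(vocab["themes"])))]
    t_lo, t_hi = config.theme_tags_range
    n_theme = int(rng.integers(t_lo, min(t_hi, len(theme)) + 1))
    picks = sorted(rng.choice(len(theme), size=n_theme, replace=False))
    tags.extend(theme[i] for i in picks)
    p_em = config.p_emerging_high if after_changepoint else config.p_emerging_low
    tags.extend(t for t in vocab["emerging"] if rng.random() < p_em)
    tags = list(dict.fromkeys(tags))
    # pad with further tags of the same theme: keyword lists are topical,
    # and rare (noise) tags enter only through noise papers
    remaining = [t for t in theme if t not in tags]
    while len(tags) < k and remaining:
        tags.append(remaining.pop(int(rng.integers(len(remaining)))))
    if len(tags) > k:
        keep = sorted(rng.choice(len(tags), size=k, replace=False))
        tags = [tags[i] for i in keep]
    return tags


def _noise_paper_tags(
    vocab: dict, config: GeneratorConfig, rng: np.random.Generator
) -> list[str]:
    """A paper of rare tags only: random attachment, detached from the core.

    These papers create the small, weakly connected fringe components that
    real keyword corpora exhibit (one-off jargon, project-specific terms).
    """
    lo = config.tags_per_paper[0]
    k = int(rng.integers(lo, min(lo + 3, config.tags_per_paper[1]) + 1))
    picks = rng.choice(len(vocab["noise"]), size=k, replace=False)
    return [vocab["noise"][i] for i in sorted(picks)]


def _peninsula_paper_tags(
    vocab: dict, config: GeneratorConfig, rng: np.random.Generator
) -> list[str]:
    group = vocab["peninsulas"][int(rng.integers(len(vocab["peninsulas"])))]
    members = group["members"]
    lo = config.tags_per_paper[0]
    k = int(rng.integers(max(lo, 3), config.peninsula_size + 1))
    picks = sorted(rng.choice(len(members), size=k - 1, replace=False))
    return [group["bridge"]] + [members[i] for i in picks]


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, SyntheticTruth]:
    """Generate a corpus and its ground truth; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    vocab = _make_vocabulary(config, rng)
    variant_table = (
        _variant_table(vocab, config, rng) if config.typo_rate > 0 else {}
    )
    months = month_range(config.start_month, _add_months(config.start_month, config.n_months - 1))
    records: list[PaperRecord] = []
    paper_idx = 0
    for m, month in enumerate(months):
        n_papers = int(rng.poisson(config.papers_per_month))
        for _ in range(n_papers):
            kind = rng.random()
            if kind < config.p_peninsula_paper:
                tags = _peninsula_paper_tags(vocab, config, rng)
            elif kind < config.p_peninsula_paper + config.p_noise_paper:
                tags = _noise_paper_tags(vocab, config, rng)
            else:
                tags = _core_paper_tags(vocab, config, rng, m >= config.changepoint)
            if config.typo_rate > 0:
                tags = [
                    variant_table[t][int(rng.integers(len(variant_table[t])))]
                    if rng.random() < config.typo_rate
                    else t
                    for t in tags
                ]
            day = int(rng.integers(1, 29))
            year, mon = (int(x) for x in month.split("-"))
            records.append(
                PaperRecord(
                    paper_id=f"P{paper_idx:06d}",
                    publication_date=dt.date(year, mon, day),
                    raw_tags=tuple(tags),
                )
            )
            paper_idx += 1
    corpus = Corpus(records)
    archetypes: dict[str, str] = {}
    for h in vocab["hubs"]:
        archetypes[h] = "hub"
    for g in vocab["themes"]:
        for t in g:
            archetypes[t] = "theme"
    for t in vocab["noise"]:
        archetypes[t] = "noise"
    for t in vocab["emerging"]:
        archetypes[t] = "emerging"
    for g in vocab["peninsulas"]:
        archetypes[g["bridge"]] = "peninsula"
        for t in g["members"]:
            archetypes[t] = "peninsula"
    variant_map = {v: tag for tag, vs in variant_table.items() for v in vs}
    truth = SyntheticTruth(
        archetypes=archetypes,
        variant_map=variant_map,
        theme_groups=vocab["themes"],
        peninsula_groups=vocab["peninsulas"],
        emerging_tags=list(vocab["emerging"]),
        hub_tags=list(vocab["hubs"]),
        noise_tags=list(vocab["noise"]),
        changepoint_month=months[config.changepoint],
        months=months,
    )
    return corpus, truth


def _add_months(start: str, delta: int) -> str:
    year, month = (int(x) for x in start.split("-"))
    total = year * 12 + (month - 1) + delta
    return f"{total // 12:04d}-{total % 12 + 1:02d}"
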