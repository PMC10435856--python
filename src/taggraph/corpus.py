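"""Corpus ingest: dated papers with author-keyword lists.

Readers accept three dialects — JSON Lines, a simple CSV, and the CORD-19
``metadata.csv`` layout — and apply the same validation to each record:
a parseable publication date (day or year-month precision) and at least one
non-empty keyword. Records failing validation are skipped and counted, never
fatal, so ingest is total over well-formed files.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

DIALECTS = ("jsonl", "csv", "cord19_metadata")

_YM_RE = re.compile(r"^(\d{4})-(\d{2})$")


class CorpusError(Exception):
    """Base class for ingest failures."""


class ConfigurationError(CorpusError):
    """Unknown dialect or invalid reader configuration."""


class EmptyCorpusError(CorpusError):
    """No record survived validation."""


def normalize_tag_text(tag: str) -> str:
    """NFC-normalize, trim and collapse internal whitespace.

    Case is preserved here; case-folding happens in tag normalization so
    that canonical labels keep their original surface form.
    """
    tag = unicodedata.normalize("NFC", tag)
    return " ".join(tag.split())


@dataclass(frozen=True)
class PaperRecord:
    """One paper: opaque id, publication date, ordered author keywords."""

    paper_id: str
    publication_date: dt.date
    raw_tags: tuple[str, ...]

    @property
    def month(self) -> str:
        return f"{self.publication_date.year:04d}-{self.publication_date.month:02d}"


@dataclass
class Corpus:
    """Validated records sorted by (publication_date, paper_id)."""

    records: list[PaperRecord]
    skipped_count: int = 0

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.publication_date, r.paper_id))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PaperRecord]:
        return iter(self.records)

    @property
    def date_span(self) -> tuple[dt.date, dt.date] | None:
        if not self.records:
            return None
        return (self.records[0].publication_date, self.records[-1].publication_date)

    def tag_universe(self) -> list[str]:
        """Sorted distinct tags over all records."""
        tags: set[str] = set()
        for rec in self.records:
            tags.update(rec.raw_tags)
        return sorted(tags)

    def tag_frequencies(self) -> dict[str, int]:
        """Number of papers containing each tag (deduplicated per paper)."""
        freq: dict[str, int] = {}
        for rec in self.records:
            for tag in set(rec.raw_tags):
                freq[tag] = freq.get(tag, 0) + 1
        return freq


def parse_publication_date(value: object) -> dt.date | None:
    """Parse an ISO-8601 date; year-month imputes day 01; year-only is rejected.

    Returns None when the value cannot be resolved to day or month precision.
    """
    if value is None:
        return None
    text = str(value).strip()
    if not text:
        return None
    m = _YM_RE.match(text)
    if m:
        year, month = int(m.group(1)), int(m.group(2))
        try:
            return dt.date(year, month, 1)
        except ValueError:
            return None
    try:
        return dt.date.fromisoformat(text[:10]) if len(text) >= 10 else None
    except ValueError:
        return None


def _clean_tags(tags: Iterable[str]) -> tuple[str, ...]:
    out = []
    for tag in tags:
        cleaned = normalize_tag_text(str(tag))
        if cleaned:
            out.append(cleaned)
    return tuple(out)


def _build_corpus(rows: Iterable[tuple[object, object, Iterable[str]]]) -> Corpus:
    records: list[PaperRecord] = []
    seen: set[str] = set()
    skipped = 0
    for paper_id, date_value, tags in rows:
        pid = str(paper_id).strip() if paper_id is not None else ""
        date = parse_publication_date(date_value)
        cleaned = _clean_tags(tags)
        if not pid or date is None or not cleaned or pid in seen:
            skipped += 1
            logger.debug("skipping record %r (date=%r, %d tags)", pid, date_value, len(cleaned))
            continue
        seen.add(pid)
        records.append(PaperRecord(pid, date, cleaned))
    if not records:
        raise EmptyCorpusError("no record survived validation")
    corpus = Corpus(records, skipped_count=skipped)
    logger.info("ingested %d records, skipped %d", len(records), skipped)
    return corpus


def _iter_jsonl(path: Path) -> Iterator[tuple[object, object, list[str]]]:
    with path.open("r", encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            yield obj.get("paper_id"), obj.get("publication_date"), list(obj.get("keywords") or [])


def _iter_csv(
    path: Path,
    id_col: str,
    date_col: str,
    keywords_col: str,
    delimiter: str,
) -> Iterator[tuple[object, object, list[str]]]:
    with path.open("r", encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle)
        for row in reader:
            cell = row.get(keywords_col) or ""
            yield row.get(id_col), row.get(date_col), cell.split(delimiter)


def read_corpus(
    path: str | Path,
    dialect: str = "jsonl",
    keywords_column: str | None = None,
) -> Corpus:
    """Read a corpus file in the given dialect.

    Parameters
    ----------
    path:
        Input file. Must exist and match the dialect's schema.
    dialect:
        One of ``jsonl``, ``csv`` or ``cord19_metadata``. The CORD-19 dialect
        reads ``cord_uid`` / ``publish_time`` and a configurable,
        semicolon-delimited keyword column (default ``keywords``).
    keywords_column:
        Override for the keyword column name of the CSV dialects.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "jsonl":
        rows = _iter_jsonl(path)
    elif dialect == "csv":
        rows = _iter_csv(path, "paper_id", "publication_date", keywords_column or "keywords", ";")
    else:
        rows = _iter_csv(path, "cord_uid", "publish_time", keywords_column or "keywords", ";")
    return _build_corpus(rows)


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the JSONL schema (inverse of the jsonl dialect)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for rec in corpus.records:
            obj = {
                "paper_id": rec.paper_id,
                "publication_date": rec.publication_date.isoformat(),
                "keywords": list(rec.raw_tags),
            }
            handle.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")
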