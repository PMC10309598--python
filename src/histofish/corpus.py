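"""Newspaper items: inclusion/exclusion rules and per-item occurrence capping.

An item enters the analysis only if it is not a duplicate, not an
advertisement, focuses on coastal/ocean areas and actually reports marine
animals.  Within one item a taxon counts at most once no matter how often it
is repeated — occurrence is item-level presence, and the same cap applies to
fishing gear.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .taxon_registry import InvalidNameError, normalize_name

logger = logging.getLogger("histofish")

#: Calendar-decade range matching the study period; years outside are
#: accepted but flagged in the exclusion ledger's companion warnings.
DECADE_MIN = 1840
DECADE_MAX = 2010


def decade_of(year: int) -> int:
    """Calendar decade label: 1885 → 1880 (meaning 1880–1889)."""
    return (year // 10) * 10


@dataclass(frozen=True)
class NewsItem:
    """One newspaper item with its relevance flags and raw mention lists.

    The judgement behind the flags (reading the Portuguese text) is human
    and upstream; here the flags are inputs.
    """

    item_id: str
    newspaper: str
    year: int | None
    municipality: str | None = None
    keyword_source: str = "both"  # pesca | peixe | both
    is_duplicate: bool = False
    is_advertisement: bool = False
    scope_marine: bool = True
    has_animal_report: bool = True
    mentions: tuple[str, ...] = ()
    gear_mentions: tuple[str, ...] = ()

    @property
    def decade(self) -> int | None:
        return None if self.year is None else decade_of(self.year)


@dataclass
class ExclusionLedger:
    """Counts of excluded items per reason; data output, not log text."""

    counts: Counter = field(default_factory=Counter)
    excluded_ids: dict[str, str] = field(default_factory=dict)

    def record(self, item: NewsItem, reason: str) -> None:
        self.counts[reason] += 1
        self.excluded_ids[item.item_id] = reason

    def as_dict(self) -> dict[str, int]:
        return dict(sorted(self.counts.items()))


def filter_items(
    items: Sequence[NewsItem],
) -> tuple[list[NewsItem], ExclusionLedger]:
    """Apply the inclusion rules, returning kept items and the ledger.

    Exclusion reasons, checked in order: ``undated`` (no year),
    ``duplicate`` (flagged, or an item id already seen), ``advertisement``,
    ``out_of_scope`` (not coastal/marine), ``no_animal_report``.
    Deterministic and idempotent: filtering the output again excludes
    nothing.
    """
    ledger = ExclusionLedger()
    seen: set[str] = set()
    included: list[NewsItem] = []
    for item in items:
        if item.year is None:
            ledger.record(item, "undated")
            continue
        if item.is_duplicate or item.item_id in seen:
            ledger.record(item, "duplicate")
            continue
        seen.add(item.item_id)
        if item.is_advertisement:
            ledger.record(item, "advertisement")
        elif not item.scope_marine:
            ledger.record(item, "out_of_scope")
        elif not item.has_animal_report:
            ledger.record(item, "no_animal_report")
        else:
            if not (DECADE_MIN <= item.decade <= DECADE_MAX + 9):
                logger.warning(
                    "item %s year %s outside study period", item.item_id, item.year
                )
            included.append(item)
    return included, ledger


def item_occurrences(item: NewsItem) -> tuple[set[str], set[str]]:
    """Distinct normalised taxon and gear keys for one item.

    Each key appears at most once per item regardless of repetition
    (presence cap).  Distinct normalised variants count separately — the
    counting unit is the vernacular name, not the underlying species.
    Un-normalisable (blank) mentions are dropped.
    """
    taxa: set[str] = set()
    for raw in item.mentions:
        try:
            taxa.add(normalize_name(raw))
        except InvalidNameError:
            logger.warning("item %s: blank taxon mention skipped", item.item_id)
    gear: set[str] = set()
    for raw in item.gear_mentions:
        try:
            gear.add(normalize_name(raw))
        except InvalidNameError:
            logger.warning("item %s: blank gear mention skipped", item.item_id)
    return taxa, gear


@dataclass
class CorpusSummary:
    """Per-decade counts of newspapers, matched and included items."""

    newspapers: dict[int, int]
    included_items: dict[int, int]
    matched_by_keyword: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "newspapers": {str(k): v for k, v in sorted(self.newspapers.items())},
            "included_items": {
                str(k): v for k, v in sorted(self.included_items.items())
            },
            "matched_by_keyword": dict(sorted(self.matched_by_keyword.items())),
        }


def summarize_corpus(
    included: Sequence[NewsItem],
    newspapers_per_decade: dict[int, int] | None = None,
) -> CorpusSummary:
    """Summarise an included corpus.

    Keyword counts are reported both ways because an item matched by both
    keywords could be tallied once (``both``) or under each keyword
    (``pesca_or_both`` / ``peixe_or_both``).
    """
    per_decade: Counter = Counter(i.decade for i in included)
    kw: Counter = Counter(i.keyword_source for i in included)
    matched = {
        "pesca": kw.get("pesca", 0),
        "peixe": kw.get("peixe", 0),
        "both": kw.get("both", 0),
        "pesca_or_both": kw.get("pesca", 0) + kw.get("both", 0),
        "peixe_or_both": kw.get("peixe", 0) + kw.get("both", 0),
    }
    if newspapers_per_decade is None:
        newspapers_per_decade = {
            d: len({i.newspaper for i in included if i.decade == d})
            for d in per_decade
        }
    return CorpusSummary(
        newspapers=dict(newspapers_per_decade),
        included_items=dict(per_decade),
        matched_by_keyword=matched,
    )


# -- item-table readers/writers ---------------------------------------

ITEM_COLUMNS = (
    "item_id",
    "newspaper",
    "year",
    "municipality",
    "keyword_source",
    "is_duplicate",
    "is_advertisement",
    "scope_marine",
    "has_animal_report",
    "mentions",
    "gear_mentions",
)

_TRUE = {"1", "true", "yes"}


def _parse_bool(v: object) -> bool:
    return str(v).strip().lower() in _TRUE


def _parse_list(v: object, delimiter: str) -> tuple[str, ...]:
    s = str(v or "").strip()
    if not s:
        return ()
    return tuple(p.strip() for p in s.split(delimiter) if p.strip())


def read_items_csv(
    path: str | Path, sep: str | None = None, list_delimiter: str = "|"
) -> list[NewsItem]:
    """Read an item table (CSV/TSV, one record per item).

    ``mentions`` and ``gear_mentions`` are delimiter-separated list fields
    ("|" by default).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    items: list[NewsItem] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        missing = {"item_id", "newspaper", "year"} - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing item columns {sorted(missing)}")
        for i, row in enumerate(reader):
            try:
                year_raw = str(row.get("year", "") or "").strip()
                items.append(
                    NewsItem(
                        item_id=str(row["item_id"]),
                        newspaper=str(row["newspaper"]),
                        year=int(year_raw) if year_raw else None,
                        municipality=(row.get("municipality") or None),
                        keyword_source=str(row.get("keyword_source", "both") or "both"),
                        is_duplicate=_parse_bool(row.get("is_duplicate", "")),
                        is_advertisement=_parse_bool(row.get("is_advertisement", "")),
                        scope_marine=_parse_bool(row.get("scope_marine", "true")),
                        has_animal_report=_parse_bool(row.get("has_animal_report", "true")),
                        mentions=_parse_list(row.get("mentions"), list_delimiter),
                        gear_mentions=_parse_list(row.get("gear_mentions"), list_delimiter),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path} row {i}: field error: {exc}") from exc
    return items


def read_items_jsonl(path: str | Path) -> list[NewsItem]:
    """Read an item table in JSON-lines form (lists as native arrays)."""
    items: list[NewsItem] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                items.append(
                    NewsItem(
                        item_id=str(rec["item_id"]),
                        newspaper=str(rec.get("newspaper", "")),
                        year=rec.get("year"),
                        municipality=rec.get("municipality"),
                        keyword_source=rec.get("keyword_source", "both"),
                        is_duplicate=bool(rec.get("is_duplicate", False)),
                        is_advertisement=bool(rec.get("is_advertisement", False)),
                        scope_marine=bool(rec.get("scope_marine", True)),
                        has_animal_report=bool(rec.get("has_animal_report", True)),
                        mentions=tuple(rec.get("mentions", ())),
                        gear_mentions=tuple(rec.get("gear_mentions", ())),
                    )
                )
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise ValueError(f"{path} line {i}: {exc}") from exc
    return items


def write_items_csv(
    items: Iterable[NewsItem], path: str | Path, list_delimiter: str = "|"
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ITEM_COLUMNS)
        for it in items:
            writer.writerow(
                [
                    it.item_id,
                    it.newspaper,
                    "" if it.year is None else it.year,
                    it.municipality or "",
                    it.keyword_source,
                    str(it.is_duplicate).lower(),
                    str(it.is_advertisement).lower(),
                    str(it.scope_marine).lower(),
                    str(it.has_animal_report).lower(),
                    list_delimiter.join(it.mentions),
                    list_delimiter.join(it.gear_mentions),
                ]
            )
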