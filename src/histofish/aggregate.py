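"""Decade × taxon occurrence tables, richness and group summaries.

The abundance of a taxon in a decade is the number of included items in that
decade mentioning it (the per-item presence cap has already collapsed
repeats).  Tables exist at two levels: vernacular keys (the counting unit)
and scientific taxa (via the registry mapping, again capped at one per item
so two folk variants of the same species in one item count once).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .corpus import NewsItem, item_occurrences
from .taxon_registry import Ambiguity, Group, TaxonRegistry


class UndefinedDenominatorError(ZeroDivisionError):
    """Raised when a relative abundance is requested against a zero total."""


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero — the single rounding convention here.

    Python's builtin ``round`` is banker's rounding; printed historical
    percentages follow the half-up convention instead.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DecadalTable:
    """Occurrence matrix (rows: decades, columns: normalised keys).

    ``items_per_decade`` is the margin of included-item counts; every cell
    is bounded above by its row's margin.
    """

    counts: pd.DataFrame
    items_per_decade: pd.Series
    level: str = "vernacular"

    @property
    def decades(self) -> list[int]:
        return list(self.counts.index)

    @property
    def keys(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0).astype(int)

    def tidy(self) -> pd.DataFrame:
        """Long-format view: (decade, taxon, level, count), nonzero cells."""
        long = (
            self.counts.rename_axis(index="decade", columns="taxon")
            .stack()
            .rename("count")
            .reset_index()
        )
        long = long[long["count"] > 0].reset_index(drop=True)
        long.insert(2, "level", self.level)
        return long


def decadal_abundance(
    included: Sequence[NewsItem],
    registry: TaxonRegistry | None = None,
    level: str = "vernacular",
) -> DecadalTable:
    """Build the decade × key occurrence table from an included corpus.

    At ``scientific`` level each vernacular mention is mapped through the
    registry; unresolved keys are dropped there (they have no taxon), and an
    item mentioning several folk variants of one taxon still contributes a
    single count to that taxon.
    """
    if level not in ("vernacular", "scientific"):
        raise ValueError(f"unknown aggregation level {level!r}")
    if level == "scientific" and registry is None:
        raise ValueError("scientific-level aggregation requires a registry")

    cell_counts: Counter = Counter()
    item_margin: Counter = Counter()
    for item in included:
        d = item.decade
        item_margin[d] += 1
        taxa_keys, _ = item_occurrences(item)
        if level == "vernacular":
            keys = taxa_keys
        else:
            keys = set()
            for k in taxa_keys:
                keys.update(registry.resolve(k).taxon_ids)  # cap via set union
        for k in keys:
            cell_counts[(d, k)] += 1

    decades = sorted(item_margin)
    columns = sorted({k for _, k in cell_counts})
    counts = pd.DataFrame(0, index=decades, columns=columns, dtype=int)
    for (d, k), n in cell_counts.items():
        counts.at[d, k] = n
    margin = pd.Series(
        {d: item_margin[d] for d in decades}, dtype=int, name="included_items"
    )
    return DecadalTable(counts=counts, items_per_decade=margin, level=level)


def richness(table: DecadalTable) -> tuple[pd.Series, int]:
    """Distinct taxa with nonzero occurrence, per decade and overall.

    Overall richness counts a taxon once across all decades.
    """
    per_decade = (table.counts > 0).sum(axis=1).astype(int)
    overall = int((table.counts.sum(axis=0) > 0).sum())
    return per_decade, overall


def relative_abundance(count: int, total: int) -> float:
    """Percentage share of a count, rounded half-up to one decimal.

    The denominator is the grand total over ALL groups (native, non-native,
    freshwater alike).
    """
    if total <= 0:
        raise UndefinedDenominatorError("relative abundance with total <= 0")
    if count < 0 or count > total:
        raise ValueError(f"count {count} outside [0, total={total}]")
    return round_half_up(100.0 * count / total, 1)


UNASSIGNED = "unassigned"


def group_of_key(key: str, registry: TaxonRegistry) -> str:
    """Group label for a vernacular key, or ``unassigned``.

    A key is assigned to a group only when all its mapped taxa agree;
    unresolved and mixed-group keys go to the ``unassigned`` bucket and are
    reported separately.
    """
    records = registry.resolve_taxa(key)
    groups = {r.group for r in records}
    if len(groups) == 1:
        return groups.pop().value
    return UNASSIGNED


@dataclass
class GroupSummary:
    """Per-group abundance and richness (vernacular and scientific)."""

    abundance: dict[str, int]
    vernacular_richness: dict[str, int]
    scientific_richness: dict[str, int]

    @property
    def total_abundance(self) -> int:
        return sum(self.abundance.values())

    @property
    def total_vernacular_richness(self) -> int:
        return sum(self.vernacular_richness.values())

    @property
    def total_scientific_richness(self) -> int:
        return sum(self.scientific_richness.values())

    def as_frame(self) -> pd.DataFrame:
        groups = sorted(
            set(self.abundance) | set(self.vernacular_richness) | set(self.scientific_richness)
        )
        return pd.DataFrame(
            {
                "group": groups,
                "abundance": [self.abundance.get(g, 0) for g in groups],
                "vernacular_richness": [self.vernacular_richness.get(g, 0) for g in groups],
                "scientific_richness": [self.scientific_richness.get(g, 0) for g in groups],
            }
        )


def group_summary(
    vernacular_table: DecadalTable, registry: TaxonRegistry
) -> GroupSummary:
    """Tally abundance and richness per taxonomic group.

    Abundance and vernacular richness are counted on vernacular keys
    (unresolved keys are mentions too, under ``unassigned``); scientific
    richness counts distinct taxa, each in its own group.
    """
    abundance: Counter = Counter()
    vern_rich: Counter = Counter()
    sci_by_group: dict[str, set[str]] = {}
    totals = vernacular_table.column_totals()
    for key in vernacular_table.keys:
        n = int(totals[key])
        if n == 0:
            continue
        g = group_of_key(key, registry)
        abundance[g] += n
        vern_rich[g] += 1
        for rec in registry.resolve_taxa(key):
            sci_by_group.setdefault(rec.group.value, set()).add(rec.taxon_id)
    return GroupSummary(
        abundance=dict(abundance),
        vernacular_richness=dict(vern_rich),
        scientific_richness={g: len(s) for g, s in sci_by_group.items()},
    )


def unresolved_report(
    vernacular_table: DecadalTable, registry: TaxonRegistry
) -> pd.DataFrame:
    """Keys that resolve to no taxon, with their total occurrence counts."""
    rows = []
    totals = vernacular_table.column_totals()
    for key in vernacular_table.keys:
        if registry.resolve(key).ambiguity is Ambiguity.UNRESOLVED:
            rows.append({"vernacular_key": key, "occurrences": int(totals[key])})
    return pd.DataFrame(rows, columns=["vernacular_key", "occurrences"])
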