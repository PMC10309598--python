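"""Decadal trophic indicators: WATL, Pis/Pla, Inv/Fis and gear summaries.

WATL (weighted average trophic level) for a decade weights each eligible
taxon's trophic level by its occurrence count:

    WATL_d = Σ_i TL_i · n_{i,d} / Σ_i n_{i,d}

over native marine fish with known TL.  Pis/Pla is the occurrence ratio of
piscivorous to planktivorous fish, Inv/Fis of native marine invertebrates
(crustaceans, molluscs and — switchable — echinoderms) to native marine
fish.  Non-native and freshwater organisms, reptiles, birds and sea mammals
are excluded from all three.  Decades with an empty eligible set are
missing, never zero.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

import pandas as pd

from .aggregate import DecadalTable
from .corpus import NewsItem, item_occurrences
from .taxon_registry import (
    INVERTEBRATE_GROUPS,
    Group,
    Guild,
    TaxonRegistry,
)

logger = logging.getLogger("histofish")


@dataclass
class IndicatorSeries:
    """Per-decade values of one indicator with missingness preserved.

    ``values`` maps decade → value or ``None`` (missing); ``n_eligible``
    records the occurrence mass behind each value, so sparse decades are
    visible downstream.
    """

    indicator: str
    values: dict[int, float | None]
    n_eligible: dict[int, int] = field(default_factory=dict)
    exclusions_applied: tuple[str, ...] = ()

    def as_series(self) -> pd.Series:
        return pd.Series(
            {d: (math.nan if v is None else v) for d, v in sorted(self.values.items())},
            name=self.indicator,
            dtype=float,
        )

    def tidy(self) -> pd.DataFrame:
        rows = [
            {
                "decade": d,
                "indicator": self.indicator,
                "value": self.values[d],
                "n_eligible": self.n_eligible.get(d, 0),
            }
            for d in sorted(self.values)
        ]
        df = pd.DataFrame(rows)
        if not df.empty:
            df["value"] = df["value"].astype(float)
        return df


DEFAULT_EXCLUSIONS = ("non_native", "freshwater", "reptile", "bird", "sea_mammal")


def _key_groups(key: str, registry: TaxonRegistry) -> set[Group]:
    return {r.group for r in registry.resolve_taxa(key)}


def _watl_weights(
    table: DecadalTable,
    registry: TaxonRegistry,
    eligible_groups: frozenset[Group],
) -> dict[str, float]:
    """TL per eligible column key; keys mapping outside the eligible set,
    to a mixed fish/non-fish taxon set, or lacking a TL are dropped."""
    weights: dict[str, float] = {}
    for key in table.keys:
        groups = _key_groups(key, registry)
        if not groups:
            continue
        if not groups <= eligible_groups:
            if groups & eligible_groups:
                logger.info(
                    "key %r maps across eligible and excluded groups; "
                    "left out of WATL", key
                )
            continue
        tl = registry.key_trophic_level(key)
        if tl is not None:
            weights[key] = tl
    return weights


def watl(
    table: DecadalTable,
    registry: TaxonRegistry,
    decade: int,
    eligible_groups: Sequence[Group] = (Group.NATIVE_MARINE_FISH,),
) -> float | None:
    """WATL for one decade, or ``None`` when no eligible occurrences."""
    series = watl_series(table, registry, eligible_groups)
    return series.values.get(decade)


def watl_series(
    table: DecadalTable,
    registry: TaxonRegistry,
    eligible_groups: Sequence[Group] = (Group.NATIVE_MARINE_FISH,),
) -> IndicatorSeries:
    """WATL across all decades of a vernacular-level table."""
    eligible = frozenset(eligible_groups)
    tls = _watl_weights(table, registry, eligible)
    values: dict[int, float | None] = {}
    n_eligible: dict[int, int] = {}
    for d in table.decades:
        row = table.counts.loc[d]
        num = 0.0
        den = 0
        for key, tl in tls.items():
            n = int(row[key])
            num += tl * n
            den += n
        n_eligible[d] = den
        values[d] = (num / den) if den > 0 else None
    return IndicatorSeries(
        indicator="WATL",
        values=values,
        n_eligible=n_eligible,
        exclusions_applied=DEFAULT_EXCLUSIONS,
    )


def _ratio_series(
    table: DecadalTable,
    numerator_keys: set[str],
    denominator_keys: set[str],
    name: str,
) -> IndicatorSeries:
    values: dict[int, float | None] = {}
    n_eligible: dict[int, int] = {}
    for d in table.decades:
        row = table.counts.loc[d]
        num = int(row[list(numerator_keys)].sum()) if numerator_keys else 0
        den = int(row[list(denominator_keys)].sum()) if denominator_keys else 0
        n_eligible[d] = num + den
        values[d] = (num / den) if den > 0 else None
    return IndicatorSeries(
        indicator=name,
        values=values,
        n_eligible=n_eligible,
        exclusions_applied=DEFAULT_EXCLUSIONS,
    )


def _guild_keys(table: DecadalTable, registry: TaxonRegistry, guild: Guild) -> set[str]:
    keys = set()
    for key in table.keys:
        records = registry.resolve_taxa(key)
        if not records:
            continue
        if all(
            r.group is Group.NATIVE_MARINE_FISH and r.trophic_guild is guild
            for r in records
        ):
            keys.add(key)
    return keys


def pis_pla_series(table: DecadalTable, registry: TaxonRegistry) -> IndicatorSeries:
    """Fish-based piscivore/planktivore occurrence ratio per decade.

    Missing when the planktivore sum is zero.  Keys mapping to taxa of
    mixed guilds contribute to neither side.
    """
    pis = _guild_keys(table, registry, Guild.PISCIVORE)
    pla = _guild_keys(table, registry, Guild.PLANKTIVORE)
    return _ratio_series(table, pis, pla, "PisPla")


def pis_pla(table: DecadalTable, registry: TaxonRegistry, decade: int) -> float | None:
    return pis_pla_series(table, registry).values.get(decade)


def inv_fis_series(
    table: DecadalTable,
    registry: TaxonRegistry,
    include_echinoderms: bool = True,
) -> IndicatorSeries:
    """Native-invertebrate / native-fish occurrence ratio per decade.

    Echinoderms sit in the invertebrate numerator by default (they are
    native marine invertebrates and are not on the exclusion list); the
    switch lets users restrict the numerator to crustaceans + molluscs.
    Missing when the fish sum is zero.
    """
    inv_groups = set(INVERTEBRATE_GROUPS)
    if not include_echinoderms:
        inv_groups.discard(Group.ECHINODERM)
    inv_keys: set[str] = set()
    fis_keys: set[str] = set()
    for key in table.keys:
        groups = _key_groups(key, registry)
        if not groups:
            continue
        if groups <= inv_groups:
            inv_keys.add(key)
        elif groups == {Group.NATIVE_MARINE_FISH}:
            fis_keys.add(key)
    return _ratio_series(table, inv_keys, fis_keys, "InvFis")


def inv_fis(
    table: DecadalTable,
    registry: TaxonRegistry,
    decade: int,
    include_echinoderms: bool = True,
) -> float | None:
    return inv_fis_series(table, registry, include_echinoderms).values.get(decade)


# -- fishing gear ------------------------------------------------------


@dataclass
class GearSummary:
    """Gear occurrence (item-capped) per decade and overall.

    ``category_frequency`` rolls raw gear variants up into broad standard
    categories via the mapping file (e.g. every net variant → "rede");
    ``variant_richness`` counts distinct raw variants per category.
    Unmapped gear names are reported, never dropped.
    """

    per_decade_frequency: pd.DataFrame  # decades × categories
    category_frequency: dict[str, int]
    variant_richness: dict[str, int]
    unmapped: dict[str, int]

    @property
    def total_frequency(self) -> int:
        return sum(self.category_frequency.values())

    def overall_richness(self) -> int:
        return sum(self.variant_richness.values())


def gear_summary(
    included: Sequence[NewsItem],
    gear_map: Mapping[str, str] | None = None,
) -> GearSummary:
    """Standardise and tally gear mentions with the per-item presence cap.

    ``gear_map`` maps normalised raw gear names to standard categories; raw
    names absent from the map stay under their own name and are listed in
    ``unmapped``.
    """
    gear_map = dict(gear_map or {})
    cat_of: dict[str, str] = {}

    def category(raw_key: str) -> str:
        return gear_map.get(raw_key, raw_key)

    cell: Counter = Counter()  # (decade, category) → items
    cat_total: Counter = Counter()
    variants: dict[str, set[str]] = {}
    unmapped: Counter = Counter()
    for item in included:
        _, gear_keys = item_occurrences(item)
        cats = set()
        for g in gear_keys:
            c = category(g)
            cats.add(c)
            variants.setdefault(c, set()).add(g)
            if g not in gear_map:
                unmapped[g] += 1
        for c in cats:  # cap at category level too: one item, one count
            cell[(item.decade, c)] += 1
            cat_total[c] += 1
    decades = sorted({d for d, _ in cell})
    cats = sorted({c for _, c in cell})
    per_decade = pd.DataFrame(0, index=decades, columns=cats, dtype=int)
    for (d, c), n in cell.items():
        per_decade.at[d, c] = n
    return GearSummary(
        per_decade_frequency=per_decade,
        category_frequency=dict(cat_total),
        variant_richness={c: len(v) for c, v in variants.items()},
        unmapped=dict(unmapped),
    )
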