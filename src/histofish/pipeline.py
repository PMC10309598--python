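"""End-to-end pipeline: ingest → filter → aggregate → indicators → trends.

Writes, in order: the exclusion ledger, the decadal tables (vernacular and
scientific), the group summary, the indicator series, the trend results and
the unresolved-name report, plus one machine-readable JSON summary whose
every number mirrors a table cell.  Re-running on identical inputs yields
identical outputs (no hidden state, no timestamps in data files).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import aggregate as agg
from . import indicators as ind
from . import trends as tr
from .corpus import (
    ExclusionLedger,
    NewsItem,
    filter_items,
    read_items_csv,
    read_items_jsonl,
    summarize_corpus,
)
from .taxon_registry import TaxonRegistry

logger = logging.getLogger("histofish")


@dataclass
class PipelineConfig:
    """Paths and options binding the stages together."""

    dictionary_path: Path | None = None
    items_path: Path | None = None
    gear_map_path: Path | None = None
    landings_path: Path | None = None
    out_dir: Path = Path("histofish-out")
    decade_range: tuple[int, int] | None = None
    include_echinoderms: bool = True
    list_delimiter: str = "|"

    def __post_init__(self) -> None:
        for name in ("dictionary_path", "items_path", "gear_map_path", "landings_path"):
            p = getattr(self, name)
            if p is not None:
                setattr(self, name, Path(p))
        self.out_dir = Path(self.out_dir)
        if self.decade_range is not None and self.decade_range[0] > self.decade_range[1]:
            raise ValueError(f"decade range {self.decade_range} not well-ordered")


def read_gear_map(path: str | Path) -> dict[str, str]:
    """Two-column CSV (raw_gear, standard_category), normalised keys."""
    from .taxon_registry import normalize_name

    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if not {"raw_gear", "standard_category"} <= set(reader.fieldnames or ()):
            raise ValueError(f"{path}: gear map needs raw_gear, standard_category")
        for row in reader:
            mapping[normalize_name(row["raw_gear"])] = normalize_name(
                row["standard_category"]
            )
    return mapping


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run."""

    included: list[NewsItem]
    ledger: ExclusionLedger
    vernacular_table: agg.DecadalTable
    scientific_table: agg.DecadalTable
    group_summary: agg.GroupSummary
    indicator_series: dict[str, ind.IndicatorSeries]
    gear: ind.GearSummary
    trends: dict[str, tr.TrendResult | None]
    unresolved: pd.DataFrame
    landings_comparison: pd.DataFrame | None = None

    def json_summary(self) -> dict:
        summary = {
            "included_items": len(self.included),
            "exclusions": self.ledger.as_dict(),
            "grand_total_mentions": self.vernacular_table.grand_total,
            "vernacular_richness": agg.richness(self.vernacular_table)[1],
            "scientific_richness": agg.richness(self.scientific_table)[1],
            "group_summary": {
                "abundance": dict(sorted(self.group_summary.abundance.items())),
                "vernacular_richness": dict(
                    sorted(self.group_summary.vernacular_richness.items())
                ),
                "scientific_richness": dict(
                    sorted(self.group_summary.scientific_richness.items())
                ),
                "totals": {
                    "abundance": self.group_summary.total_abundance,
                    "vernacular_richness": self.group_summary.total_vernacular_richness,
                    "scientific_richness": self.group_summary.total_scientific_richness,
                },
            },
            "indicators": {
                name: {str(d): v for d, v in sorted(s.values.items())}
                for name, s in self.indicator_series.items()
            },
            "gear": {
                "category_frequency": dict(sorted(self.gear.category_frequency.items())),
                "variant_richness": dict(sorted(self.gear.variant_richness.items())),
                "unmapped": dict(sorted(self.gear.unmapped.items())),
            },
            "trends": {
                name: (res.as_dict() if res is not None else None)
                for name, res in sorted(self.trends.items())
            },
            "unresolved_names": self.unresolved.to_dict(orient="records"),
        }
        return summary


def run_pipeline(
    config: PipelineConfig,
    items: Sequence[NewsItem] | None = None,
    registry: TaxonRegistry | None = None,
) -> ReportBundle:
    """Run every stage and write the report bundle to ``config.out_dir``.

    ``items`` and ``registry`` may be passed directly (e.g. from the
    synthetic generator); otherwise they are loaded from the configured
    paths.
    """
    if registry is None:
        if config.dictionary_path is None:
            raise ValueError("no taxon dictionary given")
        registry = TaxonRegistry.from_csv(config.dictionary_path)
    if items is None:
        if config.items_path is None:
            raise ValueError("no item table given")
        if config.items_path.suffix.lower() in (".jsonl", ".ndjson"):
            items = read_items_jsonl(config.items_path)
        else:
            items = read_items_csv(
                config.items_path, list_delimiter=config.list_delimiter
            )

    included, ledger = filter_items(list(items))
    if config.decade_range is not None:
        lo, hi = config.decade_range
        included = [i for i in included if lo <= i.decade <= hi]
    if not included:
        logger.warning("no items included; all indicators will be missing")

    vern = agg.decadal_abundance(included, registry, level="vernacular")
    sci = agg.decadal_abundance(included, registry, level="scientific")
    groups = agg.group_summary(vern, registry)
    series = {
        "WATL": ind.watl_series(vern, registry),
        "PisPla": ind.pis_pla_series(vern, registry),
        "InvFis": ind.inv_fis_series(
            vern, registry, include_echinoderms=config.include_echinoderms
        ),
    }
    rich_per_decade, _ = agg.richness(vern)
    series["richness"] = ind.IndicatorSeries(
        indicator="richness",
        values={int(d): float(v) for d, v in rich_per_decade.items()},
        n_eligible={
            int(d): int(vern.items_per_decade[d]) for d in vern.decades
        },
    )
    series["abundance"] = ind.IndicatorSeries(
        indicator="abundance",
        values={int(d): float(vern.counts.loc[d].sum()) for d in vern.decades},
        n_eligible={int(d): int(vern.items_per_decade[d]) for d in vern.decades},
    )

    gear_map = (
        read_gear_map(config.gear_map_path) if config.gear_map_path else None
    )
    gear = ind.gear_summary(included, gear_map)

    trend_results: dict[str, tr.TrendResult | None] = {}
    for name in ("WATL", "PisPla", "InvFis", "richness", "abundance"):
        try:
            trend_results[f"{name}_vs_decade"] = tr.series_trend(series[name])
        except (tr.InsufficientDataError, tr.UndefinedCorrelationError):
            trend_results[f"{name}_vs_decade"] = None

    summary = summarize_corpus(included)
    newspapers = pd.Series(summary.newspapers, dtype=float).sort_index()
    try:
        trend_results["richness_vs_newspapers"] = tr.pearson_trend(
            newspapers.reindex(series["richness"].as_series().index).to_numpy(),
            series["richness"].as_series().to_numpy(),
        )
    except (tr.InsufficientDataError, tr.UndefinedCorrelationError):
        trend_results["richness_vs_newspapers"] = None

    landings_cmp = None
    if config.landings_path is not None:
        landings = tr.read_landings_csv(config.landings_path)
        landings_cmp, landings_trend = tr.compare_with_landings(
            series["InvFis"], landings
        )
        trend_results["inv_fis_vs_landings"] = landings_trend

    unresolved = agg.unresolved_report(vern, registry)
    bundle = ReportBundle(
        included=list(included),
        ledger=ledger,
        vernacular_table=vern,
        scientific_table=sci,
        group_summary=groups,
        indicator_series=series,
        gear=gear,
        trends=trend_results,
        unresolved=unresolved,
        landings_comparison=landings_cmp,
    )
    write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write every output table as CSV plus the mirroring JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "exclusion_ledger.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["reason", "count"])
        for reason, n in sorted(bundle.ledger.counts.items()):
            writer.writerow([reason, n])

    for name, table in (
        ("decadal_vernacular", bundle.vernacular_table),
        ("decadal_scientific", bundle.scientific_table),
    ):
        table.counts.rename_axis("decade").to_csv(out / f"{name}_wide.csv")
        table.tidy().to_csv(out / f"{name}_tidy.csv", index=False)

    bundle.group_summary.as_frame().to_csv(out / "group_summary.csv", index=False)

    pd.concat(
        [s.tidy() for s in bundle.indicator_series.values()], ignore_index=True
    ).to_csv(out / "indicators.csv", index=False)

    trend_rows = []
    for name, res in sorted(bundle.trends.items()):
        row = {"trend": name}
        row.update(res.as_dict() if res is not None else {})
        trend_rows.append(row)
    pd.DataFrame(trend_rows).to_csv(out / "trends.csv", index=False)

    bundle.unresolved.to_csv(out / "unresolved_names.csv", index=False)
    if bundle.landings_comparison is not None:
        bundle.landings_comparison.to_csv(out / "landings_comparison.csv")

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.json_summary(), fh, indent=2, ensure_ascii=False, sort_keys=True)
        fh.write("\n")
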