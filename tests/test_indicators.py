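from collections import Counter

import pytest

import histofish as hf
from histofish.corpus import NewsItem, item_occurrences


def registry_from(specs):
    """specs: list of (vernacular, group, tl, guild)."""
    rows = []
    for vern, group, tl, guild in specs:
        rows.append(
            dict(vernacular_name=vern, scientific_name=vern.title(),
                 taxonomic_level="species", group=group,
                 habitat="marine",
                 native_status="non_native" if group == "non_native" else "native",
                 trophic_level=tl, trophic_guild=guild)
        )
    return hf.TaxonRegistry.from_rows(rows)


def table_from(reg, decade_mentions):
    """decade_mentions: {decade: [mention tuple per item]}."""
    items = []
    k = 0
    for decade, per_item in decade_mentions.items():
        for mentions in per_item:
            items.append(NewsItem(item_id=f"i{k}", newspaper="g",
                                  year=decade, mentions=tuple(mentions)))
            k += 1
    return hf.decadal_abundance(items, reg)


class TestWatl:
    def test_single_species(self):
        reg = registry_from([("tainha", "native_marine_fish", 3.0, "unknown")])
        table = table_from(reg, {1900: [("tainha",)]})
        assert hf.watl(table, reg, 1900) == pytest.approx(3.0)

    def test_weighted_mean(self):
        reg = registry_from(
            [("a", "native_marine_fish", 2.0, "unknown"),
             ("b", "native_marine_fish", 4.0, "unknown")]
        )
        table = table_from(
            reg, {1900: [("a", "b"), ("b",), ("b",)]}
        )  # a: n=1, b: n=3
        assert hf.watl(table, reg, 1900) == pytest.approx(3.5)

    def test_only_excluded_taxa_is_missing(self):
        reg = registry_from(
            [("tilapia", "non_native", 2.2, "unknown"),
             ("baleia", "sea_mammal", 3.4, "unknown")]
        )
        table = table_from(reg, {1900: [("tilapia", "baleia")]})
        assert hf.watl(table, reg, 1900) is None

    def test_missing_tl_excluded_from_weighting(self):
        rows = [
            dict(vernacular_name="a", scientific_name="A", taxonomic_level="species",
                 group="native_marine_fish", habitat="marine", native_status="native",
                 trophic_level=3.0, trophic_guild="unknown"),
            dict(vernacular_name="b", scientific_name="B", taxonomic_level="genus",
                 group="native_marine_fish", habitat="marine", native_status="native",
                 trophic_level="", trophic_guild="unknown"),
        ]
        reg = hf.TaxonRegistry.from_rows(rows)
        table = table_from(reg, {1900: [("a", "b"), ("b",)]})
        assert hf.watl(table, reg, 1900) == pytest.approx(3.0)

    def test_equal_counts_equal_plain_mean(self):
        tls = [2.2, 3.1, 4.4]
        reg = registry_from(
            [(f"f{i}", "native_marine_fish", tl, "unknown")
             for i, tl in enumerate(tls)]
        )
        table = table_from(reg, {1900: [("f0", "f1", "f2")] * 4})
        assert hf.watl(table, reg, 1900) == pytest.approx(sum(tls) / len(tls))

    def test_scale_invariance_of_weights(self):
        reg = registry_from(
            [("a", "native_marine_fish", 2.0, "unknown"),
             ("b", "native_marine_fish", 4.0, "unknown")]
        )
        once = table_from(reg, {1900: [("a",), ("b",), ("b",)]})
        tripled = table_from(reg, {1900: [("a",), ("b",), ("b",)] * 3})
        assert hf.watl(once, reg, 1900) == pytest.approx(
            hf.watl(tripled, reg, 1900)
        )

    def test_bounded_by_eligible_tls(self):
        cfg = hf.SyntheticConfig(
            decades=(1900, 1950, 2000),
            newspapers_per_decade=(3, 3, 3),
            items_per_decade=(50, 50, 50),
            trophic_decline_effect=0.4,
            seed=11,
        )
        items, reg, _ = hf.generate_corpus(cfg)
        included, _ = hf.filter_items(items)
        table = hf.decadal_abundance(included, reg)
        fish_tls = [t.trophic_level for t in cfg.taxon_pool
                    if t.group == "native_marine_fish"]
        series = hf.watl_series(table, reg)
        for value in series.values.values():
            if value is not None:
                assert min(fish_tls) <= value <= max(fish_tls)

    def test_mixed_fish_nonfish_key_contributes_to_neither(self):
        rows = [
            dict(vernacular_name="bicho", scientific_name="Fishus one",
                 taxonomic_level="species", group="native_marine_fish",
                 habitat="marine", native_status="native",
                 trophic_level=4.0, trophic_guild="unknown"),
            dict(vernacular_name="bicho", scientific_name="Crabus one",
                 taxonomic_level="species", group="crustacean",
                 habitat="marine", native_status="native",
                 trophic_level=2.5, trophic_guild="unknown"),
            dict(vernacular_name="peixe bom", scientific_name="Fishus two",
                 taxonomic_level="species", group="native_marine_fish",
                 habitat="marine", native_status="native",
                 trophic_level=3.0, trophic_guild="unknown"),
        ]
        reg = hf.TaxonRegistry.from_rows(rows)
        table = table_from(reg, {1900: [("bicho", "peixe bom")]})
        assert hf.watl(table, reg, 1900) == pytest.approx(3.0)
        inv = hf.inv_fis(table, reg, 1900)
        assert inv == 0.0  # "bicho" sits in neither numerator nor denominator


class TestRatios:
    @pytest.fixture()
    def guild_registry(self):
        return registry_from(
            [("anchova", "native_marine_fish", 4.5, "piscivore"),
             ("sardinha", "native_marine_fish", 3.0, "planktivore"),
             ("camarao", "crustacean", 2.7, "unknown"),
             ("ourico", "echinoderm", 2.5, "unknown")]
        )

    def test_pis_pla_ratios(self, guild_registry):
        table = table_from(
            guild_registry,
            {1900: [("anchova",)] * 4 + [("sardinha",)] * 2},
        )
        assert hf.pis_pla(table, guild_registry, 1900) == pytest.approx(2.0)

    def test_pis_pla_unity(self, guild_registry):
        table = table_from(
            guild_registry,
            {1900: [("anchova", "sardinha")] * 5},
        )
        assert hf.pis_pla(table, guild_registry, 1900) == pytest.approx(1.0)

    def test_pis_pla_missing_without_planktivores(self, guild_registry):
        table = table_from(guild_registry, {1900: [("anchova",)]})
        assert hf.pis_pla(table, guild_registry, 1900) is None

    def test_inv_fis(self, guild_registry):
        table = table_from(
            guild_registry,
            {1900: [("camarao",)] * 10 + [("anchova", "sardinha")] * 10},
        )
        assert hf.inv_fis(table, guild_registry, 1900) == pytest.approx(0.5)

    def test_inv_fis_zero_and_missing(self, guild_registry):
        fish_only = table_from(guild_registry, {1900: [("anchova",)] * 3})
        assert hf.inv_fis(fish_only, guild_registry, 1900) == 0.0
        inv_only = table_from(guild_registry, {1900: [("camarao",)] * 3})
        assert hf.inv_fis(inv_only, guild_registry, 1900) is None

    def test_echinoderm_switch(self, guild_registry):
        table = table_from(
            guild_registry,
            {1900: [("camarao",), ("ourico",)] + [("anchova",)] * 2},
        )
        with_ech = hf.inv_fis(table, guild_registry, 1900, include_echinoderms=True)
        without = hf.inv_fis(table, guild_registry, 1900, include_echinoderms=False)
        assert with_ech == pytest.approx(1.0)
        assert without == pytest.approx(0.5)


class TestGearSummary:
    def test_variant_rollup(self):
        gear_map = {"rede de arrasto": "rede", "rede de emalhe": "rede",
                    "tarrafa": "rede"}
        items = [
            NewsItem(item_id=f"i{k}", newspaper="g", year=1900,
                     gear_mentions=(g,))
            for k, g in enumerate(
                ["rede de arrasto", "rede de emalhe", "tarrafa"]
            )
        ]
        gs = hf.gear_summary(items, gear_map)
        assert gs.category_frequency == {"rede": 3}
        assert gs.variant_richness == {"rede": 3}
        assert gs.unmapped == {}

    def test_empty_gear(self):
        items = [NewsItem(item_id="a", newspaper="g", year=1900)]
        gs = hf.gear_summary(items)
        assert gs.category_frequency == {}
        assert gs.total_frequency == 0

    def test_unmapped_reported_not_dropped(self):
        items = [NewsItem(item_id="a", newspaper="g", year=1900,
                          gear_mentions=("dinamite",))]
        gs = hf.gear_summary(items, {"rede de arrasto": "rede"})
        assert gs.category_frequency == {"dinamite": 1}
        assert gs.unmapped == {"dinamite": 1}

    def test_matches_brute_force_recount(self):
        gear_map = {"rede de arrasto": "rede", "rede de emalhe": "rede"}
        for seed in range(5):
            cfg = hf.SyntheticConfig(
                decades=(1900, 1950),
                newspapers_per_decade=(3, 4),
                items_per_decade=(40, 40),
                seed=seed,
            )
            items, _, _ = hf.generate_corpus(cfg)
            included, _ = hf.filter_items(items)
            gs = hf.gear_summary(included, gear_map)
            brute = Counter()
            for item in included:
                _, gear_keys = item_occurrences(item)
                cats = {gear_map.get(g, g) for g in gear_keys}
                for c in cats:
                    brute[c] += 1
            assert gs.category_frequency == dict(brute)
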