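import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import histofish as hf
from histofish.taxon_registry import TaxonRecord, TrophicTable


class TestNormalizeName:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Tainha", "tainha"),
            ("camarão sete  barbas", "camarao sete barbas"),
            ("tainha-assú", "tainha-assu"),
            ("  Raia   Prego ", "raia prego"),
        ],
    )
    def test_examples(self, raw, expected):
        assert hf.normalize_name(raw) == expected

    @pytest.mark.parametrize("raw", ["", "   ", "\t\n"])
    def test_blank_rejected(self, raw):
        with pytest.raises(hf.InvalidNameError):
            hf.normalize_name(raw)

    @given(
        st.text(
            alphabet="abcãáéíóúç ABZ-àü", min_size=1, max_size=30
        ).filter(lambda s: s.strip())
    )
    @settings(derandomize=True)
    def test_idempotent(self, raw):
        once = hf.normalize_name(raw)
        assert hf.normalize_name(once) == once

    def test_hyphens_preserved(self):
        assert "-" in hf.normalize_name("tainha-assú")


class TestResolve:
    def test_one_folk_many_sci(self, stingray_registry):
        mapping = stingray_registry.resolve("raia prego")
        assert len(mapping.taxon_ids) == 4
        assert mapping.ambiguity is hf.Ambiguity.ONE_FOLK_MANY_SCI

    def test_many_folk_one_sci(self, stingray_registry):
        mapping = stingray_registry.resolve("tainhota")
        assert mapping.taxon_ids == frozenset({"Mugil liza"})
        assert mapping.ambiguity is hf.Ambiguity.MANY_FOLK_ONE_SCI

    def test_one_to_one(self, stingray_registry):
        mapping = stingray_registry.resolve("camarão")
        assert mapping.ambiguity is hf.Ambiguity.ONE_TO_ONE

    def test_unknown_returns_empty_and_logs(self, stingray_registry):
        mapping = stingray_registry.resolve("xyzfish")
        assert mapping.taxon_ids == frozenset()
        assert mapping.ambiguity is hf.Ambiguity.UNRESOLVED
        assert "xyzfish" in stingray_registry.unresolved_log

    def test_round_trip_every_variant(self, stingray_registry):
        for taxon_id in stingray_registry.taxa:
            for variant in stingray_registry.variants_of(taxon_id):
                assert taxon_id in stingray_registry.resolve(variant).taxon_ids

    def test_pure_function_of_key(self, stingray_registry):
        a = stingray_registry.resolve("raia prego")
        b = stingray_registry.resolve("raia prego")
        assert a == b


class TestValidation:
    def test_trophic_level_bounds_rejected(self):
        with pytest.raises(hf.RegistryValidationError):
            TaxonRecord("x", "x", hf.TaxonomicLevel.SPECIES,
                        hf.Group.NATIVE_MARINE_FISH, trophic_level=5.5)

    def test_fish_guild_on_invertebrate_rejected(self):
        with pytest.raises(hf.RegistryValidationError):
            TaxonRecord("x", "x", hf.TaxonomicLevel.FAMILY,
                        hf.Group.CRUSTACEAN, trophic_guild=hf.Guild.PISCIVORE)

    def test_missing_dictionary_column(self, tmp_path):
        p = tmp_path / "dict.csv"
        p.write_text("vernacular_name,scientific_name\na,b\n", encoding="utf-8")
        with pytest.raises(hf.RegistryValidationError):
            hf.TaxonRegistry.from_csv(p)


class TestTrophicAssignment:
    @pytest.fixture()
    def table(self):
        return TrophicTable(
            [
                {"species": "Mugil liza", "genus": "Mugil", "family": "Mugilidae",
                 "trophic_level": 2.5},
                {"species": "Mugil curema", "genus": "Mugil", "family": "Mugilidae",
                 "trophic_level": 2.1},
                {"species": "Cynoscion acoupa", "genus": "Cynoscion",
                 "family": "Sciaenidae", "trophic_level": 3.2},
                {"species": "Cynoscion leiarchus", "genus": "Cynoscion",
                 "family": "Sciaenidae", "trophic_level": 3.6},
            ]
        )

    def test_species_lookup(self, table):
        rec = TaxonRecord("Mugil liza", "Mugil liza", hf.TaxonomicLevel.SPECIES,
                          hf.Group.NATIVE_MARINE_FISH)
        assert hf.assign_trophic_level(rec, table) == 2.5

    def test_genus_mean_of_members(self, table):
        rec = TaxonRecord("Cynoscion sp.", "Cynoscion sp.",
                          hf.TaxonomicLevel.GENUS, hf.Group.NATIVE_MARINE_FISH)
        assert hf.assign_trophic_level(rec, table) == pytest.approx(3.4)

    def test_family_mean_of_members(self, table):
        rec = TaxonRecord("Mugilidae", "Mugilidae", hf.TaxonomicLevel.FAMILY,
                          hf.Group.NATIVE_MARINE_FISH)
        assert hf.assign_trophic_level(rec, table) == pytest.approx(2.3)

    def test_no_members_is_missing(self, table):
        rec = TaxonRecord("Ariidae", "Ariidae", hf.TaxonomicLevel.FAMILY,
                          hf.Group.NATIVE_MARINE_FISH)
        assert hf.assign_trophic_level(rec, table) is None

    def test_out_of_range_tl_rejected_at_load(self):
        with pytest.raises(hf.RegistryValidationError):
            TrophicTable([{"species": "X y", "trophic_level": 1.5}])

    def test_fallback_mean_matches_brute_force(self):
        """Genus/family averaging equals an independent recount on random
        species tables."""
        rng = random.Random(7)
        for _ in range(20):
            genera = [f"Genus{g}" for g in range(rng.randint(1, 4))]
            rows = []
            for g in genera:
                for s in range(rng.randint(1, 5)):
                    rows.append(
                        {"species": f"{g} sp{s}", "genus": g,
                         "family": f"Fam{g}",
                         "trophic_level": round(rng.uniform(2.0, 5.0), 2)}
                    )
            table = TrophicTable(rows)
            for g in genera:
                member_tls = [r["trophic_level"] for r in rows if r["genus"] == g]
                expected = sum(member_tls) / len(member_tls)
                rec = TaxonRecord(g, g, hf.TaxonomicLevel.GENUS,
                                  hf.Group.NATIVE_MARINE_FISH)
                assert hf.assign_trophic_level(rec, table) == pytest.approx(expected)


class TestLoaders:
    def test_csv_round_trip(self, tmp_path):
        p = tmp_path / "dict.csv"
        p.write_text(
            "vernacular_name,scientific_name,taxonomic_level,group,habitat,"
            "native_status,trophic_level,trophic_guild\n"
            "tainha,Mugil liza,species,native_marine_fish,estuarine,native,"
            "2.5,planktivore\n",
            encoding="utf-8",
        )
        reg = hf.TaxonRegistry.from_csv(p)
        assert reg.resolve("Tainha").taxon_ids == frozenset({"Mugil liza"})

    def test_xlsx_with_column_map(self, tmp_path):
        openpyxl = pytest.importorskip("openpyxl")
        wb = openpyxl.Workbook()
        ws = wb.active
        ws.append(["Common name", "Species", "Level", "Group", "Habitat",
                   "Status", "TL", "Guild"])
        ws.append(["garoupa", "Epinephelus marginatus", "species",
                   "native_marine_fish", "marine", "native", 4.1, "piscivore"])
        path = tmp_path / "dict.xlsx"
        wb.save(path)
        reg = hf.TaxonRegistry.from_xlsx(
            path,
            column_map={
                "vernacular_name": "Common name", "scientific_name": "Species",
                "taxonomic_level": "Level", "group": "Group",
                "habitat": "Habitat", "native_status": "Status",
                "trophic_level": "TL", "trophic_guild": "Guild",
            },
        )
        rec = reg.resolve_taxa("garoupa")[0]
        assert rec.trophic_level == 4.1
        assert rec.trophic_guild is hf.Guild.PISCIVORE
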