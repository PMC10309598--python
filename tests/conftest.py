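import pytest

import histofish as hf

# Group composition profile of the published corpus: per group
# (abundance n, vernacular richness v, scientific richness s), with the
# four best-documented folk names pinned to their exact counts.
STUDY_PROFILES = (
    hf.GroupProfile("native_marine_fish", 1041, 192, 143),
    hf.GroupProfile("crustacean", 181, 17, 9),
    hf.GroupProfile("freshwater", 111, 22, 15),
    hf.GroupProfile("mollusc", 99, 11, 9),
    hf.GroupProfile("sea_mammal", 81, 9, 7),
    hf.GroupProfile("echinoderm", 2, 2, 2),
    hf.GroupProfile("reptile", 7, 1, 1),
    hf.GroupProfile("bird", 1, 1, 1),
    hf.GroupProfile("non_native", 132, 22, 16),
)

STUDY_NAMED_KEYS = {
    "tainha": ("native_marine_fish", 187),
    "camarao": ("crustacean", 154),
    "anchova": ("native_marine_fish", 63),
    "bagre": ("native_marine_fish", 47),
}


@pytest.fixture(scope="session")
def study_corpus():
    """Deterministic corpus matching the published group composition."""
    return hf.structured_corpus(STUDY_PROFILES, STUDY_NAMED_KEYS)


@pytest.fixture()
def stingray_registry():
    """Small registry with the classic folk-name ambiguities:
    one folk name over four stingray genera, several folk names on one
    mullet species, plus an unambiguous shrimp family."""
    rows = []
    for genus in ("Hypanus sp.", "Dasyatis sp.", "Fontitrygon sp.", "Bathytoshia sp."):
        rows.append(
            dict(vernacular_name="raia prego", scientific_name=genus,
                 taxonomic_level="genus", group="native_marine_fish",
                 habitat="marine", native_status="native",
                 trophic_level=3.5, trophic_guild="other")
        )
    for folk in ("tainha", "tainhota", "tanhota", "tainha-assú"):
        rows.append(
            dict(vernacular_name=folk, scientific_name="Mugil liza",
                 taxonomic_level="species", group="native_marine_fish",
                 habitat="estuarine", native_status="native",
                 trophic_level=2.5, trophic_guild="planktivore")
        )
    rows.append(
        dict(vernacular_name="camarão", scientific_name="Penaeidae",
             taxonomic_level="family", group="crustacean",
             habitat="marine", native_status="native",
             trophic_level=2.7, trophic_guild="unknown")
    )
    return hf.TaxonRegistry.from_rows(rows)
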