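"""Taxon dictionary: folk-name normalisation, resolution and trophic metadata.

Historical newspapers report marine animals almost exclusively under
vernacular (folk) names.  One folk name may cover several scientific taxa
("raia prego" = four stingray genera) and one species may carry several folk
names ("tainha", "tainhota", "tanhota" = *Mugil liza*).  This module holds
the dictionary that links the two naming systems, classifies the ambiguity
of every link, and assigns trophic levels with a genus/family fallback: a
taxon identified only to genus or family receives the arithmetic mean of the
trophic levels of its listed member species.
"""

from __future__ import annotations

import csv
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger("histofish")

TL_MIN = 2.0
TL_MAX = 5.0


class InvalidNameError(ValueError):
    """Raised for empty or whitespace-only vernacular names."""


class RegistryValidationError(ValueError):
    """Raised when a dictionary row violates the schema at load time."""


class TaxonomicLevel(str, Enum):
    SPECIES = "species"
    GENUS = "genus"
    FAMILY = "family"
    ORDER = "order"
    UNRESOLVED = "unresolved"


class Group(str, Enum):
    NATIVE_MARINE_FISH = "native_marine_fish"
    CRUSTACEAN = "crustacean"
    MOLLUSC = "mollusc"
    ECHINODERM = "echinoderm"
    SEA_MAMMAL = "sea_mammal"
    REPTILE = "reptile"
    BIRD = "bird"
    FRESHWATER = "freshwater"
    NON_NATIVE = "non_native"


#: Groups counted as (native marine) invertebrates in the Inv/Fis ratio.
INVERTEBRATE_GROUPS = frozenset(
    {Group.CRUSTACEAN, Group.MOLLUSC, Group.ECHINODERM}
)

#: Groups excluded from every trophic indicator (WATL, Pis/Pla, Inv/Fis):
#: non-native and freshwater organisms, reptiles, birds and sea mammals.
INDICATOR_EXCLUDED_GROUPS = frozenset(
    {Group.NON_NATIVE, Group.FRESHWATER, Group.REPTILE, Group.BIRD, Group.SEA_MAMMAL}
)


class Guild(str, Enum):
    PISCIVORE = "piscivore"
    PLANKTIVORE = "planktivore"
    OTHER = "other"
    UNKNOWN = "unknown"


class Habitat(str, Enum):
    MARINE = "marine"
    ESTUARINE = "estuarine"
    FRESHWATER = "freshwater"
    MIXED = "mixed"


class Ambiguity(str, Enum):
    ONE_TO_ONE = "one_to_one"
    ONE_FOLK_MANY_SCI = "one_folk_many_sci"
    MANY_FOLK_ONE_SCI = "many_folk_one_sci"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class TaxonRecord:
    """One resolvable taxon with its group, habitat and trophic metadata.

    ``trophic_level`` is the adult-diet trophic level where known, in
    [2.0, 5.0]; ``None`` marks a taxon whose TL must come from the
    genus/family fallback or stay missing.  Piscivore/planktivore guilds are
    fish-based, so they are only legal on native marine fish.
    """

    taxon_id: str
    scientific_name: str
    taxonomic_level: TaxonomicLevel
    group: Group
    trophic_level: float | None = None
    trophic_guild: Guild = Guild.UNKNOWN
    habitat: Habitat = Habitat.MARINE

    def __post_init__(self) -> None:
        if self.trophic_level is not None and not (
            TL_MIN <= self.trophic_level <= TL_MAX
        ):
            raise RegistryValidationError(
                f"trophic level {self.trophic_level} for {self.scientific_name!r} "
                f"outside [{TL_MIN}, {TL_MAX}]"
            )
        if (
            self.trophic_guild in (Guild.PISCIVORE, Guild.PLANKTIVORE)
            and self.group is not Group.NATIVE_MARINE_FISH
        ):
            raise RegistryValidationError(
                f"guild {self.trophic_guild.value!r} on non-fish taxon "
                f"{self.scientific_name!r}: Pis/Pla guilds are fish-based"
            )


@dataclass(frozen=True)
class NameMapping:
    """A vernacular key with the set of taxa it maps to and its ambiguity class."""

    vernacular_key: str
    taxon_ids: frozenset[str]
    ambiguity: Ambiguity


_WS = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Normalise a vernacular name into a canonical lookup key.

    Lowercases, strips diacritics (historical spellings vary:
    "tainha-assú" vs "tainha-assu"), collapses internal whitespace and trims.
    Hyphens are preserved because they distinguish compound folk names.
    Idempotent.

    Raises :class:`InvalidNameError` on empty/whitespace-only input.
    """
    if raw is None or not raw.strip():
        raise InvalidNameError(f"empty or whitespace-only vernacular name: {raw!r}")
    decomposed = unicodedata.normalize("NFKD", raw)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return _WS.sub(" ", stripped).strip().lower()


#: Canonical dictionary columns, one row per (vernacular, scientific) pair.
DICTIONARY_COLUMNS = (
    "vernacular_name",
    "scientific_name",
    "taxonomic_level",
    "group",
    "habitat",
    "native_status",
    "trophic_level",
    "trophic_guild",
)


class TaxonRegistry:
    """Holds taxon records and the vernacular↔scientific name mappings."""

    def __init__(self) -> None:
        self._taxa: dict[str, TaxonRecord] = {}
        self._vern_to_taxa: dict[str, set[str]] = {}
        self._taxon_to_verns: dict[str, set[str]] = {}
        self.unresolved_log: list[str] = []

    # -- construction -------------------------------------------------

    def add(self, vernacular_name: str, record: TaxonRecord) -> None:
        key = normalize_name(vernacular_name)
        existing = self._taxa.get(record.taxon_id)
        if existing is not None and existing != record:
            raise RegistryValidationError(
                f"conflicting records for taxon id {record.taxon_id!r}"
            )
        self._taxa[record.taxon_id] = record
        self._vern_to_taxa.setdefault(key, set()).add(record.taxon_id)
        self._taxon_to_verns.setdefault(record.taxon_id, set()).add(key)

    @classmethod
    def from_rows(cls, rows: Iterable[Mapping[str, object]]) -> "TaxonRegistry":
        """Build a registry from canonical-schema dictionary rows.

        ``native_status`` ∈ {native, non_native}; a non-native row is forced
        into the ``non_native`` group so every indicator's exclusion filter
        catches it.
        """
        reg = cls()
        for i, row in enumerate(rows):
            try:
                group = Group(str(row["group"]))
                status = str(row.get("native_status", "native")).strip().lower()
                if status == "non_native":
                    group = Group.NON_NATIVE
                tl_raw = row.get("trophic_level", "")
                tl = None if tl_raw in ("", None) else float(tl_raw)  # type: ignore[arg-type]
                record = TaxonRecord(
                    taxon_id=str(row["scientific_name"]),
                    scientific_name=str(row["scientific_name"]),
                    taxonomic_level=TaxonomicLevel(str(row["taxonomic_level"])),
                    group=group,
                    trophic_level=tl,
                    trophic_guild=Guild(str(row.get("trophic_guild", "unknown") or "unknown")),
                    habitat=Habitat(str(row.get("habitat", "marine") or "marine")),
                )
                reg.add(str(row["vernacular_name"]), record)
            except (KeyError, ValueError) as exc:
                raise RegistryValidationError(
                    f"taxon dictionary row {i}: {exc}"
                ) from exc
        return reg

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None) -> "TaxonRegistry":
        """Load the canonical TSV/CSV dictionary (UTF-8, header row)."""
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter=sep)
            missing = set(DICTIONARY_COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise RegistryValidationError(
                    f"{path}: missing dictionary columns {sorted(missing)}"
                )
            return cls.from_rows(reader)

    @classmethod
    def from_xlsx(
        cls,
        path: str | Path,
        column_map: Mapping[str, str],
        sheet: str | int = 0,
    ) -> "TaxonRegistry":
        """Load a spreadsheet dictionary via a user-supplied column map.

        ``column_map`` maps canonical column names to spreadsheet header
        names, so externally curated dictionaries with arbitrary layouts can
        be mounted onto the canonical schema.
        """
        from openpyxl import load_workbook

        wb = load_workbook(filename=str(path), read_only=True, data_only=True)
        ws = wb[wb.sheetnames[sheet]] if isinstance(sheet, int) else wb[sheet]
        rows_iter = ws.iter_rows(values_only=True)
        header = [str(h) if h is not None else "" for h in next(rows_iter)]
        idx = {}
        for canonical in DICTIONARY_COLUMNS:
            source = column_map.get(canonical, canonical)
            if source in header:
                idx[canonical] = header.index(source)
        rows = []
        for raw in rows_iter:
            if raw is None or all(v is None for v in raw):
                continue
            rows.append(
                {
                    col: ("" if raw[j] is None else raw[j])
                    for col, j in idx.items()
                }
            )
        return cls.from_rows(rows)

    # -- queries ------------------------------------------------------

    def __len__(self) -> int:
        return len(self._taxa)

    @property
    def taxa(self) -> dict[str, TaxonRecord]:
        return dict(self._taxa)

    @property
    def vernacular_keys(self) -> set[str]:
        return set(self._vern_to_taxa)

    def get(self, taxon_id: str) -> TaxonRecord | None:
        return self._taxa.get(taxon_id)

    def variants_of(self, taxon_id: str) -> set[str]:
        """All normalised vernacular keys pointing at a taxon."""
        return set(self._taxon_to_verns.get(taxon_id, set()))

    def resolve(self, vernacular_key: str) -> NameMapping:
        """Resolve a normalised vernacular key to its taxon set.

        Unknown keys are a data condition, not an error: they return an
        empty set with ``unresolved`` ambiguity and are accumulated in
        ``unresolved_log`` for the end-of-run report.
        """
        key = normalize_name(vernacular_key)
        ids = self._vern_to_taxa.get(key)
        if not ids:
            self.unresolved_log.append(key)
            logger.debug("unresolved vernacular name: %s", key)
            return NameMapping(key, frozenset(), Ambiguity.UNRESOLVED)
        if len(ids) > 1:
            amb = Ambiguity.ONE_FOLK_MANY_SCI
        else:
            (only,) = ids
            amb = (
                Ambiguity.ONE_TO_ONE
                if len(self._taxon_to_verns[only]) == 1
                else Ambiguity.MANY_FOLK_ONE_SCI
            )
        return NameMapping(key, frozenset(ids), amb)

    def resolve_taxa(self, vernacular_key: str) -> list[TaxonRecord]:
        """Records mapped by a key, sorted by taxon id for determinism."""
        mapping = self.resolve(vernacular_key)
        return sorted(
            (self._taxa[t] for t in mapping.taxon_ids), key=lambda r: r.taxon_id
        )

    def key_trophic_level(self, vernacular_key: str) -> float | None:
        """Mean TL over the taxa a key maps to, ignoring missing TLs.

        One folk name covering several taxa contributes the mean of their
        trophic levels; missing if no mapped taxon has a TL.
        """
        tls = [
            r.trophic_level
            for r in self.resolve_taxa(vernacular_key)
            if r.trophic_level is not None
        ]
        return sum(tls) / len(tls) if tls else None


class TrophicTable:
    """Species-level trophic levels with genus and family membership.

    Backs the fallback rule: a genus- or family-level taxon receives the
    arithmetic mean of the trophic levels of its listed member species.
    """

    def __init__(self, rows: Iterable[Mapping[str, object]]) -> None:
        self._species_tl: dict[str, float] = {}
        self._genus_members: dict[str, list[float]] = {}
        self._family_members: dict[str, list[float]] = {}
        for i, row in enumerate(rows):
            species = str(row["species"]).strip()
            tl = float(row["trophic_level"])  # type: ignore[arg-type]
            if not (TL_MIN <= tl <= TL_MAX):
                raise RegistryValidationError(
                    f"trophic table row {i}: TL {tl} for {species!r} "
                    f"outside [{TL_MIN}, {TL_MAX}]"
                )
            self._species_tl[species] = tl
            genus = str(row.get("genus", "") or "").strip() or species.split()[0]
            family = str(row.get("family", "") or "").strip()
            self._genus_members.setdefault(genus, []).append(tl)
            if family:
                self._family_members.setdefault(family, []).append(tl)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str | None = None) -> "TrophicTable":
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        with open(path, encoding="utf-8", newline="") as fh:
            return cls(csv.DictReader(fh, delimiter=sep))

    def species_tl(self, species: str) -> float | None:
        return self._species_tl.get(species)

    def assign(self, taxon: TaxonRecord) -> float | None:
        """Trophic level for a taxon, with taxonomic-level fallback.

        Species-level taxa take their table value directly; genus- and
        family-level taxa take the mean over their member species; taxa
        with no member entries return ``None`` (excluded from WATL).
        """
        if taxon.taxonomic_level is TaxonomicLevel.SPECIES:
            return self._species_tl.get(taxon.scientific_name)
        name = taxon.scientific_name.removesuffix(" sp.").strip()
        if taxon.taxonomic_level is TaxonomicLevel.GENUS:
            members = self._genus_members.get(name)
        elif taxon.taxonomic_level is TaxonomicLevel.FAMILY:
            members = self._family_members.get(name)
        else:
            members = None
        if not members:
            return None
        return sum(members) / len(members)


def assign_trophic_level(taxon: TaxonRecord, tl_table: TrophicTable) -> float | None:
    """Functional wrapper around :meth:`TrophicTable.assign`."""
    return tl_table.assign(taxon)
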