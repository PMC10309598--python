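"""Seeded synthetic corpora with known trophic structure.

The generator emulates the shape of a historical-newspaper occurrence
dataset: per-decade item counts that track archive size (more digitised
newspapers → more items), items carrying short lists of folk-name taxon
mentions drawn from a pool with known trophic levels, planted duplicates
and advertisements to exercise the inclusion filter, and a controllable
decadal trophic-decline effect δ.

Sampling model.  Decade *j* has standardised index t_j ∈ [−1, 1].  Taxon
*i* gets log-weight  log w_i = log b_i − δ·TL_i·t_j , turned into category
probabilities p_i(t) by softmax: δ > 0 shifts sampling mass from high- to
low-trophic-level taxa through time, δ = 0 is exchangeable across decades.
Each item draws a Poisson(λ) number of mentions with those category
probabilities, which thins into independent per-taxon Poisson(λ·p_i)
mention counts, so after the per-item presence cap each taxon is present
in an item with probability  q_i(t) = 1 − exp(−λ·p_i(t))  independently.
Because occurrences are counted per vernacular key and a taxon's mentions
split uniformly over its V_i folk-name variants, the expected per-item
occurrence mass of taxon i is  w_i(t) = V_i·(1 − exp(−λ·p_i(t)/V_i)),
giving the decadal WATL a closed-form oracle:

    E[WATL_j] ≈ Σ_i TL_i·w_i(t_j) / Σ_i w_i(t_j)

(the ratio of expectations; the pipeline estimate converges to it as the
per-decade item count grows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import NewsItem
from .taxon_registry import TaxonRegistry


class InvalidConfigError(ValueError):
    """Raised on an unusable generator configuration."""


@dataclass(frozen=True)
class SyntheticTaxon:
    """One pool entry: folk-name variants and trophic metadata."""

    vernacular_variants: tuple[str, ...]
    scientific_name: str
    taxonomic_level: str
    group: str
    trophic_level: float
    trophic_guild: str = "unknown"
    habitat: str = "marine"
    native_status: str = "native"
    base_weight: float = 1.0


# A realistic southern-Brazil coastal pool: folk names spanning native
# marine fish across guilds and trophic levels, invertebrates, a sea
# mammal, a reptile, plus freshwater and non-native taxa so every
# exclusion rule is exercised.
DEFAULT_TAXON_POOL: tuple[SyntheticTaxon, ...] = (
    SyntheticTaxon(("tainha", "tainhota", "tanhota"), "Mugil liza", "species",
                   "native_marine_fish", 2.5, "planktivore", "estuarine"),
    SyntheticTaxon(("parati",), "Mugil curema", "species",
                   "native_marine_fish", 2.1, "planktivore", "estuarine"),
    SyntheticTaxon(("sardinha",), "Sardinella brasiliensis", "species",
                   "native_marine_fish", 3.0, "planktivore"),
    SyntheticTaxon(("anchova", "enchova"), "Pomatomus saltatrix", "species",
                   "native_marine_fish", 4.5, "piscivore"),
    SyntheticTaxon(("garoupa",), "Epinephelus marginatus", "species",
                   "native_marine_fish", 4.1, "piscivore"),
    SyntheticTaxon(("robalo",), "Centropomus parallelus", "species",
                   "native_marine_fish", 4.0, "piscivore"),
    SyntheticTaxon(("pescada",), "Cynoscion sp.", "genus",
                   "native_marine_fish", 4.2, "piscivore"),
    SyntheticTaxon(("cacao", "tubarao", "mangona"), "Carcharhinidae", "family",
                   "native_marine_fish", 4.5, "piscivore"),
    SyntheticTaxon(("corvina",), "Micropogonias furnieri", "species",
                   "native_marine_fish", 3.6, "other", "estuarine"),
    SyntheticTaxon(("bagre",), "Ariidae", "family",
                   "native_marine_fish", 3.4, "other", "estuarine"),
    SyntheticTaxon(("camarao", "camarao sete barbas"), "Penaeidae", "family",
                   "crustacean", 2.7),
    SyntheticTaxon(("siri",), "Callinectes sp.", "genus", "crustacean", 2.6),
    SyntheticTaxon(("ostra",), "Crassostrea rhizophorae", "species",
                   "mollusc", 2.0, "unknown", "estuarine"),
    SyntheticTaxon(("marisco",), "Perna perna", "species", "mollusc", 2.1),
    SyntheticTaxon(("lula",), "Doryteuthis sp.", "genus", "mollusc", 3.7),
    SyntheticTaxon(("ourico do mar",), "Echinometra lucunter", "species",
                   "echinoderm", 2.5),
    SyntheticTaxon(("baleia",), "Mysticeti", "order", "sea_mammal", 3.4),
    SyntheticTaxon(("tartaruga",), "Chelonia mydas", "species", "reptile", 2.4),
    SyntheticTaxon(("traira",), "Hoplias malabaricus", "species",
                   "freshwater", 4.0, "unknown", "freshwater"),
    SyntheticTaxon(("tilapia",), "Oreochromis niloticus", "species",
                   "non_native", 2.2, "unknown", "freshwater", "non_native"),
)

#: Default per-decade newspaper counts: the archive grows through time,
#: emulating the digitised-corpus-size bias.
DEFAULT_DECADES = tuple(range(1870, 2020, 10))  # 15 decades
DEFAULT_NEWSPAPERS = (2, 3, 4, 6, 8, 10, 13, 16, 20, 25, 30, 36, 43, 51, 60)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults define the standard study corpus.

    ``items_per_decade=None`` derives item counts proportional to
    ``newspapers_per_decade`` (``items_per_newspaper`` each), reproducing
    the sampling-effort coupling; an explicit tuple fixes them instead.
    ``trophic_decline_effect`` is the δ of the sampling model (0 = no
    trend).
    """

    decades: tuple[int, ...] = DEFAULT_DECADES
    newspapers_per_decade: tuple[int, ...] = DEFAULT_NEWSPAPERS
    items_per_decade: tuple[int, ...] | None = (200,) * len(DEFAULT_DECADES)
    items_per_newspaper: float = 4.0
    taxon_pool: tuple[SyntheticTaxon, ...] = DEFAULT_TAXON_POOL
    mention_rate: float = 2.5
    trophic_decline_effect: float = 0.0
    duplicate_rate: float = 0.05
    advertisement_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.taxon_pool:
            raise InvalidConfigError("empty taxon pool")
        if not self.decades:
            raise InvalidConfigError("no decades configured")
        if len(self.newspapers_per_decade) != len(self.decades):
            raise InvalidConfigError("newspapers_per_decade length mismatch")
        if self.items_per_decade is not None and len(self.items_per_decade) != len(
            self.decades
        ):
            raise InvalidConfigError("items_per_decade length mismatch")
        for p in (self.duplicate_rate, self.advertisement_rate):
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"rate {p} outside [0, 1]")
        if self.mention_rate <= 0:
            raise InvalidConfigError("mention_rate must be positive")

    def resolved_items_per_decade(self) -> tuple[int, ...]:
        if self.items_per_decade is not None:
            return tuple(self.items_per_decade)
        return tuple(
            max(1, int(round(n * self.items_per_newspaper)))
            for n in self.newspapers_per_decade
        )


def decade_index(config: SyntheticConfig) -> np.ndarray:
    """Standardised decade index t ∈ [−1, 1] (0 for a single decade)."""
    d = len(config.decades)
    if d == 1:
        return np.zeros(1)
    j = np.arange(d, dtype=float)
    half = (d - 1) / 2.0
    return (j - half) / half


def sampling_probabilities(config: SyntheticConfig) -> np.ndarray:
    """Per-decade softmax category probabilities, shape (decades, taxa)."""
    tls = np.array([t.trophic_level for t in config.taxon_pool])
    base = np.log([t.base_weight for t in config.taxon_pool])
    t = decade_index(config)
    logw = base[None, :] - config.trophic_decline_effect * tls[None, :] * t[:, None]
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def presence_probabilities(config: SyntheticConfig) -> np.ndarray:
    """Per-item presence probability q_i(t) = 1 − exp(−λ·p_i(t))."""
    return 1.0 - np.exp(-config.mention_rate * sampling_probabilities(config))


def occurrence_weights(config: SyntheticConfig) -> np.ndarray:
    """Expected per-item occurrence mass per taxon, shape (decades, taxa).

    Counting happens at the vernacular-key level: a taxon's Poisson(λ·p_i)
    mention stream splits uniformly over its V_i folk-name variants into
    independent Poisson(λ·p_i/V_i) streams, each capped at presence, so
    the expected occurrence mass is  V_i · (1 − exp(−λ·p_i/V_i)).
    """
    p = sampling_probabilities(config)
    v = np.array([len(t.vernacular_variants) for t in config.taxon_pool])
    return v * (1.0 - np.exp(-config.mention_rate * p / v))


def expected_watl(config: SyntheticConfig, decade: int) -> float:
    """Closed-form expected WATL for one decade under the generator.

    Restricted, like the pipeline, to native marine fish; the weights are
    the expected per-item occurrence masses (ratio of expectations — the
    pipeline estimate converges to this as the per-decade item count
    grows).
    """
    j = config.decades.index(decade)
    w = occurrence_weights(config)[j]
    fish = np.array(
        [t.group == "native_marine_fish" for t in config.taxon_pool]
    )
    tls = np.array([t.trophic_level for t in config.taxon_pool])
    den = w[fish].sum()
    if den == 0:
        raise InvalidConfigError("no native marine fish in taxon pool")
    return float((tls[fish] * w[fish]).sum() / den)


def registry_from_pool(pool: tuple[SyntheticTaxon, ...]) -> TaxonRegistry:
    """Materialise the pool as a taxon dictionary registry."""
    rows = []
    for t in pool:
        for v in t.vernacular_variants:
            rows.append(
                {
                    "vernacular_name": v,
                    "scientific_name": t.scientific_name,
                    "taxonomic_level": t.taxonomic_level,
                    "group": t.group,
                    "habitat": t.habitat,
                    "native_status": t.native_status,
                    "trophic_level": t.trophic_level,
                    "trophic_guild": t.trophic_guild,
                }
            )
    return TaxonRegistry.from_rows(rows)


def _decade_rng(seed: int, decade: int) -> np.random.Generator:
    # per-decade substream keyed by the decade label: adding decades to a
    # config never perturbs the draws of earlier ones
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(decade)]))


DEFAULT_GEAR_POOL = (
    "rede", "rede de arrasto", "rede de emalhe", "tarrafa", "anzol", "espinhel",
)


@dataclass
class TruthRecord:
    """What the generator actually planted, for parameter-recovery tests."""

    trophic_decline_effect: float
    seed: int
    decades: tuple[int, ...]
    expected_watl: dict[int, float]
    sampling_probabilities: dict[int, list[float]]
    presence_probabilities: dict[int, list[float]]
    taxon_order: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "trophic_decline_effect": self.trophic_decline_effect,
            "seed": self.seed,
            "decades": list(self.decades),
            "expected_watl": {str(d): v for d, v in self.expected_watl.items()},
            "sampling_probabilities": {
                str(d): v for d, v in self.sampling_probabilities.items()
            },
            "presence_probabilities": {
                str(d): v for d, v in self.presence_probabilities.items()
            },
            "taxon_order": list(self.taxon_order),
        }


@dataclass(frozen=True)
class GroupProfile:
    """Exact per-group targets for a structured corpus.

    ``abundance`` mentions spread over ``vernacular_richness`` distinct folk
    keys mapping onto ``scientific_richness`` distinct taxa.  Requires
    abundance ≥ vernacular ≥ scientific richness (each key carries at least
    one mention, each taxon at least one key).
    """

    group: str
    abundance: int
    vernacular_richness: int
    scientific_richness: int

    def __post_init__(self) -> None:
        if not (
            self.abundance >= self.vernacular_richness >= self.scientific_richness >= 1
        ):
            raise InvalidConfigError(
                f"group {self.group}: need abundance >= vernacular >= "
                f"scientific richness >= 1"
            )


_GROUP_HABITAT = {"freshwater": "freshwater", "non_native": "freshwater"}


def structured_corpus(
    profiles: tuple[GroupProfile, ...],
    named_keys: dict[str, tuple[str, int]] | None = None,
    decade: int = 1900,
) -> tuple[list[NewsItem], TaxonRegistry]:
    """Build a deterministic corpus hitting exact group composition targets.

    ``named_keys`` pins specific vernacular keys to exact mention counts,
    e.g. ``{"tainha": ("native_marine_fish", 187)}``; they count against
    their group's abundance and richness budgets.  Every mention becomes its
    own one-mention item (so occurrence counts equal mention counts), all in
    one decade.  No randomness: useful as a fixture with known marginals.
    """
    named_keys = dict(named_keys or {})
    rows = []
    key_counts: list[tuple[str, int]] = []
    for prof in profiles:
        named = [
            (k, n) for k, (g, n) in sorted(named_keys.items()) if g == prof.group
        ]
        n_named = sum(n for _, n in named)
        v_rest = prof.vernacular_richness - len(named)
        n_rest = prof.abundance - n_named
        if v_rest < 0 or n_rest < v_rest:
            raise InvalidConfigError(
                f"group {prof.group}: named keys exceed the group budget"
            )
        keys = [k for k, _ in named] + [
            f"{prof.group.replace('_', ' ')} {i:03d}" for i in range(v_rest)
        ]
        counts = [n for _, n in named] + [1] * v_rest
        if v_rest:
            counts[len(named)] += n_rest - v_rest  # dump remainder on first
        sci = [
            f"{prof.group.title().replace('_', '')}us species{j:03d}"
            for j in range(prof.scientific_richness)
        ]
        for i, key in enumerate(keys):
            rows.append(
                {
                    "vernacular_name": key,
                    "scientific_name": sci[i % len(sci)],
                    "taxonomic_level": "species",
                    "group": prof.group,
                    "habitat": _GROUP_HABITAT.get(prof.group, "marine"),
                    "native_status": (
                        "non_native" if prof.group == "non_native" else "native"
                    ),
                    "trophic_level": 3.0,
                    "trophic_guild": "unknown",
                }
            )
        key_counts.extend(zip(keys, counts))
    registry = TaxonRegistry.from_rows(rows)
    items: list[NewsItem] = []
    i = 0
    for key, count in key_counts:
        for _ in range(count):
            items.append(
                NewsItem(
                    item_id=f"fx-{i:05d}",
                    newspaper="gazeta",
                    year=decade,
                    mentions=(key,),
                )
            )
            i += 1
    return items, registry


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[list[NewsItem], TaxonRegistry, TruthRecord]:
    """Generate a seeded corpus with its registry and truth record.

    Per-decade item counts are exactly the configured values (duplicates
    and advertisements are planted among them, not added on top), so
    inclusion rates are the only stochastic corpus-size component.
    Deterministic given the config seed.
    """
    p = sampling_probabilities(config)
    q = presence_probabilities(config)
    items_per_decade = config.resolved_items_per_decade()
    pool = config.taxon_pool
    n_taxa = len(pool)
    items: list[NewsItem] = []
    for j, decade in enumerate(config.decades):
        rng = _decade_rng(config.seed, decade)
        n_items = items_per_decade[j]
        n_papers = config.newspapers_per_decade[j]
        paper_names = [f"jornal-{decade}-{k:02d}" for k in range(n_papers)]
        # per-taxon Poisson thinning of the Poisson(λ) mention process
        counts = rng.poisson(config.mention_rate * p[j], size=(n_items, n_taxa))
        papers = rng.integers(0, n_papers, size=n_items)
        years = rng.integers(decade, decade + 10, size=n_items)
        dup_draw = rng.random(n_items) < config.duplicate_rate
        ad_draw = rng.random(n_items) < config.advertisement_rate
        n_gear = rng.poisson(0.4, size=n_items)
        for i in range(n_items):
            mentions: list[str] = []
            for k in np.nonzero(counts[i])[0]:
                variants = pool[k].vernacular_variants
                for _ in range(counts[i, k]):
                    mentions.append(variants[rng.integers(0, len(variants))])
            gear = [
                DEFAULT_GEAR_POOL[rng.integers(0, len(DEFAULT_GEAR_POOL))]
                for _ in range(n_gear[i])
            ]
            is_dup = bool(dup_draw[i]) and i > 0
            item_id = f"{decade}-{i - 1:05d}" if is_dup else f"{decade}-{i:05d}"
            items.append(
                NewsItem(
                    item_id=item_id,
                    newspaper=paper_names[papers[i]],
                    year=int(years[i]),
                    municipality="florianopolis",
                    keyword_source=("pesca", "peixe", "both")[int(rng.integers(0, 3))],
                    is_duplicate=is_dup,
                    is_advertisement=bool(ad_draw[i]),
                    scope_marine=True,
                    has_animal_report=True,
                    mentions=tuple(mentions),
                    gear_mentions=tuple(gear),
                )
            )
    truth = TruthRecord(
        trophic_decline_effect=config.trophic_decline_effect,
        seed=config.seed,
        decades=tuple(config.decades),
        expected_watl={d: expected_watl(config, d) for d in config.decades},
        sampling_probabilities={
            d: p[j].tolist() for j, d in enumerate(config.decades)
        },
        presence_probabilities={
            d: q[j].tolist() for j, d in enumerate(config.decades)
        },
        taxon_order=tuple(t.scientific_name for t in pool),
    )
    return items, registry_from_pool(pool), truth
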