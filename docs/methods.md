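# Methods

## Data model

The sampling unit is the *news item*: one newspaper article, letter,
regulation or report that passed four inclusion conditions — not a
duplicate, not an advertisement, focused on coastal/ocean areas, and
actually reporting aquatic animals. The judgement behind those conditions
is made upstream by a human reader; the pipeline consumes them as boolean
flags and accounts for every exclusion in a ledger (reasons: `undated`,
`duplicate`, `advertisement`, `out_of_scope`, `no_animal_report`).
Duplicate detection inside the pipeline is by exact item id only; textual
near-duplicate detection is out of scope.

Occurrence is item-level presence: a taxon repeated five times in one item
counts once. The counting unit is the *normalised vernacular name* —
lowercased, diacritics stripped (historical spellings vary:
"tainha-assú"/"tainha-assu"), whitespace collapsed, hyphens kept because
they distinguish compound folk names. Two folk variants of the same
species in one item therefore count as two vernacular occurrences but only
one scientific-level occurrence; the parallel decade × taxon table at the
scientific level applies the presence cap again after name resolution, so
users can re-aggregate at either level.

Name resolution is exact-match against the taxon dictionary (no fuzzy
matching). One folk name may map to several taxa and vice versa; every
mapping is labelled `one_to_one`, `one_folk_many_sci`, `many_folk_one_sci`
or `unresolved`. Unknown names never abort a run: they stay in the
abundance totals (they are mentions), are excluded from scientific-level
richness, and accumulate in an unresolved-name report.

Decades are calendar decades (1880 = 1880–1889); years outside 1840–2019
are accepted with a warning.

## Trophic levels

Each dictionary row carries a trophic level in [2.0, 5.0] (values outside
reject the row at load time — a sanity envelope for marine consumers).
Taxa identified only to genus or family receive the arithmetic mean of the
trophic levels of their listed member species (the `TrophicTable`
fallback); taxa with no member entries stay missing and drop out of WATL.
A folk name mapping to several taxa contributes the mean TL of the mapped
taxa — a deliberate choice, since vernacular-level counting provides no way
to apportion such mentions; names mapping across the eligible/excluded
boundary (e.g. part fish, part invertebrate) contribute to no trophic
indicator and are logged.

## Indicators

- `WATL_d = Σ TL_i·n_{i,d} / Σ n_{i,d}` over native marine fish with
  known TL; missing when the denominator is zero.
- `Pis/Pla`: piscivore/planktivore occurrence ratio among native marine
  fish (guilds are fish-based by construction; a guild label on a non-fish
  row is a validation error); missing when the planktivore sum is zero.
- `Inv/Fis`: native marine invertebrates over native marine fish. The
  exclusion list names non-native and freshwater organisms, reptiles,
  birds and sea mammals — echinoderms are therefore *included* in the
  numerator by default, with a switch (`include_echinoderms=False`) to
  restrict it to crustaceans + molluscs.
- Gear mentions are normalised like taxon names, capped per item, and
  rolled up into broad categories via a two-column mapping file; unmapped
  names are reported, never dropped.

Ratios and series are left unsmoothed; missing decades propagate to trend
fits as absent points (pairwise deletion, no imputation — sparse early
decades are a documented feature of this kind of data, not noise to paper
over).

## Statistics

`pearson_trend` reports Pearson r, R² = r², the two-sided p-value from the
t-distribution with n−2 degrees of freedom, and the least-squares
slope/intercept on the same pairs (computed via scipy). Two-sided tests
are used throughout because the questions are directional only after the
fact. Constant series and fewer than three pairs raise typed errors rather
than returning NaNs. Since it is not obvious whether a decadal trend
should be read as a correlation or a regression on the decade index, both
r and the slope are always reported.

Percent changes are rounded half-up to integers and returned together with
the raw value; relative abundances are rounded half-up to one decimal.
Half-up (not banker's) rounding is the single rounding convention of the
package. The landings comparison aggregates tonnes to decades by summation
*before* forming the invertebrate/fish ratio, and its correlation against
the newspaper series is labelled exploratory — media presence and catch
volume measure different things.

## Synthetic corpus generator

The generator emulates the structural features that matter for validating
the pipeline:

- **Archive-size coupling.** Per-decade newspaper counts grow through time
  (default 2 → 60 across 15 decades, 1870–2010); item counts can be fixed
  (default 200/decade) or derived proportionally (4 items per newspaper)
  to reproduce the sampling-effort bias.
- **Folk-name structure.** The default pool of 20 taxa spans native marine
  fish across guilds (TL 2.1–4.5), crustaceans, molluscs, an echinoderm, a
  sea mammal, a reptile, and freshwater/non-native taxa, several with
  multiple vernacular variants — so ambiguity handling and every exclusion
  rule are exercised.
- **Trophic decline.** Decade *j* has standardised index t_j ∈ [−1, 1];
  taxon sampling probabilities are
  `p_i(t) = softmax(log b_i − δ·TL_i·t)`. δ = 0 is exchangeable through
  time; δ > 0 shifts mention mass from high- to low-TL taxa. The softmax
  form was chosen precisely so the expectation is analytic.
- **Closed-form oracle.** Each item draws Poisson(λ) mentions (λ = 2.5
  expected taxa per item by default) with those category probabilities;
  Poisson thinning makes per-taxon mention counts independent
  Poisson(λ·p_i), and a taxon's mentions split uniformly over its V_i
  variants, so its expected per-item occurrence mass after the presence
  cap is `w_i(t) = V_i·(1 − exp(−λ·p_i(t)/V_i))` and
  `E[WATL] ≈ Σ TL_i·w_i / Σ w_i` (ratio of expectations; the pipeline
  estimate converges to it in the per-decade item count, and a
  200-replicate Monte-Carlo test checks agreement within three standard
  errors).
- **Noise.** Duplicates and advertisements are planted at 5% each within
  the fixed per-decade item counts, so the inclusion filter always has
  work to do; with both rates at zero the filter passes everything.
- **Determinism.** One integer seed; per-decade substreams are keyed by
  `(seed, decade_label)`, so extending the decade range never perturbs
  items already generated for earlier decades.

Defaults for δ-recovery studies use δ = 0.5: over the ±1 index range this
shifts log-weights by one TL unit per unit of TL, producing a WATL decline
of roughly 0.6 — comparable in magnitude to the declines such corpora are
used to detect.

What the generator does *not* emulate: OCR noise, Portuguese text, real
folk-name frequency distributions (mentions are exchangeable given the
weights), within-decade temporal structure, or municipality effects.
Passing recovery tests therefore show that the pipeline is an unbiased,
correctly-plumbed estimator under a known sampling law — not that any
particular historical archive satisfies that law.

A second, fully deterministic builder (`structured_corpus`) constructs a
corpus hitting exact per-group abundance and richness margins, with chosen
folk names pinned to exact counts; it is the fixture used to check that
group sums, richness totals and relative abundances reproduce a known
composition exactly.

## Problem sizes

The replicate studies run 200 seeded replicates of 15 decades × 200 items
(recovery and null) and 200 replicates of the proportional-items corpus
(~1300 items each, bias study); the brute-force oracle comparison uses 100
random corpora of at most 500 items. These sizes give binomial standard
errors of about 3.5 percentage points on the reported rates.

## Known limitations

- Exact-match resolution: historical misspellings not in the dictionary
  surface as unresolved names rather than being fuzzily matched.
- One folk name spanning several families contributes a single mean TL;
  there is no occurrence apportionment model.
- No autocorrelation-corrected inference, breakpoint detection, or
  smoothing: the statistics are plain Pearson/OLS on decadal points.
- Items matched by both search keywords are stored once with
  `keyword_source="both"`; per-keyword counts are reported under both
  tallying conventions rather than resolved.
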