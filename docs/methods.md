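# Methods

## Survey model

A survey is a pair (registry, formulations). The registry holds one record
per *plant material* — a specific part of a botanical species, so the stem
and leaf of one plant are two materials sharing a scientific name — with
its family, part used, cultivated/wild source flags, traditional property
(cold/cool/neutral/warm/hot, or unknown where the compendia are silent),
flavors (a subset of sour/bitter/sweet/spicy/salty/plain), and free-text
function and pharmacology tags. Each formulation is a *set* of material
ids with a store id and a region (north/central/south/unknown): membership
is binary, so a material counts once per store however much of it the
recipe uses. Validation enforces referential integrity (every formulation
material exists in the registry), non-empty recipes, unique store ids, and
closed attribute vocabularies; messages name the offending record.
Duplicate occurrence rows are a transcription normality and collapse with
a warning rather than failing the load.

## Indices

**Use value.** UV = Ui/N with Ui the store count and N the number of
formulations. Values are kept as exact float ratios; only display rounds,
half-to-even at 3 decimals. Half-to-even matters at the quarter ties this
denominator produces: 10/32 = 0.3125 prints as 0.312, which round-half-up
would miss. Percentages print at 1 decimal (or 0 where a table
conventionally shows integers), same tie rule, implemented by quantizing
the shortest decimal representation (`decimal.Decimal`) rather than
`round()` on binary floats.

**Shannon diversity.** H = −Σ Pi·log2 Pi in bits (a `base` option exists;
2 is the default). Pi is material *i*'s share of **total material
occurrences** (Σ counts), not of N — with 183 occurrences, a material used
10 times has Pi = 10/183 and contributes ≈ 0.2292 bits. Zero-count
materials carry no mass and drop out before normalization, so padding the
registry never moves H; H = 0 for a single material and log2 S for S
equally-frequent ones.

**Attribute tables.** Family statistics separate two denominators: species
share over distinct scientific names (so split-part materials count once)
and formulation share over N. Property and flavor shares use the
*annotated* denominator — materials whose property is recorded — because
surveys typically carry a few materials absent from the compendia;
flavors are multi-membership (a material counts once per flavor it
carries, so shares may sum above 1), the natural reading when source
compendia list several flavors per material. Source flags are independent
(cultivated + wild may exceed 100%; "both" is reported separately).

## Inventory comparison

Regional subsets keep a region's formulations and exactly the materials
they use; subsets partition the survey, so per-region formulation counts
sum to N. Venn partitions classify every element of the union of 2–5
inventories by its k-bit membership signature; exclusive counts and
shares fall out of the single-bit signatures. Cross-tradition matching
keys on normalized scientific names — lowercased, authority strings and
parenthesized authors stripped, genus + epithet retained — because
independent inventories never share internal ids. Top-k comparisons rank
by UV descending, breaking ties by frequency descending then name
ascending; surveys with many materials tied at low UV make an explicit
tie-break necessary for a reproducible top-15.

## Core network

Pair counting enumerates each formulation's C(|F|,2) unordered 2-subsets;
keys are canonicalized (sorted endpoints), self-pairs are impossible, and
count(A,B) ≤ min(U_A, U_B) by construction. The core network keeps pairs
with count **strictly greater** than the threshold (default 4) — the
convention under which a network of top pairs at count 5 over 32
formulations retains exactly those pairs — with edge endpoints as nodes
weighted by UV and isolated materials excluded; raising the threshold can
only remove edges. Core materials rank by weighted degree (sum of incident
edge counts), chosen because a core ingredient is one with many frequent
partners; the scoring rule is pluggable (`degree`, `eigenvector` via
networkx) since association-mining tools do not document theirs. Exports
(GraphML with `uv`/`count` attributes, TSV edge list, JSON) are sorted and
byte-deterministic.

## Synthetic generator

The generator emulates the summary structure of a 32-store bitter-tea
survey; it never attempts the actual recipes.

- **Popularity**: material sampling weights follow rank^(−s). The default
  s = 0.44 was calibrated once, by simulating the default configuration
  over 60 seeds and matching the mean top-material frequency to the
  documented ≈ 10 of 32. At this exponent the realized tail is somewhat
  flatter than the study's (≈ 30 rather than 24 materials at frequency
  ≥ 3); the top-frequency anchor was prioritized, and the exponent is the
  knob governing the tail (the frequency-1 vs frequency-2 split of rare
  materials is emergent, not separately parameterized).
- **Recipe sizes**: Poisson conditioned on ≥ 1 with the rate solved
  (Brent) so the truncated mean equals `mean_size` (default 5.7); sizes
  are also capped at the inventory size. Materials within a recipe are
  drawn without replacement.
- **Regions**: store regions are drawn from a mix proportional to the
  49/34/20 north/central/south richness gradient, which reproduces the
  north-rich diversity ordering on average.
- **Attributes**: one draw per material, independent across attributes —
  property from the configured marginal (46.5% cold, 26.8% cool by
  default) with a 2/73 unknown rate, flavors as independent Bernoullis
  (bitter 0.69) with "plain" as fallback so no material is flavorless, a
  four-cell cultivated×wild table (both = 0.37), part from the
  whole-plant-dominated marginal (0.411), and function tags as Bernoullis.
  A `cold_bitter_coupling` knob (default 0, independent) lets the cold
  property raise the bitter-flavor probability. One species contributes
  two materials (stem and leaf) so a 73-material inventory spans 72
  species.
- **Determinism**: a single `numpy.random.Generator` seeded by the caller
  drives everything in fixed iteration order; identical (config, seed)
  give byte-identical serialized surveys.

`plant_core_structure` minimally edits formulations to force a chosen pair
to co-occur exactly *t* times (dropping one endpoint from surplus recipes,
adding both to deficit recipes), preserving all invariants — the fixture
for end-to-end core-network recovery.

### What the generator does and does not capture

Marginals are faithful; dependence is not. Real recipes share backbones,
so material usage is positively correlated and frequent pairs are common
(a real 32-store survey showed eight pairs above threshold 4); independent
sampling spreads co-occurrence thin, which is why network demonstrations
and tests plant the core structure explicitly. Likewise attributes are
independent unless coupled, regional floras differ only through sampling
noise, and names are synthetic binomials. Passing tests therefore show the
*computations* are correct under the study's marginal conditions, not that
the generator reproduces a real tradition's joint structure.

## Test and recovery conditions

Store-level statistics (mean recipe size) are checked on 500-store
surveys at 10% relative tolerance. Material-level attribute marginals are
drawn once per material, so they cannot tighten with store count; their
recovery is checked on a 10× inventory (730 materials, where the binomial
standard error is ≈ 1.8 points) at the same 10%. The popularity
calibration is checked at the study scale — mean top frequency over 20
seeds ≈ 10 of 32 — because the *maximum* frequency among 73 materials at
32 stores is an extreme-value quantity: at 500 stores the top UV converges
to the underlying inclusion probability (≈ 0.28), structurally below the
finite-survey 10/32. Brute-force oracles (exhaustive pair enumeration on
≤ 8 × ≤ 10 datasets, per-element Venn classification) are independent
double loops, not the production code path. All suites run in a few
seconds on one CPU.

## Known limitations

- Survey-scale headline diversity values from any particular real survey
  cannot be re-derived without its full frequency vector; the package
  verifies formulas, not unpublished tables.
- One-decimal percentage displays assume standard rounding; a source that
  prints 48.0% for 35/73 (= 47.95%) under an unknown rule cannot be
  matched exactly, only its integer display (48%).
- Name normalization is string surgery, not taxonomic resolution; synonyms
  (e.g. a species listed under different genera) will not match.
- The CLI's `all` bundle removes a freshly created output directory on
  failure but leaves pre-existing directories in place.
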