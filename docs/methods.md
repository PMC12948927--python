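# Methods

This note documents the models and procedures `slime` implements, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generator does and does not emulate.

## Study design being modelled

Five (by default) closed high-pressure reactor experiments, each seeded
with formation water from a different deep aquifer, are followed through
time with 16S rRNA (cDNA) amplicon sequencing. Day coordinates are
integers centered on the first H₂ injection (day 0, which belongs to the
post-injection phase). Besides injections, the only other disturbances
are water refills (filter-sterilized formation water, i.e. nutrients but
no immigration). The analysis works on cDNA-derived ASVs because closed
reactors accumulate necromass and dormant cells that distort DNA-based
profiles; a DNA companion table (active community plus a persistent
necromass set) can be generated for sensitivity work but is excluded by
the pipeline's default nucleic-acid filter.

## Alpha diversity

* Richness = number of ASVs with count > 0.
* The Stoddart index is implemented as the reciprocal of Simpson's
  concentration, D = 1/Σpᵢ². The name is used in the genotypic-diversity
  tradition ("an analog of the Simpson index"); the formula is the
  standard inverse-Simpson effective number. A Gini–Simpson variant
  (1 − Σpᵢ²) is available through `stoddart(..., variant="gini")` for
  sensitivity analyses.
* Shannon uses the natural logarithm, which makes Pielou evenness
  exactly H/ln S. Pielou is reported missing (NaN) for single-ASV
  samples.
* Indices are computed on counts as given. The generator fixes the
  sequencing depth exactly (multinomial resampling), so rarefaction
  would be a no-op on synthetic data; for real tables with unequal
  depths note that richness is depth-sensitive while Stoddart, Shannon
  and Pielou depend on relative abundances only.

## Time categories

For each experiment: *Before* = the latest sample with day < 0 (the
fixed "one day prior" of the emulated design generalizes to arbitrary
grids); *After* = the earliest sample with day ≥ 0; *Furthest* = the
latest sample with 0 ≤ day < min(next injection, first refill after
injection), falling back to the last sample when no such event exists.
After and Furthest may coincide. For experiments with several
injections, categories are anchored to the first injection with the
second injection as the Furthest cutoff; this is a documented choice —
anchoring to later injections is not implemented.

## The mock-community null model

Incidence (presence/absence) Jaccard dissimilarity between two
communities depends strongly on the sizes of their species pools, so raw
values are not comparable across pairs. The null model asks: how
dissimilar would two samples of the observed richness be if they were
assembled at random from everything these two experiments can host?

* Pool: the union of the two experiments' total observed ASV sets —
  every ASV seen in any of their samples, regardless of time.
* Mock communities: uniform without-replacement subsets of the pool.
  Richness is matched to the two real samples being compared (one mock
  of each richness per pair). The matching rule preserves the richness
  structure Jaccard is sensitive to; a `uniform` alternative (richness
  drawn uniformly between the two observed values) is available for
  sensitivity. Published z magnitudes from any other matching convention
  will differ.
* 1,000 disjoint consecutive pairs are formed from the (conceptually
  10,000) mock draws; the surplus draws beyond the 2,000 the pairing
  consumes are never materialized — they would not influence any pair,
  so the distribution is identical and the cost drops fivefold.
* z = (J_obs − mean)/sd with the sample standard deviation (ddof = 1) of
  the 1,000 null values. sd = 0 (e.g. richness saturating the pool)
  yields a flagged missing z rather than ±∞.
* Significance is strict: |z| > 1.96 (the 95% normal band). Substantive
  convergence calls use the lower tail only (z < −1.96 = less dissimilar
  than random assembly); large positive z is reported but never labelled
  convergence.

Self-calibration: when observed pairs are drawn by the null's own
scheme, z is centered with an |z| > 1.96 rate statistically compatible
with 5% (the acceptance suite checks this with 1,000 independent
replicates, each building its own null, so the rate's sampling noise is
binomial).

Within-experiment comparisons use the same machinery with both presence
sets from one experiment and the pool being that experiment's own
time-pooled ASV set; consecutive samples in day order are compared by
default (`all` pairs optionally). Because successive samples of one
reactor share most ASVs while the time-pooled null mixes all regimes,
these z-scores are strongly negative in any plausibly autocorrelated
community — a useful positive control.

## Convergence patterns

With sig(c) ≡ z_c < −1.96, precedence persistent > progressive >
transient > null-like:

| label | rule |
|---|---|
| persistent_convergence | sig at Before, After and Furthest |
| progressive_convergence | not sig Before, sig Furthest |
| transient_convergence | not sig Before, sig After, not sig Furthest |
| null_like | everything else |

Combinations outside the four narrative cases (e.g. significant Before
that lapses later) map to null-like with an `atypical` flag. Missing
categories are treated as non-significant and the label is marked
`partial`.

The Spearman bias check correlates |day_A − day_B| (the day gap between
the two samples of a matched category, nonzero mainly at Furthest) with
z, two-sided; p ≤ 0.05 flags the category matching as time-biased. It
needs at least five informative pairs and reports an undefined
correlation on constant input.

## Sampling-loss correction

Chemical inventories in a closed reactor shrink at every liquid sampling.
With `removed[k]` the amount withdrawn by the sampling event that
produced measurement k (measurements reflect the system after their
withdrawal), the corrected series is
corrected(t_k) = measured(t_k) + Σ_{j≤k} removed(t_j).
For a closed, non-reacting system this is constant, so any residual
trend is biology or abiotic reaction, not sampling. Negative removals
are rejected.

## Guild profiling

The functional layer is a static, shipped genus → guild table rather
than a marker-gene inference: transparent, reproducible offline, and
user-replaceable (`--guilds my_table.tsv`). Guild ↔ module pairing is
one-to-one: methanogenesis ↔ M00567, sulfate reduction ↔ M00596,
Wood–Ljungdahl ↔ M00377, fermentation ↔ the placeholder module id FERM.
The fermentation KO list is a stand-in (the enrichment-derived list it
represents is external and unpublished in table form) and is expected to
be replaced by users who need real KO identities. Multi-guild genera are
allowed; trajectory fractions then dual-count such ASVs (full weight to
each guild), which is stated in the output metadata — for single-guild
tables the guild fractions plus the unannotated fraction sum to 1 per
day. Chord-diagram edges are attribute fan-outs: every KO edge of an ASV
at a timepoint carries the ASV's relative abundance, with rows ordered
by timepoint, genus, then decreasing abundance.

## Synthetic-data generator

The generator produces presence-first community chains and then counts:

* **Pools.** A global pool (default 400 ASVs) is partitioned into guilds
  (fermentation 0.45, sulfate reduction 0.25, Wood–Ljungdahl 0.15,
  methanogenesis 0.15 — fermenters carry most taxonomic diversity in
  these systems) and each ASV gets a genus drawn from its guild's genus
  list, so every synthetic ASV is annotatable by the packaged table.
* **Richness.** Each experiment has a characteristic richness drawn
  uniformly from 40–60, jittered ±5% per sample and clipped to the
  27–86 range the emulated communities span.
* **Shared core.** Designated experiments (default 2, 3, 4) hold a
  common *ranked* core: an ordered subset of a shared pool (120 ASVs),
  evolving with slow in-place turnover (0.01 per sample step). Every
  designated sample contains a prefix of the current ranking sized
  `shared_pool_fraction × richness` (default 0.6). The ranking is what
  makes engineered pairs share the *same* ASVs at matched times; merely
  drawing from a common pool would not depress Jaccard dissimilarity
  below a null that pools the union of everything the two experiments
  host. All remaining ("private") ASVs are uniform draws from the global
  pool, so non-designated pairs overlap exactly as the hypergeometric
  expectation r_a·r_b/N predicts.
* **Dynamics.** Between successive samples each private ASV turns over
  with probability 0.15 — high enough that an experiment's time-pooled
  ASV set substantially exceeds any single sample (as the emulated data
  show, with dozens of ASVs appearing and disappearing per transition),
  which is what gives the time-pooled null its discriminating power,
  yet low enough that within-experiment z stays far below −1.96.
* **Injection response**, applied to presence and abundance
  independently so alpha and beta effects can be toggled separately:
  each fermenter ASV becomes unavailable with `fermenter_loss_prob`
  (default 0.5 — about half the fermenter richness disappears, matching
  the emulated losses of ~40 of 90 ASVs); half of the lost richness is
  replaced by new recruits (`injection_recruit_fraction`), the rest is
  a richness suppression that persists until a water refill. Exclusion
  is permanent while H₂ is present: refills restore richness (a
  transient detection bump of `refill_recruit_fraction`, default 0.15)
  but never resurrect lost fermenters, since refill water is sterile.
  Abundance weights of sulfate reducers and methanogens are multiplied
  by `hydrogenotroph_boost` (default 4) after injection.
* **Counts.** Per-ASV log-normal weights (σ = 1.2, giving realistic
  dominance of the top ASV at tens of percent of reads), one guaranteed
  read per present ASV plus a multinomial draw to an exact depth of
  10,000 — so realized richness equals the presence chain's richness
  and per-sample depth is exact.
* **Events.** The default schedule mirrors the emulated design:
  experiments 1–2 one 10% H₂ injection, 3 and 5 three 2% injections,
  4 one 2% injection; refills on days 31, 9, 6, 7 after injection for
  experiments 1, 3, 4, 5; nine sampling days from −29 to 56.

Determinism: one root seed; per-experiment, per-pair and per-stage child
generators are derived by hashing string labels into `SeedSequence`
spawn keys, so outputs are bit-identical across runs and adding an
experiment never perturbs the others.

What the generator does **not** emulate: read-level noise (chimeras,
PCR/sequencing error beyond optional singleton spikes), taxonomic
mis-assignment, compositional abundance dynamics beyond the single boost
factor, DNA/cDNA discordance beyond a simple necromass union, aquifer
chemistry feedbacks, and continuous (non-pulse) community drift in
response to chemistry. Passing tests on synthetic data therefore
demonstrate the statistical machinery — calibration of the null,
recovery of engineered sharing, correct bookkeeping — not the ecological
fidelity of any particular real system.

## Numerical choices and degenerate inputs

* Mock subsets are sampled by partial-sorting uniform keys
  (`argpartition`), vectorized over all draws.
* Null sd uses ddof = 1; mean/sd are always recomputable from the
  stored draws.
* Degenerate nulls (sd = 0), all-zero samples, single-ASV Pielou,
  missing categories and empty presence sets all produce flagged
  missing values or warnings rather than exceptions, except where the
  input is structurally invalid (negative counts, duplicate ids,
  richness exceeding the pool), which raises with the offending ids.
* The singleton filter removes ASVs with a per-experiment total of
  exactly 1; it is idempotent and warns when it empties a table.

## Scale of the shipped checks

The test suite runs the full five-experiment study across 100 seeds for
pattern recovery with the null scaled to 2,000 mock communities (1,000
pairs, i.e. every draw used), 1,000 independent replicates for null
self-calibration, 1,000 seeds for the hypergeometric-overlap check of
the generator and 500 for the engineered-sharing comparison; these
sizes hold the whole suite to about a minute while keeping every
statistical assertion comfortably powered. The acceptance script runs
the pipeline at full null scale (10,000 mock communities).

## Known limitations

* The null model conditions on the *observed* total pools; very short
  time series make the pool barely larger than single samples and
  compress all z-scores toward zero.
* The richness-matching rule is a convention; z magnitudes are not
  comparable across different matching rules.
* Guild annotation is genus-level and static; ecotype-level metabolic
  variation within a genus is invisible.
* Between-experiment comparisons assume a shared ASV namespace (same
  denoising reference across experiments).
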