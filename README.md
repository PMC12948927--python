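# slime

Succession analysis of deep-subsurface microbial communities under
experimental H₂ injection.

Underground gas storage in deep aquifers exposes oligotrophic microbial
ecosystems to sudden pulses of dihydrogen, an electron donor that feeds
hydrogenotrophic sulfate reducers, methanogens and acetogens while
inhibiting many fermenters. `slime` implements the statistical side of
such studies for 16S rRNA (cDNA) amplicon time series from several
independent reactor experiments: does H₂ drive initially distinct
communities toward a shared composition (deterministic assembly), or do
they stay as different as random draws from their joint species pool?

## What it computes

**Alpha diversity.** Per-sample ASV richness, the Stoddart index
D = 1/Σᵢpᵢ² (inverse Simpson concentration — the effective number of
equally abundant ASVs, robust to the richness inflation of ASV-level
data), Shannon entropy H = −Σᵢpᵢ ln pᵢ and Pielou evenness J = H/ln S.

**Null-model beta diversity.** For each experiment pair, samples are
aligned to three categories relative to the first H₂ injection (day 0):
*Before* (latest pre-injection sample), *After* (first sample at day ≥ 0)
and *Furthest* (latest sample before the next disturbance — second
injection or water refill). The observed Jaccard dissimilarity
J = 1 − |A∩B|/|A∪B| of the two presence sets is normalized against a
null distribution: the pair's total observed ASV sets are pooled
regardless of time, 1,000 pairs of mock communities are drawn from
10,000 uniform without-replacement subsets with richness matched to the
real samples, and z = (J_obs − μ_null)/σ_null. z < −1.96 marks a pair
sharing more ASVs than random assembly predicts.

**Convergence patterns.** A pair's three z-scores classify it as
`persistent_convergence` (significant at all three categories),
`progressive_convergence` (not Before, significant Furthest),
`transient_convergence` (significant only After) or `null_like`.
A Spearman test checks that z is not biased by the day gap between the
paired samples.

**Guild profiling.** ASVs are mapped via genus to four energy-metabolism
guilds — fermentation, dissimilatory sulfate reduction (KEGG M00596),
the Wood–Ljungdahl pathway (M00377) and hydrogenotrophic methanogenesis
(M00567) — through a shipped, editable genus table; the package computes
per-day guild fractions, shared (core) communities across experiments
and a chord-diagram edge list (ASV × timepoint × KO, weighted by
relative abundance).

**Synthetic data.** A generator emulates the whole multi-experiment
design — overlapping ASV pools with an engineered persistent core shared
by designated experiments, injection-triggered fermenter loss,
hydrogenotroph abundance boosts, water refills, log-normal abundances
multinomially resampled to fixed depth — so the full pipeline runs and
is testable with no downloads.

## Worked example

```python
from slime import RunConfig, run

report = run(RunConfig(seed=1))          # default synthetic 5-experiment study
print(report.patterns.to_string(index=False))
```

```
     pair                pattern  partial  atypical
exp1~exp2              null_like    False     False
exp1~exp3              null_like    False     False
exp1~exp4              null_like    False     False
exp1~exp5              null_like    False     False
exp2~exp3 persistent_convergence    False     False
exp2~exp4 persistent_convergence    False     False
exp2~exp5              null_like    False     False
exp3~exp4 persistent_convergence    False     False
exp3~exp5              null_like    False     False
exp4~exp5              null_like    False     False
```

Experiments 2, 3 and 4 are the ones the generator engineered to share a
persistent core community; the pipeline recovers exactly those pairs as
persistently convergent (their dissimilarity sits 3–6 null standard
deviations below the mock-community expectation at every category),
while all other pairs are indistinguishable from random assembly. The
per-category z-scores are in `report.beta`, within-experiment
comparisons (always strongly negative: successive samples of one
reactor are far more similar than the null expects) in `report.within`,
and `report.bias.p_value` gives the Spearman day-gap check.

The same run from the shell:

```bash
slime simulate --out data/ --seed 1
slime run --out results/ --seed 1
slime beta-null --tables data/ --n-mock 10000 --n-pairs 1000 --seed 7 --out beta.tsv
```

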