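# Methods

## The simulated mutation-accumulation design

The generator emulates a multi-population MA study in an asexual diploid:
3 populations × 3 genotypes, each genotype contributing one sequenced
starting control (SC), 8 MA lines and 2 extant-control (EC) lines by
default, with G = 12 generations per descendant line and junction-read
evidence at a mean depth of 50×. These defaults mirror the scale of
published *Daphnia*-style MA panels; any of them can be overridden in the
config.

Each SC genome is a set of occupied TE sites drawn without replacement
from a synthetic genome (10 contigs × 1 Mb), with per-family copy numbers
fixed exactly by the family specification and a disjoint pool of empty
candidate positions available for new insertions. Each occupied site is
heterozygous (z = 1) with probability `het_fraction` (default 0.3,
a design choice — real SC genotypes carry a mix of fixed and segregating
insertions and no canonical value exists) and homozygous (z = 2)
otherwise.

### Transition model

Per generation, independently, and always conditioned on the state at the
start of the generation:

- every occupied site (z ≥ 1) seeds a novel insertion with probability
  `u01`; the target is drawn uniformly from the candidate pool and starts
  heterozygous (a single insertion event touches one homolog). The event
  is attributed to the new site and the source copy is unchanged, so the
  expected number of novel gains per generation is `u01 ×` (occupied
  sites), matching the per-copy denominator of the rate estimator;
- each heterozygous site becomes homozygous with probability `u12`
  (homolog-dependent repair / gene conversion) or empty with probability
  `u10` (excision, deletion or conversion to the absence allele), mutually
  exclusively;
- each homozygous site loses one allele with probability `u21`.

At most one transition per site per generation; 0→2 and 2→0 cannot occur
in one step but can arise over G generations as two-step paths, which the
caller sees as apparent double transitions and excludes. Every realized
transition is appended to a ground-truth event log `(line, site, family,
type, generation)`.

Default rates are the per-type means observed in the motivating MA study
(u01 = 1.17, u12 = 0.22, u10 = 1.67, u21 = 0.04, all ×10⁻⁵ per copy per
generation). EC lines are simulated as MA lines with gains multiplied by
1/695 and losses by 1/7.4 — the realized retention factors that selection
produced in that study — rather than with an explicit fitness model, since
only the realized reduction is observable.

### Evidence model

Per line and site, total junction reads n ~ Poisson(depth) and presence
reads ~ Binomial(n, f) with f = ε for z = 0, 0.5 for z = 1 and 1 − ε for
z = 2; ε (default 0.01) is the probability a read misreports the allele.
A `detect_weight` multiplier (default 1) scales the presence-read
probability and stands in for length-dependent detectability of real TE
junctions; it is a monotone abstraction, not a mechanistic read model.
What the generator deliberately does not emulate: alignment and mapping
artifacts, repeat-induced multi-mapping, length- and family-specific
breakpoint ambiguity, and batch effects between sequencing runs. Passing
tests therefore demonstrate the statistical machinery is correct for the
stated evidence model, not that any particular short-read TE caller
achieves these error rates on real libraries.

### Copy divergence and TIP panels

Copy sequences diverge from a family consensus on a star tree: each copy
independently substitutes each site with probability `mu_t` to a uniformly
chosen different base. Two copies then differ at a site with probability
`2p(1−p) + (2/3)p²`, the closed form used as the oracle for the MPD tests.

Population panels place sites into three classes — shared (occupied in
≥ 2 genotypes spanning ≥ 2 populations, capped below full occupancy so
the site stays polymorphic), population-private (≥ 2 genotypes, one
population) and singleton (exactly one genotype). `n_pop_private` is a
total, spread across populations as evenly as possible (round-robin over
a shuffled population order); occupying genotypes are drawn uniformly
given the class.

## Calling and classification

Zygosity is called from the presence fraction f = p/(p+a): NoCall if
coverage < `c_min` (default 10), absent if f < `t0` (0.25), heterozygous
in [t0, t2], homozygous above `t2` (0.75). These thresholds are this
package's own operating point, exposed in config and swept by the
validation module. Each MA/EC line is compared only to its genotype's SC
over the union of sites with evidence in either line; NoCall on either
side excludes the site (counted per line), apparent double transitions
are excluded rather than split into two events — counting them twice
would inflate N_m for categories the assay cannot attribute.

## Rate estimation

`rate = N_m/(N_SC·G)` per line × family × type, with N_SC taken from the
SC calls (site-level copies: z = 1 and z = 2 each count once — detection
is site-based, so allele dosage is not the denominator). Families with
zero SC copies are excluded. A line's rate per type is the unweighted
mean across its genotype's families; genotype, population and overall
rates are unweighted means across MA lines. Population aggregation
defaults to the mean over all the population's lines; a `genotype-mean`
mode averages genotype means instead (the two differ on unbalanced
designs). Aggregates are `gain_all = gain01 + gain12`, `loss_all = loss10
+ loss21`, `total = gain_all + loss_all`, `net = gain_all − loss_all`
(the only aggregate allowed to be negative).

Confidence intervals are percentile bootstrap across lines (default
B = 10,000, α = 0.05), the simplest defensible choice given only "resample
lines" as a constraint; BCa was considered and rejected as unwarranted
complexity at n = 5–12 lines per genotype. A single line (or identical
lines) collapses the interval to a point. FDR correction is
multiplicative, `rate × (1 − FDR)`, applied per type with aggregates
recomposed from adjusted types.

## Spike-in validation

The validation module simulates SC + descendant lines with boosted rates
(5×10⁻³ per copy per generation over 4 generations, half the ancestor
heterozygous) so every event type is spiked in hundreds of times, runs
the full evidence → calling path, and matches calls to the truth at the
**net** level: the true ancestral zygosity against the true final
zygosity per (line, site). Intermediate paths that cancel are "none";
net two-step paths are "double" and excluded on both sides. True
negatives are restricted to evaluable cells — pairs whose true ancestral
state permits the event type (novel gains at empty sites, 1→2 and 1→0 at
heterozygous sites, 2→1 at homozygous sites) — because an omission rate
over impossible cells is meaningless. Sites gained in one line provide
the empty-site cells for every other line of the replicate.

At the default operating point (depth 50, ε = 0.01, default thresholds)
the measured FDR is ~1% for every type, comfortably under the 3%
ceiling the pipeline is designed around; FOR is of order 10⁻⁵.

## Rate-recovery experiment

The end-to-end check simulates 30 MA lines from a 1000-copy ancestor
(G = 12, u01 = u10 = 10⁻³) and asks whether the pipeline's 95% bootstrap
CI (B = 2000) covers each true rate. The ancestor is fully heterozygous
here: the estimator divides by all SC copies, so u10 is only the
estimand when every copy is loss-eligible — with a mixed ancestor the
pipeline would correctly estimate the *realized* loss rate per copy,
which is `u10 × het_fraction`, not u10. Two small opposing biases remain
and are expected: net surviving gains fall slightly below `u01·N·G`
(later losses remove some), while ancestor-call errors add a small
false-positive floor shared across lines.

## Numerical and degenerate-input choices

- Coordinates are 0-based; all tables are TSV with required headers so
  fixtures diff cleanly.
- All randomness flows from one configured seed through
  `numpy.random.SeedSequence` children; re-running with the same config
  and inputs reproduces outputs byte-identically. Experiment-level code
  draws child seeds from a master stream rather than by arithmetic on the
  base seed, so different base seeds give statistically independent
  replicates.
- Unknown TE classes are retained and parse to `Unknown`; whether they
  enter rate summaries is a config flag (default off).
- G-test: zero observed cells contribute 0; a zero expected proportion
  with positive observed count is an error, not ±inf. No Williams
  correction (the uncorrected statistic matches the worked value the
  package tests against).
- Spearman t: |ρ| = 1 reports t = ±inf explicitly rather than raising.
- MPD uses pairwise gap deletion on provided alignments; a pair with no
  comparable columns is dropped, and fewer than two copies yields an
  undefined (None) MPD rather than zero.
- PCA centers the binary TIP matrix without variance scaling (0/1 data
  needs no standardization) and drops monomorphic sites first; k-means
  purity runs best-of-20 restarts on the 2-component embedding by
  default, seeded for determinism.
- `bootstrap_ci` with one line returns a degenerate (r, r) interval.

## Problem sizes

Test and validation runs use deliberately modest sizes — spike-ins of
~2000 sites × 10 lines × 5 replicates, recovery over 40 replicate
experiments of 30 lines each, panels of tens of sites — chosen so the
full suite completes in well under a minute of simulation time per
experiment while leaving every Monte-Carlo tolerance at 3 standard
errors or better.

## Known limitations

- The evidence model is site-level; length-stratified detectability is
  abstracted into `detect_weight` and cannot reproduce mechanistic length
  effects of real junction mapping.
- EC lines use realized retention factors, not a fitness model; the
  simulator cannot answer questions about the shape of selection.
- The caller compares each descendant only to its SC; no cross-line
  re-genotyping or ancestor-concordance filtering is attempted.
- FDR/FOR estimates characterize *this* caller under *this* evidence
  model; they are not transferable to alignment-based TE callers.
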