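# Methods

## Strain comparison model

A sample × species **allele profile** stores read counts of A/C/G/T at every
covered 0-based genome position (multi-scaffold genomes are concatenated by
the reader in sidecar order). All downstream comparison is conditional on
joint **presence**: a species is present in a sample when at least
`min_breadth` (default 0.25) of its genome is covered at ≥ `min_depth`
(default 5×); dyad-level sharing statistics only ever count species present
in both members, so absent species contribute to neither numerator nor
denominator.

At each position covered at ≥ `min_depth` in both samples, an allele is
**detected** when its count is ≥ `min_count` (default 2) and its within-site
frequency ≥ `min_freq` (default 0.05). These fixed thresholds stand in for a
profiler's error-aware null model; they are deterministic, and at the error
rates the simulator generates (≤ 0.1% per read) a 2-read/5% floor keeps the
false-allele rate per site far below the scale of the strain threshold.
The two substitution definitions are:

- **popANI** substitution: the detected-allele sets are disjoint;
- **conANI** substitution: the consensus alleles differ (ties broken
  alphabetically A<C<G<T for determinism).

Disjoint allele sets imply differing consensus alleles whenever the
consensus is itself detected (always true at the default thresholds); the
containment is enforced outright so that `popANI ≥ conANI` survives
non-default threshold combinations. Two samples share a strain when
`popANI ≥ ani_threshold` (default 0.99999). Note what this means at real
genome sizes: at 50,000 compared positions a *single* disjoint site already
gives popANI 0.99998, so sharing effectively requires zero such sites; the
threshold is a near-identity criterion, and shared minor alleles (mixed
strain populations) are what keep truly related samples above it.

## Transplant design and the filter cascade

The cascade evaluates donor → recipient-post sharing events against three
cumulative predicates, each using the same popANI threshold as dyad sharing:

1. **absent pre-FMT** — the donor does not share the strain with the
   recipient's pre-FMT sample (species absent pre-FMT, or present but below
   threshold). This is donor-anchored ("previously absent from recipient"
   interpreted as the donor's strain); an event failing it is plain
   background sharing.
2. **unique to one donor** — no other donor's pre-FMT sample shares the
   strain with the source donor. Divergent conspecific strains in other
   donors do not disqualify: uniqueness is of the strain, not the species.
   By default only donors are checked (`scope="donors"`); a wider mode also
   checks recipients' pre-FMT samples.
3. **unique to one recipient** — no other recipient's post-FMT sample
   shares the strain.

Tier t therefore satisfies all predicates ≤ t and the tier sets are nested
by construction (asserted at run time).

**Tier-specific sharing rates.** At tier t the denominator is the jointly
present species that survive the cumulative donor-anchored filters up to t,
and the numerator is those also shared. Holding the denominator at tier 0
would force the matched-vs-mismatched contrast to shrink as true events are
filtered; the tier-conditional rate is the quantity the cascade is designed
to improve.

**Contrast summary.** The headline matched-vs-mismatched contrast is the
difference of per-dyad *median* rates. At the strictest tier a dyad's rate
often rests on one or two surviving species, so per-dyad means are dominated
by degenerate 0/1 values; with eight recipients drawing on five donors, a
donor serving two recipients also has most of its genuinely engrafted
strains excluded by the recipient-uniqueness filter (they are detected in
two recipients), which can nudge the *mean* matched rate down between tiers
2 and 3 even though the event set is strictly cleaner. The median is
insensitive to both artefacts; the mean contrast is still monotone through
tiers 0–2 and is reported alongside.

## Enrichment tests

- **Family composition**: family × group contingency table; Fisher's exact
  test for 2×2, and for r×2 a conditional Monte Carlo exact test — group-A
  counts drawn from the multivariate hypergeometric at the observed margins
  (default 10⁵ draws, seeded), chi-square discrepancy, add-one p-value.
- **Family log₂ odds**: Haldane–Anscombe +0.5 on all cells when any cell is
  zero; Woolf (log-normal) 95% CI. Antisymmetric under group swap.
- **Prevalence**: per event, the number of baseline samples (donors and/or
  pre-FMT recipients — both baselines are supported; the donor+pre set is
  the default in the pipeline) where the species passes presence; matched vs
  mismatched prevalences compared by Welch t.
- **Permutation trait enrichment**: the filtered subset's trait proportion
  is compared with `n_perm` (default 1000) same-size subsets drawn from the
  full event list without replacement. The p-value is the raw proportion of
  draws at least as extreme, one-sided in the direction of interest by
  default (a two-sided absolute-deviation mode is provided); its attainable
  floor is `1/n_perm` and no +1 smoothing is applied. Events with unknown
  trait are excluded from both observed and permuted sets and logged. The
  trait count of a without-replacement subset is hypergeometric, so draws
  are sampled directly from that distribution — distributionally identical
  to materialising subsets, and checked in the tests against the exact tail
  computed independently.

## Category statistics and downsampling

Sharing rates are compared across dyad categories with Welch's
unequal-variance t-test (BH-corrected across all category pairs of one run)
or one-way Tukey HSD (Tukey–Kramer for unbalanced groups). Dyads with no
jointly present species have undefined rates and are excluded listwise with
a logged warning; category pairs with fewer than two defined rates are
flagged not-computable rather than dropped.

`downsample_robustness` guards against hosts appearing in multiple dyads.
The default mode retains a random *host-disjoint* subset of dyads per
iteration (greedy over a seeded permutation; a longitudinal self-pair counts
as one use of its host). A literal one-sample-per-host mode is also
provided, with the caveat that it necessarily destroys every longitudinal
self-pair — which is why it is not the default.

`phylo_share` supports both readings of a "normalized distance ≤ 0.1" rule:
division by the species' maximum pairwise distance (default; invariant to
global rescaling) or the 10th-percentile cutoff (`mode="quantile"`). Neither
is asserted to be the canonical one; they coincide only for particular
distance distributions.

## Covariates

Diet vectors are compared by quantitative Bray–Curtis (default) or
presence/absence Jaccard; diet data are aggregated to social-group × year
vectors before dyad comparison, so diet covariates are meaningful only for
dyads from different groups (or non-overlapping lives). Month distance is
the circular distance on the 12-month cycle (≤ 6). The rainfall covariate
sums daily rainfall by calendar month and combines the two samples' monthly
totals additively by default (`mean_both_months` selectable); the two totals
are summed even when both samples fall in the same month. Each covariate is
related to the dyad sharing rate by simple OLS with the slope's two-sided t
test at n − 2 degrees of freedom.

## The forward simulator

The simulator is the package's validation instrument: it generates the same
tables the analysis consumes, with a truth label
(`resident | pre_existing | transmitted | environmental`) for every strain
instance.

**Species pool.** Each of `n_species` (default 40) species has
`n_haplotypes` (default 8) haplotypes over `sites_per_genome` (default
10,000) sites. Each haplotype carries a private block of
`inter_haplotype_divergence` (default 10) substitutions on a shared
ancestral genome, so pairwise Hamming distance is ≥ 2× the divergence and
distinct haplotypes compare at ≈ 99.8% popANI — far below the sharing
threshold — while transmission copies haplotypes exactly (mutation rate 0 by
default) and compares at 100%. Species carriage prevalence is geometric
(`p = 0.2`, scaled by 13 hosts, clipped to 1), giving the rare-vs-widespread
contrast the donor-uniqueness filter exploits.

**Sequencing.** Per site: depth ~ Poisson(`mean_depth`, default 20×), reads
multinomial over the sample's strain frequencies, and each read misread to a
uniform other base with `error_rate` (default 0.001). Optional breadth
masking zeroes a random site fraction. At these defaults a shared haplotype
is detected in both samples at essentially every site, so false popANI
substitutions between same-strain samples are vanishingly rare, and the
transmitted-vs-distinct separation around 99.999% is sharp.

**FMT design.** Five donors, eight recipients, designated donors drawn
uniformly (donors can serve several recipients, as in a small clinical
cohort). Recipient pre-FMT communities undergo independent per-strain
depletion (`depletion_survival`, default 0.2 — the antibiotic-conditioning
analogue); each species carried by the designated donor engrafts with
`engraftment_prob` (default 0.8); post-FMT samples acquire, per species, a
random pool haplotype with `environmental_acquisition_rate` (default 0.05).
When an engrafted strain is identical to a retained pre-FMT strain the
merged instance is labelled `pre_existing` (the transfer is unobservable);
an engrafted strain absorbing an identical environmental acquisition stays
`transmitted`.

**Wild-population design.** Dyad counts default to 23 never-overlapped, 20
different-group, 26 close-partner, and 22 longitudinal pairs. Every sample
assembles its community from an environmental pool in which the haplotype
drawn for a species follows the host's diet latent with probability
`diet_coupling` (default 0.5), the sampling month with `season_coupling`
(default 0.2), and is uniform otherwise — so pool overlap rises with diet
similarity and seasonal proximity. Rainfall follows a five-month dry season;
rainier months add minor strains per species (`rain_microdiversity`,
default 0.5), reproducing elevated within-species diversity and
minor-strain sharing in wet periods. Close partners exchange strains with
`social_transmission_prob` (default 0.05) each way; longitudinal second
samples retain strains with `persistence` (default 0.9) and acquire new ones
at a turnover rate scaling with 1 − persistence, so full persistence implies
a longitudinal sharing rate of exactly 1. Diet vectors are sparse
compositions over 10 food types generated from the same 1-D latent that
drives pool coupling.

**What the simulator does and does not emulate.** It reproduces the
design-level structure of the two study types — presence/absence of
strains, microdiversity, detection noise, nested filters, environmental
confounding — but not read-level artefacts (mapping bias, chimeric
assemblies, conspecific mis-mapping), real strain phylogenies (haplotypes
are equidistant), abundance dynamics, or recombination. Passing tests
therefore demonstrate that the *inference machinery* is correct and that the
cascade behaves as designed under known ground truth; they do not certify
performance on real metagenomes, where database coverage and persistence
dynamics dominate.

## Numerical and procedural choices

- All randomness flows through `numpy.random.default_rng` seeded from the
  configuration; identical config + seed reproduces outputs exactly.
- Sharing comparisons use exact integer substitution counts; popANI is
  computed as `1 − n_pop/n_compared` in double precision and compared
  directly to the threshold (test cases sit far from representability
  issues: one substitution in 50,000 is 0.99998 < 0.99999).
- Welch t on two identical constant groups is defined as t = 0, p = 1
  rather than the 0/0 the formula produces.
- Monte Carlo p-values: the r×2 composition test uses add-one smoothing
  (it approximates an exact conditional test); the trait permutation test
  reports the raw proportion, as its definition prescribes.
- Non-evaluable comparisons (no jointly covered sites) are never "shared";
  they raise if a sharing decision is forced on them.

## Problem sizes used in the tests and the acceptance run

Unit and property tests run on toy profiles (≤ 50 sites) plus small cohorts
(6–12 species, 600–1,500-site genomes). The acceptance run simulates the
full FMT design at the default configuration (40 species, 10-kb genomes,
21 samples; twice, once with environmental acquisition disabled for the
precision check), a full wild-population design (91 dyads, 182 samples),
100 + 100 replicate different-group cohorts (25 species, 2-kb genomes) for
the diet-effect sign-recovery experiment, and 500 null datasets × 1,000
permutations for calibration — together about two minutes on one CPU.

## Known limitations

- The compared-position rule (depth ≥ 5 in both samples) mirrors the
  presence depth criterion; a profiler's own site filters may differ.
- Fixed allele-detection thresholds ignore depth-dependent error structure;
  at depths ≫ 100× a frequency floor of 5% is conservative, at depths < 4×
  the consensus itself can fail `min_count` and such sites contribute
  popANI substitutions between identical samples (excluded by the default
  `min_depth = 5`).
- The donor-uniqueness and recipient-uniqueness predicates assume
  approximate transitivity of near-identity, which exact haplotype copies
  satisfy; heavily mixed real populations can violate it near the
  threshold.
- `SharingEvent.matched` and the dyad categories are design metadata, not
  inferences; miscoded metadata propagates silently.
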