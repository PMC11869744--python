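# strainshare

Strain-resolved inference of microbiome transmission from shotgun
metagenomes. `strainshare` is for microbial ecologists who want to know
whether two hosts *share a strain* — and whether strain sharing can be read
as *transmission* — given per-site allele counts of reads mapped to
species-representative genomes (as produced by an inStrain-style profiler),
sample metadata, and host covariates.

## What it computes

**Strain comparison.** For each species jointly present in two samples
(presence = ≥ 25% of the genome covered at ≥ 5× in both), every position
covered at ≥ 5× in both is compared:

- **conANI** counts a substitution where the consensus alleles differ:
  `conANI = 1 − n_con / n_compared`;
- **popANI** is microdiversity-aware and counts a substitution only where
  the two samples share *no* detected allele, major or minor:
  `popANI = 1 − n_pop / n_compared`, so popANI ≥ conANI.

Two samples share a strain of a species when `popANI ≥ 0.99999`. A dyad's
**strain-sharing rate** is shared strains over jointly present species.

**Transmission-filter cascade.** In a fecal microbiota transplant (FMT)
design — donors, recipients sampled pre/post, one designated donor each —
raw sharing events are upgraded through cumulative criteria: tier 1, strain
previously absent from the recipient; tier 2, additionally unique to one
donor pre-FMT; tier 3, additionally unique to one recipient post-FMT. Tier
sets are nested; stricter tiers trade events for fidelity to the true
transmission network.

**Networks, enrichment, covariates.** Dyads are categorized (matched vs
mismatched donor-recipient pairs; or never-overlapping lives, different
social groups, close social partners, longitudinal self-pairs in a
wild-population design) and compared with Welch t-tests under
Benjamini–Hochberg correction or Tukey HSD, with host-disjoint downsampling
for robustness. Event sets are tested for family composition (Fisher exact /
conditional Monte Carlo), family log₂ odds ratios, baseline prevalence, and
trait enrichment by subset permutation. Dyad sharing rates are regressed on
diet dissimilarity (Bray–Curtis or Jaccard), circular month distance,
monthly rainfall, and demographic covariates. A marker-gene route is also
supported: `phylo_share` flags pairs at ≤ 0.1 normalized phylogenetic
distance (or the 10th-percentile variant) from a supplied distance matrix.

**Forward simulator.** `simulate_fmt_cohort` and `simulate_social_cohort`
generate both study designs end to end — species pools of well-separated
haplotypes, engraftment, depletion, environmental acquisition coupled to
diet and season, within-host persistence, Poisson/multinomial sequencing
with read errors — and emit a ground-truth table labelling every strain
instance `resident`, `pre_existing`, `transmitted`, or `environmental`, so
every inference stage can be scored against what actually happened.

## Worked example

```python
from strainshare import SimulationConfig, simulate_fmt_cohort
from strainshare.pipeline import PipelineConfig, analyze_fmt

sim = simulate_fmt_cohort(SimulationConfig(seed=11, n_species=25, sites_per_genome=4000))
result = analyze_fmt(sim, PipelineConfig(seed=11))
```

Running `python examples/02_fmt_cascade.py` (the same computation) prints:

```
events per cumulative tier:
  tier 0: 85
  tier 1: 71
  tier 2: 49
  tier 3: 9

median per-dyad sharing rate (shared strains / considered species):
  tier 0: matched 1.00  mismatched 0.13
  tier 1: matched 1.00  mismatched 0.00
  tier 2: matched 1.00  mismatched 0.00
  tier 3: matched 1.00  mismatched 0.00

Welch t matched vs mismatched at tier 0: t=21.48, BH-adjusted p=2.39e-13
```

85 donor→recipient strain-sharing events survive as 9 putative transmission
events at the strictest tier; matched (true donor) pairs share essentially
every considered strain while mismatched pairs collapse to zero once
widespread strains are filtered out — the cascade recovers the transmission
network. The other scripts in `examples/` demonstrate pairwise comparison
(`01`), dyad categories in a wild-population design (`03`), and
environmental covariates (`04`, which prints
`sharing rate ~ diet similarity: slope=0.75, df=18, p=0.0005`: hosts that
never interact share more strains when they eat similar diets).

A thin CLI mirrors the stages on TSV files:

```bash
strainshare simulate --design fmt --seed 11 --out run/
strainshare compare --profiles run/profiles.tsv --lengths run/lengths.tsv --out run/
strainshare filter --comparisons run/comparisons.tsv --presence run/presence.tsv \
    --metadata run/metadata.tsv --out run/events.tsv
```

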