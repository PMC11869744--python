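"""End-to-end analysis drivers and the pipeline configuration.

:class:`PipelineConfig` gathers every threshold in one serialisable object
(the ``paper_defaults`` preset is 5x depth, 25% breadth, 99.999% popANI).
:func:`analyze_fmt` and :func:`analyze_social` run the full analysis on
simulated (or loaded) cohorts; :func:`run_pipeline` dispatches on the design
and simulates inputs when none are provided. Stage counts are logged and
returned so no record is dropped silently.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import covariates as cov
from .cascade import (
    CohortComparisons,
    FMTDesign,
    all_cohort_pairs,
    assign_tiers,
    dyad_tier_table,
    events_to_frame,
    find_sharing_events,
    tier_counts,
    tier_sharing_rates,
)
from .enrichment import (
    TaxonAnnotation,
    family_composition_test,
    permutation_trait_enrichment,
    prevalence_of_events,
)
from .profiles import (
    AlleleProfile,
    PairwiseComparison,
    PresenceCall,
    compare_profiles,
    presence_call,
)
from .sharing import (
    DyadSummary,
    compare_sharing_across_categories,
    summarize_dyad,
)
from .simulate import (
    FMTSimulation,
    SimulationConfig,
    SocialDesign,
    SocialSimulation,
    simulate_fmt_cohort,
    simulate_social_cohort,
    synthetic_annotations,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """All thresholds and options of one analysis run."""

    min_depth: int = 5
    min_breadth: float = 0.25
    ani_threshold: float = 0.99999
    allele_min_count: int = 2
    allele_min_freq: float = 0.05
    test_method: str = "welch_bh"  # welch_bh | tukey
    n_perm: int = 1000
    mc_draws: int = 100_000
    seed: int = 0
    design: str = "fmt"  # fmt | social
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 <= self.min_breadth <= 1.0:
            raise ValueError("min_breadth must lie in [0, 1]")
        if not 0.0 < self.ani_threshold <= 1.0:
            raise ValueError("ani_threshold must lie in (0, 1]")
        if not 0.0 <= self.allele_min_freq <= 1.0:
            raise ValueError("allele_min_freq must lie in [0, 1]")
        if self.design not in ("fmt", "social"):
            raise ValueError("design must be 'fmt' or 'social'")
        if isinstance(self.simulation, Mapping):
            self.simulation = SimulationConfig(**self.simulation)

    @classmethod
    def paper_defaults(cls, **overrides) -> "PipelineConfig":
        """The canonical thresholds: presence at >= 25% breadth with >= 5x
        depth in both samples, strain identity at 99.999% popANI."""
        return cls(**overrides)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def compute_presence(
    profiles: Iterable[AlleleProfile], config: PipelineConfig
) -> dict[tuple[str, str], PresenceCall]:
    return {
        (p.sample_id, p.species_id): presence_call(
            p, min_depth=config.min_depth, min_breadth=config.min_breadth
        )
        for p in profiles
    }


def compute_comparisons(
    profiles: Iterable[AlleleProfile],
    pairs: Sequence[tuple[str, str]],
    config: PipelineConfig,
) -> list[PairwiseComparison]:
    """Compare the requested sample pairs at every species profiled in both."""
    by_sample: dict[str, dict[str, AlleleProfile]] = {}
    for p in profiles:
        by_sample.setdefault(p.sample_id, {})[p.species_id] = p
    out = []
    for a, b in pairs:
        pa = by_sample.get(a, {})
        pb = by_sample.get(b, {})
        for species in sorted(set(pa) & set(pb)):
            out.append(
                compare_profiles(
                    pa[species],
                    pb[species],
                    min_depth=config.min_depth,
                    min_count=config.allele_min_count,
                    min_freq=config.allele_min_freq,
                )
            )
    return out


def comparisons_to_frame(comparisons: Iterable[PairwiseComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_a": c.sample_a,
                "sample_b": c.sample_b,
                "species_id": c.species_id,
                "n_compared": c.n_compared,
                "n_pop_subs": c.n_pop_subs,
                "n_con_subs": c.n_con_subs,
                "popani": c.popani,
                "conani": c.conani,
            }
            for c in comparisons
        ],
        columns=[
            "sample_a", "sample_b", "species_id", "n_compared",
            "n_pop_subs", "n_con_subs", "popani", "conani",
        ],
    )


@dataclasses.dataclass
class FMTResult:
    presence: dict[tuple[str, str], PresenceCall]
    comparisons: pd.DataFrame
    events: pd.DataFrame
    tier_table: pd.DataFrame
    tier_rates: pd.DataFrame
    category_stats: pd.DataFrame
    prevalence: pd.DataFrame
    prevalence_t: float | None
    prevalence_p: float | None
    family_p: float | None
    trait_enrichment: pd.DataFrame
    stage_counts: dict[str, int]


def analyze_fmt(
    sim: FMTSimulation,
    config: PipelineConfig,
    annotations: Mapping[str, TaxonAnnotation] | None = None,
) -> FMTResult:
    """Full transplant analysis: presence, pairwise popANI, the cumulative
    filter cascade, matched-vs-mismatched rate tests per tier, baseline
    prevalence, family composition, and trait permutation enrichment."""
    if annotations is None:
        annotations = synthetic_annotations(sim.pool, seed=config.seed)
    presence = compute_presence(sim.profiles, config)
    pairs = all_cohort_pairs(sim.design)
    comparisons = compute_comparisons(sim.profiles, pairs, config)
    cohort = CohortComparisons(presence, comparisons)
    logger.info(
        "fmt: %d profiles, %d species detected, %d comparisons",
        len(sim.profiles),
        len({p.species_id for p in sim.profiles}),
        len(comparisons),
    )

    events = find_sharing_events(cohort, sim.design, config.ani_threshold)
    events = assign_tiers(events, cohort, sim.design, config.ani_threshold)
    counts = tier_counts(events)
    logger.info("fmt: events per cumulative tier: %s", counts)

    tier_table = dyad_tier_table(cohort, sim.design, config.ani_threshold)
    rates = tier_sharing_rates(tier_table)

    stats_rows = []
    for tier in range(4):
        sub = rates[(rates["tier"] == tier) & rates["rate"].notna()]
        groups = {
            "matched": sub.loc[sub["matched"], "rate"].to_numpy(),
            "mismatched": sub.loc[~sub["matched"], "rate"].to_numpy(),
        }
        if min(len(v) for v in groups.values()) >= 2:
            table = compare_sharing_across_categories(groups, method="welch_bh")
            row = table.iloc[0]
            stats_rows.append(
                {
                    "tier": tier,
                    "matched_mean": groups["matched"].mean(),
                    "mismatched_mean": groups["mismatched"].mean(),
                    "statistic": row["statistic"],
                    "p_raw": row["p_raw"],
                    "computable": True,
                }
            )
        else:
            stats_rows.append(
                {
                    "tier": tier,
                    "matched_mean": groups["matched"].mean() if len(groups["matched"]) else float("nan"),
                    "mismatched_mean": groups["mismatched"].mean() if len(groups["mismatched"]) else float("nan"),
                    "statistic": float("nan"),
                    "p_raw": float("nan"),
                    "computable": False,
                }
            )
    category_stats = pd.DataFrame(stats_rows)
    ok = category_stats["computable"] & category_stats["p_raw"].notna()
    category_stats["p_adj"] = float("nan")
    if ok.any():
        from statsmodels.stats.multitest import multipletests

        category_stats.loc[ok, "p_adj"] = multipletests(
            category_stats.loc[ok, "p_raw"].to_numpy(), method="fdr_bh"
        )[1]

    baseline = list(sim.design.donor_samples) + [
        r.pre_sample for r in sim.design.recipients
    ]
    prevalence, prev_t, prev_p = prevalence_of_events(events, presence, baseline)

    matched_events = [e for e in events if e.matched]
    mismatched_events = [e for e in events if not e.matched]
    family_p = None
    if matched_events and mismatched_events:
        family_p = family_composition_test(
            matched_events,
            mismatched_events,
            annotations=annotations,
            n_mc=config.mc_draws,
            seed=config.seed,
        )

    trait_rows = []
    for trait, getter in (
        ("anaerobic", lambda sp: annotations[sp].oxygen == "anaerobic"
         if annotations[sp].oxygen != "unknown" else None),
        ("single_host", lambda sp: annotations[sp].host_range == "single_host"
         if annotations[sp].host_range != "unknown" else None),
    ):
        all_traits = [getter(e.species_id) for e in events]
        for tier in (1, 2, 3):
            subset = [getter(e.species_id) for e in events if e.tier >= tier]
            if not any(t is not None for t in subset):
                continue
            res = permutation_trait_enrichment(
                all_traits,
                subset,
                n_perm=config.n_perm,
                seed=config.seed + tier,
            )
            trait_rows.append(
                {
                    "trait": trait,
                    "tier": tier,
                    "observed_proportion": res.observed_proportion,
                    "p_value": res.p_value,
                    "n_perm": res.n_perm,
                    "subset_size": res.subset_size,
                }
            )
    trait_enrichment = pd.DataFrame(
        trait_rows,
        columns=["trait", "tier", "observed_proportion", "p_value", "n_perm", "subset_size"],
    )

    stage_counts = {
        "profiles": len(sim.profiles),
        "species_detected": len({p.species_id for p in sim.profiles}),
        "comparisons": len(comparisons),
        **{f"events_tier_{t}": counts[t] for t in range(4)},
    }
    return FMTResult(
        presence=presence,
        comparisons=comparisons_to_frame(comparisons),
        events=events_to_frame(events),
        tier_table=tier_table,
        tier_rates=rates,
        category_stats=category_stats,
        prevalence=prevalence,
        prevalence_t=prev_t,
        prevalence_p=prev_p,
        family_p=family_p,
        trait_enrichment=trait_enrichment,
        stage_counts=stage_counts,
    )


@dataclasses.dataclass
class SocialResult:
    presence: dict[tuple[str, str], PresenceCall]
    comparisons: pd.DataFrame
    summaries: list[DyadSummary]
    dyad_table: pd.DataFrame
    category_stats: pd.DataFrame
    covariate_table: pd.DataFrame
    covariate_report: pd.DataFrame
    stage_counts: dict[str, int]


def analyze_social(sim: SocialSimulation, config: PipelineConfig) -> SocialResult:
    """Wild-population analysis: per-dyad sharing rates, category contrasts
    (Tukey HSD by default), and simple regressions of sharing on diet,
    season, rainfall, and demographic covariates within the dyad categories
    where each predictor is defined."""
    presence = compute_presence(sim.profiles, config)
    pairs = [(r.sample_a, r.sample_b) for r in sim.dyads.itertuples()]
    comparisons = compute_comparisons(sim.profiles, pairs, config)
    by_pair: dict[frozenset[str], list[PairwiseComparison]] = {}
    for c in comparisons:
        by_pair.setdefault(frozenset((c.sample_a, c.sample_b)), []).append(c)

    summaries = []
    for row in sim.dyads.itertuples():
        comps = by_pair.get(frozenset((row.sample_a, row.sample_b)), [])
        summaries.append(
            summarize_dyad(
                row.sample_a,
                row.sample_b,
                comps,
                presence,
                ani_threshold=config.ani_threshold,
                category=row.category,
            )
        )
    dyad_table = pd.DataFrame(
        [
            {
                "sample_a": s.sample_a,
                "sample_b": s.sample_b,
                "category": s.category,
                "n_shared_species": s.n_shared_species,
                "n_shared_strains": s.n_shared_strains,
                "sharing_rate": s.sharing_rate,
            }
            for s in summaries
        ]
    )
    method = "tukey" if config.test_method == "tukey" else config.test_method
    n_categories = dyad_table.loc[
        dyad_table["sharing_rate"].notna(), "category"
    ].nunique()
    if n_categories >= 2:
        category_stats = compare_sharing_across_categories(summaries, method=method)
    else:  # single-category designs have no contrast to test
        category_stats = pd.DataFrame(
            columns=["category_a", "category_b", "statistic", "p_adj", "computable"]
        )

    covariate_table = sim.covariates.merge(
        dyad_table[["sample_a", "sample_b", "sharing_rate"]],
        on=["sample_a", "sample_b"],
    )
    # predictors evaluated within the dyad categories where they are defined
    reports = []
    spec = [
        ("diet_similarity_jaccard", "different_groups"),
        ("diet_dissimilarity", "different_groups"),
        ("month_distance", "different_groups"),
        ("rainfall_total", "never_overlapped"),
        ("years_between", "never_overlapped"),
        ("age_difference", None),
    ]
    for predictor, category in spec:
        sub = covariate_table
        if category is not None:
            sub = sub[sub["category"] == category]
        rep = cov.covariate_report(
            sub[[predictor, "sharing_rate"]].dropna(),
            response="sharing_rate",
            predictors=[predictor],
        )
        rep.insert(1, "category", category or "all")
        reports.append(rep)
    covariate_rep = pd.concat(reports, ignore_index=True)

    stage_counts = {
        "profiles": len(sim.profiles),
        "species_detected": len({p.species_id for p in sim.profiles}),
        "comparisons": len(comparisons),
        "dyads": len(summaries),
        "dyads_with_defined_rate": int(dyad_table["sharing_rate"].notna().sum()),
    }
    logger.info("social: stage counts %s", stage_counts)
    return SocialResult(
        presence=presence,
        comparisons=comparisons_to_frame(comparisons),
        summaries=summaries,
        dyad_table=dyad_table,
        category_stats=category_stats,
        covariate_table=covariate_table,
        covariate_report=covariate_rep,
        stage_counts=stage_counts,
    )


def run_pipeline(
    config: PipelineConfig,
    sim: FMTSimulation | SocialSimulation | None = None,
):
    """Simulate (unless a cohort is supplied) and analyze under ``config``.

    Returns the :class:`FMTResult` or :class:`SocialResult` bundle for the
    configured design. Fully reproducible: all randomness flows from
    ``config.simulation.seed`` (generation) and ``config.seed`` (tests).
    """
    if config.design == "fmt":
        if sim is None:
            sim = simulate_fmt_cohort(config.simulation)
        if not isinstance(sim, FMTSimulation):
            raise ValueError("design 'fmt' requires an FMT cohort")
        return analyze_fmt(sim, config)
    if sim is None:
        sim = simulate_social_cohort(config.simulation, SocialDesign())
    if not isinstance(sim, SocialSimulation):
        raise ValueError("design 'social' requires a social cohort")
    return analyze_social(sim, config)
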