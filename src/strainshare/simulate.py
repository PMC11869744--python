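"""Forward simulator of strain transmission with known ground truth.

The generator emulates two study designs end to end, emitting exactly the
inputs the analysis modules consume (allele profiles, sample metadata, taxon
annotations, dyad covariates) together with a truth table labelling the
origin of every strain instance:

* a fecal microbiota transplant (FMT) cohort — healthy donors, recipients
  sampled pre and post transplant, single designated donor per recipient,
  antibiotic-style depletion before engraftment, plus environmental
  acquisition from a shared strain pool;
* a wild social-population cohort — host dyads whose lives never overlapped,
  dyads in different social groups sampled close in time, close social
  partners, and longitudinal self-pairs, with environmental strain pools
  coupled to diet and season and within-host persistence across repeat
  samples.

Species are modelled as pools of well-separated haplotypes: transmission
copies a haplotype exactly (optionally with mutation), so with the default
inter-haplotype divergence a transmitted strain compares at popANI 1.0 while
distinct haplotypes fall far below the 99.999% strain-identity threshold.
Sequencing draws Poisson depth per site and multinomial base counts over the
sample's haplotype frequencies with a uniform misread error rate.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import itertools
from typing import Mapping

import numpy as np
import pandas as pd

from .cascade import FMTDesign, Recipient
from .enrichment import TaxonAnnotation
from .profiles import AlleleProfile
from .sharing import SampleRecord

Community = dict[int, list[tuple["StrainInstance", float]]]


@dataclasses.dataclass
class SimulationConfig:
    """Generative parameters shared by both cohort designs.

    The defaults encode the simulated study conditions: 10 kb genomes, pools
    of 8 haplotypes per species at >= 10 substitutions pairwise divergence
    (so distinct haplotypes sit near 99.8% popANI, far below the 99.999%
    sharing threshold, while exact transmission copies sit at 100%),
    geometric species prevalence over hosts, 20x mean sequencing depth and a
    0.1% read error rate.
    """

    n_species: int = 40
    n_haplotypes: int = 8
    sites_per_genome: int = 10_000
    inter_haplotype_divergence: int = 10
    prevalence_geom_p: float = 0.2
    prevalence_max_hosts: int = 13
    within_host_mutation_rate: float = 0.0
    engraftment_prob: float = 0.8
    depletion_survival: float = 0.2
    environmental_acquisition_rate: float = 0.05
    mean_depth: float = 20.0
    error_rate: float = 0.001
    genome_breadth: float = 1.0
    # social-cohort couplings
    diet_coupling: float = 0.5
    season_coupling: float = 0.2
    persistence: float = 0.9
    social_transmission_prob: float = 0.05
    rain_microdiversity: float = 0.5
    n_food_types: int = 10
    diet_latent_spread: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_haplotypes < 1:
            raise ValueError("n_species and n_haplotypes must be positive")
        if self.n_haplotypes * self.inter_haplotype_divergence > self.sites_per_genome:
            raise ValueError(
                "inter-haplotype divergence infeasible for the genome length"
            )
        for name in (
            "prevalence_geom_p",
            "within_host_mutation_rate",
            "engraftment_prob",
            "depletion_survival",
            "environmental_acquisition_rate",
            "error_rate",
            "genome_breadth",
            "diet_coupling",
            "season_coupling",
            "persistence",
            "social_transmission_prob",
            "rain_microdiversity",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if self.diet_coupling + self.season_coupling > 1.0:
            raise ValueError("diet_coupling + season_coupling must not exceed 1")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclasses.dataclass
class SpeciesPool:
    """Per-species haplotype genotypes and carriage prevalence."""

    species_ids: list[str]
    genotypes: np.ndarray  # (S, K, L) uint8 base indices
    prevalence: np.ndarray  # (S,) carriage probability per host

    @property
    def n_species(self) -> int:
        return len(self.species_ids)


@dataclasses.dataclass
class StrainInstance:
    species: int
    haplotype: int  # pool index, or -1 for a mutated derivative
    genotype: np.ndarray  # (L,) uint8
    origin: str  # resident | pre_existing | transmitted | environmental
    source_sample: str | None
    label: str


def simulate_species_pool(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SpeciesPool:
    """Draw the species pool: K haplotypes per species with pairwise Hamming
    distance >= the configured divergence (each haplotype carries a private
    block of substitutions on a shared ancestral genome), and a geometric
    carriage prevalence per species."""
    rng = config.rng() if rng is None else rng
    S, K, L = config.n_species, config.n_haplotypes, config.sites_per_genome
    div = config.inter_haplotype_divergence
    genotypes = np.empty((S, K, L), dtype=np.uint8)
    for s in range(S):
        base = rng.integers(0, 4, size=L, dtype=np.uint8)
        private = rng.choice(L, size=K * div, replace=False)
        for k in range(K):
            geno = base.copy()
            pos = private[k * div : (k + 1) * div]
            geno[pos] = (geno[pos] + rng.integers(1, 4, size=div)) % 4
            genotypes[s, k] = geno
    carriers = rng.geometric(config.prevalence_geom_p, size=S)
    prevalence = np.clip(carriers / config.prevalence_max_hosts, 0.0, 1.0)
    species_ids = [f"sp{s:03d}" for s in range(S)]
    return SpeciesPool(species_ids, genotypes, prevalence)


def sequence_profiles(
    communities: Mapping[str, Community],
    pool: SpeciesPool,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[AlleleProfile]:
    """Sequence every (sample, species) community into an allele profile.

    Per site: depth ~ Poisson(mean_depth), reads split multinomially over
    the sample's strain frequencies, and each read misreads to a uniform
    other base with probability ``error_rate``. ``genome_breadth`` < 1 masks
    a random fraction of sites to zero depth.
    """
    rng = config.rng() if rng is None else rng
    L = config.sites_per_genome
    profiles = []
    for sample_id in communities:
        for species in sorted(communities[sample_id]):
            strains = communities[sample_id][species]
            if not strains:
                continue
            freqs = np.array([w for _, w in strains], dtype=float)
            total = freqs.sum()
            if total <= 0:
                raise ValueError("strain frequencies must sum to a positive value")
            freqs = freqs / total
            depth = rng.poisson(config.mean_depth, size=L)
            if config.genome_breadth < 1.0:
                depth = depth * (rng.random(L) < config.genome_breadth)
            reads = rng.multinomial(depth, freqs)  # (L, H)
            counts = np.zeros((L, 4), dtype=np.int64)
            rows = np.arange(L)
            for j, (strain, _) in enumerate(strains):
                counts[rows, strain.genotype] += reads[:, j]
            if config.error_rate > 0:
                err = rng.binomial(counts, config.error_rate)
                counts -= err
                third = np.full(3, 1 / 3)
                for b in range(4):
                    others = [x for x in range(4) if x != b]
                    counts[:, others] += rng.multinomial(err[:, b], third)
            covered = counts.sum(axis=1) > 0
            profiles.append(
                AlleleProfile(
                    sample_id=sample_id,
                    species_id=pool.species_ids[species],
                    genome_length=L,
                    positions=np.flatnonzero(covered),
                    counts=counts[covered],
                )
            )
    return profiles


def _copy_strain(
    strain: StrainInstance,
    origin: str,
    source_sample: str | None,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> StrainInstance:
    """Copy a strain across a transfer, optionally mutating it."""
    genotype = strain.genotype
    haplotype = strain.haplotype
    label = strain.label
    if config.within_host_mutation_rate > 0:
        n_mut = rng.binomial(genotype.size, config.within_host_mutation_rate)
        if n_mut:
            genotype = genotype.copy()
            pos = rng.choice(genotype.size, size=n_mut, replace=False)
            genotype[pos] = (genotype[pos] + rng.integers(1, 4, size=n_mut)) % 4
            haplotype = -1
            label = f"{label}.m"
    return StrainInstance(
        species=strain.species,
        haplotype=haplotype,
        genotype=genotype,
        origin=origin,
        source_sample=source_sample,
        label=label,
    )


def _pool_strain(
    pool: SpeciesPool,
    species: int,
    haplotype: int,
    origin: str,
    source_sample: str | None = None,
) -> StrainInstance:
    return StrainInstance(
        species=species,
        haplotype=haplotype,
        genotype=pool.genotypes[species, haplotype],
        origin=origin,
        source_sample=source_sample,
        label=f"{pool.species_ids[species]}.h{haplotype}",
    )


def _add_strain(community: Community, strain: StrainInstance, weight: float = 1.0) -> None:
    """Add a strain, merging genotype-identical instances.

    Merge keeps the earlier origin: a pre-existing strain identical to an
    engrafted one stays pre_existing (the transfer is unobservable), and a
    transmitted strain absorbs an identical environmental acquisition.
    """
    strains = community.setdefault(strain.species, [])
    for existing, _ in strains:
        if existing.haplotype == strain.haplotype and (
            strain.haplotype != -1
            or np.array_equal(existing.genotype, strain.genotype)
        ):
            return
    strains.append((strain, weight))


def _truth_frame(communities: Mapping[str, Community], pool: SpeciesPool) -> pd.DataFrame:
    rows = []
    for sample_id in communities:
        for species in sorted(communities[sample_id]):
            for strain, _ in communities[sample_id][species]:
                rows.append(
                    {
                        "sample_id": sample_id,
                        "species_id": pool.species_ids[species],
                        "strain_label": strain.label,
                        "origin": strain.origin,
                        "source_sample": strain.source_sample or "",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "species_id", "strain_label", "origin", "source_sample"],
    )


@dataclasses.dataclass
class FMTSimulation:
    config: SimulationConfig
    pool: SpeciesPool
    profiles: list[AlleleProfile]
    metadata: list[SampleRecord]
    design: FMTDesign
    truth: pd.DataFrame
    communities: dict[str, Community]


def simulate_fmt_cohort(
    config: SimulationConfig,
    n_donors: int = 5,
    n_recipients: int = 8,
) -> FMTSimulation:
    """Simulate the transplant design: donor samples, recipient pre/post
    samples, one designated donor per recipient.

    Recipient pre-FMT communities undergo independent per-strain depletion
    (surviving with ``depletion_survival``, the antibiotic analogue); each
    species carried by the designated donor engrafts with
    ``engraftment_prob`` (recorded as a transmitted strain); post-FMT samples
    additionally acquire, per species, a random pool haplotype with
    ``environmental_acquisition_rate``.
    """
    rng = config.rng()
    pool = simulate_species_pool(config, rng)
    S = pool.n_species

    donor_samples = [f"D{i + 1}" for i in range(n_donors)]
    designated = rng.integers(0, n_donors, size=n_recipients)

    # carriage and haplotype per host
    def draw_carriage() -> dict[int, int]:
        carried = np.flatnonzero(rng.random(S) < pool.prevalence)
        return {int(s): int(rng.integers(config.n_haplotypes)) for s in carried}

    communities: dict[str, Community] = {}
    for d in donor_samples:
        communities[d] = {}
        for s, h in draw_carriage().items():
            _add_strain(communities[d], _pool_strain(pool, s, h, "resident"))

    recipients = []
    metadata = [
        SampleRecord(sample_id=d, host_id=d, date=dt.date(2020, 1, 1), role="donor")
        for d in donor_samples
    ]
    base_date = dt.date(2020, 1, 1)
    for i in range(n_recipients):
        host = f"R{i + 1}"
        pre, post = f"{host}_pre", f"{host}_post"
        donor = donor_samples[designated[i]]
        recipients.append(
            Recipient(
                host_id=host,
                pre_sample=pre,
                post_sample=post,
                designated_donor_sample=donor,
            )
        )
        metadata += [
            SampleRecord(pre, host, base_date, role="recipient", timepoint="pre",
                         designated_donor=donor),
            SampleRecord(post, host, base_date + dt.timedelta(days=20),
                         role="recipient", timepoint="post", designated_donor=donor),
        ]

        pre_comm: Community = {}
        for s, h in draw_carriage().items():
            _add_strain(pre_comm, _pool_strain(pool, s, h, "resident"))
        communities[pre] = pre_comm

        post_comm: Community = {}
        # retained pre-FMT strains first, so identical engraftments merge
        # into pre_existing
        for s, strains in pre_comm.items():
            for strain, _ in strains:
                if rng.random() < config.depletion_survival:
                    _add_strain(
                        post_comm,
                        dataclasses.replace(
                            strain, origin="pre_existing", source_sample=pre
                        ),
                    )
        for s, strains in communities[donor].items():
            for strain, _ in strains:
                if rng.random() < config.engraftment_prob:
                    _add_strain(
                        post_comm,
                        _copy_strain(strain, "transmitted", donor, config, rng),
                    )
        env = np.flatnonzero(
            rng.random(S) < config.environmental_acquisition_rate
        )
        for s in env:
            h = int(rng.integers(config.n_haplotypes))
            _add_strain(post_comm, _pool_strain(pool, int(s), h, "environmental"))
        communities[post] = post_comm

    profiles = sequence_profiles(communities, pool, config, rng)
    design = FMTDesign(tuple(donor_samples), tuple(recipients))
    return FMTSimulation(
        config=config,
        pool=pool,
        profiles=profiles,
        metadata=metadata,
        design=design,
        truth=_truth_frame(communities, pool),
        communities=communities,
    )


@dataclasses.dataclass
class SocialDesign:
    """Dyad category counts for the wild-population design."""

    n_never_overlapped: int = 23
    n_different_groups: int = 20
    n_close_partners: int = 26
    n_longitudinal: int = 22

    def __post_init__(self) -> None:
        counts = (
            self.n_never_overlapped,
            self.n_different_groups,
            self.n_close_partners,
            self.n_longitudinal,
        )
        if any(c < 0 for c in counts) or sum(counts) == 0:
            raise ValueError("category counts must be non-negative, not all zero")


@dataclasses.dataclass
class SocialSimulation:
    config: SimulationConfig
    pool: SpeciesPool
    profiles: list[AlleleProfile]
    metadata: list[SampleRecord]
    dyads: pd.DataFrame  # sample_a, sample_b, host_a, host_b, category
    covariates: pd.DataFrame
    diets: dict[str, pd.Series]  # sample_id -> diet composition
    rainfall: pd.Series  # daily mm
    lifespans: dict[str, tuple[dt.date, dt.date | None]]
    close_partners: set[frozenset[str]]
    truth: pd.DataFrame
    communities: dict[str, Community]


def generate_rainfall(
    rng: np.random.Generator,
    start_year: int = 2007,
    end_year: int = 2017,
    dry_months: tuple[int, ...] = (6, 7, 8, 9, 10),
    wet_mean: float = 60.0,
    dry_mean: float = 5.0,
) -> pd.Series:
    """Daily rainfall series (mm) with a 5-month dry season: monthly totals
    are Gamma-distributed around a seasonal mean and spread uniformly over
    the month's days."""
    dates, values = [], []
    for year in range(start_year, end_year + 1):
        for month in range(1, 13):
            mean = dry_mean if month in dry_months else wet_mean
            total = rng.gamma(2.0, mean / 2.0)
            ndays = pd.Period(f"{year}-{month:02d}").days_in_month
            for day in range(1, ndays + 1):
                dates.append(dt.date(year, month, day))
                values.append(total / ndays)
    return pd.Series(values, index=pd.DatetimeIndex(dates), name="rainfall_mm")


def _diet_vector(z: float, n_foods: int, rng: np.random.Generator) -> pd.Series:
    """Sparse diet composition from a 1-D latent environmental coordinate."""
    centers = (np.arange(n_foods) + 0.5) / n_foods
    w = np.exp(-0.5 * ((centers - z) / 0.12) ** 2)
    w = w * (1 + 0.1 * rng.random(n_foods))
    w[w < 0.2 * w.max()] = 0.0
    w = w / w.sum()
    return pd.Series(w, index=[f"food_{i:02d}" for i in range(n_foods)])


def simulate_social_cohort(
    config: SimulationConfig,
    design: SocialDesign | None = None,
) -> SocialSimulation:
    """Simulate the wild-population dyad design.

    Every host-sample assembles its community from an environmental strain
    pool: with probability ``diet_coupling`` the haplotype acquired for a
    species is determined by the host's diet latent, with
    ``season_coupling`` by the sampling month, otherwise uniform — so
    environmental-pool overlap increases with diet similarity and seasonal
    proximity. Rainy months add extra minor strains per species
    (``rain_microdiversity``), close partners exchange strains with
    ``social_transmission_prob``, and longitudinal self-pairs retain strains
    with ``persistence`` (turnover, i.e. new acquisition in the second
    sample, scales with 1 - persistence).
    """
    design = design or SocialDesign()
    rng = config.rng()
    pool = simulate_species_pool(config, rng)
    S, K = pool.n_species, config.n_haplotypes
    rainfall = generate_rainfall(rng)
    monthly = rainfall.groupby(pd.DatetimeIndex(rainfall.index).to_period("M")).sum()
    max_monthly = float(monthly.max())

    metadata: list[SampleRecord] = []
    communities: dict[str, Community] = {}
    diets: dict[str, pd.Series] = {}
    lifespans: dict[str, tuple[dt.date, dt.date | None]] = {}
    close_partners: set[frozenset[str]] = set()
    dyad_rows = []

    def rand_date(y0: int, y1: int) -> dt.date:
        start = dt.date(y0, 1, 1).toordinal()
        end = dt.date(y1, 12, 31).toordinal()
        return dt.date.fromordinal(int(rng.integers(start, end + 1)))

    def assemble(sample_id: str, z: float, date: dt.date) -> Community:
        """Environmental community assembly for one sample."""
        rain_norm = float(monthly[pd.Period(date, freq="M")]) / max_monthly
        k_diet = min(K - 1, int(z * K))
        k_season = (date.month - 1) * K // 12
        comm: Community = {}
        carried = np.flatnonzero(rng.random(S) < pool.prevalence)
        for s in carried:
            u = rng.random()
            if u < config.diet_coupling:
                h = k_diet
            elif u < config.diet_coupling + config.season_coupling:
                h = k_season
            else:
                h = int(rng.integers(K))
            _add_strain(comm, _pool_strain(pool, int(s), h, "environmental"))
            if rng.random() < config.rain_microdiversity * rain_norm:
                h2 = int(rng.integers(K))
                _add_strain(
                    comm, _pool_strain(pool, int(s), h2, "environmental"), weight=0.5
                )
        return comm

    def new_host(prefix: str, i: int, suffix: str) -> str:
        return f"{prefix}{i + 1}{suffix}"

    # --- never-overlapped dyads: first host dies before the second is born
    for i in range(design.n_never_overlapped):
        ha, hb = new_host("N", i, "a"), new_host("N", i, "b")
        sa, sb = f"{ha}_s1", f"{hb}_s1"
        birth_a = rand_date(1998, 2000)
        death_a = rand_date(2008, 2009)
        birth_b = rand_date(2010, 2011)
        lifespans[ha] = (birth_a, death_a)
        lifespans[hb] = (birth_b, None)
        date_a = rand_date(2007, death_a.year - 1)
        date_b = rand_date(birth_b.year + 1, 2017)
        za = rng.random()
        zb = rng.random()
        ga, gb = f"G_N{i}a", f"G_N{i}b"
        metadata += [
            SampleRecord(sa, ha, date_a, group=ga),
            SampleRecord(sb, hb, date_b, group=gb),
        ]
        diets[sa] = _diet_vector(za, config.n_food_types, rng)
        diets[sb] = _diet_vector(zb, config.n_food_types, rng)
        communities[sa] = assemble(sa, za, date_a)
        communities[sb] = assemble(sb, zb, date_b)
        dyad_rows.append((sa, sb, ha, hb, "never_overlapped"))

    # --- different social groups, sampled < 150 days apart
    for i in range(design.n_different_groups):
        ha, hb = new_host("DG", i, "a"), new_host("DG", i, "b")
        sa, sb = f"{ha}_s1", f"{hb}_s1"
        for h in (ha, hb):
            lifespans[h] = (rand_date(2000, 2004), None)
        date_a = rand_date(2008, 2016)
        date_b = date_a + dt.timedelta(days=int(rng.integers(0, 150)))
        za = rng.random()
        zb = float(np.clip(za + rng.normal(0, config.diet_latent_spread), 0, 1))
        metadata += [
            SampleRecord(sa, ha, date_a, group=f"G_DG{i}a"),
            SampleRecord(sb, hb, date_b, group=f"G_DG{i}b"),
        ]
        diets[sa] = _diet_vector(za, config.n_food_types, rng)
        diets[sb] = _diet_vector(zb, config.n_food_types, rng)
        communities[sa] = assemble(sa, za, date_a)
        communities[sb] = assemble(sb, zb, date_b)
        dyad_rows.append((sa, sb, ha, hb, "different_groups"))

    # --- close social partners: same group, < 4 days apart
    for i in range(design.n_close_partners):
        ha, hb = new_host("CP", i, "a"), new_host("CP", i, "b")
        sa, sb = f"{ha}_s1", f"{hb}_s1"
        for h in (ha, hb):
            lifespans[h] = (rand_date(2000, 2004), None)
        group = f"G_CP{i}"
        date_a = rand_date(2008, 2016)
        date_b = date_a + dt.timedelta(days=int(rng.integers(0, 4)))
        # same group, same year: shared group-level diet
        z = rng.random()
        metadata += [
            SampleRecord(sa, ha, date_a, group=group),
            SampleRecord(sb, hb, date_b, group=group),
        ]
        diets[sa] = diets[sb] = _diet_vector(z, config.n_food_types, rng)
        close_partners.add(frozenset((ha, hb)))
        ca = assemble(sa, z, date_a)
        cb = assemble(sb, z, date_b)
        # social transmission both ways, from pre-exchange snapshots
        for src, src_id, dst in ((ca, sa, cb), (dict(cb), sb, ca)):
            for s, strains in list(src.items()):
                for strain, _ in list(strains):
                    if strain.origin != "environmental":
                        continue
                    if rng.random() < config.social_transmission_prob:
                        _add_strain(
                            dst, _copy_strain(strain, "transmitted", src_id, config, rng)
                        )
        communities[sa] = ca
        communities[sb] = cb
        dyad_rows.append((sa, sb, ha, hb, "close_partners"))

    # --- longitudinal self-pairs, 120-150 days apart
    for i in range(design.n_longitudinal):
        host = new_host("L", i, "")
        sa, sb = f"{host}_s1", f"{host}_s2"
        lifespans[host] = (rand_date(2000, 2004), None)
        group = f"G_L{i}"
        date_a = rand_date(2008, 2016)
        date_b = date_a + dt.timedelta(days=int(rng.integers(120, 151)))
        z = rng.random()
        metadata += [
            SampleRecord(sa, host, date_a, group=group),
            SampleRecord(sb, host, date_b, group=group),
        ]
        diets[sa] = diets[sb] = _diet_vector(z, config.n_food_types, rng)
        first = assemble(sa, z, date_a)
        second: Community = {}
        for s, strains in first.items():
            for strain, w in strains:
                if rng.random() < config.persistence:
                    _add_strain(
                        second,
                        dataclasses.replace(
                            strain, origin="pre_existing", source_sample=sa
                        ),
                        weight=w,
                    )
        # turnover: new environmental acquisition scales with 1 - persistence
        turnover = (1 - config.persistence) * pool.prevalence
        for s in np.flatnonzero(rng.random(S) < turnover):
            h = int(rng.integers(K))
            _add_strain(second, _pool_strain(pool, int(s), h, "environmental"))
        communities[sa] = first
        communities[sb] = second
        dyad_rows.append((sa, sb, host, host, "longitudinal"))

    profiles = sequence_profiles(communities, pool, config, rng)
    dyads = pd.DataFrame(
        dyad_rows, columns=["sample_a", "sample_b", "host_a", "host_b", "category"]
    )

    # dyad covariates (the same quantities the covariates module computes
    # from raw inputs; kept here so simulations expose ready-made predictors)
    from . import covariates as cov

    records = {m.sample_id: m for m in metadata}
    cov_rows = []
    for row in dyads.itertuples():
        a, b = records[row.sample_a], records[row.sample_b]
        births = {h: lifespans[h][0] for h in (row.host_a, row.host_b)}
        age_a = (a.date - births[row.host_a]).days / 365.25
        age_b = (b.date - births[row.host_b]).days / 365.25
        cov_rows.append(
            {
                "sample_a": row.sample_a,
                "sample_b": row.sample_b,
                "category": row.category,
                "diet_dissimilarity": cov.diet_dissimilarity(
                    diets[row.sample_a], diets[row.sample_b], metric="bray_curtis"
                ),
                "diet_similarity_jaccard": 1.0
                - cov.diet_dissimilarity(
                    diets[row.sample_a], diets[row.sample_b], metric="jaccard"
                ),
                "month_distance": cov.month_distance(a.date.month, b.date.month),
                "rainfall_total": cov.rainfall_covariate(rainfall, a.date, b.date),
                "years_between": abs((a.date - b.date).days) / 365.25,
                "age_difference": abs(age_a - age_b),
            }
        )
    covariate_df = pd.DataFrame(cov_rows)

    return SocialSimulation(
        config=config,
        pool=pool,
        profiles=profiles,
        metadata=metadata,
        dyads=dyads,
        covariates=covariate_df,
        diets=diets,
        rainfall=rainfall,
        lifespans=lifespans,
        close_partners=close_partners,
        truth=_truth_frame(communities, pool),
        communities=communities,
    )


def synthetic_annotations(
    pool: SpeciesPool,
    seed: int = 0,
    n_families: int = 8,
) -> dict[str, TaxonAnnotation]:
    """Synthetic taxon annotations for a simulated species pool: random
    family/genus assignment and genus-level oxygen / host-range labels drawn
    with gut-community-like proportions."""
    rng = np.random.default_rng(seed)
    out = {}
    for i, sp in enumerate(pool.species_ids):
        fam = f"family_{rng.integers(n_families):02d}"
        oxygen = rng.choice(
            ["aerobic", "anaerobic", "mixed", "unknown"], p=[0.1, 0.55, 0.25, 0.1]
        )
        host_range = rng.choice(
            ["single_host", "multi_host", "unknown"], p=[0.35, 0.55, 0.1]
        )
        out[sp] = TaxonAnnotation(
            species_id=sp,
            family=fam,
            genus=f"genus_{i:03d}",
            oxygen=str(oxygen),
            host_range=str(host_range),
        )
    return out


def all_sample_pairs(samples: list[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(samples, 2))
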