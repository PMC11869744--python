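import numpy as np
import pytest

from strainshare import AlleleProfile, SimulationConfig
from strainshare.simulate import simulate_fmt_cohort


def make_profile(sample_id, species_id, genome_length, sites):
    """Build an AlleleProfile from {position: (A, C, G, T)}."""
    positions = np.array(sorted(sites), dtype=np.int64)
    counts = np.array([sites[p] for p in positions], dtype=np.int64).reshape(-1, 4)
    return AlleleProfile(sample_id, species_id, genome_length, positions, counts)


def brute_force_comparison(sites_a, sites_b, min_depth=5, min_count=2, min_freq=0.05):
    """Independent site-by-site popANI/conANI enumeration in pure Python.

    Returns (n_compared, n_pop_subs, n_con_subs).
    """
    n = pop = con = 0
    for pos in set(sites_a) & set(sites_b):
        ca, cb = sites_a[pos], sites_b[pos]
        da, db = sum(ca), sum(cb)
        if da < min_depth or db < min_depth:
            continue
        n += 1

        def detected(c, d):
            return {i for i in range(4) if c[i] >= min_count and c[i] / d >= min_freq}

        def consensus(c):
            # highest count; ties go to the alphabetically first base
            return max(range(4), key=lambda i: (c[i], -i))

        if not (detected(ca, da) & detected(cb, db)):
            pop += 1
            con += 1
        elif consensus(ca) != consensus(cb):
            con += 1
    return n, pop, con


def random_sites(rng, max_sites=50, genome_length=50):
    """Random sparse site map with mixed depths straddling the thresholds."""
    n = int(rng.integers(0, max_sites + 1))
    positions = rng.choice(genome_length, size=n, replace=False)
    sites = {}
    for p in positions:
        counts = rng.integers(0, 12, size=4)
        if rng.random() < 0.3:  # occasional high-depth biallelic site
            major = int(rng.integers(4))
            counts[major] += int(rng.integers(5, 30))
        sites[int(p)] = tuple(int(c) for c in counts)
    return sites


@pytest.fixture(scope="session")
def small_fmt():
    """Small transplant cohort reused by several test modules."""
    config = SimulationConfig(
        seed=7, n_species=12, sites_per_genome=1500, n_haplotypes=6,
    )
    return simulate_fmt_cohort(config)
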