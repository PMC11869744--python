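"""Taxonomic/functional annotation of sharing events and enrichment tests.

Species are annotated at genus level for oxygen tolerance (all entries in
the genus obligate aerobes -> aerobic; all obligate anaerobes -> anaerobic;
any mixture -> mixed) and host range (reported in a single host taxon ->
single_host, otherwise multi_host). Event sets are compared by family
composition (Fisher exact / conditional Monte Carlo), family-wise log2 odds
ratios, baseline species prevalence, and subset permutation tests against
the full event list.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cascade import SharingEvent
from .profiles import PresenceCall

logger = logging.getLogger(__name__)

OXYGEN_LABELS = ("aerobic", "anaerobic", "mixed", "unknown")
HOST_RANGE_LABELS = ("single_host", "multi_host", "unknown")


@dataclasses.dataclass(frozen=True)
class TaxonAnnotation:
    species_id: str
    family: str
    genus: str
    oxygen: str = "unknown"
    host_range: str = "unknown"
    prevalence: int | None = None

    def __post_init__(self) -> None:
        if self.oxygen not in OXYGEN_LABELS:
            raise ValueError(f"oxygen must be one of {OXYGEN_LABELS}")
        if self.host_range not in HOST_RANGE_LABELS:
            raise ValueError(f"host_range must be one of {HOST_RANGE_LABELS}")


def annotate_oxygen(genus_entries: Iterable[str]) -> str:
    """Genus-level oxygen label from per-entry phenotypes.

    Entries use the vocabulary {'aerobe', 'anaerobe', 'facultative'}.
    """
    entries = [e.lower() for e in genus_entries]
    if not entries:
        return "unknown"
    bad = set(entries) - {"aerobe", "anaerobe", "facultative"}
    if bad:
        raise ValueError(f"unknown oxygen phenotypes: {sorted(bad)}")
    if all(e == "aerobe" for e in entries):
        return "aerobic"
    if all(e == "anaerobe" for e in entries):
        return "anaerobic"
    return "mixed"


def annotate_host_range(genus_entries: Iterable[str]) -> str:
    """single_host when every entry in the genus reports one host taxon."""
    hosts = {h for h in genus_entries}
    if not hosts:
        return "unknown"
    return "single_host" if len(hosts) == 1 else "multi_host"


def _families(events: Iterable[SharingEvent | str], annotations: Mapping[str, TaxonAnnotation] | None) -> list[str]:
    fams = []
    for e in events:
        if isinstance(e, SharingEvent):
            if annotations is None:
                raise ValueError("annotations required to resolve event families")
            fams.append(annotations[e.species_id].family)
        else:
            fams.append(e)
    return fams


def family_composition_test(
    events_a: Iterable[SharingEvent | str],
    events_b: Iterable[SharingEvent | str],
    annotations: Mapping[str, TaxonAnnotation] | None = None,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Test whether two event sets draw from different family compositions.

    Builds the family x group contingency table. 2x2 tables get the exact
    Fisher test; r x 2 tables get a conditional Monte Carlo exact test:
    group-A family counts are drawn from the multivariate hypergeometric
    distribution fixed at the observed margins and compared on the chi-square
    discrepancy. A single family overall is untestable (p = 1).
    """
    fam_a = _families(events_a, annotations)
    fam_b = _families(events_b, annotations)
    if not fam_a or not fam_b:
        raise ValueError("both event groups must be non-empty")
    families = sorted(set(fam_a) | set(fam_b))
    if len(families) == 1:
        return 1.0
    ca = Counter(fam_a)
    cb = Counter(fam_b)
    a = np.array([ca.get(f, 0) for f in families], dtype=np.int64)
    b = np.array([cb.get(f, 0) for f in families], dtype=np.int64)

    if len(families) == 2:
        table = np.array([[a[0], b[0]], [a[1], b[1]]])
        return float(stats.fisher_exact(table)[1])

    totals = a + b
    n_a, n_b = int(a.sum()), int(b.sum())
    n = n_a + n_b
    ea = totals * (n_a / n)
    eb = totals * (n_b / n)

    def chi2(draw_a: np.ndarray) -> np.ndarray:
        draw_b = totals - draw_a
        return ((draw_a - ea) ** 2 / ea + (draw_b - eb) ** 2 / eb).sum(axis=-1)

    observed = float(chi2(a))
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(totals, n_a, size=n_mc)
    simulated = chi2(draws)
    # add-one so the Monte Carlo p never reports an impossible zero
    return float((1 + np.count_nonzero(simulated >= observed - 1e-12)) / (n_mc + 1))


@dataclasses.dataclass(frozen=True)
class LogOddsResult:
    family: str
    log2_odds: float
    ci_low: float
    ci_high: float
    table: tuple[int, int, int, int]  # (a_in, a_out, b_in, b_out)


def family_log_odds(
    events_a: Iterable[SharingEvent | str],
    events_b: Iterable[SharingEvent | str],
    family: str,
    annotations: Mapping[str, TaxonAnnotation] | None = None,
    ci: float = 0.95,
) -> LogOddsResult:
    """log2 odds ratio of family membership between two event groups.

    Haldane-Anscombe: 0.5 is added to every cell when any cell is zero. The
    confidence interval is the Woolf (log-scale normal) interval.
    """
    fam_a = _families(events_a, annotations)
    fam_b = _families(events_b, annotations)
    a_in = sum(f == family for f in fam_a)
    a_out = len(fam_a) - a_in
    b_in = sum(f == family for f in fam_b)
    b_out = len(fam_b) - b_in
    cells = np.array([a_in, a_out, b_in, b_out], dtype=float)
    if np.any(cells == 0):
        cells = cells + 0.5
    log_or = math.log(cells[0] * cells[3] / (cells[1] * cells[2]))
    se = math.sqrt((1.0 / cells).sum())
    z = stats.norm.ppf(0.5 + ci / 2)
    ln2 = math.log(2.0)
    return LogOddsResult(
        family=family,
        log2_odds=log_or / ln2,
        ci_low=(log_or - z * se) / ln2,
        ci_high=(log_or + z * se) / ln2,
        table=(a_in, a_out, b_in, b_out),
    )


def prevalence_of_events(
    events: Sequence[SharingEvent],
    presence: Mapping[tuple[str, str], PresenceCall | bool],
    baseline_samples: Sequence[str],
) -> tuple[pd.DataFrame, float | None, float | None]:
    """Baseline population prevalence of each event's species.

    Prevalence is the number of ``baseline_samples`` (e.g. donors and/or
    pre-FMT recipients) in which the species passes the presence criterion.
    Returns the per-event table and, when events carry matched/mismatched
    labels, the Welch t comparison of matched vs mismatched prevalences.
    """
    if not baseline_samples:
        raise ValueError("baseline_samples must be non-empty")

    def _present(sample: str, species: str) -> bool:
        call = presence.get((sample, species), False)
        return call.present if isinstance(call, PresenceCall) else bool(call)

    rows = []
    for e in events:
        prev = sum(_present(s, e.species_id) for s in baseline_samples)
        rows.append(
            {
                "donor_sample": e.donor_sample,
                "recipient_sample": e.recipient_sample,
                "species_id": e.species_id,
                "matched": e.matched,
                "prevalence": prev,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["donor_sample", "recipient_sample", "species_id", "matched", "prevalence"],
    )
    matched = df.loc[df["matched"] == True, "prevalence"]  # noqa: E712
    mismatched = df.loc[df["matched"] == False, "prevalence"]  # noqa: E712
    if len(matched) >= 2 and len(mismatched) >= 2:
        if matched.var() == 0 and mismatched.var() == 0 and matched.mean() == mismatched.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(matched, mismatched, equal_var=False)
        return df, float(t), float(p)
    return df, None, None


@dataclasses.dataclass(frozen=True)
class PermutationResult:
    p_value: float
    observed_proportion: float
    subset_size: int
    n_events: int
    n_excluded: int
    n_perm: int

    def __float__(self) -> float:
        return self.p_value


def permutation_trait_enrichment(
    all_traits: Sequence[bool | None],
    subset_traits: Sequence[bool | None],
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
) -> PermutationResult:
    """Permutation test for trait enrichment in a filtered event subset.

    ``all_traits`` flags a trait (e.g. obligately anaerobic, single-host)
    per event in the full sharing list; ``subset_traits`` is the same flag
    for the events surviving a filter. ``n_perm`` subsets of the same size
    are drawn from the full list without replacement and the p-value is the
    raw proportion of draws whose trait proportion is as or more extreme
    than observed — at least the observed proportion for
    ``alternative='greater'`` (enrichment), at most it for ``'less'``
    (depletion), or at least as far from the null expectation for
    ``'two-sided'``. Events with unknown trait (None/NaN) are excluded from
    both lists and logged. The attainable floor of the raw proportion is
    1/n_perm.

    Each draw's trait count is sampled directly from the hypergeometric
    distribution of a without-replacement subset, which is distributionally
    identical to materialising the subset and counting.
    """
    def _clean(traits: Sequence[bool | None]) -> np.ndarray:
        vals = []
        excluded = 0
        for t in traits:
            if t is None or (isinstance(t, float) and math.isnan(t)):
                excluded += 1
                continue
            vals.append(bool(t))
        return np.asarray(vals, dtype=bool), excluded

    pool, excl_pool = _clean(all_traits)
    subset, excl_sub = _clean(subset_traits)
    n_excluded = excl_pool + excl_sub
    if n_excluded:
        logger.info("excluded %d events with unknown trait", n_excluded)
    k = subset.size
    n = pool.size
    if k == 0:
        raise ValueError("observed subset is empty after exclusions")
    if k > n:
        raise ValueError("subset larger than the full event list")

    n_trait = int(pool.sum())
    obs = int(subset.sum())
    rng = np.random.default_rng(seed)
    sims = rng.hypergeometric(n_trait, n - n_trait, k, size=n_perm)

    if alternative == "greater":
        p = np.count_nonzero(sims >= obs) / n_perm
    elif alternative == "less":
        p = np.count_nonzero(sims <= obs) / n_perm
    elif alternative == "two-sided":
        center = k * n_trait / n
        p = np.count_nonzero(np.abs(sims - center) >= abs(obs - center) - 1e-12) / n_perm
    else:
        raise ValueError("alternative must be 'greater', 'less' or 'two-sided'")
    return PermutationResult(
        p_value=float(p),
        observed_proportion=obs / k,
        subset_size=k,
        n_events=n,
        n_excluded=n_excluded,
        n_perm=n_perm,
    )
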