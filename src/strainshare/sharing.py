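"""Dyad-level strain-sharing summaries and category comparisons.

A *dyad* is a pair of samples. Its strain-sharing rate is the fraction of
species jointly present in both samples whose pairwise popANI meets the
strain-identity threshold. Dyads are grouped into study-design categories —
matched/mismatched donor-recipient pairs in a transplant design, or, in a
wild-population design, pairs of hosts whose lives never overlapped, hosts in
different social groups sampled close in time, close social partners, and
longitudinal self-pairs — and rates are compared across categories with
Welch t-tests (Benjamini-Hochberg corrected) or one-way Tukey HSD.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import (
    DEFAULT_ANI_THRESHOLD,
    PairwiseComparison,
    PresenceCall,
    is_strain_shared,
)

logger = logging.getLogger(__name__)

FMT_CATEGORIES = ("matched", "mismatched")
POPULATION_CATEGORIES = (
    "never_overlapped",
    "different_groups",
    "close_partners",
    "longitudinal",
)
UNCATEGORIZED = "uncategorized"


@dataclasses.dataclass(frozen=True)
class SampleRecord:
    """Metadata for one sequenced sample."""

    sample_id: str
    host_id: str
    date: dt.date | None = None
    group: str | None = None
    role: str = "none"  # donor | recipient | none
    timepoint: str = "none"  # pre | post | none
    designated_donor: str | None = None  # donor host_id, recipients only

    def __post_init__(self) -> None:
        if self.role not in ("donor", "recipient", "none"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.timepoint not in ("pre", "post", "none"):
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.role == "recipient" and self.timepoint == "none":
            raise ValueError("recipient samples require a pre/post timepoint")


@dataclasses.dataclass(frozen=True)
class DyadSummary:
    sample_a: str
    sample_b: str
    category: str
    n_shared_species: int
    n_shared_strains: int

    def __post_init__(self) -> None:
        if self.n_shared_strains > self.n_shared_species:
            raise ValueError("n_shared_strains cannot exceed n_shared_species")

    @property
    def sharing_rate(self) -> float | None:
        """Shared strains over jointly present species; None when the dyad
        shares no species (excluded from category statistics)."""
        if self.n_shared_species == 0:
            return None
        return self.n_shared_strains / self.n_shared_species


def summarize_dyad(
    sample_a: str,
    sample_b: str,
    comparisons: Iterable[PairwiseComparison],
    presence: Mapping[tuple[str, str], PresenceCall | bool],
    ani_threshold: float = DEFAULT_ANI_THRESHOLD,
    category: str = UNCATEGORIZED,
) -> DyadSummary:
    """Aggregate per-species comparisons for one sample pair.

    ``presence`` maps (sample_id, species_id) to a presence call (or plain
    bool). Species jointly present form the denominator; those whose
    comparison is evaluable and meets the popANI threshold form the
    numerator.
    """

    def _present(sample: str, species: str) -> bool:
        call = presence.get((sample, species), False)
        return call.present if isinstance(call, PresenceCall) else bool(call)

    n_species = 0
    n_strains = 0
    for comp in comparisons:
        if {comp.sample_a, comp.sample_b} != {sample_a, sample_b} and (
            sample_a != sample_b or comp.sample_a != comp.sample_b
        ):
            raise ValueError(
                f"comparison {comp.sample_a}/{comp.sample_b} does not belong "
                f"to dyad {sample_a}/{sample_b}"
            )
        if not (_present(sample_a, comp.species_id) and _present(sample_b, comp.species_id)):
            continue
        n_species += 1
        if comp.evaluable and is_strain_shared(comp, ani_threshold):
            n_strains += 1
    if n_species == 0:
        logger.warning(
            "dyad %s/%s shares no species; sharing rate undefined",
            sample_a,
            sample_b,
        )
    return DyadSummary(sample_a, sample_b, category, n_species, n_strains)


def categorize_fmt_dyad(donor: SampleRecord, recipient: SampleRecord) -> str:
    """matched when the recipient's designated donor is this donor's host."""
    if donor.role != "donor" or recipient.role != "recipient":
        raise ValueError("expected a donor sample and a recipient sample")
    if recipient.designated_donor is None:
        raise ValueError(f"recipient {recipient.sample_id} lacks a designated donor")
    return "matched" if recipient.designated_donor == donor.host_id else "mismatched"


def categorize_dyad(
    a: SampleRecord,
    b: SampleRecord,
    lifespans: Mapping[str, tuple[dt.date, dt.date | None]] | None = None,
    close_partners: set[frozenset[str]] | None = None,
    different_group_window: int = 150,
    close_partner_window: int = 4,
    longitudinal_window: tuple[int, int] = (120, 150),
) -> str:
    """Assign a wild-population dyad category.

    * ``longitudinal``: same host, samples 120-150 days apart (inclusive).
    * ``never_overlapped``: different hosts whose life intervals are disjoint
      (requires ``lifespans``: host -> (birth, death-or-None)).
    * ``different_groups``: different hosts, different social groups, sampled
      < 150 days apart.
    * ``close_partners``: different hosts, same group, sampled < 4 days
      apart, and (when ``close_partners`` is given) listed as close social
      partners.

    Anything else is ``uncategorized`` and excluded from category statistics.
    """
    if a.date is None or b.date is None:
        raise ValueError("both samples need collection dates")
    gap = abs((a.date - b.date).days)

    if a.host_id == b.host_id:
        lo, hi = longitudinal_window
        return "longitudinal" if lo <= gap <= hi else UNCATEGORIZED

    if lifespans is not None and a.host_id in lifespans and b.host_id in lifespans:
        birth_a, death_a = lifespans[a.host_id]
        birth_b, death_b = lifespans[b.host_id]
        if (death_a is not None and death_a < birth_b) or (
            death_b is not None and death_b < birth_a
        ):
            return "never_overlapped"

    if a.group is not None and b.group is not None:
        if a.group != b.group and gap < different_group_window:
            return "different_groups"
        if a.group == b.group and gap < close_partner_window:
            pair = frozenset((a.host_id, b.host_id))
            if close_partners is None or pair in close_partners:
                return "close_partners"
    return UNCATEGORIZED


def category_rates(
    summaries: Iterable[DyadSummary],
    categories: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Defined sharing rates per category; undefined-rate dyads are dropped
    (listwise, logged) and uncategorized dyads excluded."""
    rates: dict[str, list[float]] = {}
    n_dropped = 0
    for s in summaries:
        if s.category == UNCATEGORIZED:
            continue
        if categories is not None and s.category not in categories:
            continue
        r = s.sharing_rate
        if r is None:
            n_dropped += 1
            continue
        rates.setdefault(s.category, []).append(r)
    if n_dropped:
        logger.warning("dropped %d dyads with undefined sharing rates", n_dropped)
    return {k: np.asarray(v, dtype=float) for k, v in rates.items()}


def compare_sharing_across_categories(
    summaries: Iterable[DyadSummary] | Mapping[str, Sequence[float]],
    method: str = "welch_bh",
) -> pd.DataFrame:
    """All pairwise category comparisons of sharing rates.

    ``welch_bh``: unequal-variance t-test per category pair, BH-adjusted
    across the family of pairs. ``tukey``: one-way Tukey HSD adjusted
    p-values. Pairs where either category has < 2 defined rates are flagged
    ``computable=False``.
    """
    if isinstance(summaries, Mapping):
        groups = {k: np.asarray(v, dtype=float) for k, v in summaries.items()}
    else:
        groups = category_rates(summaries)
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two categories with defined rates")
    pairs = list(itertools.combinations(names, 2))

    if method == "welch_bh":
        rows = []
        for x, y in pairs:
            gx, gy = groups[x], groups[y]
            if len(gx) < 2 or len(gy) < 2:
                rows.append((x, y, np.nan, np.nan, False))
                continue
            if np.ptp(gx) == 0 and np.ptp(gy) == 0 and gx.mean() == gy.mean():
                # identical constant groups: no evidence of a difference
                rows.append((x, y, 0.0, 1.0, True))
                continue
            t, p = stats.ttest_ind(gx, gy, equal_var=False)
            rows.append((x, y, float(t), float(p), True))
        df = pd.DataFrame(
            rows, columns=["category_a", "category_b", "statistic", "p_raw", "computable"]
        )
        df["p_adj"] = np.nan
        ok = df["computable"] & df["p_raw"].notna()
        if ok.any():
            df.loc[ok, "p_adj"] = multipletests(
                df.loc[ok, "p_raw"].to_numpy(), method="fdr_bh"
            )[1]
        return df

    if method == "tukey":
        usable = [n for n in names if len(groups[n]) >= 2]
        res = None
        if len(usable) >= 2:
            res = stats.tukey_hsd(*[groups[n] for n in usable])
        rows = []
        for x, y in pairs:
            if res is None or x not in usable or y not in usable:
                rows.append((x, y, np.nan, np.nan, False))
                continue
            i, j = usable.index(x), usable.index(y)
            rows.append(
                (x, y, float(res.statistic[i, j]), float(res.pvalue[i, j]), True)
            )
        df = pd.DataFrame(
            rows, columns=["category_a", "category_b", "statistic", "p_adj", "computable"]
        )
        return df

    raise ValueError(f"unknown method {method!r}; use 'welch_bh' or 'tukey'")


def downsample_robustness(
    summaries: Sequence[DyadSummary],
    host_map: Mapping[str, str],
    n_iter: int = 100,
    seed: int = 0,
    mode: str = "dyad",
    method: str = "tukey",
) -> pd.DataFrame:
    """Robustness of category contrasts to repeated host representation.

    Each iteration retains a random subset of dyads in which no host is
    represented more than once, then reruns the category comparison. Two
    modes:

    * ``dyad`` (default): a random host-disjoint set of dyads is kept
      greedily; a longitudinal self-pair counts as a single use of its host,
      so longitudinal dyads can survive downsampling.
    * ``sample``: one random sample is retained per host and only dyads whose
      two samples were both retained are kept (this necessarily removes all
      longitudinal self-pairs).

    Returns a long table (iteration, category_a, category_b, statistic,
    p_adj, computable); iterations that leave a category with < 2 dyads are
    flagged not-computable for the affected pairs rather than dropped.
    """
    if mode not in ("dyad", "sample"):
        raise ValueError("mode must be 'dyad' or 'sample'")
    for s in summaries:
        for sample in (s.sample_a, s.sample_b):
            if sample not in host_map:
                raise ValueError(f"host_map does not cover sample {sample!r}")
    rng = np.random.default_rng(seed)
    categories = sorted(
        {s.category for s in summaries if s.category != UNCATEGORIZED}
    )
    all_pairs = list(itertools.combinations(categories, 2))

    out = []
    for it in range(n_iter):
        if mode == "dyad":
            used_hosts: set[str] = set()
            kept = []
            for idx in rng.permutation(len(summaries)):
                s = summaries[idx]
                hosts = {host_map[s.sample_a], host_map[s.sample_b]}
                if hosts & used_hosts:
                    continue
                used_hosts |= hosts
                kept.append(s)
        else:
            by_host: dict[str, list[str]] = {}
            for s in summaries:
                for sample in (s.sample_a, s.sample_b):
                    by_host.setdefault(host_map[sample], [])
            for sample, host in host_map.items():
                if host in by_host and sample not in by_host[host]:
                    by_host[host].append(sample)
            chosen = {
                host: samples[rng.integers(len(samples))]
                for host, samples in sorted(by_host.items())
            }
            retained = set(chosen.values())
            kept = [
                s
                for s in summaries
                if s.sample_a in retained and s.sample_b in retained
            ]

        groups = category_rates(kept, categories)
        enough = {k for k, v in groups.items() if len(v) >= 2}
        if len(enough) >= 2:
            table = compare_sharing_across_categories(
                {k: groups[k] for k in enough}, method=method
            )
            lookup = {
                (r.category_a, r.category_b): r for r in table.itertuples()
            }
        else:
            lookup = {}
        for x, y in all_pairs:
            row = lookup.get((x, y))
            if row is not None and row.computable:
                out.append((it, x, y, row.statistic, row.p_adj, True))
            else:
                out.append((it, x, y, np.nan, np.nan, False))
    return pd.DataFrame(
        out,
        columns=["iteration", "category_a", "category_b", "statistic", "p_adj", "computable"],
    )


def phylo_share(
    distances: pd.DataFrame,
    threshold: float = 0.1,
    mode: str = "max_norm",
) -> pd.DataFrame:
    """Strain-sharing flags from a per-species phylogenetic distance matrix.

    ``max_norm`` divides by the species' maximum pairwise distance and flags
    pairs at or below ``threshold`` (a fixed normalized cutoff);
    ``quantile`` instead flags pairs at or below the ``threshold`` quantile
    of the off-diagonal distances. Both readings of a "normalized distance
    <= 0.1" rule are offered because field usage conflates them.
    """
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have a zero diagonal")

    if mode == "max_norm":
        mx = d.max()
        if mx == 0:
            logger.warning("all-zero distance matrix: every pair flagged shared")
            shared = np.ones_like(d, dtype=bool)
        else:
            shared = (d / mx) <= threshold
    elif mode == "quantile":
        off = d[~np.eye(d.shape[0], dtype=bool)]
        cutoff = float(np.quantile(off, threshold)) if off.size else 0.0
        shared = d <= cutoff
    else:
        raise ValueError("mode must be 'max_norm' or 'quantile'")
    np.fill_diagonal(shared, True)
    return pd.DataFrame(shared, index=distances.index, columns=distances.columns)
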