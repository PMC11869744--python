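"""Cumulative transmission-filter cascade for transplant cohorts.

Raw strain-sharing events between a donor sample and a recipient's post-FMT
sample are upgraded to putative transmission events through cumulative
criteria of increasing stringency:

* tier 0 — any strain sharing (popANI >= threshold, species jointly present);
* tier 1 — the strain was previously absent from the recipient (the donor
  does not share it with the recipient's pre-FMT sample);
* tier 2 — additionally, the strain is unique to one donor pre-FMT;
* tier 3 — additionally, the strain is unique to one recipient post-FMT.

The criteria are cumulative, so tier sets are nested. Mismatched
donor-recipient pairs run through the identical cascade with the mismatched
donor treated as the putative source, which lets matched pairs (true edges of
the transmission network) be benchmarked against the background.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Iterable, Mapping

import pandas as pd

from .profiles import (
    DEFAULT_ANI_THRESHOLD,
    PairwiseComparison,
    PresenceCall,
    is_strain_shared,
)

logger = logging.getLogger(__name__)

TIER_NAMES = {
    0: "any_sharing",
    1: "absent_pre_fmt",
    2: "unique_to_one_donor",
    3: "unique_to_one_recipient",
}


class MissingComparisonError(KeyError):
    """A required cross-comparison was not supplied to the cascade."""


@dataclasses.dataclass
class SharingEvent:
    """One (donor sample, recipient post sample, species) sharing record."""

    donor_sample: str
    recipient_sample: str
    species_id: str
    popani: float
    matched: bool | None = None
    tier: int = 0


@dataclasses.dataclass(frozen=True)
class Recipient:
    host_id: str
    pre_sample: str
    post_sample: str
    designated_donor_sample: str


@dataclasses.dataclass(frozen=True)
class FMTDesign:
    donor_samples: tuple[str, ...]
    recipients: tuple[Recipient, ...]

    def __post_init__(self) -> None:
        for r in self.recipients:
            if r.designated_donor_sample not in self.donor_samples:
                raise ValueError(
                    f"recipient {r.host_id}: designated donor sample "
                    f"{r.designated_donor_sample!r} is not a donor sample"
                )


class CohortComparisons:
    """Symmetric lookup of presence calls and pairwise comparisons."""

    def __init__(
        self,
        presence: Mapping[tuple[str, str], PresenceCall | bool],
        comparisons: Iterable[PairwiseComparison],
    ) -> None:
        self._presence = dict(presence)
        self._comparisons: dict[tuple[frozenset[str], str], PairwiseComparison] = {}
        for c in comparisons:
            self._comparisons[(frozenset((c.sample_a, c.sample_b)), c.species_id)] = c

    def present(self, sample: str, species: str) -> bool:
        call = self._presence.get((sample, species), False)
        return call.present if isinstance(call, PresenceCall) else bool(call)

    def comparison(
        self, sample_a: str, sample_b: str, species: str
    ) -> PairwiseComparison | None:
        return self._comparisons.get((frozenset((sample_a, sample_b)), species))

    def jointly_present(self, sample_a: str, sample_b: str) -> list[str]:
        species = {sp for (s, sp), _ in self._presence.items() if s == sample_a}
        return sorted(
            sp
            for sp in species
            if self.present(sample_a, sp) and self.present(sample_b, sp)
        )

    def shares(
        self,
        sample_a: str,
        sample_b: str,
        species: str,
        ani_threshold: float = DEFAULT_ANI_THRESHOLD,
    ) -> bool:
        """Joint presence + evaluable comparison + popANI >= threshold.

        Raises :class:`MissingComparisonError` when both samples carry the
        species but no comparison was supplied.
        """
        if not (self.present(sample_a, species) and self.present(sample_b, species)):
            return False
        comp = self.comparison(sample_a, sample_b, species)
        if comp is None:
            raise MissingComparisonError(
                f"missing comparison {sample_a} vs {sample_b} for {species}"
            )
        if not comp.evaluable:
            return False
        return is_strain_shared(comp, ani_threshold)


def find_sharing_events(
    cohort: CohortComparisons,
    design: FMTDesign,
    ani_threshold: float = DEFAULT_ANI_THRESHOLD,
) -> list[SharingEvent]:
    """Tier-0 events: every donor x recipient-post pair sharing a strain."""
    events = []
    for donor in design.donor_samples:
        for r in design.recipients:
            for sp in cohort.jointly_present(donor, r.post_sample):
                if cohort.shares(donor, r.post_sample, sp, ani_threshold):
                    comp = cohort.comparison(donor, r.post_sample, sp)
                    events.append(
                        SharingEvent(
                            donor_sample=donor,
                            recipient_sample=r.post_sample,
                            species_id=sp,
                            popani=comp.popani,
                            matched=donor == r.designated_donor_sample,
                            tier=0,
                        )
                    )
    return events


def _recipient_of(design: FMTDesign, post_sample: str) -> Recipient:
    for r in design.recipients:
        if r.post_sample == post_sample:
            return r
    raise ValueError(f"{post_sample!r} is not a recipient post-FMT sample")


def strain_absent_pre(
    event: SharingEvent,
    cohort: CohortComparisons,
    design: FMTDesign,
    ani_threshold: float = DEFAULT_ANI_THRESHOLD,
) -> bool:
    """True when the donor does not share the strain with the recipient's
    pre-FMT sample: the species is absent pre-FMT, or present but divergent
    (popANI below threshold). Requires the pre-FMT sample's presence and
    comparison data."""
    recipient = _recipient_of(design, event.recipient_sample)
    if not cohort.present(recipient.pre_sample, event.species_id):
        return True
    return not cohort.shares(
        event.donor_sample, recipient.pre_sample, event.species_id, ani_threshold
    )


def strain_unique_to_donor(
    event: SharingEvent,
    cohort: CohortComparisons,
    design: FMTDesign,
    ani_threshold: float = DEFAULT_ANI_THRESHOLD,
    scope: str = "donors",
) -> bool:
    """True when no other donor's pre-FMT sample shares the strain with the
    putative source donor. Divergent conspecific strains in other donors do
    not disqualify (strain, not species, uniqueness). ``scope='pre_fmt'``
    widens the check to all pre-FMT samples (donors plus recipients-pre)."""
    others = [d for d in design.donor_samples if d != event.donor_sample]
    if scope == "pre_fmt":
        recipient = _recipient_of(design, event.recipient_sample)
        others += [
            r.pre_sample for r in design.recipients if r is not recipient
        ]
    elif scope != "donors":
        raise ValueError("scope must be 'donors' or 'pre_fmt'")
    return not any(
        cohort.shares(event.donor_sample, other, event.species_id, ani_threshold)
        for other in others
    )


def strain_unique_to_recipient(
    event: SharingEvent,
    cohort: CohortComparisons,
    design: FMTDesign,
    ani_threshold: float = DEFAULT_ANI_THRESHOLD,
) -> bool:
    """True when no other recipient's post-FMT sample shares the strain with
    the focal recipient."""
    recipient = _recipient_of(design, event.recipient_sample)
    return not any(
        cohort.shares(
            event.recipient_sample, other.post_sample, event.species_id, ani_threshold
        )
        for other in design.recipients
        if other is not recipient
    )


def assign_tiers(
    events: Iterable[SharingEvent],
    cohort: CohortComparisons,
    design: FMTDesign,
    ani_threshold: float = DEFAULT_ANI_THRESHOLD,
    donor_scope: str = "donors",
) -> list[SharingEvent]:
    """Set each event's tier to the highest whose cumulative predicates all
    hold. Every event is preserved with its tier; predicate errors propagate
    with event context."""
    out = []
    for ev in events:
        tier = 0
        try:
            if strain_absent_pre(ev, cohort, design, ani_threshold):
                tier = 1
                if strain_unique_to_donor(
                    ev, cohort, design, ani_threshold, scope=donor_scope
                ):
                    tier = 2
                    if strain_unique_to_recipient(ev, cohort, design, ani_threshold):
                        tier = 3
        except MissingComparisonError as err:
            raise MissingComparisonError(
                f"{err.args[0]} (while tiering event {ev.donor_sample}->"
                f"{ev.recipient_sample} {ev.species_id})"
            ) from err
        out.append(dataclasses.replace(ev, tier=tier))
    return out


def dyad_tier_table(
    cohort: CohortComparisons,
    design: FMTDesign,
    ani_threshold: float = DEFAULT_ANI_THRESHOLD,
    donor_scope: str = "donors",
) -> pd.DataFrame:
    """Species-level cumulative filter passes for every donor x recipient dyad.

    For each jointly present species the same three donor-anchored predicates
    are evaluated whether or not the species is shared, yielding
    ``species_tier`` (the highest cumulative tier the species survives) and a
    ``shared`` flag. Tier-specific sharing rates use species surviving the
    filters up to that tier as the denominator, mirroring how increasingly
    stringent criteria shrink both the candidate species set and the shared
    subset.
    """
    rows = []
    for donor in design.donor_samples:
        for r in design.recipients:
            for sp in cohort.jointly_present(donor, r.post_sample):
                shared = cohort.shares(donor, r.post_sample, sp, ani_threshold)
                tier = 0
                probe = SharingEvent(donor, r.post_sample, sp, popani=1.0)
                if strain_absent_pre(probe, cohort, design, ani_threshold):
                    tier = 1
                    if strain_unique_to_donor(
                        probe, cohort, design, ani_threshold, scope=donor_scope
                    ):
                        tier = 2
                        # donor-anchored recipient-uniqueness: the donor's
                        # strain is found in no non-focal recipient post-FMT
                        if not any(
                            cohort.shares(donor, other.post_sample, sp, ani_threshold)
                            for other in design.recipients
                            if other is not r
                        ):
                            tier = 3
                rows.append(
                    {
                        "donor_sample": donor,
                        "recipient_sample": r.post_sample,
                        "matched": donor == r.designated_donor_sample,
                        "species_id": sp,
                        "shared": shared,
                        "species_tier": tier,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "donor_sample",
            "recipient_sample",
            "matched",
            "species_id",
            "shared",
            "species_tier",
        ],
    )


def tier_sharing_rates(tier_table: pd.DataFrame) -> pd.DataFrame:
    """Per-dyad sharing rates under each cumulative filter tier.

    At tier t the denominator is the species with ``species_tier >= t`` and
    the numerator is those also shared. Dyads whose denominator is zero at a
    tier get a NaN rate there.
    """
    rows = []
    grouped = tier_table.groupby(
        ["donor_sample", "recipient_sample", "matched"], sort=True
    )
    for (donor, recipient, matched), g in grouped:
        for t in range(4):
            considered = g[g["species_tier"] >= t]
            n = len(considered)
            k = int(considered["shared"].sum())
            rows.append(
                {
                    "donor_sample": donor,
                    "recipient_sample": recipient,
                    "matched": matched,
                    "tier": t,
                    "n_considered": n,
                    "n_shared": k,
                    "rate": k / n if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def tier_counts(events: Iterable[SharingEvent]) -> dict[int, int]:
    """Cumulative event counts per tier; non-increasing in tier by nestedness."""
    events = list(events)
    return {t: sum(1 for e in events if e.tier >= t) for t in range(4)}


def check_nestedness(events: Iterable[SharingEvent]) -> bool:
    counts = tier_counts(events)
    return all(counts[t] >= counts[t + 1] for t in range(3))


def events_to_frame(events: Iterable[SharingEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "donor_sample": e.donor_sample,
                "recipient_sample": e.recipient_sample,
                "species_id": e.species_id,
                "popani": e.popani,
                "matched": e.matched,
                "tier": e.tier,
                "tier_name": TIER_NAMES[e.tier],
            }
            for e in events
        ],
        columns=[
            "donor_sample",
            "recipient_sample",
            "species_id",
            "popani",
            "matched",
            "tier",
            "tier_name",
        ],
    )


def all_cohort_pairs(design: FMTDesign) -> list[tuple[str, str]]:
    """Every sample pair the cascade may need a comparison for."""
    samples = list(design.donor_samples)
    for r in design.recipients:
        samples += [r.pre_sample, r.post_sample]
    return list(itertools.combinations(samples, 2))
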