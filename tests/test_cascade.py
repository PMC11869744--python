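"""Cumulative transmission-filter cascade on hand-built cohorts."""

import pytest

from strainshare.cascade import (
    CohortComparisons,
    FMTDesign,
    MissingComparisonError,
    Recipient,
    SharingEvent,
    assign_tiers,
    check_nestedness,
    dyad_tier_table,
    find_sharing_events,
    strain_absent_pre,
    strain_unique_to_donor,
    strain_unique_to_recipient,
    tier_counts,
    tier_sharing_rates,
)
from strainshare.profiles import PairwiseComparison


def comp(a, b, sp, popani, n=100_000):
    subs = round((1 - popani) * n)
    return PairwiseComparison(a, b, sp, n, subs, subs)


DESIGN = FMTDesign(
    donor_samples=("D1", "D2", "D3"),
    recipients=(
        Recipient("R1", "R1_pre", "R1_post", "D1"),
        Recipient("R2", "R2_pre", "R2_post", "D2"),
    ),
)


def build_cohort(presence_species, comparisons):
    presence = {}
    samples = ["D1", "D2", "D3", "R1_pre", "R1_post", "R2_pre", "R2_post"]
    for sp, carriers in presence_species.items():
        for s in samples:
            presence[(s, sp)] = s in carriers
    return CohortComparisons(presence, comparisons)


def test_design_rejects_unknown_designated_donor():
    with pytest.raises(ValueError):
        FMTDesign(("D1",), (Recipient("R1", "R1_pre", "R1_post", "D9"),))


def test_full_cascade_tiers():
    presence = {
        # spA: unique to D1, absent everywhere else -> tier 3
        "spA": {"D1", "R1_post"},
        # spB: pre-existing strain (shared donor vs pre) -> tier 0
        "spB": {"D1", "R1_pre", "R1_post"},
        # spC: divergent pre strain but identical strain in D2 -> tier 1
        "spC": {"D1", "D2", "R1_pre", "R1_post"},
        # spD: donor-unique (divergent in other donors) but the strain also
        # shows up in R2 post -> tier 2
        "spD": {"D1", "D2", "D3", "R1_post", "R2_post"},
        # spE: in R2 post but below the sharing threshold there -> tier 3
        "spE": {"D1", "R1_post", "R2_post"},
    }
    comparisons = [
        comp("D1", "R1_post", "spA", 1.0),
        comp("D1", "R1_post", "spB", 1.0),
        comp("D1", "R1_pre", "spB", 1.0),
        comp("D1", "R1_post", "spC", 1.0),
        comp("D1", "R1_pre", "spC", 0.99),
        comp("D1", "D2", "spC", 1.0),
        comp("D2", "R1_post", "spC", 1.0),
        comp("D2", "R1_pre", "spC", 0.99),
        comp("D1", "R1_post", "spD", 1.0),
        comp("D1", "D2", "spD", 0.99),
        comp("D1", "D3", "spD", 0.99),
        comp("D2", "D3", "spD", 0.99),
        comp("D1", "R2_post", "spD", 1.0),
        comp("D2", "R1_post", "spD", 0.99),
        comp("D2", "R2_post", "spD", 1.0),
        comp("D3", "R1_post", "spD", 0.99),
        comp("D3", "R2_post", "spD", 0.99),
        comp("R1_post", "R2_post", "spD", 1.0),
        comp("D1", "R1_post", "spE", 1.0),
        comp("D1", "R2_post", "spE", 0.999),
        comp("R1_post", "R2_post", "spE", 0.999),
    ]
    cohort = build_cohort(presence, comparisons)
    events = find_sharing_events(cohort, DESIGN, 0.99999)
    events = assign_tiers(events, cohort, DESIGN, 0.99999)
    tiers = {
        (e.donor_sample, e.recipient_sample, e.species_id): e.tier for e in events
    }
    assert tiers[("D1", "R1_post", "spA")] == 3
    assert tiers[("D1", "R1_post", "spB")] == 0
    assert tiers[("D1", "R1_post", "spC")] == 1
    assert tiers[("D1", "R1_post", "spD")] == 2
    assert tiers[("D1", "R1_post", "spE")] == 3
    # D2 -> R1_post spC is a mismatched sharing event
    assert ("D2", "R1_post", "spC") in tiers
    assert not [e for e in events if e.matched and e.species_id == "spC" and e.donor_sample == "D2"]
    assert check_nestedness(events)
    counts = tier_counts(events)
    assert counts[0] >= counts[1] >= counts[2] >= counts[3]


def test_predicates_standalone():
    presence = {"spX": {"D1", "D2", "R1_pre", "R1_post", "R2_post"}}
    comparisons = [
        comp("D1", "R1_post", "spX", 1.0),
        comp("D1", "R1_pre", "spX", 0.99),
        comp("D1", "D2", "spX", 0.999),
        comp("D1", "R2_post", "spX", 1.0),
        comp("R1_post", "R2_post", "spX", 1.0),
        comp("D2", "R1_post", "spX", 0.99),
        comp("D2", "R2_post", "spX", 0.99),
    ]
    cohort = build_cohort(presence, comparisons)
    ev = SharingEvent("D1", "R1_post", "spX", 1.0)
    # divergent pre-FMT strain does not block tier 1
    assert strain_absent_pre(ev, cohort, DESIGN)
    # conspecific but divergent strain in D2 does not break donor uniqueness
    assert strain_unique_to_donor(ev, cohort, DESIGN)
    # identical strain in R2 post breaks recipient uniqueness
    assert not strain_unique_to_recipient(ev, cohort, DESIGN)


def test_identical_strain_in_second_donor_blocks_tier_two():
    presence = {"spX": {"D1", "D2", "R1_post"}}
    comparisons = [
        comp("D1", "R1_post", "spX", 1.0),
        comp("D1", "D2", "spX", 1.0),
        comp("D2", "R1_post", "spX", 1.0),
    ]
    cohort = build_cohort(presence, comparisons)
    ev = SharingEvent("D1", "R1_post", "spX", 1.0)
    assert not strain_unique_to_donor(ev, cohort, DESIGN)


def test_missing_comparison_raises_with_context():
    presence = {"spX": {"D1", "R1_pre", "R1_post"}}
    cohort = build_cohort(presence, [comp("D1", "R1_post", "spX", 1.0)])
    events = find_sharing_events(cohort, DESIGN)
    with pytest.raises(MissingComparisonError, match="spX"):
        assign_tiers(events, cohort, DESIGN)


def test_wider_donor_scope_checks_pre_fmt_recipients():
    presence = {"spX": {"D1", "R1_post", "R2_pre"}}
    comparisons = [
        comp("D1", "R1_post", "spX", 1.0),
        comp("D1", "R2_pre", "spX", 1.0),
    ]
    cohort = build_cohort(presence, comparisons)
    ev = SharingEvent("D1", "R1_post", "spX", 1.0)
    assert strain_unique_to_donor(ev, cohort, DESIGN, scope="donors")
    assert not strain_unique_to_donor(ev, cohort, DESIGN, scope="pre_fmt")


def test_tier_rates_use_tier_specific_denominators():
    presence = {
        "spA": {"D1", "R1_post"},  # tier 3, shared
        "spB": {"D1", "R1_pre", "R1_post"},  # tier 0 (pre-existing), shared
        "spC": {"D1", "R1_post"},  # tier 3, present both but not shared
    }
    comparisons = [
        comp("D1", "R1_post", "spA", 1.0),
        comp("D1", "R1_post", "spB", 1.0),
        comp("D1", "R1_pre", "spB", 1.0),
        comp("D1", "R1_post", "spC", 0.99),
    ]
    design = FMTDesign(("D1",), (Recipient("R1", "R1_pre", "R1_post", "D1"),))
    cohort = build_cohort(presence, comparisons)
    rates = tier_sharing_rates(dyad_tier_table(cohort, design))
    by_tier = rates.set_index("tier")
    assert by_tier.loc[0, "n_considered"] == 3
    assert by_tier.loc[0, "rate"] == pytest.approx(2 / 3)
    # spB drops out of the denominator at tier 1
    assert by_tier.loc[1, "n_considered"] == 2
    assert by_tier.loc[1, "rate"] == pytest.approx(1 / 2)
    assert by_tier.loc[3, "rate"] == pytest.approx(1 / 2)
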