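"""Annotation rules, composition tests, log odds, and permutation tests."""

import math

import numpy as np
import pytest
from scipy import stats

from strainshare import (
    annotate_host_range,
    annotate_oxygen,
    family_composition_test,
    family_log_odds,
    permutation_trait_enrichment,
    prevalence_of_events,
)
from strainshare.cascade import SharingEvent


@pytest.mark.parametrize(
    "entries,label",
    [
        (["anaerobe", "anaerobe", "anaerobe"], "anaerobic"),
        (["aerobe", "aerobe"], "aerobic"),
        (["aerobe", "anaerobe"], "mixed"),
        (["anaerobe", "facultative"], "mixed"),
        ([], "unknown"),
    ],
)
def test_annotate_oxygen(entries, label):
    assert annotate_oxygen(entries) == label


def test_annotate_oxygen_rejects_unknown_vocabulary():
    with pytest.raises(ValueError):
        annotate_oxygen(["aerobe", "microaerophile"])


@pytest.mark.parametrize(
    "hosts,label",
    [
        (["Homo sapiens"], "single_host"),
        (["Homo sapiens", "Homo sapiens"], "single_host"),
        (["Homo sapiens", "Sus scrofa"], "multi_host"),
        ([], "unknown"),
    ],
)
def test_annotate_host_range(hosts, label):
    assert annotate_host_range(hosts) == label


def fisher_2x2_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


def test_family_composition_2x2_matches_enumeration():
    events_a = ["famX"] * 10
    events_b = ["famY"] * 10
    p = family_composition_test(events_a, events_b)
    oracle = fisher_2x2_oracle(10, 0, 0, 10)
    assert p == pytest.approx(oracle, rel=1e-9)
    assert p == pytest.approx(1.082508822446903e-05, rel=1e-6)


def test_family_composition_degenerate_and_identical():
    assert family_composition_test(["famX"] * 5, ["famX"] * 7) == 1.0
    a = ["f1"] * 10 + ["f2"] * 10 + ["f3"] * 10
    p = family_composition_test(a, list(a), n_mc=20_000, seed=1)
    assert p > 0.9


def test_family_composition_rxc_detects_shift():
    a = ["f1"] * 30 + ["f2"] * 5 + ["f3"] * 5
    b = ["f1"] * 5 + ["f2"] * 30 + ["f3"] * 5
    p = family_composition_test(a, b, n_mc=20_000, seed=1)
    assert p < 0.001


def test_family_composition_rxc_null_is_calibrated():
    """Random splits of a pooled event list reject at about the nominal rate."""
    rng = np.random.default_rng(5)
    families = np.array(["f1"] * 40 + ["f2"] * 30 + ["f3"] * 30)
    rejections = 0
    n_rep = 200
    for _ in range(n_rep):
        perm = rng.permutation(families)
        p = family_composition_test(
            list(perm[:50]), list(perm[50:]), n_mc=2_000, seed=int(rng.integers(2**31))
        )
        rejections += p <= 0.05
    rate = rejections / n_rep
    assert 0.01 <= rate <= 0.09  # binomial 95% band around 0.05 for n=200


def test_family_log_odds_values_and_antisymmetry():
    assert family_log_odds(
        ["f"] * 5 + ["g"] * 5, ["f"] * 5 + ["g"] * 5, "f"
    ).log2_odds == pytest.approx(0.0)

    res = family_log_odds(["f"] * 20 + ["g"] * 5, ["f"] * 5 + ["g"] * 20, "f")
    assert res.log2_odds == pytest.approx(4.0)
    assert res.ci_low < 4.0 < res.ci_high

    swapped = family_log_odds(["f"] * 5 + ["g"] * 20, ["f"] * 20 + ["g"] * 5, "f")
    assert swapped.log2_odds == pytest.approx(-res.log2_odds)


def test_family_log_odds_zero_cell_is_finite():
    res = family_log_odds(["f"] * 10, ["g"] * 10, "f")
    assert math.isfinite(res.log2_odds)
    assert math.isfinite(res.ci_low) and math.isfinite(res.ci_high)


def _event(donor, recipient, sp, matched):
    return SharingEvent(donor, recipient, sp, popani=1.0, matched=matched)


def test_prevalence_of_events():
    baseline = [f"s{i}" for i in range(13)]
    presence = {(s, "spA"): True for s in baseline}
    presence.update({(s, "spB"): s in baseline[:3] for s in baseline})
    events = [
        _event("D1", "R1_post", "spA", True),
        _event("D1", "R2_post", "spA", True),
        _event("D2", "R1_post", "spB", False),
        _event("D2", "R2_post", "spB", False),
    ]
    df, t, p = prevalence_of_events(events, presence, baseline)
    assert df.loc[df.species_id == "spA", "prevalence"].tolist() == [13, 13]
    assert df.loc[df.species_id == "spB", "prevalence"].tolist() == [3, 3]
    assert t is not None and t > 0  # matched events come from commoner species here

    same = [
        _event("D1", "R1_post", "spA", True),
        _event("D1", "R2_post", "spA", True),
        _event("D2", "R1_post", "spA", False),
        _event("D2", "R2_post", "spA", False),
    ]
    _, t0, p0 = prevalence_of_events(same, presence, baseline)
    assert t0 == 0.0 and p0 == 1.0

    with pytest.raises(ValueError):
        prevalence_of_events(events, presence, [])


def test_permutation_degenerate_cases():
    traits = [True] * 10 + [False] * 10
    assert permutation_trait_enrichment(traits, traits, seed=0).p_value == 1.0
    all_true = [True] * 12
    assert permutation_trait_enrichment(all_true, all_true[:4], seed=0).p_value == 1.0
    with pytest.raises(ValueError):
        permutation_trait_enrichment(traits, [], seed=0)
    with pytest.raises(ValueError):
        permutation_trait_enrichment(traits[:3], traits, seed=0)


def test_permutation_matches_hypergeometric_tail():
    """The Monte Carlo estimate agrees with the exact tail C(10,5)/C(20,5)
    within 3 Monte Carlo standard errors."""
    traits = [True] * 10 + [False] * 10
    subset = [True] * 5
    exact = math.comb(10, 5) / math.comb(20, 5)  # = hypergeom sf at 4
    assert exact == pytest.approx(stats.hypergeom.sf(4, 20, 10, 5))
    res = permutation_trait_enrichment(traits, subset, n_perm=10_000, seed=3)
    se = math.sqrt(exact * (1 - exact) / 10_000)
    assert abs(res.p_value - exact) <= 3 * se


def test_permutation_modes_and_unknown_exclusion():
    traits = [True] * 10 + [False] * 10 + [None] * 3
    subset = [False] * 5 + [None]
    res = permutation_trait_enrichment(traits, subset, n_perm=2_000, seed=2,
                                       alternative="less")
    assert res.n_excluded == 4
    assert res.subset_size == 5 and res.n_events == 20
    assert res.p_value < 0.05  # all-non-trait subset is depleted
    two = permutation_trait_enrichment(traits, subset, n_perm=2_000, seed=2,
                                       alternative="two-sided")
    assert two.p_value < 0.1
    with pytest.raises(ValueError):
        permutation_trait_enrichment(traits, subset, alternative="bogus")
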