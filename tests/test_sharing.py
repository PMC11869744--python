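"""Dyad summaries, category assignment, and category statistics."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from strainshare import (
    DyadSummary,
    SampleRecord,
    categorize_dyad,
    categorize_fmt_dyad,
    compare_sharing_across_categories,
    downsample_robustness,
    phylo_share,
    summarize_dyad,
)
from strainshare.profiles import PairwiseComparison


def comp(a, b, sp, popani, n=100_000):
    subs = round((1 - popani) * n)
    return PairwiseComparison(a, b, sp, n, subs, subs)


def test_summarize_dyad_rates():
    presence = {("a", f"sp{i}"): True for i in range(10)}
    presence.update({("b", f"sp{i}"): True for i in range(10)})
    comps = [comp("a", "b", f"sp{i}", 1.0 if i < 4 else 0.99) for i in range(10)]
    s = summarize_dyad("a", "b", comps, presence)
    assert (s.n_shared_species, s.n_shared_strains) == (10, 4)
    assert s.sharing_rate == pytest.approx(0.4)


def test_self_dyad_rate_is_one_and_empty_dyad_undefined():
    presence = {("a", "sp0"): True, ("b", "sp0"): False}
    s = summarize_dyad("a", "a", [comp("a", "a", "sp0", 1.0)], {("a", "sp0"): True})
    assert s.sharing_rate == 1.0
    empty = summarize_dyad("a", "b", [comp("a", "b", "sp0", 1.0)], presence)
    assert empty.n_shared_species == 0 and empty.sharing_rate is None


def test_jointly_present_species_absent_from_numerator_and_denominator():
    presence = {("a", "sp0"): True, ("b", "sp0"): True, ("a", "sp1"): True}
    s = summarize_dyad("a", "b", [comp("a", "b", "sp0", 1.0)], presence)
    assert s.n_shared_species == 1


def rec(sample, host, date, group=None):
    return SampleRecord(sample, host, date, group=group)


def test_categorize_longitudinal_windows():
    d0 = dt.date(2012, 1, 1)
    a = rec("s1", "h1", d0)
    assert categorize_dyad(a, rec("s2", "h1", d0 + dt.timedelta(days=130))) == "longitudinal"
    assert categorize_dyad(a, rec("s2", "h1", d0 + dt.timedelta(days=200))) == "uncategorized"
    assert categorize_dyad(a, rec("s2", "h1", d0 + dt.timedelta(days=100))) == "uncategorized"


def test_categorize_never_overlapped_and_groups():
    lifespans = {
        "h1": (dt.date(2000, 1, 1), dt.date(2008, 1, 1)),
        "h2": (dt.date(2010, 1, 1), None),
    }
    a = rec("s1", "h1", dt.date(2007, 6, 1), group="G1")
    b = rec("s2", "h2", dt.date(2012, 6, 1), group="G2")
    assert categorize_dyad(a, b, lifespans=lifespans) == "never_overlapped"

    c = rec("s3", "h3", dt.date(2012, 6, 10), group="G3")
    assert categorize_dyad(b, c) == "different_groups"  # 9 days apart
    far = rec("s4", "h4", dt.date(2013, 6, 1), group="G4")
    assert categorize_dyad(b, far) == "uncategorized"  # 360 days apart

    partner = rec("s5", "h5", dt.date(2012, 6, 3), group="G2")
    assert categorize_dyad(b, partner) == "close_partners"
    assert (
        categorize_dyad(b, partner, close_partners={frozenset(("h2", "x"))})
        == "uncategorized"
    )


def test_categorize_fmt_dyad():
    donor = SampleRecord("D1", "D1", dt.date(2020, 1, 1), role="donor")
    recipient = SampleRecord(
        "R1_post", "R1", dt.date(2020, 1, 21), role="recipient",
        timepoint="post", designated_donor="D1",
    )
    assert categorize_fmt_dyad(donor, recipient) == "matched"
    other = SampleRecord("D2", "D2", dt.date(2020, 1, 1), role="donor")
    assert categorize_fmt_dyad(other, recipient) == "mismatched"


def test_welch_bh_identical_groups_and_flags():
    groups = {"x": [0.2, 0.2, 0.2], "y": [0.2, 0.2, 0.2], "z": [0.9]}
    table = compare_sharing_across_categories(groups, method="welch_bh")
    xy = table[(table.category_a == "x") & (table.category_b == "y")].iloc[0]
    assert xy.statistic == 0.0 and xy.p_adj == 1.0
    xz = table[(table.category_a == "x") & (table.category_b == "z")].iloc[0]
    assert not xz.computable


def test_tukey_small_category_flagged_not_computable():
    groups = {"x": [0.1, 0.2, 0.15], "y": [0.5, 0.6, 0.55], "z": [0.3]}
    table = compare_sharing_across_categories(groups, method="tukey")
    assert not table[(table.category_b == "z") | (table.category_a == "z")][
        "computable"
    ].any()
    xy = table[(table.category_a == "x") & (table.category_b == "y")].iloc[0]
    assert xy.computable and xy.p_adj < 0.05


def test_separated_categories_reject_with_high_power():
    """Two categories with a 0.1 mean difference at sd 0.02 and n=20 are
    detected (adjusted p < 0.001) in at least 95% of seeded replicates."""
    rng = np.random.default_rng(7)
    hits = 0
    n_rep = 60
    for _ in range(n_rep):
        groups = {
            "lo": rng.normal(0.2, 0.02, 20),
            "hi": rng.normal(0.3, 0.02, 20),
        }
        table = compare_sharing_across_categories(groups, method="welch_bh")
        if table.iloc[0].p_adj < 0.001:
            hits += 1
    assert hits / n_rep >= 0.95


def _summaries():
    out = []
    # one dyad per pair of distinct hosts; hosts unique per dyad
    for i in range(6):
        out.append(
            DyadSummary(f"a{i}", f"b{i}", "never_overlapped", 10, 1)
        )
    for i in range(6):
        out.append(DyadSummary(f"c{i}", f"d{i}", "different_groups", 10, 2))
    for i in range(6):
        out.append(DyadSummary(f"l{i}_s1", f"l{i}_s2", "longitudinal", 10, 9))
    return out


def _host_map(summaries):
    host_map = {}
    for s in summaries:
        for sample in (s.sample_a, s.sample_b):
            host_map[sample] = sample.split("_")[0]
    return host_map


def test_downsample_identity_when_hosts_are_disjoint():
    summaries = _summaries()
    host_map = _host_map(summaries)
    full = compare_sharing_across_categories(summaries, method="tukey")
    table = downsample_robustness(summaries, host_map, n_iter=5, seed=0)
    # every host appears in exactly one dyad, so each iteration keeps all
    merged = table.merge(
        full, on=["category_a", "category_b"], suffixes=("", "_full")
    )
    assert np.allclose(merged.p_adj, merged.p_adj_full)


def test_downsample_is_deterministic_and_preserves_direction():
    summaries = _summaries()
    # make hosts collide across categories so downsampling bites
    host_map = _host_map(summaries)
    host_map["a0"] = "c0"
    host_map["b1"] = "d1"
    t1 = downsample_robustness(summaries, host_map, n_iter=20, seed=3)
    t2 = downsample_robustness(summaries, host_map, n_iter=20, seed=3)
    pd.testing.assert_frame_equal(t1, t2)
    # the longitudinal-vs-rest effect survives in >= 90% of iterations
    long_rows = t1[
        (t1.category_a == "different_groups") & (t1.category_b == "longitudinal")
    ]
    ok = long_rows[long_rows.computable]
    assert (ok.statistic < 0).mean() >= 0.9  # different_groups mean below


def test_downsample_sample_mode_removes_longitudinal():
    summaries = _summaries()
    host_map = _host_map(summaries)
    table = downsample_robustness(
        summaries, host_map, n_iter=3, seed=0, mode="sample"
    )
    long_rows = table[
        (table.category_a == "different_groups")
        & (table.category_b == "longitudinal")
    ]
    assert not long_rows.computable.any()


def test_phylo_share_normalization_and_scale_invariance():
    labels = ["s1", "s2", "s3"]
    d = pd.DataFrame(
        [[0, 0.05, 1.0], [0.05, 0, 1.0], [1.0, 1.0, 0]], index=labels, columns=labels
    )
    shared = phylo_share(d, threshold=0.1)
    assert shared.loc["s1", "s2"] and not shared.loc["s1", "s3"]
    scaled = phylo_share(d * 37.0, threshold=0.1)
    pd.testing.assert_frame_equal(shared, scaled)
    # identical samples (distance zero) always share
    assert shared.loc["s1", "s1"]


def test_phylo_share_quantile_mode_and_degenerate_matrix():
    labels = [f"s{i}" for i in range(5)]
    rng = np.random.default_rng(0)
    m = rng.random((5, 5))
    d = pd.DataFrame((m + m.T) / 2, index=labels, columns=labels)
    np.fill_diagonal(d.values, 0)
    q = phylo_share(d, threshold=0.1, mode="quantile")
    off = d.to_numpy()[~np.eye(5, dtype=bool)]
    cutoff = np.quantile(off, 0.1)
    assert q.to_numpy()[0, 1] == (d.iloc[0, 1] <= cutoff)

    zero = pd.DataFrame(np.zeros((3, 3)), index=labels[:3], columns=labels[:3])
    assert phylo_share(zero).to_numpy().all()
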