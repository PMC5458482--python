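"""DGMB screen: primitive-statistic oracles, clustering, crossing, profiling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melmeth import (
    anova_screen,
    bh_adjust,
    compartment_profile,
    cross_hit_lists,
    dgmb_compare,
    mann_whitney,
    report_partition_fractions,
    share_pct,
    ward_cluster,
)
from melmeth.screen import GroupComparison, fisher_island_test

from conftest import make_annotation, make_beta


# ---------------------------------------------------------------------------
# independent oracles


def mw_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of assignments."""
    pooled = list(a) + list(b)
    na = len(a)
    m = na * len(b) / 2.0

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y) + \
            0.5 * sum(1 for x in group_a for y in group_b if x == y)

    u_obs = u_stat(a, b)
    dist = []
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        dist.append(u_stat(ga, gb))
    return sum(1 for u in dist if abs(u - m) >= abs(u_obs - m) - 1e-12) / len(dist)


def bh_oracle(p):
    """Brute-force step-up definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


def fisher_oracle(table):
    """Two-tailed Fisher p: sum hypergeometric probabilities of all tables
    with the observed margins that are as or less probable."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def logp(x):
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1) - math.lgamma(r2 - c1 + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = math.exp(logp(a))
    return sum(math.exp(logp(x)) for x in range(lo, hi + 1)
               if math.exp(logp(x)) <= p_obs * (1 + 1e-7))


# ---------------------------------------------------------------------------
# Mann-Whitney


def test_mann_whitney_textbook_exact_value():
    # U = 0, most extreme of C(6,3)=20 assignments on both tails -> 2/20
    assert mann_whitney([1, 2, 3], [4, 5, 6], min_group_n=3) == pytest.approx(0.1)


def test_mann_whitney_identical_groups_is_one():
    assert mann_whitney([0.2, 0.5, 0.9], [0.9, 0.2, 0.5]) == 1.0


def test_mann_whitney_requires_min_group_size():
    with pytest.raises(ValueError, match="at least 3"):
        mann_whitney([1.0, 2.0], [3.0, 4.0, 5.0])


@pytest.mark.parametrize("na,nb", [(p, q) for p in range(1, 8) for q in range(1, 8) if p + q <= 10])
def test_exact_mann_whitney_matches_enumeration(na, nb):
    rng = np.random.default_rng(na * 100 + nb)
    a = rng.permutation(np.arange(1.0, na + nb + 1))[:na]
    b = np.setdiff1d(np.arange(1.0, na + nb + 1), a)
    p_impl = mann_whitney(a, b, mode="exact", min_group_n=1)
    assert p_impl == pytest.approx(mw_exact_oracle(list(a), list(b)), abs=1e-12)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_hand_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_trivial_cases():
    assert bh_adjust([0.37])[0] == pytest.approx(0.37)
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=60))
def test_bh_matches_brute_force_stepup(p):
    np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


# ---------------------------------------------------------------------------
# ANOVA screen


def test_anova_f_statistic_matches_hand_decomposition():
    data = np.array([[0.1, 0.2, 0.15, 0.6, 0.55, 0.65, 0.9, 0.85, 0.95]])
    bm = make_beta(data, probes=["p0"], samples=[f"s{i}" for i in range(9)])
    groups = {"g1": ["s0", "s1", "s2"], "g2": ["s3", "s4", "s5"], "g3": ["s6", "s7", "s8"]}
    _, table = anova_screen(bm, groups, delta=0.33, conf=0.99, return_table=True)
    vals = data.reshape(3, 3)
    grand = vals.mean()
    ss_between = 3 * sum((v.mean() - grand) ** 2 for v in vals)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in vals)
    f_hand = (ss_between / 2) / (ss_within / 6)
    assert table.loc["p0", "F"] == pytest.approx(f_hand, rel=1e-12)
    assert table.loc["p0", "selected"]


def test_anova_constant_probe_not_selected():
    bm = make_beta(np.full((1, 9), 0.5))
    groups = {"a": [f"s{i}" for i in range(3)],
              "b": [f"s{i}" for i in range(3, 6)],
              "c": [f"s{i}" for i in range(6, 9)]}
    assert len(anova_screen(bm, groups)) == 0


def test_anova_separated_medians_selected_and_empty_group_rejected():
    rng = np.random.default_rng(0)
    row = np.concatenate([0.1 + 0.01 * rng.random(5), 0.5 + 0.01 * rng.random(5),
                          0.9 + 0.01 * rng.random(5)])
    bm = make_beta(row[None, :])
    groups = {"a": [f"s{i}" for i in range(5)], "b": [f"s{i}" for i in range(5, 10)],
              "c": [f"s{i}" for i in range(10, 15)]}
    assert len(anova_screen(bm, groups)) == 1
    with pytest.raises(ValueError, match="no samples"):
        anova_screen(bm, {"a": [], "b": groups["b"]})


# ---------------------------------------------------------------------------
# Ward clustering


def test_ward_recovers_two_separated_groups():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(1)
    left = rng.normal(0.2, 0.02, size=(50, 10))
    right = rng.normal(0.8, 0.02, size=(50, 10))
    bm = make_beta(np.clip(np.hstack([left, right]), 0, 1))
    _, labels = ward_cluster(bm, k=2)
    truth = [0] * 10 + [1] * 10
    assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0


def test_ward_duplicated_sample_merges_at_height_zero():
    rng = np.random.default_rng(2)
    x = rng.random((20, 4))
    x[:, 3] = x[:, 0]  # duplicate of first sample
    z, _ = ward_cluster(make_beta(np.clip(x, 0, 1)))
    assert z[0, 2] == 0.0
    assert {int(z[0, 0]), int(z[0, 1])} == {0, 3}


def test_ward_three_point_merge_order_matches_brute_force():
    # samples on a line at 0, 1, 2 (scaled into [0,1]): pairwise distances
    # 1,1,2 (x0.4); Ward's criterion first merges a distance-1 pair, then
    # joins the remaining point at sqrt(3) x 0.4 (Lance-Williams update)
    bm = make_beta(np.array([[0.0, 0.4, 0.8]]))
    z, _ = ward_cluster(bm, k=2)
    assert z[0, 2] == pytest.approx(0.4)
    assert z[1, 2] == pytest.approx(np.sqrt(3) * 0.4)
    # ESS increase of candidate first merges: (0,1) and (1,2) tie at 0.08,
    # (0,2) costs 0.32 -> the first merge must involve sample 1
    assert 1 in {int(z[0, 0]), int(z[0, 1])}


def test_ward_needs_two_samples():
    with pytest.raises(ValueError, match="two samples"):
        ward_cluster(make_beta(np.array([[0.5]])))


# ---------------------------------------------------------------------------
# DGMB comparison


def _toy_bm(seed=0, n_probes=40, n=8, delta=0.4):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.2, 0.5, size=n_probes)
    a = np.clip(base[:, None] + rng.normal(0, 0.02, (n_probes, n)), 0, 1)
    b = a.copy()
    b[:10] = np.clip(base[:10, None] + delta + rng.normal(0, 0.02, (10, n)), 0, 1)
    cols_a = [f"a{i}" for i in range(n)]
    cols_b = [f"b{i}" for i in range(n)]
    bm = make_beta(np.hstack([a, b]), samples=cols_a + cols_b)
    return bm, cols_a, cols_b


def test_dgmb_antisymmetry():
    bm, ca, cb = _toy_bm()
    fwd = dgmb_compare(bm, ca, cb)
    rev = dgmb_compare(bm, cb, ca)
    np.testing.assert_allclose(fwd.table["dgmb"], -rev.table["dgmb"], atol=1e-12)


def test_dgmb_identical_groups_yield_nothing():
    bm, ca, cb = _toy_bm(delta=0.0)
    res = dgmb_compare(bm, ca, cb)
    assert res.table["significant"].sum() == 0


def test_dgmb_effect_gate_beats_tiny_p():
    # 0.24 median shift with an arbitrarily strong p must not pass the gate
    n = 30
    a = np.full((1, n), 0.30)
    b = np.full((1, n), 0.54)
    a += np.linspace(-0.001, 0.001, n)
    b += np.linspace(-0.001, 0.001, n)
    bm = make_beta(np.hstack([a, b]), samples=[f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)])
    res = dgmb_compare(bm, [f"a{i}" for i in range(n)], [f"b{i}" for i in range(n)])
    assert abs(res.table["dgmb"].iloc[0]) == pytest.approx(0.24, abs=1e-9)
    assert not res.table["significant"].iloc[0]
    assert not res.table["tested"].iloc[0]  # gate applied before testing


def test_dgmb_overlapping_groups_rejected():
    bm, ca, cb = _toy_bm()
    with pytest.raises(ValueError, match="overlap"):
        dgmb_compare(bm, ca, ca[:3] + cb)


def test_dgmb_threshold_monotonicity():
    bm, ca, cb = _toy_bm(seed=5)
    base = dgmb_compare(bm, ca, cb, dgmb_min=0.25, alpha=0.05)
    stricter_effect = dgmb_compare(bm, ca, cb, dgmb_min=0.35, alpha=0.05)
    stricter_alpha = dgmb_compare(bm, ca, cb, dgmb_min=0.25, alpha=0.005)
    assert set(stricter_effect.significant_probes) <= set(base.significant_probes)
    assert set(stricter_alpha.significant_probes) <= set(base.significant_probes)


def test_dgmb_gate_first_family_is_smaller_than_test_first():
    bm, ca, cb = _toy_bm(seed=6)
    gated = dgmb_compare(bm, ca, cb, gate_order="gate_first")
    tested = dgmb_compare(bm, ca, cb, gate_order="test_first")
    assert gated.table["tested"].sum() <= tested.table["tested"].sum()
    assert tested.table["tested"].all()


# ---------------------------------------------------------------------------
# crossing


def _fake_cmp(name, sig):
    """GroupComparison with given {probe: direction} significance."""
    probes = [f"p{i}" for i in range(8)]
    tab = pd.DataFrame(
        {
            "median_a": 0.2, "median_b": 0.5, "dgmb": 0.3, "tested": True,
            "p_raw": 0.001, "p_adj": 0.004,
            "direction": [sig.get(p, ("hyper",))[0] if p in sig else "hyper" for p in probes],
            "significant": [p in sig for p in probes],
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return GroupComparison(name, ("a",), ("b",), tab, 0.25, 0.05)


def test_cross_hit_lists_set_algebra():
    np_cmp = _fake_cmp("np", {"p1": ("hyper",), "p2": ("hyper",), "p3": ("hypo",), "p4": ("hyper",)})
    nm_cmp = _fake_cmp("nm", {"p2": ("hyper",), "p3": ("hypo",), "p4": ("hypo",), "p5": ("hyper",)})
    pm_cmp = _fake_cmp("pm", {"p6": ("hyper",)})
    part = cross_hit_lists(np_cmp, nm_cmp, pm_cmp)
    assert list(part.dev_hyper_probes) == ["p2"]
    assert list(part.dev_hypo_probes) == ["p3"]
    assert list(part.dev_conflict) == ["p4"]  # hyper in one, hypo in the other
    assert set(part.dev_single) == {"p1", "p5"}
    assert list(part.prog_hyper_probes) == ["p6"]


def test_cross_empty_progression_gives_no_common_genes():
    ann = make_annotation([(f"p{i}", 100 + i, None, f"G{i}", "Body") for i in range(8)])
    np_cmp = _fake_cmp("np", {"p1": ("hyper",)})
    nm_cmp = _fake_cmp("nm", {"p1": ("hyper",)})
    pm_cmp = _fake_cmp("pm", {})
    part = cross_hit_lists(np_cmp, nm_cmp, pm_cmp, ann)
    assert part.gene_sets["dev_hyper"] == {"G1"}
    assert part.common_genes == set()


# ---------------------------------------------------------------------------
# compartment profile & Fisher


def test_fisher_matches_enumeration_on_example_tables():
    for table in ([[10, 2], [3, 9]], [[5, 5], [5, 5]], [[1, 9], [9, 1]], [[0, 7], [5, 2]]):
        assert fisher_island_test(table) == pytest.approx(fisher_oracle(table), rel=1e-9)
    assert fisher_island_test([[5, 5], [5, 5]]) == 1.0


def test_compartment_profile_counts_and_fractions():
    ann = make_annotation([
        ("p0", 5500, (5000, 6000), "G1", "TSS200"),   # island
        ("p1", 4500, (5000, 6000), "G1", "TSS1500"),  # shore
        ("p2", 2500, (5000, 6000), "G2", "Body"),     # shelf
        ("p3", 100, (5000, 6000), "", ""),            # open sea
    ])
    prof = compartment_profile(["p0", "p1"], ["p2", "p3"], ann)
    assert prof.context_counts.loc["hyper"].tolist() == [1, 1, 0, 0]
    assert prof.context_counts.loc["hypo"].tolist() == [0, 0, 1, 1]
    assert prof.context_fractions.loc["hyper"].sum() == pytest.approx(1.0)
    assert prof.feature_counts.loc["hyper", "TSS200"] == 1
    assert prof.fisher_table.tolist() == [[1, 1], [0, 2]]


def test_compartment_profile_single_compartment_degenerate():
    ann = make_annotation([(f"p{i}", 5500, (5000, 6000), "", "") for i in range(4)])
    prof = compartment_profile(["p0", "p1"], ["p2", "p3"], ann)
    assert prof.context_fractions.loc["hyper", "island"] == 1.0
    assert prof.fisher_p == 1.0


# ---------------------------------------------------------------------------
# reporting identities


def test_share_pct_reporting_identities():
    assert share_pct(457, 457 + 131) == 77.7
    assert share_pct(131, 588) == 22.3
    assert share_pct(255, 457) == 55.8
    assert share_pct(0, 0) is None
    assert share_pct(10, 10) == 100.0


def test_report_partition_fractions_from_gene_sets():
    from melmeth import StagePartition

    part = StagePartition(
        dev_hyper_probes=pd.Index([]), dev_hypo_probes=pd.Index([]),
        prog_hyper_probes=pd.Index([]), prog_hypo_probes=pd.Index([]),
        dev_single=pd.Index([]), dev_conflict=pd.Index([]),
        gene_sets={"dev_hyper": {f"G{i}" for i in range(457)},
                   "prog_hyper": {f"H{i}" for i in range(131)},
                   "dev_hypo": set(), "prog_hypo": {f"K{i}" for i in range(10)}},
    )
    rep = report_partition_fractions(part)
    assert rep["hyper"]["dev_share_pct"] == 77.7
    assert rep["hyper"]["prog_share_pct"] == 22.3
    assert rep["hypo"]["dev_share_pct"] == 0.0
    assert rep["hypo"]["prog_share_pct"] == 100.0
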