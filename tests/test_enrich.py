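from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cladecons.enrich import (
    chi2_term_enrichment,
    cross_species_candidate_filter,
    fisher_2x2,
    permute_interval_overlap,
    tau_specificity,
)
from cladecons.intervals import IntervalSet


def test_annotation_equals_workspace_is_trivial():
    ws = IntervalSet([("c", 0, 10_000)])
    q = IntervalSet([("c", 100, 200), ("c", 5_000, 5_400)])
    res = permute_interval_overlap(q, ws, ws, n_sims=200, seed=1)
    assert res.observed == q.total_length
    assert res.fold == pytest.approx(1.0)
    assert res.p_enriched == pytest.approx(1.0)
    assert res.sd == 0.0


def test_point_queries_match_analytic_expectation():
    ws = IntervalSet([("c", 0, 10_000)])
    ann = IntervalSet([("c", 1_000, 3_000)])  # 20% of the workspace
    q = IntervalSet([("c", i * 50, i * 50 + 1) for i in range(40)])
    res = permute_interval_overlap(q, ann, ws, n_sims=3_000, seed=2)
    expect = q.total_length * ann.total_length / ws.total_length
    se = res.sd / np.sqrt(res.n_sims)
    assert abs(res.expected - expect) < 3 * se + 1e-9


def test_permutation_deterministic_given_seed():
    ws = IntervalSet([("c", 0, 5_000)])
    ann = IntervalSet([("c", 0, 500)])
    q = IntervalSet([("c", 100, 160), ("c", 2_000, 2_030)])
    a = permute_interval_overlap(q, ann, ws, n_sims=500, seed=9)
    b = permute_interval_overlap(q, ann, ws, n_sims=500, seed=9)
    assert a == b


def test_permutation_respects_workspace_gaps():
    ws = IntervalSet([("c", 0, 100), ("c", 10_000, 10_100)])
    q = IntervalSet([("c", 0, 80)])
    ann = IntervalSet([("c", 10_000, 10_100)])
    res = permute_interval_overlap(q, ann, ws, n_sims=400, seed=3)
    # a segment never straddles the gap: overlap is always 0 or 80, never partial
    assert res.observed == 0
    assert res.expected * res.n_sims % 80 == pytest.approx(0, abs=1e-6)


def test_planted_enrichment_detected():
    from cladecons.simdata import simulate_intervals

    ws = IntervalSet([("c", 0, 50_000)])
    targets = [(i * 5_000, i * 5_000 + 500) for i in range(10)]
    ann = IntervalSet([("c", a, b) for a, b in targets])
    hits = 0
    for rep in range(20):
        iv = simulate_intervals([(0, 50_000)], 40, 50, targets, 0.5, seed=rep,
                                chrom="c")
        q = IntervalSet(iv)
        res = permute_interval_overlap(q, ann, ws, n_sims=2_000, seed=rep)
        hits += res.p_enriched < 0.01
    assert hits >= 19  # 95% of replicates


def test_empirical_p_never_zero_and_monotone():
    ws = IntervalSet([("c", 0, 2_000)])
    ann = IntervalSet([("c", 0, 1_000)])
    q = IntervalSet([("c", 0, 900)])
    res = permute_interval_overlap(q, ann, ws, n_sims=1_000, seed=5)
    assert 0 < res.p_enriched <= 1 and 0 < res.p_depleted <= 1


# --------------------------------------------------------------------- #
def test_chi2_proportional_term_null():
    bg = {f"g{i}" for i in range(1000)}
    gl = {f"g{i}" for i in range(100)}  # 10% of background
    term = {f"g{i}" for i in range(0, 1000, 10)}  # contains exactly 10 of list
    df = chi2_term_enrichment(gl, {"T": term}, bg)
    assert df.loc[0, "chi2"] == pytest.approx(0.0, abs=1e-9)
    assert df.loc[0, "p"] == pytest.approx(1.0)


def test_chi2_hand_oracle():
    # table: in-list&term 30, in-list 470, rest&term 70, rest 14,430;
    # the smallest expected count (500*100/15000 = 3.3) is below 5, so the
    # continuity-corrected Pearson statistic is the right hand value
    bg = {f"g{i}" for i in range(15_000)}
    gl = {f"g{i}" for i in range(500)}
    term = {f"g{i}" for i in range(30)} | {f"g{i}" for i in range(500, 570)}
    df = chi2_term_enrichment(gl, {"T": term}, bg)
    a, b, c, d = 30, 470, 70, 14_430
    n = a + b + c + d
    want = n * (abs(a * d - b * c) - n / 2) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    assert df.loc[0, "chi2"] == pytest.approx(want, rel=1e-9)
    assert df.loc[0, "direction"] == "enriched"


def test_chi2_q_equals_bh(jc):
    from cladecons.clade import bh_fdr

    rng = np.random.default_rng(0)
    bg = {f"g{i}" for i in range(500)}
    gl = set(rng.choice(sorted(bg), 60, replace=False))
    terms = {f"T{k}": set(rng.choice(sorted(bg), 40, replace=False)) for k in range(8)}
    df = chi2_term_enrichment(gl, terms, bg)
    assert np.allclose(df["q"], bh_fdr(df["p"].to_numpy()))


# --------------------------------------------------------------------- #
def fisher_enumeration(table):
    """Oracle: sum probabilities of all margin-fixed tables <= observed."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


def test_fisher_balanced_table():
    assert fisher_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)


def test_fisher_degenerate_margin():
    assert fisher_2x2([[0, 0], [3, 7]]) == 1.0


@given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_fisher_matches_enumeration(cells):
    table = [[cells[0], cells[1]], [cells[2], cells[3]]]
    got = fisher_2x2(table)
    t = np.asarray(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        assert got == 1.0
    else:
        assert got == pytest.approx(fisher_enumeration(table), abs=1e-12)
    # transpose symmetry
    assert got == pytest.approx(fisher_2x2(np.asarray(table).T), abs=1e-12)


def test_fisher_chi2_direction_agreement():
    """Both tests call the same direction on clearly unbalanced tables."""
    bg = {f"g{i}" for i in range(400)}
    gl = {f"g{i}" for i in range(50)}
    term = {f"g{i}" for i in range(40)}  # heavily in-list
    df = chi2_term_enrichment(gl, {"T": term}, bg)
    assert df.loc[0, "direction"] == "enriched"
    p_f = fisher_2x2([[40, 10], [0, 350]])
    assert p_f < 0.05 and df.loc[0, "p"] < 0.05


# --------------------------------------------------------------------- #
@pytest.mark.parametrize(
    "vec,want",
    [
        ([0, 0, 5, 0], 1.0),
        ([3, 3, 3], 0.0),
        ([1, 2], 0.5),
        ([0, 1, 2], 0.75),
    ],
)
def test_tau_values(vec, want):
    assert tau_specificity(vec) == pytest.approx(want)


def test_tau_errors():
    with pytest.raises(ValueError):
        tau_specificity([0, 0, 0])
    with pytest.raises(ValueError):
        tau_specificity([5])
    with pytest.raises(ValueError):
        tau_specificity([1, -1])


# --------------------------------------------------------------------- #
def _filter_frames(rows):
    genes = [r[0] for r in rows]
    fc1 = pd.DataFrame({"c1": [r[1] for r in rows]}, index=genes)
    deg = pd.DataFrame({"c1": [r[2] for r in rows]}, index=genes)
    fc2 = pd.DataFrame({"c1": [r[4] for r in rows if r[3]]},
                       index=[f"t_{r[0]}" for r in rows if r[3]])
    orth = {r[0]: f"t_{r[0]}" for r in rows if r[3]}
    return fc1, deg, fc2, orth


def test_candidate_filter_boundaries():
    rows = [
        ("keep", 6.0, True, True, 1.5),
        ("turtle_high", 6.0, True, True, 2.5),
        ("exactly5", 5.0, True, True, 1.5),   # strict >5 drops it
        ("turtle2", 6.0, True, True, 2.0),    # strict <2 drops it
        ("not_deg", 6.0, False, True, 1.5),
        ("no_orth", 6.0, True, False, None),
    ]
    fc1, deg, fc2, orth = _filter_frames(rows)
    kept, missing = cross_species_candidate_filter(fc1, deg, fc2, orth)
    assert kept == ["keep"]
    assert missing == ["no_orth"]


def test_candidate_filter_rejects_nonpositive_fc():
    fc1 = pd.DataFrame({"c1": [0.0]}, index=["g"])
    deg = pd.DataFrame({"c1": [True]}, index=["g"])
    with pytest.raises(ValueError):
        cross_species_candidate_filter(fc1, deg, pd.DataFrame({"c1": []}), {})
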