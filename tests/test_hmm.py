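import itertools

import numpy as np
import pytest

from cladecons.hmm import (
    ConservedElement,
    PhyloHMMParams,
    element_log_odds,
    emission_table,
    estimate_rho,
    forward_backward,
    viterbi_elements,
    viterbi_path,
)
from cladecons.likelihood import column_log_likelihood
from cladecons.simdata import plant_elements, simulate_alignment


def brute_posteriors(E, params):
    L = len(E)
    A, pi = params.transition, params.stationary
    tot, Z = np.zeros(L), 0.0
    for path in itertools.product([0, 1], repeat=L):
        w = pi[path[0]] * np.exp(E[0, path[0]])
        for t in range(1, L):
            w *= A[path[t - 1], path[t]] * np.exp(E[t, path[t]])
        Z += w
        for t in range(L):
            if path[t] == 0:
                tot[t] += w
    return tot / Z, np.log(Z)


def test_forward_backward_matches_enumeration():
    rng = np.random.default_rng(0)
    params = PhyloHMMParams(0.4, 0.2, 0.1)
    for _ in range(5):
        E = rng.normal(0, 2, (8, 2))
        post, ll = forward_backward(E, params)
        want, ll_want = brute_posteriors(E, params)
        assert np.allclose(post, want, atol=1e-10)
        assert ll == pytest.approx(ll_want, abs=1e-10)


def test_uninformative_emissions_give_stationary():
    params = PhyloHMMParams(1.0, 0.03, 0.01)
    E = np.zeros((50, 2))
    post, _ = forward_backward(E, params)
    assert np.allclose(post, params.stationary[0], atol=1e-12)


def test_reversal_symmetry():
    rng = np.random.default_rng(3)
    E = rng.normal(0, 1, (30, 2))
    params = PhyloHMMParams(0.3, 0.05, 0.05)  # symmetric transitions
    post, _ = forward_backward(E, params)
    rpost, _ = forward_backward(E[::-1], params)
    assert np.allclose(post, rpost[::-1], atol=1e-12)


def test_forward_backward_stable_on_million_columns():
    rng = np.random.default_rng(1)
    E = rng.normal(-50, 30, (1_000_000, 2))
    post, ll = forward_backward(E, PhyloHMMParams())
    assert np.isfinite(ll)
    assert np.all((post >= 0) & (post <= 1))
    states = viterbi_path(E[:200_000], PhyloHMMParams())
    assert states.shape == (200_000,)


def test_empty_emissions_rejected():
    with pytest.raises(ValueError):
        forward_backward(np.zeros((0, 2)), PhyloHMMParams())


# --------------------------------------------------------------------- #
def test_emission_table_contract(tree6, jc):
    aln = simulate_alignment(tree6, jc, 40, seed=2)
    E = emission_table(aln, tree6, jc, rho=0.3)
    for j in (0, 7, 33):
        col = {sp: aln.row_string(sp)[j] for sp in aln.species}
        assert E[j, 0] == pytest.approx(
            column_log_likelihood(tree6, jc, 0.3, col), abs=1e-12
        )
        assert E[j, 1] == pytest.approx(
            column_log_likelihood(tree6, jc, 1.0, col), abs=1e-12
        )
    # rho = 1: both entries equal
    E1 = emission_table(aln, tree6, jc, rho=1.0)
    assert np.allclose(E1[:, 0], E1[:, 1], atol=1e-12)


def test_invariant_column_favors_conserved(tree6, jc):
    from cladecons.alignment import MultipleAlignment

    aln = MultipleAlignment.from_strings({n: "A" * 5 for n in tree6.leaf_names})
    E = emission_table(aln, tree6, jc, rho=0.2)
    assert np.all(E[:, 0] > E[:, 1])


def test_uniform_penalty_yields_no_elements():
    """A constant 1-nat tilt to nonconserved can never beat the transition
    penalty, so Viterbi stays in the nonconserved state throughout."""
    E = np.zeros((500, 2))
    E[:, 1] = 1.0
    params = PhyloHMMParams(0.3, 0.01, 0.01)
    els = viterbi_elements(E, params, np.arange(500), "chr1")
    assert els == []
    assert np.all(viterbi_path(E, params) == 1)


def test_min_length_boundary():
    """A 19-column conserved run is dropped, a 20-column run is kept."""
    for run, expect in [(19, 0), (20, 1)]:
        E = np.zeros((200, 2))
        E[:, 1] = 3.0
        E[90:90 + run, 0] = E[90:90 + run, 1] + 6.0  # strong conserved signal
        els = viterbi_elements(E, PhyloHMMParams(0.3, 0.05, 0.01), np.arange(200), "chr1")
        assert len(els) == expect
        if els:
            assert (els[0].start, els[0].end) == (90, 110)


def test_elements_split_at_reference_gaps():
    E = np.zeros((100, 2))
    E[20:80, 0] = 6.0  # 60-column conserved block
    ref = np.arange(100)
    ref[45:50] = -1  # reference gap in the middle
    ref[50:] -= 5
    els = viterbi_elements(E, PhyloHMMParams(0.3, 0.05, 0.01), ref, "chr1")
    assert len(els) == 2
    assert els[0].end <= 45 and els[1].start >= 45


def test_element_log_odds_additive(tree6, jc):
    rng = np.random.default_rng(4)
    E = rng.normal(0, 1, (120, 2))
    ref = np.arange(120)
    e1 = ConservedElement("chr1", 10, 40, 0.0)
    e2 = ConservedElement("chr1", 40, 70, 0.0)
    e12 = ConservedElement("chr1", 10, 70, 0.0)
    s1 = element_log_odds(e1, E, ref)
    s2 = element_log_odds(e2, E, ref)
    assert s1 + s2 == pytest.approx(element_log_odds(e12, E, ref), abs=1e-10)
    # independent oracle: direct column-by-column sum
    want = sum(float(E[j, 0] - E[j, 1]) for j in range(10, 40))
    assert s1 == pytest.approx(want, abs=1e-12)
    # rho = 1 scores are identically zero
    aln = simulate_alignment(tree6, jc, 60, seed=5)
    E1 = emission_table(aln, tree6, jc, rho=1.0)
    e = ConservedElement("chr1", 0, 60, 0.0)
    assert element_log_odds(e, E1, aln.ref_positions) == pytest.approx(0.0, abs=1e-10)


# --------------------------------------------------------------------- #
def test_planted_element_recovery_jaccard(tree6, jc):
    """rho=0.2 planted elements >=50 columns recovered with Jaccard >= 0.8."""
    params = PhyloHMMParams.from_tuning(0.25)
    jaccards = []
    for rep in range(20):
        aln = simulate_alignment(tree6, jc, 3000, seed=100 + rep)
        spec = [(1000, 100, 0.2, "shared-conserved", tree6.leaf_names)]
        planted, truth = plant_elements(aln, tree6, jc, spec, seed=200 + rep)
        E = emission_table(planted, tree6, jc, params.rho)
        els = viterbi_elements(E, params, planted.ref_positions, "chr1")
        called = np.zeros(3000, bool)
        for e in els:
            called[e.start:e.end] = True
        true = np.zeros(3000, bool)
        true[1000:1100] = True
        jaccards.append((called & true).sum() / max((called | true).sum(), 1))
    assert np.mean(jaccards) >= 0.8


def test_estimate_rho_monotone_and_recovers(tree6, jc):
    """EM log-likelihood never decreases; rho recovered from mixed data."""
    rng_specs = []
    aln = simulate_alignment(tree6, jc, 20_000, seed=42)
    spec = [(i * 1000 + 300, 300, 0.25, "shared-conserved", tree6.leaf_names)
            for i in range(20)]  # 30% of columns conserved at rho=0.25
    planted, _ = plant_elements(aln, tree6, jc, spec, seed=43)
    params, info = estimate_rho(planted, tree6, jc, max_iter=15)
    trace = np.asarray(info["loglik_trace"])
    assert np.all(np.diff(trace) >= -1e-6)
    assert 0.15 <= params.rho <= 0.4


def test_estimate_rho_neutral_data_hits_boundary(tree6, jc):
    aln = simulate_alignment(tree6, jc, 5000, seed=7)
    params, info = estimate_rho(aln, tree6, jc, max_iter=10)
    assert params.rho > 0.7 or info["occupancy"] < 0.02
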