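import numpy as np
import pytest
from scipy import stats as sps

from degsample import (
    DegreeDistributionSpec,
    degree_pmf,
    draw_graphical_sequence,
    is_graphical,
    structural_cutoff,
)


def test_uniform_pmf_is_flat():
    ks, p = degree_pmf(
        DegreeDistributionSpec(family="uniform", k_max=4, cutoff_policy="fixed"), 50
    )
    assert tuple(ks) == (1, 2, 3, 4)
    assert np.allclose(p, 0.25)


def test_power_law_gamma_zero_equals_uniform():
    spec_pl = DegreeDistributionSpec(
        family="power_law", gamma=0.0, k_max=6, cutoff_policy="fixed"
    )
    spec_u = DegreeDistributionSpec(family="uniform", k_max=6, cutoff_policy="fixed")
    ks1, p1 = degree_pmf(spec_pl, 30)
    ks2, p2 = degree_pmf(spec_u, 30)
    assert np.array_equal(ks1, ks2) and np.allclose(p1, p2)
    a, _ = draw_graphical_sequence(spec_pl, 30, seed=11)
    b, _ = draw_graphical_sequence(spec_u, 30, seed=11)
    assert np.array_equal(a.values, b.values)


def test_power_law_pmf_normalization():
    ks, p = degree_pmf(
        DegreeDistributionSpec(family="power_law", gamma=2.0, k_max=4, cutoff_policy="fixed"),
        20,
    )
    raw = np.array([1.0, 1 / 4, 1 / 9, 1 / 16])
    assert np.allclose(p, raw / raw.sum())


def test_binomial_pmf_truncated_and_renormalized():
    spec = DegreeDistributionSpec(family="binomial", connect_prob=0.1, k_min=2)
    ks, p = degree_pmf(spec, 30)
    assert ks[0] == 2
    full = sps.binom.pmf(ks, 29, 0.1)
    assert np.allclose(p, full / full.sum())


def test_degenerate_binomial_gives_complete_graph():
    spec = DegreeDistributionSpec(family="binomial", connect_prob=1.0)
    seq, diag = draw_graphical_sequence(spec, 4, seed=0)
    assert tuple(seq.values) == (3, 3, 3, 3)
    assert diag.parity_fixes == 0 and diag.graphicality_rejections == 0


def test_point_mass_pmf_draws_triangle():
    spec = DegreeDistributionSpec(
        family="uniform", k_min=2, k_max=2, cutoff_policy="fixed"
    )
    seq, _ = draw_graphical_sequence(spec, 3, seed=0)
    assert tuple(seq.values) == (2, 2, 2)


@pytest.mark.parametrize(
    "N, mean_k, expect",
    [(100, 4.0, 20), (2, 1.0, 1), (10**4, 1.0, 100)],
)
def test_structural_cutoff_values(N, mean_k, expect):
    assert structural_cutoff(N, mean_k) == expect


def test_structural_policy_caps_support():
    spec = DegreeDistributionSpec(
        family="power_law", gamma=3.0, cutoff_policy="structural"
    )
    ks, p = degree_pmf(spec, 1000)
    # cutoff ~ sqrt(<k> N) with <k> ~ 1.37 for gamma = 3
    assert 30 <= ks[-1] <= 45


@pytest.mark.parametrize(
    "spec",
    [
        DegreeDistributionSpec(family="power_law", gamma=2.5, k_max=40, cutoff_policy="fixed"),
        DegreeDistributionSpec(family="binomial", connect_prob=0.05),
        DegreeDistributionSpec(family="uniform", k_max=30, cutoff_policy="fixed"),
    ],
    ids=["power_law", "binomial", "uniform"],
)
def test_draw_histogram_matches_pmf(spec):
    N = 200
    ks, p = degree_pmf(spec, N)
    rng = np.random.default_rng(99)
    draws = rng.choice(ks, size=10**5, p=p)
    counts = np.bincount(draws, minlength=ks[-1] + 1)[ks[0] :]
    expected = 10**5 * p
    # pool low-expectation bins for a valid chi-square
    order = np.argsort(-expected)
    obs, exp = [], []
    acc_o = acc_e = 0.0
    for j in order:
        acc_o += counts[j]
        acc_e += expected[j]
        if acc_e >= 5:
            obs.append(acc_o)
            exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and exp:
        obs[-1] += acc_o
        exp[-1] += acc_e
    chi = sps.chisquare(obs, np.array(exp) * (sum(obs) / sum(exp)))
    assert chi.pvalue > 0.001


def test_drawn_sequences_are_graphical_and_reproducible():
    spec = DegreeDistributionSpec(family="uniform", k_max=5, cutoff_policy="fixed")
    a, da = draw_graphical_sequence(spec, 100, seed=21)
    b, db = draw_graphical_sequence(spec, 100, seed=21)
    assert np.array_equal(a.values, b.values)
    assert (da.parity_fixes, da.graphicality_rejections) == (
        db.parity_fixes,
        db.graphicality_rejections,
    )
    assert bool(is_graphical(a))
    assert a.degree_sum % 2 == 0
    assert da.parity_fixes >= 0 and da.graphicality_rejections >= 0


def test_spec_validation():
    with pytest.raises(ValueError):
        DegreeDistributionSpec(family="power_law")  # missing gamma
    with pytest.raises(ValueError):
        DegreeDistributionSpec(family="binomial", connect_prob=1.5)
    with pytest.raises(ValueError):
        DegreeDistributionSpec(family="uniform", k_min=0)
    with pytest.raises(ValueError):
        DegreeDistributionSpec(family="uniform", cutoff_policy="fixed")
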