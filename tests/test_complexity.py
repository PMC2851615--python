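import numpy as np
import pytest

from degsample import (
    DegreeDistributionSpec,
    degree_pmf,
    expected_complexity,
    expected_degree_profile,
    fit_complexity_exponent,
    fit_power_law,
    sample_graph,
    worst_case_bound,
)

from conftest import draw_mixed_graphical


def test_worst_case_smallest_sequence():
    est = worst_case_bound([1, 1])
    assert est.worst_case == 2  # one stub, two-node window
    assert est.n_links == 1 and est.nm_equivalent == 2


def test_worst_case_complete_graph_scales_cubically():
    Ns = [10, 20, 40]
    vals = [worst_case_bound([n - 1] * n).worst_case for n in Ns]
    slope, _ = fit_power_law(Ns, vals)
    assert slope == pytest.approx(3.0, abs=0.1)


def test_worst_case_star_scales_quadratically():
    Ns = [100, 1000, 10000]
    vals = [worst_case_bound([n - 1] + [1] * (n - 1)).worst_case for n in Ns]
    slope, _ = fit_power_law(Ns, vals)
    assert slope == pytest.approx(2.0, abs=0.1)


def test_worst_case_below_sequence_independent_cubic():
    rng = np.random.default_rng(5)
    for i in range(10):
        n = int(rng.integers(5, 200))
        seq = draw_mixed_graphical(i, n, rng)
        assert worst_case_bound(seq).worst_case <= n**3


def test_measured_steps_below_worst_case_bound(rng):
    for i in range(10):
        seq = draw_mixed_graphical(i, int(rng.integers(10, 80)), rng)
        s = sample_graph(seq, seed=i)
        assert 0 < s.steps <= worst_case_bound(seq).worst_case


def test_profile_point_mass():
    spec = DegreeDistributionSpec(
        family="uniform", k_min=3, k_max=3, cutoff_policy="fixed"
    )
    prof = expected_degree_profile(spec, 12)
    assert np.all(prof == 3)


def test_profile_uniform_against_direct_search():
    spec = DegreeDistributionSpec(family="uniform")
    N = 100
    prof = expected_degree_profile(spec, N)
    assert prof[0] == 99 and prof[-1] == 1
    ks, p = degree_pmf(spec, N)
    tail = {d: N * p[ks >= d].sum() for d in ks}
    for i in (1, 7, 25, 50, 99, 100):
        direct = max(d for d in ks if tail[d] >= i - 1e-9)
        assert prof[i - 1] == direct


def test_profile_monotone_and_maximal():
    spec = DegreeDistributionSpec(
        family="power_law", gamma=3.0, cutoff_policy="structural"
    )
    N = 1000
    prof = expected_degree_profile(spec, N)
    assert np.all(prof[:-1] >= prof[1:])
    ks, p = degree_pmf(spec, N)
    assert prof[0] <= ks[-1]
    # maximality: one degree higher would violate the defining inequality
    tail = np.cumsum(p[::-1])[::-1] * N
    for i in (1, 10, 500, 1000):
        d = prof[i - 1]
        if d < ks[-1]:
            assert tail[d + 1 - ks[0]] < i


def test_expected_complexity_closed_forms():
    point2 = DegreeDistributionSpec(
        family="uniform", k_min=2, k_max=2, cutoff_policy="fixed"
    )
    assert expected_complexity(point2, 10).expected_total == 110
    any_min1 = DegreeDistributionSpec(family="uniform")
    assert expected_complexity(any_min1, 2).expected_total == 3


def test_expected_complexity_uniform_approaches_one_third_cubed():
    spec = DegreeDistributionSpec(family="uniform")
    for N in (10**3, 10**4, 10**5):
        ratio = expected_complexity(spec, N).expected_total / N**3
        assert ratio == pytest.approx(1 / 3, rel=0.05)


def test_expected_complexity_monotone_in_N():
    spec = DegreeDistributionSpec(family="power_law", gamma=2.5)
    totals = [expected_complexity(spec, N).expected_total for N in (100, 200, 400)]
    assert totals[0] < totals[1] < totals[2]


def test_fit_exact_cubic():
    Ns = [100, 1000, 10000, 100000]
    slope, err = fit_power_law(Ns, [float(n) ** 3 for n in Ns])
    assert slope == pytest.approx(3.0, abs=1e-12)


def test_fit_point_mass_spec_is_quadratic():
    spec = DegreeDistributionSpec(
        family="uniform", k_min=4, k_max=4, cutoff_policy="fixed"
    )
    est = fit_complexity_exponent(spec, [10**2, 10**3, 10**4, 10**5])
    assert est.fitted_exponent == pytest.approx(2.0, abs=0.05)


def test_fit_requires_enough_range():
    spec = DegreeDistributionSpec(family="uniform")
    with pytest.raises(ValueError):
        fit_complexity_exponent(spec, [100, 200, 400])
    with pytest.raises(ValueError):
        fit_complexity_exponent(spec, [100, 200, 400, 800])


def test_uniform_exponent_converges_to_three():
    """Shifting the fitted N-range upward tightens the slope toward 3."""
    spec = DegreeDistributionSpec(family="uniform")
    low = fit_complexity_exponent(spec, [10**2, 10**3, 10**4, 10**5])
    high = fit_complexity_exponent(spec, [10**3, 10**4, 10**5, 10**6])
    assert abs(high.fitted_exponent - 3.0) < abs(low.fitted_exponent - 3.0)
    assert high.fitted_exponent == pytest.approx(3.0, abs=1e-4)
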