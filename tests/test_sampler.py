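import math

import numpy as np
import pytest

from degsample import (
    SamplerRun,
    TestSequence,
    exact_weight,
    max_fail_degree,
    normalize_sequence,
    sample_graph,
    sample_graphs,
)
from degsample.oracles import naive_allowed_set

from conftest import draw_mixed_graphical


@pytest.mark.parametrize(
    "seq, logw, m_rec, hub_rec",
    [
        ((1, 1, 1, 1), math.log(3), (3, 1), (1, 1)),
        ((2, 2, 2), 0.0, (2, 1, 1), (2, 1)),
        ((4, 1, 1, 1, 1), 0.0, (4, 3, 2, 1), (4,)),
    ],
)
def test_weight_law_examples(seq, logw, m_rec, hub_rec):
    for seed in range(5):
        s = sample_graph(seq, seed=seed)
        assert s.log_weight == pytest.approx(logw, abs=1e-12)
        assert s.m_record == m_rec
        assert s.hub_record == hub_rec


def test_matching_sampler_reaches_all_matchings():
    seen = set()
    for s in sample_graphs((1, 1, 1, 1), 60, master_seed=0):
        seen.add(s.edges)
    assert seen == {
        ((0, 1), (2, 3)),
        ((0, 2), (1, 3)),
        ((0, 3), (1, 2)),
    }


def test_sample_has_exact_degrees_and_is_simple(rng):
    for i in range(24):
        N = int(rng.integers(10, 120))
        seq = draw_mixed_graphical(i, N, rng)
        s = sample_graph(seq, seed=i)
        assert len(set(s.edges)) == len(s.edges)
        assert all(u != v for u, v in s.edges)
        assert s.degrees() == seq.degree_of()
        # log weight agrees with exact integer evaluation
        assert s.log_weight == pytest.approx(s.exact_log_weight(), abs=1e-9)
        assert s.log_weight >= -1e-12  # w >= 1


def test_same_seed_reproduces_sample():
    seq = normalize_sequence([4, 3, 3, 2, 2, 2, 1, 1])
    a = sample_graph(seq, seed=7)
    b = sample_graph(seq, seed=7)
    assert a.edges == b.edges and a.log_weight == b.log_weight


def test_non_graphical_input_is_refused():
    with pytest.raises(ValueError, match="odd"):
        sample_graph((1, 1, 1))
    with pytest.raises(ValueError, match="k = 2"):
        sample_graph((3, 3, 1, 1))


def test_fresh_hub_allows_everything():
    run = SamplerRun(normalize_sequence([2, 2, 1, 1]))
    A = run.allowed_set()
    assert A.fresh and A.fail_degree is None
    assert set(int(v) for v in A.members) == {1, 2, 3}


def test_allowed_set_after_low_degree_link():
    # linking the degree-2 hub of (2,2,1,1) to a degree-1 node forces the
    # other degree-2 node next: both realizations are paths with the
    # degree-2 nodes adjacent.
    run = SamplerRun(normalize_sequence([2, 2, 1, 1]))
    run.place_link(2)
    T = run.build_test_sequence()
    assert T.entries == ((1, 2, False), (3, 1, False), (0, 1, True))
    assert T.temp_linked == ()
    assert max_fail_degree(T) == 1
    A = run.allowed_set()
    assert A.fail_degree == 1
    assert set(int(v) for v in A.members) == {1}


def test_test_sequence_with_temporary_links():
    # residual hub=2 with partners (3, 3, 1, 1): temp-link one degree-3
    # node; linking the hub to a degree-1 node would leave (3,3,1,1),
    # which is not graphical.
    T = TestSequence(
        entries=(
            ("c", 3, False),
            ("b", 2, True),
            ("e", 1, False),
            ("f", 1, False),
            ("hub", 1, True),
        ),
        temp_linked=("b",),
        hub="hub",
    )
    assert max_fail_degree(T) == 1
    assert max_fail_degree(T, scan="full") == 1


def test_two_remaining_singletons_have_no_fail_degree():
    T = TestSequence(
        entries=(("v", 1, False), ("hub", 1, True)), temp_linked=(), hub="hub"
    )
    assert max_fail_degree(T) is None
    assert max_fail_degree(T, scan="full") is None


def test_place_link_rejects_targets_outside_allowed_set():
    run = SamplerRun(normalize_sequence([2, 2, 1, 1]))
    run.place_link(2)
    with pytest.raises(ValueError, match="not in the allowed set"):
        run.place_link(3)


def test_allowed_sets_are_upward_closed_and_respect_leftmost(rng):
    """Monotonicity of fail-degrees and safety of the leftmost set.

    The allowed set must contain every non-forbidden active node whose
    residual degree exceeds that of any member, and every returned
    fail-degree must be strictly below the smallest degree in the hub's
    leftmost adjacency set.
    """
    for i in range(12):
        seq = draw_mixed_graphical(i, int(rng.integers(8, 50)), rng)
        run = SamplerRun(seq)
        pick = np.random.default_rng(i)
        while not run.complete:
            A = run.allowed_set()
            res = run.residual()
            forb = run.forbidden_labels()
            members = set(int(v) for v in A.members)
            floor = min(res[v] for v in members)
            for v, d in res.items():
                if v not in forb and d >= floor and v != run.current_hub:
                    assert v in members
            if A.fail_degree is not None:
                h = res[run.current_hub]
                lm_degrees = sorted(
                    (res[v] for v in res if v not in forb), reverse=True
                )[:h]
                assert A.fail_degree < min(lm_degrees)
            target = int(pick.choice(sorted(members)))
            run.place_link(target)
        assert run.run(pick).degrees() == seq.degree_of()


def test_manual_and_automatic_paths_agree_with_naive_oracle(rng):
    for i in range(6):
        seq = draw_mixed_graphical(i, 30, rng)
        run = SamplerRun(seq)
        pick = np.random.default_rng(100 + i)
        while not run.complete:
            A = run.allowed_set()
            naive = naive_allowed_set(
                run.residual(), run.current_hub, set(run.forbidden_labels())
            )
            assert sorted(int(v) for v in A.members) == naive
            run.place_link(int(pick.choice(naive)))


def test_exact_weight_helper():
    w = exact_weight((3, 1), (1, 1))
    assert w == 3
    w = exact_weight((4, 3, 2, 1), (4,))
    assert w == 1
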