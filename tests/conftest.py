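"""Shared fixtures and sequence generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from degsample import DegreeDistributionSpec, draw_graphical_sequence


def mixed_family_spec(index: int, rng: np.random.Generator) -> DegreeDistributionSpec:
    """Cycle through the ensemble families used throughout the suite."""
    fam = index % 4
    if fam == 0:
        return DegreeDistributionSpec(
            family="power_law", gamma=2.0, cutoff_policy="structural"
        )
    if fam == 1:
        return DegreeDistributionSpec(
            family="power_law", gamma=3.0, cutoff_policy="structural"
        )
    if fam == 2:
        return DegreeDistributionSpec(
            family="binomial", connect_prob=float(rng.uniform(0.02, 0.2))
        )
    return DegreeDistributionSpec(family="uniform", cutoff_policy="structural")


def draw_mixed_graphical(index: int, N: int, rng: np.random.Generator):
    """One graphical sequence from the family cycle."""
    spec = mixed_family_spec(index, rng)
    seq, _ = draw_graphical_sequence(spec, N, rng=rng)
    return seq


def random_degree_list(rng: np.random.Generator, n_max: int = 500) -> list[int]:
    """A random positive-integer sequence (graphical or not)."""
    n = int(rng.integers(1, n_max + 1))
    fam = int(rng.integers(3))
    if fam == 0:  # heavy tail
        d = np.minimum(rng.zipf(2.5, size=n), max(2, n))
    elif fam == 1:
        d = rng.integers(1, max(2, n), size=n)
    else:
        d = 1 + rng.binomial(max(1, n - 1), 0.1, size=n)
    return sorted((int(v) for v in d), reverse=True)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
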