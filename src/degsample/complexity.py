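"""Step-count bounds and distribution-level expected complexity.

For a concrete sequence the construction of one sample costs at most

.. math:: C(D) \\;\\le\\; \\sum_j \\hat k_j \\, N_j, \\qquad
          N_j = N - j + 1,

elementary steps, where the j-th hub has residual degree :math:`\\hat k_j`
when chosen and :math:`N_j` bounds the residual-sequence length at that
point; equivalently :math:`C = O(N \\cdot M)` with M the number of links,
hence a sequence-independent :math:`O(N^3)`.  An elementary step is one
residual-sequence entry visited while building the test sequence or
running the k-scan, matching the per-stub O(residual length) accounting;
:attr:`degsample.sampler.SamplerRun.steps` counts exactly that.

At the distribution level the expected cost is conservatively estimated by
replacing :math:`\\hat k_j` with the expected degree profile

.. math:: \\bar d_i = \\max\\{d : N \\sum_{k \\ge d} p(k) \\ge i\\},

the largest degree for which the expected number of nodes with equal or
larger degree is at least i, giving

.. math:: E[C] \\approx \\sum_{i=1}^{N} \\bar d_i \\,(N - i + 1).

This per-rank form is a reconstruction built on the per-stub accounting
above; it reproduces the known limiting exponent 3 for uniform degree
distributions without a cutoff (flagged as a reconstruction in reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ensembles import DegreeDistributionSpec, degree_pmf
from .estimation import fit_power_law
from .sequence import DegreeSequence, normalize_sequence

__all__ = [
    "ComplexityEstimate",
    "worst_case_bound",
    "expected_degree_profile",
    "expected_complexity",
    "fit_complexity_exponent",
]


@dataclass(frozen=True)
class ComplexityEstimate:
    """Step bounds / expected-cost estimates; unset fields are None."""

    worst_case: int | None = None
    nm_equivalent: int | None = None
    n_links: int | None = None
    expected_total: float | None = None
    expected_profile: np.ndarray | None = None
    fitted_exponent: float | None = None
    fit_stderr: float | None = None
    note: str = ""


def worst_case_bound(seq: DegreeSequence | Sequence[int]) -> ComplexityEstimate:
    """Sum over hub ranks j of d_j * (N - j + 1), plus the N*M equivalent.

    With the deterministic maximum-degree hub policy the j-th hub's
    residual degree is at most the j-th largest input degree, so the input
    degrees bound the hub record term by term.
    """
    s = seq if isinstance(seq, DegreeSequence) else normalize_sequence(seq)
    n = s.n
    d = s.values
    m = s.degree_sum // 2
    # Each link is placed by exactly one hub, so the hub residual degrees
    # sum to M; the j-th hub's residual is at most the j-th largest input
    # degree.  The dot product with the shrinking windows N - j + 1 is
    # maximized by loading the earliest (largest-window) ranks greedily.
    prev = np.concatenate([[0], np.cumsum(d)[:-1]])
    khat = np.clip(m - prev, 0, d)
    window = np.arange(n, 0, -1, dtype=np.int64)  # N - j + 1 for j = 1..N
    bound = int(khat @ window)
    return ComplexityEstimate(
        worst_case=bound,
        nm_equivalent=int(n * m),
        n_links=int(m),
    )


def expected_degree_profile(spec: DegreeDistributionSpec, N: int) -> np.ndarray:
    """Expected degree of the rank-i node, i = 1..N (non-increasing).

    ``profile[i-1]`` is the largest degree d with ``N * P(K >= d) >= i``;
    ranks beyond the expected node count at the minimum degree saturate at
    ``k_min``.
    """
    ks, pmf = degree_pmf(spec, N)
    # tail[j] = N * P(K >= ks[j]); non-increasing in j.
    tail = N * np.cumsum(pmf[::-1])[::-1]
    ranks = np.arange(1, N + 1, dtype=float)
    # Largest j with tail[j] >= i ==> d = ks[j]; tail reversed is non-decreasing.
    idx = np.searchsorted(tail[::-1], ranks, side="left")
    j = ks.size - 1 - idx.clip(max=ks.size - 1)
    profile = ks[j.clip(min=0)]
    # Ranks exceeding N * P(K >= k_min) = N cannot occur, but guard anyway.
    profile = np.where(idx >= ks.size, ks[0], profile)
    return profile.astype(np.int64)


def expected_complexity(spec: DegreeDistributionSpec, N: int) -> ComplexityEstimate:
    """Distribution-level estimate E[C] = sum_i dbar_i (N - i + 1)."""
    profile = expected_degree_profile(spec, N)
    window = np.arange(N, 0, -1, dtype=np.float64)
    total = float(profile.astype(np.float64) @ window)
    return ComplexityEstimate(
        expected_total=total,
        expected_profile=profile,
        note="per-rank expected-cost reconstruction",
    )


def fit_complexity_exponent(
    spec: DegreeDistributionSpec, N_list: Sequence[int]
) -> ComplexityEstimate:
    """Leading power of N of the expected-complexity estimate.

    Least squares on log E[C] vs log N; requires at least 4 sizes spanning
    at least two decades.
    """
    Ns = sorted(int(n) for n in N_list)
    if len(Ns) < 4:
        raise ValueError("need at least 4 N values")
    if Ns[-1] < 100 * Ns[0]:
        raise ValueError("N values should span at least two decades")
    totals = [expected_complexity(spec, n).expected_total for n in Ns]
    slope, err = fit_power_law(Ns, totals)
    return ComplexityEstimate(
        fitted_exponent=slope,
        fit_stderr=err,
        expected_total=totals[-1],
        note="per-rank expected-cost reconstruction",
    )
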