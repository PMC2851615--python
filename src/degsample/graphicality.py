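"""Erdos-Gallai graphicality testing via recurrences and a crossing-index table.

A non-increasing positive sequence :math:`d_1 \\ge \\dots \\ge d_n` is
graphical (realizable by a simple graph) iff its sum is even and for every
relevant :math:`k`

.. math:: L_k \\equiv \\sum_{i \\le k} d_i \\;\\le\\; k(k-1) +
          \\sum_{i > k} \\min(k, d_i) \\equiv R_k .

Both sides are computed incrementally: :math:`L_k = L_{k-1} + d_k` and

.. math:: R_k = R_{k-1} + 2(k-1) - \\min(k-1, d_k) + \\#\\{i > k : d_i \\ge k\\},

where the last (Heaviside-like indicator) term is read off a crossing-index
table: :math:`x_k` is the position of the first entry with degree below
:math:`k` (sentinel ``n + 1`` when absent), so the count equals
:math:`\\max(0, x_k - k - 1)`.  Because :math:`x_k` cannot increase with
:math:`k`, the term vanishes for all :math:`k \\ge k^*` and the recurrence
reduces to its crossing-free form.  It suffices to check the inequalities up
to the Durfee number, the largest :math:`k` with :math:`d_k \\ge k`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .sequence import DegreeSequence

__all__ = [
    "EGState",
    "GraphicalityVerdict",
    "compute_eg_tables",
    "is_graphical",
    "leftmost_adjacency_set",
]


@dataclass(frozen=True)
class EGState:
    """Erdos-Gallai tables for one non-increasing positive sequence.

    ``left_sums[k-1]`` is :math:`L_k`, ``right_sums[k-1]`` is :math:`R_k`,
    ``crossing_index[k-1]`` is :math:`x_k` (1-based position, sentinel
    ``n + 1``) and ``heaviside_counts[k-1]`` is the indicator term
    :math:`\\#\\{i > k : d_i \\ge k\\}` entering the R-recurrence, for
    :math:`k = 1 \\dots n`.
    """

    left_sums: np.ndarray
    right_sums: np.ndarray
    crossing_index: np.ndarray
    heaviside_counts: np.ndarray
    durfee: int
    kstar: int


@dataclass(frozen=True)
class GraphicalityVerdict:
    """Outcome of an Erdos-Gallai test."""

    graphical: bool
    reason: Literal["graphical", "odd_sum", "fails_at_k"]
    k: int | None = None

    def __bool__(self) -> bool:
        return self.graphical


def _as_values(seq: DegreeSequence | Iterable[int]) -> np.ndarray:
    if isinstance(seq, DegreeSequence):
        return seq.values
    d = np.asarray(list(seq), dtype=np.int64)
    if d.size and np.any(d[:-1] < d[1:]):
        raise ValueError("sequence must be non-increasing")
    if np.any(d < 1):
        raise ValueError("sequence entries must be positive")
    return d


def crossing_index_table(d: np.ndarray) -> np.ndarray:
    """Crossing indices x_k for k = 1..n, built in one histogram pass.

    ``x_k`` is the 1-based position of the first entry with degree < k,
    i.e. ``count(d >= k) + 1``; the sentinel ``n + 1`` appears when every
    entry has degree >= k.
    """
    n = d.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    # count_ge[k-1] = #{i : d_i >= k}; degrees above n behave like n here.
    hist = np.bincount(np.minimum(d, n), minlength=n + 1)
    count_ge = n - np.cumsum(hist)[:-1]  # for thresholds 1..n
    return count_ge + 1


def compute_eg_tables(seq: DegreeSequence | Iterable[int]) -> EGState:
    """Populate L/R tables incrementally via the recurrences.

    Contract: ``left_sums`` and ``right_sums`` equal the direct-summation
    definitions :math:`L_k = \\sum_{i\\le k} d_i` and
    :math:`R_k = k(k-1) + \\sum_{i>k} \\min(k, d_i)` for every k, exactly.
    """
    d = _as_values(seq)
    n = d.size
    if n == 0:
        e = np.empty(0, dtype=np.int64)
        return EGState(e, e, e, e, durfee=0, kstar=1)
    k = np.arange(1, n + 1, dtype=np.int64)
    x = crossing_index_table(d)
    hc = np.maximum(0, x - k - 1)
    left = np.cumsum(d)
    # Cumulative sum of the per-k recurrence increments.
    right = np.cumsum(2 * (k - 1) - np.minimum(k - 1, d) + hc)
    durfee = int(np.sum(d >= k))
    # x_k - k is strictly decreasing, so {k : x_k > k} is a prefix.
    kstar = int(np.sum(x > k)) + 1
    return EGState(left, right, x, hc, durfee=durfee, kstar=kstar)


def is_graphical(
    seq: DegreeSequence | Iterable[int],
    check_range: Literal["durfee", "full"] = "durfee",
) -> GraphicalityVerdict:
    """Erdos-Gallai test: even sum plus L_k <= R_k for all checked k.

    The empty sequence is graphical (vacuous conditions).  ``check_range``
    selects the checked k-range: ``"durfee"`` (default; inequalities beyond
    the Durfee number hold automatically) or ``"full"`` (k = 1..n, kept as
    an oracle variant).  On failure the smallest violating k is reported.
    """
    d = _as_values(seq)
    if d.size == 0:
        return GraphicalityVerdict(True, "graphical")
    if int(d.sum()) % 2 != 0:
        return GraphicalityVerdict(False, "odd_sum")
    eg = compute_eg_tables(d)
    kmax = eg.durfee if check_range == "durfee" else d.size
    bad = np.nonzero(eg.left_sums[:kmax] > eg.right_sums[:kmax])[0]
    if bad.size:
        return GraphicalityVerdict(False, "fails_at_k", k=int(bad[0]) + 1)
    return GraphicalityVerdict(True, "graphical")


def leftmost_adjacency_set(
    seq: DegreeSequence,
    hub: int,
    forbidden: Iterable[int],
    h: int | None = None,
) -> np.ndarray:
    """The h highest-degree nodes available to a hub with h remaining stubs.

    Returns the original labels of the first ``h`` positions of the
    non-increasing order that are neither forbidden nor the hub itself
    (ties resolved by position).  ``h`` defaults to the hub's degree in
    ``seq``.

    Raises
    ------
    ValueError
        If fewer than ``h`` candidates exist (cannot occur from a valid
        star-constrained graphical state).
    """
    forb = set(int(f) for f in forbidden)
    forb.add(int(hub))
    if h is None:
        match = seq.labels == hub
        if not match.any():
            raise ValueError(f"hub {hub} not in sequence")
        h = int(seq.values[match][0])
    if h < 1:
        raise ValueError("hub must have at least one remaining stub")
    out = [int(l) for l in seq.labels if int(l) not in forb]
    if len(out) < h:
        raise ValueError("fewer candidates than hub stubs: invalid state")
    return np.asarray(out[:h], dtype=np.int64)
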