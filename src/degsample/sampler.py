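"""Rejection-free biased sampling of simple graphs realizing a degree sequence.

The construction places all links of one "hub" node before moving to the
next.  The hub is always an active node of maximum residual degree (ties
broken by smallest original label; a deterministic policy, which is what
makes the per-graph path count exactly the product of hub-degree
factorials and hence the importance weight exact).  For each stub of the
hub the set of *allowed* targets ``A`` is built: the nodes that can be
linked to the hub such that the remaining residual sequence stays
graphical under the star constraint of the hub's forbidden set.  A target
is drawn uniformly from ``A``, so a sample's relative generation
probability is :math:`\\prod_i m_i^{-1}` up to hub-stub exchange symmetry,
and its importance weight is

.. math:: w(G) = \\frac{\\prod_i m_i}{\\prod_j \\hat k_j!} \\;\\ge\\; 1,

with :math:`m_i = |A|` at the i-th link placement and :math:`\\hat k_j`
the residual degree of the j-th hub when chosen.  Weighted averages over
samples then estimate observables uniformly over the realization ensemble.

Allowed sets are found without per-candidate graphicality tests.  Fail
degrees (degrees whose nodes would break graphicality if linked to the
hub) are downward-closed, so only the *maximum* fail-degree ``d*`` is
needed: ``A`` is every non-forbidden active node with residual degree
above ``d*``.  For a fresh maximum-degree hub there is no fail-degree
(Havel-Hakimi / Corollary of the star-constrained theorem) and ``A`` is
everything else.  Otherwise a test sequence ``D''`` is formed by
temporarily linking the hub to all but the last member of its leftmost
adjacency set, leaving the hub with one stub, and a single Erdos-Gallai
scan of ``D''`` classifies each prefix length ``k``:

* case (1), ``L_k = R_k``: linking the final stub to any non-forbidden
  node past position ``k`` breaks graphicality — its degree is a
  fail-degree candidate;
* case (2), ``L_k = R_k - 1``: only nodes past position ``k`` with degree
  at most ``k`` are candidates;
* case (3), ``L_k <= R_k - 2``: no candidate at this ``k``.

The scan runs over ``k`` up to the Durfee number of ``D''`` and may stop
early at the first case (1); an exhaustive variant over every ``k`` is
kept for oracle tests.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterator, Literal, Sequence

import numpy as np

from .graphicality import is_graphical
from .sequence import DegreeSequence, normalize_sequence

__all__ = [
    "AllowedSet",
    "AllowedSetEvent",
    "GraphSample",
    "SamplerRun",
    "TestSequence",
    "exact_weight",
    "max_fail_degree",
    "sample_graph",
    "sample_graphs",
    "derive_sample_seed",
]


@dataclass(frozen=True)
class TestSequence:
    """The sequence ``D''`` scanned for fail-degrees.

    ``entries`` holds ``(label, residual_degree, marked)`` triples in the
    scan convention: non-increasing by degree, marked (forbidden) entries
    before unmarked ones of equal degree, and the hub — reduced to residual
    degree 1 by the temporary links — last.  ``temp_linked`` lists the
    members of the hub's leftmost adjacency set that were temporarily
    connected (all but its last, lowest-degree member).
    """

    __test__ = False  # not a pytest class, despite the Test* name

    entries: tuple[tuple[int, int, bool], ...]
    temp_linked: tuple[int, ...]
    hub: int

    @property
    def degrees(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries], dtype=np.int64)

    @property
    def unmarked_mask(self) -> np.ndarray:
        return np.array([not e[2] for e in self.entries], dtype=bool)


@dataclass(frozen=True)
class AllowedSet:
    """Targets the hub may link to without destroying graphicality."""

    members: np.ndarray  # original labels
    size: int
    fail_degree: int | None
    fresh: bool


@dataclass(frozen=True)
class AllowedSetEvent:
    """Snapshot passed to the ``on_allowed`` hook at each link placement."""

    hub: int
    hub_residual: int
    residual: dict[int, int]
    forbidden: frozenset[int]
    allowed: AllowedSet


@dataclass(frozen=True)
class GraphSample:
    """One realization with its exact importance weight.

    ``log_weight`` is :math:`\\ln w = \\sum_i \\ln m_i - \\sum_j \\ln \\hat
    k_j!`, accumulated in the log domain; :meth:`exact_log_weight` evaluates
    the same quantity from the integer records.
    """

    edges: tuple[tuple[int, int], ...]
    log_weight: float
    m_record: tuple[int, ...]
    hub_record: tuple[int, ...]
    seed: int | None = None
    steps: int = 0

    def exact_weight(self) -> Fraction:
        return exact_weight(self.m_record, self.hub_record)

    def exact_log_weight(self) -> float:
        w = self.exact_weight()
        return math.log(w.numerator) - math.log(w.denominator)

    def degrees(self) -> dict[int, int]:
        deg: dict[int, int] = {}
        for u, v in self.edges:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
        return deg


def exact_weight(m_record: Sequence[int], hub_record: Sequence[int]) -> Fraction:
    """w = (prod of allowed-set sizes) / (prod of hub residual factorials)."""
    num = 1
    for m in m_record:
        num *= int(m)
    den = 1
    for k in hub_record:
        den *= math.factorial(int(k))
    return Fraction(num, den)


def _scan_fail_degree(
    degs: np.ndarray,
    marked_starts: np.ndarray,
    marked_ends: np.ndarray,
    scan: Literal["bounded", "full"] = "bounded",
) -> int | None:
    """Maximum fail-degree of a test sequence.

    ``degs`` must be non-increasing and include the hub's final entry of
    degree 1.  Forbidden entries (and the hub) occupy the position runs
    ``[marked_starts[i], marked_ends[i])``, sorted and disjoint — the
    marked-before-unmarked tie convention makes each run a block prefix.
    Only prefix-length (Durfee-bounded) arrays are touched in the default
    scan, so a call costs O(n) for the histogram plus O(durfee) for the
    scan itself.
    """
    sz = int(degs.size)
    if sz == 0:
        return None
    d1 = int(degs[0])
    kupper = min(sz, d1)
    durfee = int(np.sum(degs[:kupper] >= np.arange(1, kupper + 1)))
    kmax = durfee if scan == "bounded" else sz
    if kmax == 0:
        return None
    pref = degs[:kmax]
    kk = np.arange(1, kmax + 1, dtype=np.int64)
    left = np.cumsum(pref)
    # Crossing positions x_t = count(deg >= t) + 1 for thresholds 1..kmax+1.
    hist = np.bincount(np.minimum(degs, kmax + 1), minlength=kmax + 2)
    x = sz - np.cumsum(hist)[: kmax + 1] + 1
    hc = np.maximum(0, x[:kmax] - kk - 1)
    right = np.cumsum(2 * (kk - 1) - np.minimum(kk - 1, pref) + hc)
    diff = right - left
    if np.any(diff < 0):
        bad = int(np.nonzero(diff < 0)[0][0]) + 1
        raise RuntimeError(
            f"test sequence is not graphical (L_{bad} > R_{bad}): invalid state"
        )

    def next_unmarked(q: int) -> int:
        i = bisect_right(marked_starts, q) - 1
        if i >= 0 and q < marked_ends[i]:
            q = int(marked_ends[i])
        i += 1
        while i < marked_starts.size and marked_starts[i] <= q:
            if q < marked_ends[i]:
                q = int(marked_ends[i])
            i += 1
        return q

    if scan == "bounded" and kmax <= 32:
        # scalar scan: cheaper than array machinery at small Durfee numbers
        dl = diff.tolist()
        xl = x.tolist()
        best = -1
        for k in range(1, kmax + 1):
            dk = dl[k - 1]
            if dk == 0:
                q = next_unmarked(k)
                if q < sz:
                    best = max(best, int(degs[q]))
                break
            if dk == 1:
                q = next_unmarked(max(k, xl[k] - 1))
                if q < sz:
                    best = max(best, int(degs[q]))
        return best if best >= 0 else None

    case1 = diff == 0
    case2 = diff == 1
    if scan == "bounded" and case1.any():
        stop = int(np.argmax(case1)) + 1  # first case (1), kept inclusive
        kk, case1, case2 = kk[:stop], case1[:stop], case2[:stop]
    # Query position per k: case (1) looks at any entry past position k;
    # case (2) only at entries past k with degree <= k, which start at the
    # crossing position of threshold k+1.
    p = np.where(case1, kk, np.maximum(kk, x[kk] - 1))
    p[~(case1 | case2)] = sz
    if marked_starts.size:
        # hop over marked runs to the first non-forbidden entry
        idx = np.searchsorted(marked_starts, p, side="right") - 1
        inside = (idx >= 0) & (p < marked_ends[np.maximum(idx, 0)])
        for j in np.nonzero(inside)[0]:
            p[j] = next_unmarked(int(p[j]))
    cand = np.where(p < sz, degs[np.minimum(p, sz - 1)], -1)
    best = int(cand.max()) if cand.size else -1
    return best if best >= 0 else None


def max_fail_degree(
    T: TestSequence, scan: Literal["bounded", "full"] = "bounded"
) -> int | None:
    """Maximum fail-degree of a :class:`TestSequence`, or ``None``.

    ``scan="bounded"`` stops at the Durfee number of ``D''`` and at the
    first case (1); ``scan="full"`` examines every ``k`` (oracle variant).
    """
    marked = np.nonzero(~T.unmarked_mask)[0]
    # collapse consecutive marked positions into runs
    if marked.size:
        brk = np.nonzero(np.diff(marked) > 1)[0]
        starts = marked[np.concatenate([[0], brk + 1])]
        ends = np.concatenate([marked[brk], [marked[-1]]]) + 1
    else:
        starts = ends = np.empty(0, dtype=np.int64)
    return _scan_fail_degree(T.degrees, starts, ends, scan=scan)


class SamplerRun:
    """Mutable state of one sample construction.

    Residual degrees are kept sorted (ascending internally) and updated by
    O(1) block swaps per decrement.  The run can be driven automatically
    (:meth:`run`), stepped one link at a time (:meth:`advance`), or driven
    manually through :meth:`allowed_set` / :meth:`place_link` — the latter
    is how the exact decision-tree enumeration forks it.
    """

    def __init__(self, seq: DegreeSequence, *, scan: Literal["bounded", "full"] = "bounded"):
        n = seq.n
        self._seq = seq
        self._scan: Literal["bounded", "full"] = scan
        order = np.argsort(seq.values, kind="stable")  # ascending degrees
        self._deg = seq.values[order].copy()
        self._node = order.astype(np.int64)  # internal ids = sorted positions of seq
        self._pos = np.empty(n, dtype=np.int64)
        self._pos[self._node] = np.arange(n)
        self._a0 = 0  # first active position; zeros live in [0, a0)
        self._hub = -1  # internal id of current hub, -1 between phases
        self._epoch = 0
        self._forb_epoch = np.zeros(n, dtype=np.int64)
        self._forb: list[int] = []  # forbidden ids this phase, hub excluded
        self._fresh = True
        self._edges: list[tuple[int, int]] = []
        self.m_record: list[int] = []
        self.hub_record: list[int] = []
        self.steps = 0
        self._version = 0
        self._cache: tuple[int, tuple] | None = None

    # ---------------------------------------------------------------- state

    @property
    def complete(self) -> bool:
        return self._a0 == self._deg.size

    @property
    def n_active(self) -> int:
        return int(self._deg.size - self._a0)

    @property
    def current_hub(self) -> int | None:
        """Original label of the current hub (starting a phase if needed)."""
        if self.complete:
            return None
        self._ensure_hub()
        return int(self._seq.labels[self._hub])

    def residual(self) -> dict[int, int]:
        """Original label -> residual degree, active nodes only."""
        lab = self._seq.labels
        return {
            int(lab[self._node[p]]): int(self._deg[p])
            for p in range(self._a0, self._deg.size)
        }

    def forbidden_labels(self) -> frozenset[int]:
        """Labels barred from the current hub (hub included)."""
        if self._hub < 0:
            return frozenset()
        lab = self._seq.labels
        out = {int(lab[self._hub])}
        out.update(int(lab[f]) for f in self._forb)
        return frozenset(out)

    def edges(self) -> tuple[tuple[int, int], ...]:
        lab = self._seq.labels
        es = [tuple(sorted((int(lab[u]), int(lab[v])))) for u, v in self._edges]
        return tuple(sorted(es))

    def copy(self) -> "SamplerRun":
        """Independent fork (used by the decision-tree enumerator)."""
        new = object.__new__(SamplerRun)
        new._seq = self._seq
        new._scan = self._scan
        new._deg = self._deg.copy()
        new._node = self._node.copy()
        new._pos = self._pos.copy()
        new._a0 = self._a0
        new._hub = self._hub
        new._epoch = self._epoch
        new._forb_epoch = self._forb_epoch.copy()
        new._forb = list(self._forb)
        new._fresh = self._fresh
        new._edges = list(self._edges)
        new.m_record = list(self.m_record)
        new.hub_record = list(self.hub_record)
        new.steps = self.steps
        new._version = self._version
        new._cache = self._cache
        return new

    # ------------------------------------------------------------ internals

    def _decrement(self, i: int) -> None:
        p = self._pos[i]
        v = self._deg[p]
        lo = int(np.searchsorted(self._deg, v, side="left"))
        j = self._node[lo]
        self._deg[lo], self._deg[p] = self._deg[p], self._deg[lo]
        self._node[lo], self._node[p] = i, j
        self._pos[i], self._pos[j] = lo, p
        self._deg[lo] = v - 1
        if v == 1:
            self._a0 += 1

    def _ensure_hub(self) -> None:
        if self._hub >= 0 or self.complete:
            return
        vmax = int(self._deg[-1])
        lo = int(np.searchsorted(self._deg, vmax, side="left"))
        block = self._node[lo:]
        labels = self._seq.labels[block]
        self._hub = int(block[np.argmin(labels)])
        self._epoch += 1
        self._forb_epoch[self._hub] = self._epoch
        self._forb = []
        self._fresh = True
        self.hub_record.append(vmax)
        self._version += 1

    def _leftmost_ids(self, h: int) -> np.ndarray:
        """Internal ids of the hub's leftmost adjacency set (size h)."""
        take = min(self.n_active, h + len(self._forb) + 1)
        cand = self._node[self._deg.size - take :][::-1]
        keep = self._forb_epoch[cand] != self._epoch  # excludes hub too
        out = cand[keep][:h]
        if out.size < h:
            raise RuntimeError("leftmost adjacency set smaller than hub stubs")
        return out

    def _threshold(self) -> tuple[int | None, int, int, list[int], bool]:
        """(fail_degree, min allowed residual t, m, excluded positions, fresh)."""
        if self._cache is not None and self._cache[0] == self._version:
            return self._cache[1]
        self._ensure_hub()
        hub = self._hub
        h = int(self._deg[self._pos[hub]])
        if h < 1:
            raise RuntimeError("hub has no remaining stubs")
        fresh = self._fresh
        if fresh:
            dstar: int | None = None
        else:
            dstar = self._scan_state(h)
        t = 1 if dstar is None else dstar + 1
        c0 = int(np.searchsorted(self._deg, t, side="left"))
        barred = np.asarray(self._forb + [hub], dtype=np.int64)
        excluded = np.sort(self._pos[barred][self._pos[barred] >= c0])
        m = int(self._deg.size - c0 - excluded.size)
        if m < 1:
            raise RuntimeError("empty allowed set: invalid sampler state")
        result = (dstar, t, m, excluded, fresh)
        self._cache = (self._version, result)
        return result

    def _scan_state(self, h: int) -> int | None:
        """Fail-degree scan of D'' built in histogram form (no re-sort)."""
        lm = self._leftmost_ids(h)
        dmax = int(self._deg[-1])
        counts = np.bincount(self._deg[self._a0 :], minlength=dmax + 2)
        counts[self._deg[self._pos[self._hub]]] -= 1  # hub re-enters at degree 1
        counts[1] += 1
        marked = np.zeros(dmax + 2, dtype=np.int64)
        temp = lm[: h - 1]  # temporary links: all but the last member
        if temp.size:
            w = self._deg[self._pos[temp]]
            np.subtract.at(counts, w, 1)
            np.add.at(counts, w - 1, 1)
            np.add.at(marked, w - 1, 1)
            marked[0] = 0  # exhausted temp-linked nodes drop out of D''
        if self._forb:
            np.add.at(marked, self._deg[self._pos[np.asarray(self._forb)]], 1)
        counts = counts[: dmax + 1]
        marked = marked[: dmax + 1]
        sz = int(counts[1:].sum())
        degs = np.repeat(np.arange(dmax, 0, -1, dtype=np.int64), counts[dmax:0:-1])
        # Marked entries sit at the start of their degree block; block start
        # is the number of entries with a strictly larger degree.
        cge = np.cumsum(counts[:0:-1])  # cge[j] = #{deg >= dmax - j}
        nz = np.nonzero(marked[1:])[0] + 1  # degrees with marked entries, asc
        starts = np.where(nz < dmax, cge[np.minimum(dmax - nz - 1, dmax - 1)], 0)[::-1]
        ends = starts + marked[nz][::-1]
        # append the hub, last entry of the degree-1 block
        starts = np.concatenate([starts, [sz - 1]])
        ends = np.concatenate([ends, [sz]])
        return _scan_fail_degree(degs, starts, ends, scan=self._scan)

    # ------------------------------------------------------------ operations

    def build_test_sequence(self) -> TestSequence:
        """Explicit ``D''`` for the current state (inspection/tests).

        Entries are ordered non-increasing by degree, marked before
        unmarked among equal degrees (then by original label), hub last at
        residual degree 1.
        """
        self._ensure_hub()
        hub = self._hub
        h = int(self._deg[self._pos[hub]])
        lm = self._leftmost_ids(h)
        temp = lm[: h - 1]
        lab = self._seq.labels
        rows: list[tuple[int, int, bool]] = []
        for p in range(self._a0, self._deg.size):
            i = int(self._node[p])
            if i == hub:
                continue
            d = int(self._deg[p])
            markedf = self._forb_epoch[i] == self._epoch
            if i in temp:
                d -= 1
                markedf = True
            if d >= 1:
                rows.append((int(lab[i]), d, bool(markedf)))
        rows.sort(key=lambda r: (-r[1], not r[2], r[0]))
        rows.append((int(lab[hub]), 1, True))
        return TestSequence(
            entries=tuple(rows),
            temp_linked=tuple(int(lab[i]) for i in temp),
            hub=int(lab[hub]),
        )

    def allowed_set(self) -> AllowedSet:
        """Materialize the allowed set for the current state."""
        dstar, t, m, excluded, fresh = self._threshold()
        c0 = int(np.searchsorted(self._deg, t, side="left"))
        keep = np.ones(self._deg.size - c0, dtype=bool)
        if excluded.size:
            keep[excluded - c0] = False
        members = self._seq.labels[self._node[c0:][keep]]
        return AllowedSet(
            members=np.sort(members), size=m, fail_degree=dstar, fresh=fresh
        )

    def place_link(self, target_label: int) -> None:
        """Link the hub to ``target_label`` (must be in the allowed set)."""
        dstar, t, m, excluded, fresh = self._threshold()
        match = np.nonzero(self._seq.labels == target_label)[0]
        if match.size != 1:
            raise ValueError(f"unknown node label {target_label}")
        i = int(match[0])  # internal id = position in the sorted input order
        p = int(self._pos[i])
        c0 = int(np.searchsorted(self._deg, t, side="left"))
        if p < c0 or p in excluded:
            raise ValueError(f"node {target_label} is not in the allowed set")
        self._place(i, m)

    def _place(self, i: int, m: int) -> None:
        self.steps += self.n_active
        self.m_record.append(m)
        self._edges.append((self._hub, i))
        hub = self._hub
        self._decrement(hub)
        self._decrement(i)
        if self._deg[self._pos[i]] >= 1:
            self._forb_epoch[i] = self._epoch
            self._forb.append(i)
        if self._deg[self._pos[hub]] == 0:
            self._hub = -1
        self._fresh = False
        self._version += 1

    def advance(
        self, rng: np.random.Generator, on_allowed: Callable[[AllowedSetEvent], None] | None = None
    ) -> None:
        """Place one link, drawing the target uniformly from the allowed set."""
        dstar, t, m, excluded, fresh = self._threshold()
        if on_allowed is not None:
            event = AllowedSetEvent(
                hub=int(self._seq.labels[self._hub]),
                hub_residual=int(self._deg[self._pos[self._hub]]),
                residual=self.residual(),
                forbidden=self.forbidden_labels(),
                allowed=self.allowed_set(),
            )
            on_allowed(event)
        c0 = int(np.searchsorted(self._deg, t, side="left"))
        r = int(rng.integers(m))
        # r-th allowed position in [c0, n) skipping excluded positions:
        # iterate p -> c0 + r + #{excluded <= p} to its fixed point.
        p = c0 + r
        while True:
            q = c0 + r + int(np.searchsorted(excluded, p, side="right"))
            if q == p:
                break
            p = q
        self._place(int(self._node[p]), m)

    def run(
        self,
        rng: np.random.Generator,
        on_allowed: Callable[[AllowedSetEvent], None] | None = None,
        seed: int | None = None,
    ) -> GraphSample:
        """Drive the construction to completion and package the sample."""
        while not self.complete:
            self.advance(rng, on_allowed=on_allowed)
        logw = float(
            sum(math.log(m) for m in self.m_record)
            - sum(math.lgamma(k + 1) for k in self.hub_record)
        )
        return GraphSample(
            edges=self.edges(),
            log_weight=logw,
            m_record=tuple(self.m_record),
            hub_record=tuple(self.hub_record),
            seed=seed,
            steps=self.steps,
        )


def _check_graphical(seq: DegreeSequence) -> None:
    verdict = is_graphical(seq)
    if not verdict:
        if verdict.reason == "odd_sum":
            raise ValueError("degree sequence is not graphical: odd degree sum")
        raise ValueError(
            f"degree sequence is not graphical: L_k > R_k at k = {verdict.k}"
        )


def sample_graph(
    seq: DegreeSequence | Sequence[int],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    on_allowed: Callable[[AllowedSetEvent], None] | None = None,
    check: bool = True,
) -> GraphSample:
    """Draw one realization of ``seq`` with its exact importance weight.

    The construction never rejects or backtracks; a non-graphical input is
    refused up front with the failing Erdos-Gallai index (or odd parity).
    """
    if not isinstance(seq, DegreeSequence):
        seq = normalize_sequence(seq)
    if check:
        _check_graphical(seq)
    if rng is None:
        rng = np.random.default_rng(seed)
    return SamplerRun(seq).run(rng, on_allowed=on_allowed, seed=seed)


def derive_sample_seed(master_seed: int, index: int) -> int:
    """Deterministic per-sample sub-seed from (master seed, sample index)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2**31))


def sample_graphs(
    seq: DegreeSequence | Sequence[int],
    n_samples: int,
    master_seed: int,
    check: bool = True,
) -> Iterator[GraphSample]:
    """Independent samples, one fresh sub-seed per sample."""
    if not isinstance(seq, DegreeSequence):
        seq = normalize_sequence(seq)
    if check:
        _check_graphical(seq)
    for i in range(n_samples):
        sub = derive_sample_seed(master_seed, i)
        rng = np.random.default_rng(sub)
        yield SamplerRun(seq).run(rng, seed=sub)
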