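"""Brute-force oracles and the configuration-model baseline.

Everything here exists to make the sampler's correctness claims
exhaustively checkable on small instances: enumeration of all labeled
realizations of a sequence, a graphicality existence check that never
touches the Erdos-Gallai inequalities, a naive per-candidate allowed-set
construction that tests each target explicitly, an exact (rational
arithmetic) expansion of the sampler's full decision tree, and the classic
stub-matching configuration model with full restart on any self-loop or
duplicate edge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .graphicality import is_graphical
from .sequence import DegreeSequence, normalize_sequence

__all__ = [
    "RealizationSet",
    "PathEnumeration",
    "PathGroup",
    "CMResult",
    "enumerate_realizations",
    "brute_force_graphical",
    "enumerate_decision_paths",
    "naive_allowed_set",
    "paths_to_json",
    "realizations_to_json",
    "naive_max_fail_degree",
    "star_constrained_graphical",
    "configuration_model",
]

Edge = tuple[int, int]
Graph = tuple[Edge, ...]

_ENUM_GUARD = 10
_PATH_GUARD_N = 6
_PATH_GUARD_D = 5


def _as_seq(seq: DegreeSequence | Sequence[int]) -> DegreeSequence:
    return seq if isinstance(seq, DegreeSequence) else normalize_sequence(seq)


def canonical_graph(edges: Iterable[Edge]) -> Graph:
    return tuple(sorted(tuple(sorted(e)) for e in edges))


# --------------------------------------------------------------- realization


@dataclass(frozen=True)
class RealizationSet:
    """All labeled simple graphs realizing a sequence."""

    graphs: frozenset[Graph]

    @property
    def count(self) -> int:
        return len(self.graphs)


def enumerate_realizations(seq: DegreeSequence | Sequence[int]) -> RealizationSet:
    """Exhaustive search for every labeled simple realization (n <= 10).

    Nodes are completed one at a time in label order; each neighborhood
    choice leads to a distinct graph, so every realization is produced
    exactly once.  Pruning is purely counting-based (parity, enough
    partners), independent of any graphicality theory.
    """
    s = _as_seq(seq)
    if s.n > _ENUM_GUARD:
        raise ValueError(f"enumeration limited to n <= {_ENUM_GUARD} nodes")
    items = sorted(zip(s.labels.tolist(), s.values.tolist()))
    out: set[Graph] = set()

    def rec(res: list[tuple[int, int]], acc: list[Edge]) -> None:
        res = [(l, d) for l, d in res if d > 0]
        if not res:
            out.add(canonical_graph(acc))
            return
        if sum(d for _, d in res) % 2 != 0:
            return
        (lab, d), rest = res[0], res[1:]
        if d > len(rest):
            return
        for combo in itertools.combinations(range(len(rest)), d):
            nxt = list(rest)
            for j in combo:
                nxt[j] = (nxt[j][0], nxt[j][1] - 1)
            if any(v < 0 for _, v in nxt):
                continue
            rec(nxt, acc + [(lab, nxt[j][0]) for j in combo])

    rec(items, [])
    return RealizationSet(graphs=frozenset(out))


@lru_cache(maxsize=None)
def _exists(res: tuple[int, ...]) -> bool:
    if not res:
        return True
    if sum(res) % 2 != 0:
        return False
    d, rest = res[0], list(res[1:])
    if d > len(rest):
        return False
    for combo in itertools.combinations(range(len(rest)), d):
        nxt = list(rest)
        ok = True
        for j in combo:
            nxt[j] -= 1
            if nxt[j] < 0:
                ok = False
                break
        if not ok:
            continue
        if _exists(tuple(sorted((v for v in nxt if v > 0), reverse=True))):
            return True
    return False


def brute_force_graphical(degrees: Sequence[int]) -> bool:
    """Existence of a simple realization by exhaustive partner search.

    Memoized on the residual degree multiset; makes no use of the
    Erdos-Gallai criterion, so it serves as its independent oracle.
    """
    d = tuple(sorted((int(v) for v in degrees if int(v) > 0), reverse=True))
    return _exists(d)


# -------------------------------------------------- naive allowed-set oracle


def star_constrained_graphical(
    residual: dict[int, int], hub: int, forbidden: set[int]
) -> bool:
    """Can the residual sequence be completed, no hub links into ``forbidden``?

    Star-constrained graphicality test: connect the hub's remaining stubs
    to its full leftmost adjacency set, then apply the plain Erdos-Gallai
    test to what is left.
    """
    res = {l: d for l, d in residual.items() if d > 0}
    h = res.get(hub, 0)
    if h == 0:
        return bool(is_graphical(sorted(res.values(), reverse=True)))
    cands = sorted(
        (l for l in res if l != hub and l not in forbidden),
        key=lambda l: (-res[l], l),
    )
    if len(cands) < h:
        return False
    for l in cands[:h]:
        res[l] -= 1
    res[hub] = 0
    remaining = sorted((d for d in res.values() if d > 0), reverse=True)
    return bool(is_graphical(remaining))


def naive_allowed_set(
    residual: dict[int, int], hub: int, forbidden: set[int]
) -> list[int]:
    """Allowed targets found by testing every candidate explicitly."""
    out = []
    for v in residual:
        if v == hub or v in forbidden or residual[v] < 1:
            continue
        res2 = dict(residual)
        res2[hub] -= 1
        res2[v] -= 1
        forb2 = set(forbidden) | {v, hub}
        if star_constrained_graphical(res2, hub, forb2):
            out.append(v)
    return sorted(out)


def naive_max_fail_degree(
    residual: dict[int, int], hub: int, forbidden: set[int]
) -> int | None:
    """Maximum degree among explicitly-tested disallowed candidates."""
    allowed = set(naive_allowed_set(residual, hub, forbidden))
    fails = [
        d
        for v, d in residual.items()
        if v != hub and v not in forbidden and d >= 1 and v not in allowed
    ]
    return max(fails) if fails else None


# ------------------------------------------------------ decision-tree oracle


@dataclass
class PathGroup:
    """Aggregate over all sampler paths producing one graph."""

    path_count: int = 0
    total_probability: Fraction = Fraction(0)
    weighted_probability: Fraction = Fraction(0)  # sum over paths of prob * w
    weights: set[Fraction] = field(default_factory=set)
    hub_records: set[tuple[int, ...]] = field(default_factory=set)


@dataclass(frozen=True)
class PathEnumeration:
    """Exact expansion of every random choice the sampler can make."""

    per_graph: dict[Graph, PathGroup]
    total_probability: Fraction

    @property
    def reachable(self) -> frozenset[Graph]:
        return frozenset(self.per_graph)


def enumerate_decision_paths(seq: DegreeSequence | Sequence[int]) -> PathEnumeration:
    """Depth-first expansion of the sampler's decision tree (n <= 6, d1 <= 5).

    Re-implements the construction independently in exact rational
    arithmetic: deterministic hub policy (maximum residual degree, smallest
    label), allowed sets built by the naive per-candidate test, uniform
    choice over each allowed set.  Path probability is the product of
    1/m over the path's link placements; the weight is the product of m
    divided by the product of hub residual-degree factorials.
    """
    import math

    s = _as_seq(seq)
    if s.n > _PATH_GUARD_N or (s.n and int(s.values[0]) > _PATH_GUARD_D):
        raise ValueError(
            f"decision-path enumeration limited to n <= {_PATH_GUARD_N}, "
            f"d1 <= {_PATH_GUARD_D}"
        )
    verdict = is_graphical(s)
    if not verdict:
        raise ValueError(f"sequence is not graphical ({verdict.reason})")

    per_graph: dict[Graph, PathGroup] = {}
    total = Fraction(0)

    def walk(
        residual: dict[int, int],
        hub: int | None,
        forbidden: set[int],
        fresh: bool,
        edges: list[Edge],
        ms: list[int],
        hubs: list[int],
        prob: Fraction,
    ) -> None:
        nonlocal total
        active = {l: d for l, d in residual.items() if d > 0}
        if not active:
            g = canonical_graph(edges)
            grp = per_graph.setdefault(g, PathGroup())
            grp.path_count += 1
            grp.total_probability += prob
            num = 1
            for m in ms:
                num *= m
            den = 1
            for k in hubs:
                den *= math.factorial(k)
            w = Fraction(num, den)
            grp.weights.add(w)
            grp.weighted_probability += prob * w
            grp.hub_records.add(tuple(hubs))
            total += prob
            return
        if hub is None or active.get(hub, 0) == 0:
            dmax = max(active.values())
            hub = min(l for l, d in active.items() if d == dmax)
            forbidden = {hub}
            fresh = True
            hubs = hubs + [dmax]
        if fresh:
            allowed = sorted(l for l in active if l != hub)
        else:
            allowed = naive_allowed_set(residual, hub, forbidden)
        m = len(allowed)
        assert m >= 1, "empty allowed set in oracle expansion"
        for v in allowed:
            res2 = dict(residual)
            res2[hub] -= 1
            res2[v] -= 1
            forb2 = set(forbidden)
            if res2[v] > 0:
                forb2.add(v)
            walk(
                res2,
                hub,
                forb2,
                False,
                edges + [(hub, v)],
                ms + [m],
                hubs,
                prob * Fraction(1, m),
            )

    walk(dict(zip(s.labels.tolist(), s.values.tolist())), None, set(), True, [], [], [], Fraction(1))
    return PathEnumeration(per_graph=per_graph, total_probability=total)


def realizations_to_json(rs: RealizationSet) -> dict:
    """JSON-able form of a realization set (edge lists on original labels)."""
    return {
        "count": rs.count,
        "graphs": [[list(e) for e in g] for g in sorted(rs.graphs)],
    }


def paths_to_json(pe: PathEnumeration) -> dict:
    """JSON-able decision-tree summary; rationals as "num/den" strings."""

    def frac(f: Fraction) -> str:
        return f"{f.numerator}/{f.denominator}"

    return {
        "total_probability": frac(pe.total_probability),
        "graphs": [
            {
                "edges": [list(e) for e in g],
                "path_count": grp.path_count,
                "total_probability": frac(grp.total_probability),
                "weighted_probability": frac(grp.weighted_probability),
                "weights": sorted(frac(w) for w in grp.weights),
            }
            for g, grp in sorted(pe.per_graph.items())
        ],
    }


# ------------------------------------------------------- configuration model


@dataclass(frozen=True)
class CMResult:
    """Outcome of stub-matching with full restart on collisions."""

    graph: Graph | None
    attempts: int
    succeeded: bool


def configuration_model(
    seq: DegreeSequence | Sequence[int],
    seed: int | None = None,
    max_attempts: int = 10**5,
    rng: np.random.Generator | None = None,
) -> CMResult:
    """Uniform stub pairing; restart from scratch on any self-loop or
    duplicate edge; stop at the first simple graph or after ``max_attempts``.
    """
    s = _as_seq(seq)
    if s.degree_sum % 2 != 0:
        raise ValueError("configuration model requires an even degree sum")
    if rng is None:
        rng = np.random.default_rng(seed)
    stubs = np.repeat(s.labels, s.values)
    n_lab = int(s.labels.max()) + 1 if s.n else 0
    for attempt in range(1, max_attempts + 1):
        perm = rng.permutation(stubs)
        u, v = perm[0::2], perm[1::2]
        if np.any(u == v):
            continue
        lo, hi = np.minimum(u, v), np.maximum(u, v)
        codes = lo * n_lab + hi
        if np.unique(codes).size != codes.size:
            continue
        edges = canonical_graph(zip(lo.tolist(), hi.tolist()))
        return CMResult(graph=edges, attempts=attempt, succeeded=True)
    return CMResult(graph=None, attempts=max_attempts, succeeded=False)
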