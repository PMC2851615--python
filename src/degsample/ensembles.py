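"""Random graphical degree sequences from standard distribution families.

Supported families: power law :math:`p(k) \\propto k^{-\\gamma}` on
``[k_min, k_max]`` (``gamma = 0`` is the uniform distribution), the
binomial degree distribution of Erdos-Renyi graphs ``Binomial(N-1, p)``
truncated below ``k_min``, and the uniform distribution with a cap.  The
``structural`` cutoff policy caps degrees at :math:`\\sqrt{\\langle k
\\rangle N}`, the standard structural cutoff that suppresses degree
correlations in heavy-tailed ensembles.

Sequences are drawn i.i.d. from the pmf; a draw whose sum is odd or which
fails the Erdos-Gallai test is redrawn wholesale (preserving the i.i.d.
structure conditional on acceptance), with both rejection kinds counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .graphicality import is_graphical
from .sequence import DegreeSequence, normalize_sequence

__all__ = [
    "DegreeDistributionSpec",
    "DrawDiagnostics",
    "degree_pmf",
    "draw_graphical_sequence",
    "structural_cutoff",
]

_REDRAW_CAP = 10**6

Family = Literal["power_law", "binomial", "uniform"]


@dataclass(frozen=True)
class DegreeDistributionSpec:
    """Degree-distribution family with support and cutoff policy.

    ``k_max=None`` means the nominal maximum ``N - 1`` (before any cutoff
    policy).  ``cutoff_policy="structural"`` re-caps the support at
    ``floor(sqrt(<k> N))``, where ``<k>`` is the mean of the pmf truncated
    at ``N - 1`` (one iteration; an approximation, documented as such).
    """

    family: Family
    gamma: float | None = None
    connect_prob: float | None = None
    k_min: int = 1
    k_max: int | None = None
    cutoff_policy: Literal["none", "structural", "fixed"] = "none"

    def __post_init__(self) -> None:
        if self.family not in ("power_law", "binomial", "uniform"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "power_law":
            if self.gamma is None or self.gamma < 0:
                raise ValueError("power_law requires gamma >= 0")
        if self.family == "binomial":
            p = self.connect_prob
            if p is None or not (0 <= p <= 1):
                raise ValueError("binomial requires 0 <= connect_prob <= 1")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1 (zero degrees are never drawn)")
        if self.cutoff_policy == "fixed" and self.k_max is None:
            raise ValueError("fixed cutoff policy requires k_max")


@dataclass(frozen=True)
class DrawDiagnostics:
    parity_fixes: int
    graphicality_rejections: int


def structural_cutoff(N: int, mean_degree: float, k_min: int = 1) -> int:
    """floor(sqrt(<k> N)), clamped into [k_min, N - 1]."""
    if N < 2:
        raise ValueError("need N >= 2")
    if mean_degree <= 0:
        raise ValueError("mean degree must be positive")
    k = int(math.floor(math.sqrt(mean_degree * N)))
    return max(k_min, min(k, N - 1))


def _support_and_pmf(spec: DegreeDistributionSpec, N: int, k_max: int) -> tuple[np.ndarray, np.ndarray]:
    ks = np.arange(spec.k_min, k_max + 1, dtype=np.int64)
    if ks.size == 0:
        raise ValueError("empty degree support")
    if spec.family == "power_law":
        pmf = ks.astype(float) ** (-float(spec.gamma))
    elif spec.family == "uniform":
        pmf = np.ones(ks.size)
    else:  # binomial
        pmf = stats.binom.pmf(ks, N - 1, spec.connect_prob)
        if pmf.sum() <= 0:
            raise ValueError("binomial pmf vanishes on the requested support")
    return ks, pmf / pmf.sum()


def _resolve_k_max(spec: DegreeDistributionSpec, N: int) -> int:
    nominal = N - 1 if spec.k_max is None else min(spec.k_max, N - 1)
    if spec.cutoff_policy in ("none", "fixed"):
        k_max = nominal
    else:  # structural: <k> of the pmf truncated at N-1, then cap
        ks, pmf = _support_and_pmf(spec, N, N - 1 if spec.k_max is None else nominal)
        mean_k = float(ks @ pmf)
        k_max = min(nominal, structural_cutoff(N, mean_k, spec.k_min))
    if k_max < spec.k_min:
        raise ValueError("empty degree support after cutoff")
    return k_max


def degree_pmf(spec: DegreeDistributionSpec, N: int) -> tuple[np.ndarray, np.ndarray]:
    """(support, probabilities) of the degree distribution for N nodes."""
    if N < 2:
        raise ValueError("need N >= 2")
    k_max = _resolve_k_max(spec, N)
    return _support_and_pmf(spec, N, k_max)


def draw_graphical_sequence(
    spec: DegreeDistributionSpec,
    N: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DegreeSequence, DrawDiagnostics]:
    """N i.i.d. degrees, redrawn until the sequence is graphical.

    A sequence with odd sum counts as a parity fix; an even-sum sequence
    failing the Erdos-Gallai test counts as a graphicality rejection.  In
    both cases the entire sequence is redrawn.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ks, pmf = degree_pmf(spec, N)
    parity = 0
    rejects = 0
    for _ in range(_REDRAW_CAP):
        draw = rng.choice(ks, size=N, p=pmf)
        if int(draw.sum()) % 2 != 0:
            parity += 1
            continue
        seq = normalize_sequence(draw)
        if is_graphical(seq):
            return seq, DrawDiagnostics(parity, rejects)
        rejects += 1
    raise RuntimeError(
        f"exceeded {_REDRAW_CAP} redraws for spec {spec} at N={N}"
    )
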