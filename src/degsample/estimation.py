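"""Weighted estimation of graph observables and log-weight diagnostics.

The sampler is biased but exactly weighted, so an observable :math:`Q`
measured on samples :math:`G_1, \\dots, G_n` with weights :math:`w_i` is
estimated by the self-normalized (ratio) importance-sampling estimator

.. math:: \\hat Q = \\frac{\\sum_i w_i\\, Q(G_i)}{\\sum_i w_i},

computed in the log domain (weights are shifted by the maximum log-weight
before exponentiation, so log-weights up to ~1e6 cause no overflow).  For
long sequences admitting many realizations the log-weights are sums of
many effectively independent terms and are expected to be approximately
normal (log-normal weights); the diagnostics here quantify that with a
Kolmogorov-Smirnov distance and fit power laws to the growth of the mean
and standard deviation of ln w with the sequence length N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "EstimateResult",
    "WeightStats",
    "weighted_average",
    "logweight_stats",
    "fit_logweight_scaling",
    "fit_power_law",
]


@dataclass(frozen=True)
class EstimateResult:
    """Self-normalized importance-sampling estimate of one observable."""

    estimate: float
    log_normalization: float
    n_samples: int
    ess: float
    stderr: float


@dataclass(frozen=True)
class WeightStats:
    """Summary of a log-weight sample, optionally with N-scaling fits.

    ``scaling_exponents`` maps ``"mean"``/``"sd"`` to ``(exponent,
    fit standard error)`` for power laws mu(N) ~ N^a, sigma(N) ~ N^b.
    """

    mean_logw: float
    sd_logw: float
    normality_score: float
    n_samples: int
    scaling_exponents: dict[str, tuple[float, float]] = field(default_factory=dict)


def weighted_average(
    values: Sequence[float], log_weights: Sequence[float]
) -> EstimateResult:
    """Ratio estimator of an observable under importance weights.

    Invariant under adding any constant to all log-weights (rescaling the
    weights), and equal to the plain mean when all weights are equal.  The
    standard error is the linearized ratio-estimator formula
    ``sqrt(sum omega_i^2 (x_i - est)^2)`` with normalized weights omega.
    """
    x = np.asarray(values, dtype=float)
    lw = np.asarray(log_weights, dtype=float)
    if x.size == 0:
        raise ValueError("no samples")
    if x.shape != lw.shape:
        raise ValueError("values and log_weights must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(lw))):
        raise ValueError("non-finite values or log-weights")
    shift = lw.max()
    w = np.exp(lw - shift)
    sw = w.sum()
    omega = w / sw
    est = float(omega @ x)
    ess = float(sw**2 / (w @ w))
    stderr = float(np.sqrt(np.sum(omega**2 * (x - est) ** 2)))
    return EstimateResult(
        estimate=est,
        log_normalization=float(logsumexp(lw)),
        n_samples=int(x.size),
        ess=ess,
        stderr=stderr,
    )


def logweight_stats(log_weights: Sequence[float]) -> WeightStats:
    """Mean, standard deviation and a KS normality score of ln w.

    The normality score is the Kolmogorov-Smirnov distance between the
    standardized log-weights and the standard normal distribution (a
    distribution-free alternative to fitting a Gaussian to the histogram).
    A degenerate sample (zero spread) scores 0.5, the KS distance of a
    point mass from the normal.
    """
    lw = np.asarray(log_weights, dtype=float)
    if lw.size < 2:
        raise ValueError("need at least 2 samples")
    mu = float(lw.mean())
    sd = float(lw.std(ddof=1))
    if sd > 0:
        score = float(stats.kstest((lw - mu) / sd, "norm").statistic)
    else:
        score = 0.5
    return WeightStats(mean_logw=mu, sd_logw=sd, normality_score=score, n_samples=lw.size)


def fit_power_law(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Least-squares slope of log y vs log x, with its standard error."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive values")
    fit = stats.linregress(np.log(x), np.log(y))
    return float(fit.slope), float(fit.stderr)


def fit_logweight_scaling(
    Ns: Sequence[int], stats_per_N: Sequence[WeightStats]
) -> WeightStats:
    """Fit mu(N) and sigma(N) power laws across sequence lengths.

    Returns the pooled statistics of the largest N together with the fitted
    exponents; requires at least 3 distinct N and positive mu and sigma.
    """
    if len(Ns) != len(stats_per_N):
        raise ValueError("Ns and stats_per_N must align")
    if len(set(Ns)) < 3:
        raise ValueError("need at least 3 distinct N values")
    mus = [s.mean_logw for s in stats_per_N]
    sds = [s.sd_logw for s in stats_per_N]
    if any(m <= 0 for m in mus) or any(s <= 0 for s in sds):
        raise ValueError("scaling fit requires positive mean and sd of ln w")
    exps = {
        "mean": fit_power_law(Ns, mus),
        "sd": fit_power_law(Ns, sds),
    }
    last = stats_per_N[int(np.argmax(Ns))]
    return WeightStats(
        mean_logw=last.mean_logw,
        sd_logw=last.sd_logw,
        normality_score=last.normality_score,
        n_samples=last.n_samples,
        scaling_exponents=exps,
    )
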