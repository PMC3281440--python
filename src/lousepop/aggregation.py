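"""Host-level aggregation analysis of ectoparasite count data.

Parasites are almost never spread evenly across their hosts: a few hosts
carry most of the individuals.  This module quantifies that aggregation for
a sample of per-host counts (lice per examined bird) with the standard
toolkit of quantitative parasitology:

* descriptive infracommunity statistics — prevalence, mean intensity,
  sample mean abundance, variance-to-mean ratio;
* the negative-binomial exponent ``k`` (smaller k = stronger aggregation),
  by the moment estimator and by profile maximum likelihood;
* the index of discrepancy ``D``, a Gini-type measure of departure from a
  perfectly uniform distribution of parasites over hosts;
* a chi-square goodness-of-fit test of the observed count frequencies
  against the fitted negative binomial, with tail-inward class pooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "HostCounts",
    "AggregationSummary",
    "NegBinFit",
    "DiscrepancyIndex",
    "GOFResult",
    "NoHostsError",
    "NoOverdispersionError",
    "summarize_counts",
    "fit_negbin_moments",
    "fit_negbin_mle",
    "index_of_discrepancy",
    "gof_negbin",
]


class NoHostsError(ValueError):
    """Raised when an operation receives an empty host sample."""


class NoOverdispersionError(ValueError):
    """Raised when variance <= mean, where the NB moment fit is undefined."""


@dataclass(frozen=True)
class HostCounts:
    """A vector of per-host parasite counts, one entry per examined host.

    Parameters
    ----------
    counts
        Non-negative integer louse counts, one per host.
    host_ids
        Optional host labels, same length as ``counts``.
    """

    counts: np.ndarray
    host_ids: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 1 or arr.size < 1:
            raise NoHostsError("need a non-empty 1-D vector of host counts")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded, atol=0, rtol=0):
                raise ValueError("host counts must be integers")
            arr = rounded.astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        if (arr < 0).any():
            raise ValueError("host counts must be non-negative")
        object.__setattr__(self, "counts", arr)
        if self.host_ids is not None:
            ids = tuple(str(h) for h in self.host_ids)
            if len(ids) != arr.size:
                raise ValueError("host_ids length must match counts length")
            object.__setattr__(self, "host_ids", ids)

    @classmethod
    def from_sequence(
        cls, counts: Sequence[int], host_ids: Optional[Sequence[str]] = None
    ) -> "HostCounts":
        return cls(np.asarray(list(counts)), None if host_ids is None else tuple(host_ids))

    @property
    def n_hosts(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class AggregationSummary:
    """Descriptive statistics of a host-count sample.

    ``mean_intensity`` (lice per infested host) is ``None`` when no host is
    infested; it never silently defaults to zero.  ``variance`` is the
    unbiased (n-1) sample variance.
    """

    n_hosts: int
    n_infested: int
    prevalence: float
    total: int
    mean_intensity: Optional[float]
    mean_abundance: float
    count_range: Optional[tuple[int, int]]
    variance: float
    variance_to_mean: Optional[float]


@dataclass(frozen=True)
class NegBinFit:
    """A fitted negative-binomial model for per-host counts.

    ``k`` is the aggregation exponent (shape of the gamma mixing
    distribution); ``mean`` the fitted mean per host.  ``loglik`` is
    populated for the ML fit only.
    """

    k: float
    mean: float
    method: str  # "moments" or "mle"
    loglik: Optional[float] = None
    converged: bool = True


@dataclass(frozen=True)
class DiscrepancyIndex:
    """Index of discrepancy D in [0, 1): 0 = uniform, ->1 = maximal aggregation."""

    D: float


@dataclass(frozen=True)
class GOFResult:
    """Chi-square goodness of fit of count frequencies to a fitted model."""

    chi2: float
    df: int
    p_value: float
    classes: tuple[tuple[str, int, float], ...] = field(repr=False)


def summarize_counts(counts: HostCounts) -> AggregationSummary:
    """Descriptive infracommunity statistics for a host-count sample.

    Prevalence is the infested fraction of examined hosts, mean intensity
    the mean count over infested hosts, and sample mean abundance the mean
    over all hosts, so ``abundance = prevalence * intensity`` exactly
    whenever at least one host is infested.
    """
    x = counts.counts
    n = x.size
    positive = x[x > 0]
    n_inf = int(positive.size)
    total = int(x.sum())
    prevalence = n_inf / n
    mean_abundance = total / n
    mean_intensity = total / n_inf if n_inf else None
    count_range = (int(positive.min()), int(positive.max())) if n_inf else None
    variance = float(x.var(ddof=1)) if n > 1 else 0.0
    vmr = variance / mean_abundance if mean_abundance > 0 else None
    return AggregationSummary(
        n_hosts=n,
        n_infested=n_inf,
        prevalence=prevalence,
        total=total,
        mean_intensity=mean_intensity,
        mean_abundance=mean_abundance,
        count_range=count_range,
        variance=variance,
        variance_to_mean=vmr,
    )


def fit_negbin_moments(counts: HostCounts) -> NegBinFit:
    """Moment estimator of the negative-binomial exponent.

    ``k = mean**2 / (variance - mean)`` with the unbiased sample variance.
    Defined only for overdispersed samples (variance > mean).
    """
    x = counts.counts
    m = float(x.mean())
    v = float(x.var(ddof=1)) if x.size > 1 else 0.0
    if v <= m:
        raise NoOverdispersionError(
            f"sample variance ({v:.4g}) does not exceed mean ({m:.4g}); "
            "negative-binomial moment fit undefined"
        )
    k = m * m / (v - m)
    return NegBinFit(k=k, mean=m, method="moments", loglik=None, converged=True)


def _nb_loglik(x: np.ndarray, k: float, m: float) -> float:
    # NB parameterized by shape k and mean m: p = k / (k + m)
    return float(
        np.sum(
            special.gammaln(x + k)
            - special.gammaln(k)
            - special.gammaln(x + 1)
            + k * math.log(k / (k + m))
            + x * math.log(m / (k + m))
        )
    )


_LOGK_LO, _LOGK_HI = math.log(1e-8), math.log(1e8)


def fit_negbin_mle(
    counts: HostCounts, tol: float = 1e-10, max_iter: int = 200
) -> NegBinFit:
    """Profile maximum-likelihood estimate of the aggregation exponent k.

    The mean is fixed at the sample mean (its MLE under the NB model); the
    log-likelihood is maximized over log k by bounded scalar minimization.
    For samples with no aggregation signal (variance <= mean) the likelihood
    increases without bound as k -> infinity; the boundary hit is reported
    as ``converged=False`` rather than a spurious finite estimate.
    """
    x = counts.counts
    m = float(x.mean())
    if m <= 0:
        raise ValueError("all counts are zero; NB mean must be positive")
    res = optimize.minimize_scalar(
        lambda logk: -_nb_loglik(x, math.exp(logk), m),
        bounds=(_LOGK_LO, _LOGK_HI),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    k = math.exp(res.x)
    at_boundary = res.x > _LOGK_HI - 1.0 or res.x < _LOGK_LO + 1.0
    converged = bool(res.success) and not at_boundary
    return NegBinFit(
        k=k, mean=m, method="mle", loglik=_nb_loglik(x, k, m), converged=converged
    )


def index_of_discrepancy(counts: HostCounts) -> DiscrepancyIndex:
    """Poulin's index of discrepancy D.

    With counts sorted ascending over N hosts,
    ``D = 1 - 2 * sum_i(cumsum_i) / (mean * N * (N + 1))``:
    the relative area between the observed Lorenz-type curve of parasite
    accumulation over hosts and the line of perfect uniformity.  D = 0 when
    every host carries the same count; D -> 1 as one host monopolizes the
    population.
    """
    x = np.sort(counts.counts)
    n = x.size
    total = int(x.sum())
    if total == 0:
        raise ValueError("index of discrepancy undefined for all-zero counts")
    mean = total / n
    cum = np.cumsum(x)
    d = 1.0 - 2.0 * float(cum.sum()) / (mean * n * (n + 1))
    return DiscrepancyIndex(D=d)


def _class_label(lo: int, hi: Optional[int]) -> str:
    if hi is None:
        return f">={lo}"
    if lo == hi:
        return str(lo)
    return f"{lo}-{hi}"


def gof_negbin(
    counts: HostCounts, fit: NegBinFit, min_expected: float = 1.0
) -> GOFResult:
    """Chi-square goodness of fit of observed count frequencies to ``fit``.

    Count classes are 0, 1, 2, ... up to the maximum observed count, plus a
    single open upper tail; under-populated classes are pooled from the tail
    inward until every expected class count reaches ``min_expected``.
    Degrees of freedom are (pooled classes) - 1 - 2, two parameters (mean
    and k) having been estimated from the data.
    """
    if min_expected <= 0:
        raise ValueError("min_expected must be positive")
    x = counts.counts
    n = x.size
    k, m = fit.k, fit.mean
    p = k / (k + m)
    top = max(int(x.max()), 1)

    values = np.arange(top)
    expected = n * stats.nbinom.pmf(values, k, p)
    tail_expected = n * stats.nbinom.sf(top - 1, k, p)
    observed = np.bincount(x, minlength=top + 1)

    # cells: (lo, hi or None for the open tail, observed, expected)
    cells: list[list] = [[j, j, int(observed[j]), float(expected[j])] for j in values]
    cells.append([top, None, int(observed[top:].sum()), float(tail_expected)])

    # pool from the tail inward: merge the last deficient cell leftward
    while len(cells) > 1:
        deficient = [i for i, c in enumerate(cells) if c[3] < min_expected]
        if not deficient:
            break
        i = deficient[-1]
        j = i - 1 if i > 0 else i + 1  # class 0 can only absorb rightward
        a, b = (cells[j], cells[i]) if j < i else (cells[i], cells[j])
        merged = [a[0], b[1], a[2] + b[2], a[3] + b[3]]
        lo_idx = min(i, j)
        cells[lo_idx : lo_idx + 2] = [merged]

    if len(cells) < 4:
        raise ValueError(
            f"only {len(cells)} pooled classes (need >= 4 for df >= 1); "
            "sample too small or too concentrated for a chi-square test"
        )
    obs = np.array([c[2] for c in cells], dtype=float)
    exp = np.array([c[3] for c in cells], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(cells) - 3
    p_value = float(stats.chi2.sf(chi2, df))
    classes = tuple(
        (_class_label(c[0], c[1]), int(c[2]), float(c[3])) for c in cells
    )
    return GOFResult(chi2=chi2, df=df, p_value=p_value, classes=classes)
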