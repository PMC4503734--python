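"""Chi-squared goodness-of-fit and paired t tests.

Conventions follow the field's standard usage for observed-vs-expected call
counts: Pearson statistic with df = k - 1 over the k compared categories
(no continuity or small-sample correction), and two-sided paired t tests
with df = n - 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


class DegenerateVarianceError(ValueError):
    """Paired differences have zero variance but a non-zero mean."""


@dataclass(frozen=True)
class ChiSqResult:
    statistic: float
    df: int
    p: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"X^2 = {self.statistic:.3f}, df = {self.df}, P = {self.p:.4g}"


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    n: int
    mean_difference: float = float("nan")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"paired t-test, t = {self.t:.3f}, df = {self.df}, P = {self.p:.4g}"


def chisq_gof(
    observed: Sequence[float], expected: Sequence[float]
) -> ChiSqResult:
    """Pearson goodness-of-fit: statistic = sum (O-E)^2 / E, df = k - 1.

    Expected counts need not sum to the observed total (the band analysis
    deliberately compares three bands whose expectations sum to 95% of the
    calls), so the statistic is computed directly rather than through a
    renormalising helper.  The p-value is the upper tail of the chi-squared
    distribution (regularised incomplete gamma).
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise ValueError("observed and expected must be equal-length vectors")
    if len(obs) < 2:
        raise ValueError("need at least two categories")
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be positive")
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    df = len(obs) - 1
    p = float(sps.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return ChiSqResult(statistic=statistic, df=df, p=p)


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Two-sided paired t test on differences d = x - y (sample sd, df = n-1).

    All-zero differences give t = 0, p = 1; zero variance around a non-zero
    mean is an error (the t statistic is undefined).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(xa)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = xa - ya
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=0.0, df=df, p=1.0, n=n, mean_difference=0.0)
        raise DegenerateVarianceError(
            "paired differences are identical and non-zero; t is undefined"
        )
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PairedTResult(t=float(t), df=df, p=p, n=n, mean_difference=mean)


def percent(count: float, total: float) -> float:
    """Share of a printed count pair as a percentage (e.g. 249 of 1044 -> 23.85)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * count / total
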