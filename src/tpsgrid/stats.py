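"""Dispersion statistics over per-square TPS values.

Variation of per-square TPS within one grid is described by the index of
dispersion (IOD = variance / mean; > 1 flags overdispersion relative to a
Poisson-like baseline) and the coefficient of variation (COV = SD / mean,
reported in percent).  Two COVs from independent groups are compared with an
F-statistic for equality of coefficients of variation in normal samples
(Forkman's test).

Conventions: sample (n-1) variance throughout; an all-zero series has IOD
and COV defined as 0 so every scored grid is classifiable; the SD > mean
flag is only evaluated for grids whose mean TPS is at least 1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

from .errors import InsufficientDataError, ParameterError

#: Grids with mean TPS below this (percent) skip the SD > mean flag.
SD_FLAG_MIN_MEAN_TPS = 1.0


@dataclass(frozen=True)
class DispersionSummary:
    """Per-grid dispersion of square TPS values.

    ``flag_sd_gt_mean`` is ``None`` when the grid's mean TPS is below 1%,
    in which case the grid does not enter the SD > mean denominator.
    """

    grid_id: str
    n: int
    mean_tps: float
    sd_tps: float
    iod: float
    cov: float
    flag_iod_gt1: bool
    flag_sd_gt_mean: bool | None


def dispersion_summary(values, grid_id: str = "") -> DispersionSummary:
    """Summarise a series of per-square TPS percents.

    Requires at least two values.  IOD is sample variance over mean and COV
    is 100 * SD / mean; a constant-zero series yields IOD = COV = 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ParameterError("values must be one-dimensional")
    if arr.size < 2:
        raise InsufficientDataError(
            f"need >= 2 included squares, got {arr.size}"
        )
    if not np.isfinite(arr).all():
        raise ParameterError("values must be finite")
    if (arr < 0).any():
        raise ParameterError("TPS values must be non-negative")
    mean = float(arr.mean())
    var = float(arr.var(ddof=1))
    sd = math.sqrt(var)
    if mean == 0.0:
        iod = cov = 0.0
    else:
        iod = var / mean
        cov = 100.0 * sd / mean
    flag_sd: bool | None
    flag_sd = (sd > mean) if mean >= SD_FLAG_MIN_MEAN_TPS else None
    return DispersionSummary(
        grid_id=grid_id,
        n=int(arr.size),
        mean_tps=mean,
        sd_tps=sd,
        iod=iod,
        cov=cov,
        flag_iod_gt1=iod > 1.0,
        flag_sd_gt_mean=flag_sd,
    )


@dataclass(frozen=True)
class ForkmanResult:
    """Result of the two-sample COV equality test."""

    statistic: float
    df: tuple[int, int]
    p_value: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        """Significance at the conventional 0.05 level."""
        return self.p_value < 0.05


def forkman_cov_test(
    cov1: float, n1: int, cov2: float, n2: int
) -> ForkmanResult:
    """F-test for equality of two coefficients of variation (percent scale).

    With ``c_i = cov_i / 100``, the statistic

        F = [c1^2 / (1 + c1^2 (n1-1)/n1)] / [c2^2 / (1 + c2^2 (n2-1)/n2)]

    is referred to the F distribution with (n1-1, n2-1) degrees of freedom;
    the two-sided p doubles the smaller tail, capped at 1.  A zero COV in
    either group makes the comparison degenerate: the statistic collapses to
    a boundary value and the p-value is reported as its limit with the
    ``degenerate`` flag set.
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("both groups need n >= 2")
    if cov1 < 0 or cov2 < 0 or not (math.isfinite(cov1) and math.isfinite(cov2)):
        raise ParameterError("COVs must be finite and non-negative")
    df = (n1 - 1, n2 - 1)
    c1 = cov1 / 100.0
    c2 = cov2 / 100.0
    if c1 == 0.0 and c2 == 0.0:
        return ForkmanResult(statistic=1.0, df=df, p_value=1.0, degenerate=True)
    if c2 == 0.0:
        return ForkmanResult(
            statistic=math.inf, df=df, p_value=0.0, degenerate=True
        )
    if c1 == 0.0:
        return ForkmanResult(statistic=0.0, df=df, p_value=0.0, degenerate=True)

    def corrected(c: float, n: int) -> float:
        return c * c / (1.0 + c * c * (n - 1) / n)

    stat = corrected(c1, n1) / corrected(c2, n2)
    lower = f_dist.cdf(stat, *df)
    upper = f_dist.sf(stat, *df)
    p = min(1.0, 2.0 * min(lower, upper))
    return ForkmanResult(statistic=float(stat), df=df, p_value=float(p))
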