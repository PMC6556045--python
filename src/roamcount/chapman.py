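"""Chapman mark-resight abundance estimation.

The Chapman estimator is the bias-corrected Lincoln-Petersen estimator for a
closed population with a single marking round and a single resighting survey:

    N_hat = (n1 + 1)(n2 + 1) / (m + 1) - 1

where ``n1`` dogs were marked, ``n2`` dogs were sighted on the follow-up
survey, and ``m`` of those carried a mark.  Its sampling variance is the
Seber form

    var(N_hat) = (n1+1)(n2+1)(n1-m)(n2-m) / [(m+1)^2 (m+2)]

Confidence intervals are Wald-normal on N_hat, floored at zero.  Study-level
totals add the per-zone estimates and variances, treating zones (disjoint
areas) as independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from scipy import stats

from .survey_data import ZoneSurvey, zone_counts

__all__ = [
    "ChapmanResult",
    "chapman_estimate",
    "chapman_variance",
    "chapman_zone",
    "chapman_total",
    "chapman_average",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChapmanResult:
    """A Chapman abundance estimate with its variance and Wald CI."""

    estimate: float
    variance: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int
    m: int
    zone_id: str | None = None

    def __post_init__(self):
        if self.variance < 0 or self.estimate < 0:
            raise ValueError("estimate and variance must be non-negative")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def _check_counts(n1: int, n2: int, m: int) -> None:
    if n1 < 0 or n2 < 0 or m < 0:
        raise ValueError(f"counts must be non-negative, got n1={n1}, n2={n2}, m={m}")
    if m > n2:
        raise ValueError(f"m={m} marked sightings exceed n2={n2} total sightings")
    if m > n1:
        # Possible in the field through double counting of moving dogs;
        # the formula remains evaluable, so warn rather than fail.
        logger.warning("m=%d exceeds n1=%d (double counting?)", m, n1)


def chapman_estimate(n1: int, n2: int, m: int) -> float:
    """Chapman abundance estimate ``(n1+1)(n2+1)/(m+1) - 1``."""
    _check_counts(n1, n2, m)
    return (n1 + 1) * (n2 + 1) / (m + 1) - 1


def chapman_variance(n1: int, n2: int, m: int) -> float:
    """Seber variance of the Chapman estimate."""
    _check_counts(n1, n2, m)
    num = (n1 + 1) * (n2 + 1) * (n1 - m) * (n2 - m)
    return max(num, 0.0) / ((m + 1) ** 2 * (m + 2))


def chapman_zone(zone: ZoneSurvey, alpha: float = 0.05) -> ChapmanResult:
    """Chapman estimate for one zone survey with a ``1-alpha`` Wald CI."""
    n1, n2, m = zone_counts(zone)
    return chapman_from_counts(n1, n2, m, alpha=alpha, zone_id=zone.zone_id)


def chapman_from_counts(
    n1: int, n2: int, m: int, alpha: float = 0.05, zone_id: str | None = None
) -> ChapmanResult:
    """Chapman estimate, variance and Wald CI from raw counts."""
    est = chapman_estimate(n1, n2, m)
    var = chapman_variance(n1, n2, m)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * var**0.5
    return ChapmanResult(
        estimate=est,
        variance=var,
        ci_low=max(est - half, 0.0),
        ci_high=est + half,
        n1=n1,
        n2=n2,
        m=m,
        zone_id=zone_id,
    )


def chapman_total(
    zones: list[ChapmanResult], alpha: float = 0.05
) -> ChapmanResult:
    """Study-total estimate: sum of zone estimates, variances added.

    Zones are disjoint areas, so their estimates are treated as independent
    and the total variance is the sum of the per-zone variances.
    """
    if not zones:
        raise ValueError("chapman_total requires at least one zone result")
    est = sum(r.estimate for r in zones)
    var = sum(r.variance for r in zones)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * var**0.5
    return ChapmanResult(
        estimate=est,
        variance=var,
        ci_low=max(est - half, 0.0),
        ci_high=est + half,
        n1=sum(r.n1 for r in zones),
        n2=sum(r.n2 for r in zones),
        m=sum(r.m for r in zones),
        zone_id=None,
    )


def chapman_average(
    day1: ChapmanResult, day2: ChapmanResult, alpha: float = 0.05
) -> ChapmanResult:
    """Average of the two repeat surveys of the same zone.

    The two surveys are treated as independent estimates of the same zone
    abundance, so the variance of the mean is ``(var1 + var2) / 4``.
    """
    if day1.zone_id != day2.zone_id:
        raise ValueError(
            f"zone mismatch: {day1.zone_id!r} vs {day2.zone_id!r}"
        )
    est = (day1.estimate + day2.estimate) / 2
    var = (day1.variance + day2.variance) / 4
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * var**0.5
    return ChapmanResult(
        estimate=est,
        variance=var,
        ci_low=max(est - half, 0.0),
        ci_high=est + half,
        n1=day1.n1,
        n2=round((day1.n2 + day2.n2) / 2),
        m=round((day1.m + day2.m) / 2),
        zone_id=day1.zone_id,
    )
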