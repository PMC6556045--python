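"""Method-agreement statistics for paired per-zone abundance estimates.

Two estimation methods applied to the same working zones yield paired series
(x_i, y_i).  Agreement is summarised by:

* Lin's concordance correlation coefficient (CCC), which measures departure
  from the identity line — the product of Pearson precision and a bias
  correction factor C_b in (0, 1], so |CCC| <= |r| always;
* the Bland-Altman mean difference with 95% limits of agreement
  d_bar +/- 1.96 * SD(d); and
* a paired-t confidence interval for the mean difference.

CCC uses population (n-denominator) moments, following Lin's original
definition; Pearson uses the usual n-1 convention.  Mixing the two
conventions changes small-sample values, so both are stated explicitly.
CCC and Pearson CIs are computed on Fisher's z scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementResult",
    "lins_ccc",
    "bland_altman",
    "mean_difference_ci",
    "pearson_with_ci",
    "compare_methods",
]


@dataclass(frozen=True)
class AgreementResult:
    """One row of a method-comparison table."""

    comparison: str
    n_pairs: int
    mean_difference: float
    md_ci_low: float
    md_ci_high: float
    loa_low: float
    loa_high: float
    ccc: float | None
    ccc_ci_low: float | None
    ccc_ci_high: float | None
    pearson_r: float | None
    pearson_ci_low: float | None
    pearson_ci_high: float | None

    def __post_init__(self):
        if self.ccc is not None and self.pearson_r is not None:
            if abs(self.ccc) > abs(self.pearson_r) + 1e-12:
                raise ValueError("|CCC| cannot exceed |Pearson r|")
        if not (self.loa_low <= self.mean_difference <= self.loa_high):
            raise ValueError("limits of agreement must bracket the mean difference")


def _as_pairs(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("pairs must be finite")
    return x, y


def lins_ccc(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2) with n-denominator
    moments.  The CI transforms CCC to z = atanh(CCC) and uses Lin's
    asymptotic standard error.
    """
    x, y = _as_pairs(x, y, 3)
    n = len(x)
    mx, my = x.mean(), y.mean()
    sx2 = float(np.var(x))  # population variance, n denominator
    sy2 = float(np.var(y))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("both series are constant and equal: CCC undefined")
    ccc = 2 * sxy / denom

    if sx2 == 0 or sy2 == 0:
        return ccc, (float("nan"), float("nan"))
    r = sxy / math.sqrt(sx2 * sy2)
    if abs(ccc) >= 1 or r == 0:
        return ccc, (ccc, ccc)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    c2 = ccc**2
    r2 = r**2
    var_z = (
        (1 - r2) * c2 / ((1 - c2) * r2)
        + 4 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - c2) ** 2)
        - 2 * ccc**4 * u**4 / (r2 * (1 - c2) ** 2)
    ) / (n - 2)
    if var_z <= 0 or not math.isfinite(var_z):
        return ccc, (ccc, ccc)
    zq = stats.norm.ppf(1 - alpha / 2)
    z = math.atanh(ccc)
    half = zq * math.sqrt(var_z)
    return ccc, (math.tanh(z - half), math.tanh(z + half))


def pearson_with_ci(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Pearson correlation with the standard Fisher-z interval."""
    x, y = _as_pairs(x, y, 3)
    n = len(x)
    r = float(stats.pearsonr(x, y).statistic)
    if n <= 3 or abs(r) >= 1:
        return r, (float("nan"), float("nan"))
    z = math.atanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
    return r, (math.tanh(z - half), math.tanh(z + half))


def bland_altman(x, y) -> tuple[float, float, float, pd.DataFrame]:
    """Bland-Altman mean difference and 95% limits of agreement.

    Returns ``(mean_diff, loa_low, loa_high, points)`` where ``points`` holds
    the per-pair means and differences for plotting.  Limits are
    d_bar +/- 1.96 * SD(d) with the sample (n-1) standard deviation.
    """
    x, y = _as_pairs(x, y, 2)
    d = x - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    points = pd.DataFrame({"mean": (x + y) / 2, "difference": d})
    return mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd, points


def mean_difference_ci(
    x, y, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Paired-t confidence interval for the mean difference x - y."""
    x, y = _as_pairs(x, y, 2)
    d = x - y
    n = len(d)
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return mean_diff, (mean_diff, mean_diff)
    half = stats.t.ppf(1 - alpha / 2, n - 1) * sd / math.sqrt(n)
    return mean_diff, (mean_diff - half, mean_diff + half)


def _agreement_row(name: str, x, y, alpha: float) -> AgreementResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mean_diff, (md_lo, md_hi) = mean_difference_ci(x, y, alpha)
    _, loa_lo, loa_hi, _ = bland_altman(x, y)
    ccc = ccc_lo = ccc_hi = r = r_lo = r_hi = None
    if len(x) >= 3 and (np.var(x) > 0 or np.var(y) > 0):
        try:
            ccc, (ccc_lo, ccc_hi) = lins_ccc(x, y, alpha)
            r, (r_lo, r_hi) = pearson_with_ci(x, y, alpha)
        except ValueError:
            pass
    else:
        warnings.warn(
            f"{name}: fewer than 3 informative pairs, CCC omitted", stacklevel=2
        )
    return AgreementResult(
        comparison=name,
        n_pairs=len(x),
        mean_difference=mean_diff,
        md_ci_low=md_lo,
        md_ci_high=md_hi,
        loa_low=loa_lo,
        loa_high=loa_hi,
        ccc=ccc,
        ccc_ci_low=ccc_lo,
        ccc_ci_high=ccc_hi,
        pearson_r=r,
        pearson_ci_low=r_lo,
        pearson_ci_high=r_hi,
    )


#: columns compare_methods expects in its per-zone table
_REQUIRED = [
    "zone_id",
    "route_type",
    "chapman_estimate",
    "distance_abundance",
    "marked_proportion",
    "n_sighted",
]


def compare_methods(per_zone: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Build the full method-comparison battery from a per-zone results table.

    ``per_zone`` must hold one row per (zone_id, route_type) with columns
    ``zone_id``, ``route_type`` ('all_roads' or 'subset'),
    ``chapman_estimate``, ``distance_abundance``, ``marked_proportion`` and
    ``n_sighted``.  The battery compares (i) the Chapman estimate against the
    distance-sampling abundance on all-roads surveys, and (ii) all-roads
    against subset surveys for the abundance estimates of each method, the
    marked proportion, and the number of dogs counted.

    Returns a DataFrame with one row per comparison (mean difference and CI,
    limits of agreement, CCC and CI, Pearson r and CI).
    """
    missing = [c for c in _REQUIRED if c not in per_zone.columns]
    if missing:
        raise ValueError(f"per_zone table missing column(s): {missing}")
    rows: list[AgreementResult] = []

    all_roads = per_zone[per_zone["route_type"] == "all_roads"].set_index("zone_id")
    subset = per_zone[per_zone["route_type"] == "subset"].set_index("zone_id")

    if len(all_roads):
        rows.append(
            _agreement_row(
                "chapman_vs_distance",
                all_roads["chapman_estimate"].to_numpy(),
                all_roads["distance_abundance"].to_numpy(),
                alpha,
            )
        )
    common = all_roads.index.intersection(subset.index)
    if len(common):
        a = all_roads.loc[common]
        s = subset.loc[common]
        for name, col in [
            ("all_vs_subset_chapman", "chapman_estimate"),
            ("all_vs_subset_distance", "distance_abundance"),
            ("all_vs_subset_marked_proportion", "marked_proportion"),
            ("all_vs_subset_dogs_counted", "n_sighted"),
        ]:
            rows.append(
                _agreement_row(name, a[col].to_numpy(), s[col].to_numpy(), alpha)
            )
    return pd.DataFrame([vars(r) for r in rows])
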