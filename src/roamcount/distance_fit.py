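"""Binned line-transect distance sampling.

Perpendicular distances of sighted dogs are grouped into 5 m bins centred on
multiples of five (the surveyors' estimates heap on those values), truncated
at ``w`` = 37.5 m, and a detection function ``g(x)`` is fitted to the bin
counts by maximising the grouped (multinomial) likelihood

    logL = sum_i  n_i * log(pi_i),     pi_i = int_{bin i} g(x) dx / mu,

where ``mu = int_0^w g(x) dx`` is the effective strip half-width (ESW).
Candidate detection models combine a key function — uniform, half-normal
``exp(-x^2 / 2 sigma^2)`` or hazard-rate ``1 - exp(-(x/sigma)^-b)`` — with an
optional cosine, simple-polynomial or Hermite-polynomial adjustment series,
renormalised so that ``g(0) = 1``.  Models are screened by a chi-square
goodness-of-fit test and a shape check (``g <= 1`` on a grid), then the
minimum-AIC fit is selected.

Density follows from the ESW: ``D = n / (2 mu L)`` for ``n`` detections along
total line length ``L``; abundance is ``D`` times the buffered study area.
The variance of ``D`` combines the between-transect encounter-rate variance
with the delta-method detection variance from the MLE information, and the
confidence interval is log-normal.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from numpy.polynomial import hermite_e
from scipy import integrate, optimize, stats

__all__ = [
    "Key",
    "Adjustment",
    "DistanceBinning",
    "DetectionModel",
    "DetectionFit",
    "DensityEstimate",
    "FitError",
    "bin_distances",
    "detection_g",
    "effective_strip_width",
    "fit_detection",
    "select_model",
    "default_candidates",
    "estimate_density",
]

logger = logging.getLogger(__name__)

DEFAULT_TRUNCATION_M = 37.5
DEFAULT_BIN_WIDTH_M = 5.0


class FitError(RuntimeError):
    """Detection-function fitting failed to converge."""


# --- binning -----------------------------------------------------------------


@dataclass(frozen=True)
class DistanceBinning:
    """Grouped perpendicular distances.

    ``cutpoints`` are increasing, start at 0 and end at the truncation
    distance ``w``; ``counts[i]`` is the number of detections with distance in
    ``[cutpoints[i], cutpoints[i+1])`` (last bin closed at ``w``).
    """

    cutpoints: tuple[float, ...]
    counts: tuple[int, ...]

    def __post_init__(self):
        cp = np.asarray(self.cutpoints, dtype=float)
        if cp.ndim != 1 or len(cp) < 2:
            raise ValueError("need at least two cutpoints")
        if cp[0] != 0 or np.any(np.diff(cp) <= 0):
            raise ValueError("cutpoints must start at 0 and strictly increase")
        if len(self.counts) != len(cp) - 1:
            raise ValueError("len(counts) must equal len(cutpoints) - 1")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def w(self) -> float:
        return self.cutpoints[-1]

    @property
    def n(self) -> int:
        return int(sum(self.counts))


def bin_distances(
    distances: Iterable[float],
    w: float = DEFAULT_TRUNCATION_M,
    bin_width: float = DEFAULT_BIN_WIDTH_M,
) -> DistanceBinning:
    """Group distances into bins centred on multiples of ``bin_width``.

    The first bin is the half-bin ``[0, bin_width/2)`` around the transect;
    later bins are full-width and centred on multiples of ``bin_width``.
    Distances at or beyond ``w`` are discarded (right truncation).  ``w`` must
    land on a bin edge, i.e. ``w = bin_width/2 + k*bin_width`` for integer
    ``k >= 1``.
    """
    if w <= 0 or bin_width <= 0:
        raise ValueError("w and bin_width must be positive")
    k = (w - bin_width / 2) / bin_width
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError(
            f"truncation w={w} is not a bin edge for bin_width={bin_width}; "
            f"need w = bin_width/2 + k*bin_width"
        )
    edges = np.concatenate(
        [[0.0], bin_width / 2 + bin_width * np.arange(round(k) + 1)]
    )
    d = np.asarray(list(distances), dtype=float)
    if d.size and (np.any(d < 0) or not np.all(np.isfinite(d))):
        raise ValueError("distances must be finite and non-negative")
    kept = d[d < w]
    counts, _ = np.histogram(kept, bins=edges)
    return DistanceBinning(tuple(edges), tuple(int(c) for c in counts))


# --- detection models --------------------------------------------------------


class Key(str, enum.Enum):
    UNIFORM = "uniform"
    HALF_NORMAL = "half_normal"
    HAZARD_RATE = "hazard_rate"


class Adjustment(str, enum.Enum):
    NONE = "none"
    COSINE = "cosine"
    SIMPLE_POLY = "simple_poly"
    HERMITE_POLY = "hermite_poly"


#: conventional adjustment orders per key family
_DEFAULT_ORDERS = {
    Adjustment.NONE: (),
    Adjustment.COSINE: None,  # resolved per key: {2,3} for half-normal, {2} else
    Adjustment.SIMPLE_POLY: (4, 6),
    Adjustment.HERMITE_POLY: (4, 6),
}


@dataclass(frozen=True)
class DetectionModel:
    """A detection function: key family, adjustment series and parameters.

    ``sigma`` is the key scale in metres (half-normal and hazard-rate);
    ``shape`` is the hazard-rate shape ``b > 1``; ``adjustment_coefs`` are the
    series coefficients ``a_j`` matching ``adjustment_orders``.  The function
    is renormalised so ``g(0) = 1``.
    """

    key: Key
    adjustment: Adjustment = Adjustment.NONE
    adjustment_orders: tuple[int, ...] = ()
    sigma: float | None = None
    shape: float | None = None
    adjustment_coefs: tuple[float, ...] = ()
    truncation_w: float = DEFAULT_TRUNCATION_M

    def __post_init__(self):
        if self.key in (Key.HALF_NORMAL, Key.HAZARD_RATE):
            if self.sigma is not None and self.sigma <= 0:
                raise ValueError("sigma must be > 0")
        if self.key is Key.HAZARD_RATE and self.shape is not None and self.shape <= 1:
            raise ValueError("hazard-rate shape b must be > 1")
        if self.adjustment is not Adjustment.NONE and not self.adjustment_orders:
            raise ValueError("adjustment orders required when adjustment is set")
        if self.adjustment_coefs and len(self.adjustment_coefs) != len(
            self.adjustment_orders
        ):
            raise ValueError("one coefficient per adjustment order required")

    @property
    def n_free_params(self) -> int:
        k = 0
        if self.key in (Key.HALF_NORMAL, Key.HAZARD_RATE):
            k += 1
        if self.key is Key.HAZARD_RATE:
            k += 1
        k += len(self.adjustment_orders)
        return k

    def label(self) -> str:
        s = self.key.value
        if self.adjustment is not Adjustment.NONE:
            s += f"+{self.adjustment.value}{list(self.adjustment_orders)}"
        return s


def _key_eval(model: DetectionModel, x: np.ndarray) -> np.ndarray:
    if model.key is Key.UNIFORM:
        return np.ones_like(x)
    if model.sigma is None:
        raise ValueError(f"{model.key.value} key requires sigma")
    if model.key is Key.HALF_NORMAL:
        with np.errstate(over="ignore", invalid="ignore"):
            return np.exp(-(x**2) / (2 * model.sigma**2))
    # hazard-rate; x=0 maps to 1 exactly (limit of 1 - exp(-(x/sigma)^-b))
    if model.shape is None:
        raise ValueError("hazard_rate key requires shape b")
    with np.errstate(divide="ignore", over="ignore"):
        z = np.where(x > 0, (x / model.sigma) ** (-model.shape), np.inf)
    return -np.expm1(-z)


def _series_eval(model: DetectionModel, x: np.ndarray) -> np.ndarray:
    """1 + sum_j a_j * basis_j(x/w), the unnormalised adjustment multiplier."""
    if model.adjustment is Adjustment.NONE or not model.adjustment_coefs:
        return np.ones_like(x)
    xs = x / model.truncation_w
    out = np.ones_like(x)
    for order, a in zip(model.adjustment_orders, model.adjustment_coefs):
        if model.adjustment is Adjustment.COSINE:
            basis = np.cos(order * np.pi * xs)
        elif model.adjustment is Adjustment.SIMPLE_POLY:
            basis = xs**order
        else:  # Hermite (probabilists' He_n) on the scaled distance
            coef = np.zeros(order + 1)
            coef[order] = 1.0
            basis = hermite_e.hermeval(xs, coef)
        out = out + a * basis
    return out


def detection_g(x, model: DetectionModel):
    """Evaluate the detection function ``g(x)``, renormalised so ``g(0)=1``.

    Accepts scalars or arrays; negative ``x`` is a domain error.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("perpendicular distance must be >= 0")
    norm = float(_key_eval(model, np.zeros(1))[0] * _series_eval(model, np.zeros(1))[0])
    if not np.isfinite(norm) or norm == 0:
        raise ValueError("detection function is degenerate at x=0")
    val = _key_eval(model, arr) * _series_eval(model, arr) / norm
    return float(val) if np.isscalar(x) else val


def effective_strip_width(model: DetectionModel) -> float:
    """ESW ``mu = int_0^w g(x) dx`` by adaptive quadrature (abs tol 1e-8 m)."""
    if model.key is Key.UNIFORM and model.adjustment is Adjustment.NONE:
        return model.truncation_w
    mu, _ = integrate.quad(
        lambda x: detection_g(float(x), model),
        0.0,
        model.truncation_w,
        epsabs=1e-8,
        limit=200,
    )
    if not np.isfinite(mu) or mu <= 0:
        raise ArithmeticError("non-finite or non-positive ESW integral")
    return mu


# --- fitting -----------------------------------------------------------------


@dataclass(frozen=True)
class DetectionFit:
    """A fitted detection model with its likelihood-based diagnostics."""

    model: DetectionModel
    loglik: float
    n_params: int
    aic: float
    esw_mu: float
    p_detect: float
    gof_chi2: float
    gof_df: int
    gof_p: float
    esw_cv: float = 0.0  # delta-method CV of mu from the MLE information
    converged: bool = True

    def __post_init__(self):
        if not (0 < self.p_detect <= 1 + 1e-9):
            raise ValueError("p_detect must lie in (0, 1]")
        if self.esw_mu > self.model.truncation_w * (1 + 1e-9):
            raise ValueError("ESW cannot exceed the truncation distance")


def _pack_template(model: DetectionModel) -> tuple[list[str], DetectionModel]:
    """Names of free parameters, in optimisation order."""
    names = []
    if model.key in (Key.HALF_NORMAL, Key.HAZARD_RATE):
        names.append("log_sigma")
    if model.key is Key.HAZARD_RATE:
        names.append("log_shape_m1")  # b = 1 + exp(theta)
    names.extend(f"a{j}" for j in model.adjustment_orders)
    return names, model


def _theta_to_model(theta: np.ndarray, template: DetectionModel) -> DetectionModel:
    i = 0
    sigma = template.sigma
    shape = template.shape
    if template.key in (Key.HALF_NORMAL, Key.HAZARD_RATE):
        sigma = math.exp(theta[i])
        i += 1
    if template.key is Key.HAZARD_RATE:
        shape = 1.0 + math.exp(theta[i])
        i += 1
    coefs = tuple(theta[i:]) if len(theta) > i else ()
    return replace(
        template, sigma=sigma, shape=shape, adjustment_coefs=coefs
    )


def _gl_nodes(cutpoints: np.ndarray, order: int = 16):
    """Gauss-Legendre nodes/weights mapped into each bin (for fast bin ints)."""
    xg, wg = np.polynomial.legendre.leggauss(order)
    lo = cutpoints[:-1][:, None]
    hi = cutpoints[1:][:, None]
    half = (hi - lo) / 2
    nodes = (hi + lo) / 2 + half * xg[None, :]
    weights = half * wg[None, :]
    return nodes, weights


def _bin_integrals(model: DetectionModel, nodes, weights) -> np.ndarray:
    g = detection_g(nodes.ravel(), model).reshape(nodes.shape)
    return np.sum(g * weights, axis=1)


def _loglik(theta, template, counts, nodes, weights) -> float:
    try:
        model = _theta_to_model(np.asarray(theta, float), template)
    except (ValueError, OverflowError):
        return -np.inf
    try:
        ints = _bin_integrals(model, nodes, weights)
    except (ValueError, FloatingPointError):
        return -np.inf
    mu = float(np.sum(ints))
    if not np.isfinite(mu) or mu <= 0 or np.any(ints <= 0):
        return -np.inf
    pi = ints / mu
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(pi[mask])))


def _gof(counts: np.ndarray, pi: np.ndarray, k_params: int):
    """Chi-square GOF after pooling tail bins so every expected count >= 5."""
    n = counts.sum()
    expected = n * pi
    obs = list(map(float, counts))
    exp = list(map(float, expected))
    # pool from the tail inward until all expected >= 5 (or one bin remains)
    i = len(exp) - 1
    while i > 0:
        if exp[i] < 5:
            exp[i - 1] += exp[i]
            obs[i - 1] += obs[i]
            del exp[i], obs[i]
        i -= 1
    obs_a = np.array(obs)
    exp_a = np.array(exp)
    ok = exp_a > 0
    chi2 = float(np.sum((obs_a[ok] - exp_a[ok]) ** 2 / exp_a[ok]))
    df = int(ok.sum()) - 1 - k_params
    if df <= 0:
        return chi2, df, float("nan")
    return chi2, df, float(stats.chi2.sf(chi2, df))


def _mle_covariance(theta_hat, template, counts, nodes, weights) -> np.ndarray | None:
    """Observed-information covariance in the unconstrained parameter space."""
    p = len(theta_hat)
    if p == 0:
        return None
    h = 1e-4
    H = np.zeros((p, p))
    f0 = _loglik(theta_hat, template, counts, nodes, weights)

    def f(t):
        return _loglik(t, template, counts, nodes, weights)

    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h
            ej[j] = h
            if i == j:
                val = (f(theta_hat + ei) - 2 * f0 + f(theta_hat - ei)) / h**2
            else:
                val = (
                    f(theta_hat + ei + ej)
                    - f(theta_hat + ei - ej)
                    - f(theta_hat - ei + ej)
                    + f(theta_hat - ei - ej)
                ) / (4 * h**2)
            H[i, j] = H[j, i] = val
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
        return None
    return cov


def _esw_cv(theta_hat, template, cov, nodes, weights) -> float:
    """Delta-method CV of mu(theta) at the MLE."""
    if cov is None or len(theta_hat) == 0:
        return 0.0
    h = 1e-5
    p = len(theta_hat)
    grad = np.zeros(p)

    def mu_of(t):
        model = _theta_to_model(np.asarray(t, float), template)
        return float(np.sum(_bin_integrals(model, nodes, weights)))

    mu0 = mu_of(theta_hat)
    for i in range(p):
        e = np.zeros(p)
        e[i] = h
        grad[i] = (mu_of(theta_hat + e) - mu_of(theta_hat - e)) / (2 * h)
    var = float(grad @ cov @ grad)
    if var <= 0 or not np.isfinite(var):
        return 0.0
    return math.sqrt(var) / mu0


def _starts(template: DetectionModel, w: float) -> list[np.ndarray]:
    """Multi-start grid: 5 sigma starts on a log grid, neutral adjustments."""
    names, _ = _pack_template(template)
    n_adj = len(template.adjustment_orders)
    if not names:
        return [np.array([])]
    sigma_starts = np.log(np.array([0.1, 0.25, 0.5, 1.0, 2.0]) * w)
    starts = []
    for ls in sigma_starts:
        theta = []
        if template.key in (Key.HALF_NORMAL, Key.HAZARD_RATE):
            theta.append(ls)
        if template.key is Key.HAZARD_RATE:
            theta.append(math.log(2.0 - 1.0))  # b = 2
        theta.extend([0.0] * n_adj)
        starts.append(np.array(theta))
        if template.key is Key.UNIFORM:
            break  # sigma grid is irrelevant: only adjustment coefs are free
    return starts


def fit_detection(
    binning: DistanceBinning, template: DetectionModel, compute_var: bool = True
) -> DetectionFit:
    """Maximise the grouped multinomial likelihood for one model family.

    The template fixes the key and adjustment family/orders; scale, shape and
    adjustment coefficients are estimated.  Optimisation is bounded
    quasi-Newton (L-BFGS-B) from 5 starts on a log-sigma grid; the best
    finite-likelihood solution wins.

    Raises
    ------
    FitError
        If no start converges to a finite likelihood.
    """
    counts = np.asarray(binning.counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("fit requires at least one nonzero bin count")
    template = replace(template, truncation_w=binning.w)
    nodes, weights = _gl_nodes(np.asarray(binning.cutpoints))
    names, _ = _pack_template(template)
    k = len(names)

    if k == 0:
        theta_hat = np.array([])
        ll = _loglik(theta_hat, template, counts, nodes, weights)
        converged = True
    else:
        def objective(t):
            ll = _loglik(t, template, counts, nodes, weights)
            return -ll if np.isfinite(ll) else 1e12  # finite penalty for L-BFGS-B

        best = None
        for theta0 in _starts(template, binning.w):
            res = optimize.minimize(
                objective,
                theta0,
                method="L-BFGS-B",
                options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
            )
            if not np.isfinite(res.fun) or res.fun >= 1e11:
                continue
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None:
            raise FitError(
                f"no start converged for model {template.label()} "
                f"(counts={binning.counts})"
            )
        theta_hat = best.x
        ll = -float(best.fun)
        converged = bool(best.success)

    model = _theta_to_model(theta_hat, template)
    ints = _bin_integrals(model, nodes, weights)
    mu = float(np.sum(ints))
    pi = ints / mu
    chi2, df, p = _gof(counts, pi, k)
    cv = 0.0
    if compute_var and k > 0:
        cov = _mle_covariance(theta_hat, template, counts, nodes, weights)
        cv = _esw_cv(theta_hat, template, cov, nodes, weights)
    return DetectionFit(
        model=model,
        loglik=ll,
        n_params=k,
        aic=-2 * ll + 2 * k,
        esw_mu=mu,
        p_detect=min(mu / binning.w, 1.0),
        gof_chi2=chi2,
        gof_df=df,
        gof_p=p,
        esw_cv=cv,
        converged=converged,
    )


def _shape_plausible(model: DetectionModel, n_grid: int = 1000) -> bool:
    """Mechanical stand-in for eyeballing the fitted shape: g in (0, 1]."""
    x = np.linspace(0.0, model.truncation_w, n_grid)
    g = detection_g(x, model)
    return bool(np.all(g <= 1 + 1e-9) and np.all(g > 0))


def default_candidates(
    w: float = DEFAULT_TRUNCATION_M,
    keys: Sequence[Key] = (Key.UNIFORM, Key.HALF_NORMAL, Key.HAZARD_RATE),
    adjustments: Sequence[Adjustment] = (Adjustment.NONE, Adjustment.COSINE),
) -> list[DetectionModel]:
    """Conventional candidate set: each key with and without adjustments.

    Cosine orders default to (2, 3) for the half-normal key and (2,) for the
    others; polynomial adjustments use orders (4, 6).
    """
    out = []
    for key in keys:
        for adj in adjustments:
            if adj is Adjustment.NONE:
                if key is Key.UNIFORM:
                    continue  # uniform with no adjustment has nothing to fit
                out.append(DetectionModel(key=key, truncation_w=w))
                continue
            if adj is Adjustment.COSINE:
                orders = (2, 3) if key is Key.HALF_NORMAL else (2,)
            else:
                orders = _DEFAULT_ORDERS[adj]
            out.append(
                DetectionModel(
                    key=key, adjustment=adj, adjustment_orders=tuple(orders),
                    truncation_w=w,
                )
            )
    return out


def select_model(
    binning: DistanceBinning,
    candidates: Sequence[DetectionModel],
    gof_alpha: float = 0.05,
) -> DetectionFit:
    """Fit all candidates, screen for plausibility, return the minimum AIC.

    A candidate passes the screen if its chi-square GOF p-value is at least
    ``gof_alpha`` (or undefined) and its fitted shape stays within (0, 1] on a
    1000-point grid.  If every candidate fails the screen, all are retained
    with a warning.  AIC ties break toward fewer parameters, then candidate
    order.
    """
    if not candidates:
        raise ValueError("select_model requires at least one candidate")
    fits: list[tuple[int, DetectionFit]] = []
    for i, cand in enumerate(candidates):
        try:
            fits.append((i, fit_detection(binning, cand)))
        except (FitError, ValueError) as exc:
            logger.warning("candidate %s failed: %s", cand.label(), exc)
    if not fits:
        raise FitError("all candidate detection models failed to fit")

    def passes(fit: DetectionFit) -> bool:
        gof_ok = math.isnan(fit.gof_p) or fit.gof_p >= gof_alpha
        return gof_ok and _shape_plausible(fit.model)

    screened = [(i, f) for i, f in fits if passes(f)]
    if not screened:
        warnings.warn(
            "no candidate passed the GOF/shape screen; selecting by AIC alone",
            stacklevel=2,
        )
        screened = fits
    screened.sort(key=lambda item: (item[1].aic, item[1].n_params, item[0]))
    return screened[0][1]


# --- density -----------------------------------------------------------------


@dataclass(frozen=True)
class DensityEstimate:
    """Density (per km^2), abundance over an area, and a log-normal CI."""

    density_per_km2: float
    se: float
    ci_low: float
    ci_high: float
    abundance: float
    abundance_ci_low: float
    abundance_ci_high: float
    n_detected: int
    total_line_length_m: float
    area_m2: float
    cv: float

    def __post_init__(self):
        if not (self.ci_low <= self.density_per_km2 <= self.ci_high):
            raise ValueError("CI must bracket the density estimate")


def estimate_density(
    fit: DetectionFit,
    zone_counts: Sequence[tuple[int, float]],
    area_m2: float,
    alpha: float = 0.05,
) -> DensityEstimate:
    """Density and abundance from a pooled detection fit.

    ``zone_counts`` lists ``(n_i, L_i)`` per transect (zone): truncated
    detections and line length in metres.  Density is

        D = n / (2 mu L)    (animals per m^2; reported per km^2)

    and abundance ``N = D * A`` for the buffered area ``A`` (m^2).  The CV of
    ``D`` combines the between-transect encounter-rate variance (line-length
    weighted; Poisson fallback with a warning when only one transect is
    available) with the delta-method CV of the ESW.  The CI is log-normal.
    """
    if not zone_counts:
        raise ValueError("need at least one (n, L) transect")
    ns = np.array([c[0] for c in zone_counts], dtype=float)
    ls = np.array([c[1] for c in zone_counts], dtype=float)
    if np.any(ls <= 0):
        raise ValueError("line lengths must be positive")
    n = float(ns.sum())
    L = float(ls.sum())
    if n <= 0:
        raise ValueError("no detections: density is not estimable")
    mu = fit.esw_mu

    d_per_m2 = n / (2 * mu * L)
    d_per_km2 = d_per_m2 * 1e6

    # encounter-rate variance (between-transect, line-length weighted)
    k = len(ns)
    if k >= 2:
        er = n / L
        var_n = L * float(np.sum(ls * (ns / ls - er) ** 2)) / (k - 1)
    else:
        warnings.warn(
            "single transect: encounter-rate variance falls back to Poisson",
            stacklevel=2,
        )
        var_n = n
    cv_n2 = var_n / n**2
    cv2 = cv_n2 + fit.esw_cv**2
    cv = math.sqrt(cv2)
    se = d_per_km2 * cv

    z = stats.norm.ppf(1 - alpha / 2)
    if cv2 > 0:
        c = math.exp(z * math.sqrt(math.log1p(cv2)))
    else:
        c = 1.0
    ci_low = d_per_km2 / c
    ci_high = d_per_km2 * c

    abundance = d_per_m2 * area_m2
    return DensityEstimate(
        density_per_km2=d_per_km2,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        abundance=abundance,
        abundance_ci_low=ci_low * area_m2 / 1e6,
        abundance_ci_high=ci_high * area_m2 / 1e6,
        n_detected=int(n),
        total_line_length_m=L,
        area_m2=area_m2,
        cv=cv,
    )
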