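"""Causal-effect estimators for two-sample MR.

Given K harmonized instruments with exposure effects ``beta_X_k`` (SD units of
the exposure) and outcome effects ``beta_Y_k`` (log-odds) with standard error
``sigma_Y_k``, the per-SNP Wald ratio is

    theta_k = beta_Y_k / beta_X_k,      se(theta_k) = sigma_Y_k / |beta_X_k|

(first-order: exposure-side measurement error is ignored — the NOME
assumption). The pooled estimators are:

* **IVW** — the precision-weighted average

      theta_IVW = sum_k beta_X_k beta_Y_k sigma_Y_k^-2 / sum_k beta_X_k^2 sigma_Y_k^-2

  with fixed-effect standard error ``(sum_k beta_X_k^2 sigma_Y_k^-2)^-1/2``;
  the multiplicative random-effects variant inflates that by
  ``max(1, sqrt(Q/(K-1)))`` where Q is Cochran's heterogeneity statistic.
  Identical point estimates, never a smaller SE.

* **Weighted median** — the interpolated median of the ordered Wald ratios
  under inverse-variance weights; consistent when instruments carrying more
  than half the weight are valid. Its SE comes from a parametric bootstrap
  (resampling the summary statistics at their reported SEs).

* **MR-Egger** — weighted least squares of beta_Y on beta_X with a free
  intercept, after orienting all beta_X >= 0. The intercept estimates the
  average directional pleiotropic effect; the slope is a pleiotropy-adjusted
  causal estimate. Inference uses t with K-2 df, with the residual sigma
  floored at 1 so the SE never undercuts the fixed-effect one.

Effects are reported as odds ratios per 1-SD increment in the exposure, with
Wald-type confidence intervals exponentiated from the log-odds scale.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import AnalysisError, DegenerateInstrumentError
from .harmonize import HarmonizedInstrument

logger = logging.getLogger(__name__)

DEFAULT_CI_LEVEL = 0.95
DEFAULT_N_BOOT = 5000


class Method(str, Enum):
    IVW_FIXED = "ivw_fixed"
    IVW_MRE = "ivw_mre"
    WEIGHTED_MEDIAN = "weighted_median"
    EGGER_SLOPE = "egger_slope"
    EGGER_INTERCEPT = "egger_intercept"


@dataclass(frozen=True)
class WaldRatio:
    """Per-SNP causal estimate theta_k with its standard error."""

    variant_id: str
    theta: float
    se: float


@dataclass(frozen=True)
class MrEstimate:
    """One method's pooled result on the log-odds and odds-ratio scales."""

    method: Method
    n_snps: int
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    ci_level: float = DEFAULT_CI_LEVEL


def _arrays(
    instruments: Iterable[HarmonizedInstrument],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    inst = list(instruments)
    for h in inst:
        if not h.status.usable:
            raise AnalysisError(
                f"instrument {h.variant_id} has status {h.status.value}; "
                "dropped records cannot enter an estimator"
            )
    bx = np.array([h.beta_exposure for h in inst], dtype=float)
    sx = np.array([h.se_exposure for h in inst], dtype=float)
    by = np.array([h.beta_outcome for h in inst], dtype=float)
    sy = np.array([h.se_outcome for h in inst], dtype=float)
    ids = [h.variant_id for h in inst]
    return bx, sx, by, sy, ids


def to_odds_ratio(
    beta: float, se: float, ci_level: float = DEFAULT_CI_LEVEL
) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate into (OR, CI low, CI high)."""
    if not (se > 0):
        raise ValueError(f"se must be > 0, got {se}")
    if not (0 < ci_level < 1):
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


def _estimate(
    method: Method,
    n_snps: int,
    beta: float,
    se: float,
    pvalue: float,
    ci_level: float,
    df: int | None = None,
) -> MrEstimate:
    """Package beta/se into an MrEstimate.

    Confidence intervals always use the normal quantile; ``df`` is only the
    reference distribution of the *p-value* (t with K-2 df for the Egger
    quantities). This mirrors the convention of the standard R tooling, whose
    reported intervals are b ± z·se for every method.
    """
    q = stats.norm.ppf(0.5 + ci_level / 2)
    # extreme z underflows the two-sided tail to 0; keep p in (0, 1]
    pvalue = max(pvalue, float(np.finfo(float).tiny))
    return MrEstimate(
        method=method,
        n_snps=n_snps,
        beta=beta,
        se=se,
        odds_ratio=math.exp(beta),
        ci_low=math.exp(beta - q * se),
        ci_high=math.exp(beta + q * se),
        pvalue=pvalue,
        ci_level=ci_level,
    )


def wald_ratio(h: HarmonizedInstrument) -> WaldRatio:
    """theta_k = beta_Y/beta_X, se = sigma_Y/|beta_X|."""
    if h.beta_exposure == 0:
        raise DegenerateInstrumentError(
            f"{h.variant_id}: zero exposure effect, Wald ratio undefined"
        )
    return WaldRatio(
        variant_id=h.variant_id,
        theta=h.beta_outcome / h.beta_exposure,
        se=h.se_outcome / abs(h.beta_exposure),
    )


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    """Fixed-effect IVW point estimate and SE from the closed form."""
    w = bx**2 / sy**2
    beta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return beta, se


def _cochran_q(bx: np.ndarray, by: np.ndarray, sy: np.ndarray, beta_ivw: float) -> float:
    theta = by / bx
    se_theta = sy / np.abs(bx)
    return float(np.sum(((theta - beta_ivw) / se_theta) ** 2))


def ivw(
    instruments: Iterable[HarmonizedInstrument],
    model: str = "fixed",
    ci_level: float = DEFAULT_CI_LEVEL,
) -> MrEstimate:
    """Inverse-variance weighted pooled estimate.

    ``model="fixed"`` uses the closed-form SE; ``"multiplicative_random"``
    scales it by ``max(1, sqrt(Q/(K-1)))``. A single instrument reduces
    exactly to its Wald ratio (and falls back to fixed with a warning under
    the random-effects model, where the inflation factor is undefined).
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    bx, _, by, sy, _ = _arrays(instruments)
    k = bx.size
    if k == 0:
        raise AnalysisError("IVW requires at least one instrument")
    if np.any(bx == 0):
        raise DegenerateInstrumentError("zero exposure effect among instruments")
    if k == 1:
        # exact reduction to the single Wald ratio (avoids round-off in the
        # weighted form, keeping the K=1 identity bitwise)
        beta, se = float(by[0] / bx[0]), float(sy[0] / abs(bx[0]))
    else:
        beta, se = _ivw_core(bx, by, sy)
    method = Method.IVW_FIXED
    if model == "multiplicative_random":
        if k == 1:
            warnings.warn(
                "multiplicative random-effects IVW undefined for a single "
                "instrument; using the fixed-effect SE",
                stacklevel=2,
            )
        else:
            q = _cochran_q(bx, by, sy, beta)
            se *= max(1.0, math.sqrt(q / (k - 1)))
            method = Method.IVW_MRE
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return _estimate(method, k, beta, se, p, ci_level)


def _weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of ratios.

    Ratios are ordered; with normalized weights w_(j) the cumulative midpoint
    of the j-th ratio is p_j = (S_j - w_(j)/2) / S_K. The estimate
    interpolates theta linearly in p at p = 0.5 (clamped at the extremes).
    """
    order = np.argsort(theta)
    th = theta[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w)
    p = s - w / 2.0
    return float(np.interp(0.5, p, th))


def _weighted_median_boot(
    bx: np.ndarray,
    sx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> float:
    """Parametric-bootstrap SE: resample the summary stats at their SEs."""
    k = bx.size
    bx_star = rng.normal(bx, sx, size=(n_boot, k))
    by_star = rng.normal(by, sy, size=(n_boot, k))
    theta = by_star / bx_star
    w = (bx_star / sy) ** 2
    w /= w.sum(axis=1, keepdims=True)
    order = np.argsort(theta, axis=1)
    th = np.take_along_axis(theta, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    s = np.cumsum(ws, axis=1)
    p = s - ws / 2.0
    # row-wise interpolation of theta at p = 0.5
    idx = np.sum(p < 0.5, axis=1)
    est = np.empty(n_boot)
    lo_edge = idx == 0
    hi_edge = idx == k
    est[lo_edge] = th[lo_edge, 0]
    est[hi_edge] = th[hi_edge, -1]
    mid = ~(lo_edge | hi_edge)
    rows = np.nonzero(mid)[0]
    j = idx[mid]
    p0 = p[rows, j - 1]
    p1 = p[rows, j]
    t0 = th[rows, j - 1]
    t1 = th[rows, j]
    est[mid] = t0 + (t1 - t0) * (0.5 - p0) / (p1 - p0)
    return float(np.std(est, ddof=1))


def weighted_median(
    instruments: Iterable[HarmonizedInstrument],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    ci_level: float = DEFAULT_CI_LEVEL,
) -> MrEstimate:
    """Weighted-median estimate with a seeded parametric-bootstrap SE."""
    bx, sx, by, sy, _ = _arrays(instruments)
    k = bx.size
    if k < 3:
        raise AnalysisError(f"weighted median requires >= 3 instruments, got {k}")
    if np.any(bx == 0):
        raise DegenerateInstrumentError("zero exposure effect among instruments")
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} is very small; the bootstrap SE will be noisy",
            stacklevel=2,
        )
    theta = by / bx
    weights = (bx / sy) ** 2  # = 1 / se(theta_k)^2
    beta = _weighted_median_point(theta, weights)
    rng = np.random.default_rng(seed)
    se = _weighted_median_boot(bx, sx, by, sy, n_boot, rng)
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return _estimate(Method.WEIGHTED_MEDIAN, k, beta, se, p, ci_level)


def egger(
    instruments: Iterable[HarmonizedInstrument],
    ci_level: float = DEFAULT_CI_LEVEL,
) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger regression: returns (slope, intercept) estimates.

    Instruments are oriented so every exposure effect is non-negative (both
    betas of a negative-beta_X instrument are negated — an allele re-coding,
    to which the causal slope is invariant but the intercept is not), then
    beta_Y is regressed on beta_X with weights sigma_Y^-2 and a free
    intercept. SEs multiply the normal-equation SEs by max(1, sigma_resid);
    p-values use t with K-2 df.
    """
    bx, _, by, sy, _ = _arrays(instruments)
    k = bx.size
    if k < 3:
        raise AnalysisError(f"MR-Egger requires >= 3 instruments, got {k}")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise AnalysisError("zero variance in oriented exposure effects; Egger fit is collinear")
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(k), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    df = k - 2
    sigma2 = float(np.sum(w * resid**2) / df)
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    intercept, slope = float(coef[0]), float(coef[1])
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), df))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), df))
    slope_est = _estimate(Method.EGGER_SLOPE, k, slope, se_slope, p_slope, ci_level, df=df)
    int_est = _estimate(Method.EGGER_INTERCEPT, k, intercept, se_int, p_int, ci_level, df=df)
    return slope_est, int_est


def all_estimates(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    ci_level: float = DEFAULT_CI_LEVEL,
) -> dict[Method, MrEstimate]:
    """Run every estimator on one instrument set (convenience for the pipeline)."""
    out: dict[Method, MrEstimate] = {
        Method.IVW_FIXED: ivw(instruments, "fixed", ci_level),
        Method.IVW_MRE: ivw(instruments, "multiplicative_random", ci_level),
    }
    out[Method.WEIGHTED_MEDIAN] = weighted_median(instruments, n_boot, seed, ci_level)
    slope, intercept = egger(instruments, ci_level)
    out[Method.EGGER_SLOPE] = slope
    out[Method.EGGER_INTERCEPT] = intercept
    return out
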