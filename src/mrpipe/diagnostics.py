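"""Heterogeneity, pleiotropy and influence diagnostics.

Cochran's Q measures dispersion of the per-SNP Wald ratios around the
fixed-effect IVW estimate; under instrument validity it is approximately
chi-square with K-1 df, so a small tail p flags heterogeneous (possibly
pleiotropic) instruments. Leave-one-out re-estimation and the single-SNP
forest table localize which instrument drives a pooled estimate. Numeric
plot data is produced here; rendering lives in :mod:`mrpipe.plots` so the
numbers stay testable headlessly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError
from .estimators import (
    Method,
    MrEstimate,
    _arrays,
    ivw,
    to_odds_ratio,
    wald_ratio,
)
from .harmonize import HarmonizedInstrument


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its degrees of freedom (K-1) and chi-square tail p."""

    q_stat: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class LeaveOneOutResult:
    excluded_id: str
    estimate: MrEstimate


def cochran_q(instruments: list[HarmonizedInstrument]) -> HeterogeneityResult:
    """Q = sum_k ((theta_k - theta_IVW) / se(theta_k))^2, centred on fixed-effect IVW."""
    bx, _, by, sy, _ = _arrays(instruments)
    k = bx.size
    if k < 2:
        raise AnalysisError(f"Cochran's Q requires >= 2 instruments, got {k}")
    beta_ivw = ivw(instruments, "fixed").beta
    theta = by / bx
    se_theta = sy / np.abs(bx)
    q = float(np.sum(((theta - beta_ivw) / se_theta) ** 2))
    p = float(stats.chi2.sf(q, k - 1))
    return HeterogeneityResult(q_stat=q, df=k - 1, pvalue=p)


def leave_one_out(
    instruments: list[HarmonizedInstrument],
    model: str = "fixed",
    ci_level: float = 0.95,
) -> list[LeaveOneOutResult]:
    """IVW re-estimated K times, each time excluding one instrument."""
    inst = list(instruments)
    if len(inst) < 3:
        raise AnalysisError(f"leave-one-out requires >= 3 instruments, got {len(inst)}")
    results = []
    for i, h in enumerate(inst):
        rest = inst[:i] + inst[i + 1 :]
        results.append(
            LeaveOneOutResult(excluded_id=h.variant_id, estimate=ivw(rest, model, ci_level))
        )
    return results


def single_snp_forest(
    instruments: list[HarmonizedInstrument], ci_level: float = 0.95
) -> pd.DataFrame:
    """Per-SNP Wald-ratio rows plus the pooled IVW row, on the OR scale.

    Columns: SNP, BETA, SE, OR, CI_LOW, CI_HIGH; the final row is the pooled
    estimate with SNP = "All (IVW)".
    """
    inst = list(instruments)
    if not inst:
        raise AnalysisError("forest table requires at least one instrument")
    rows = []
    for h in inst:
        wr = wald_ratio(h)
        or_, lo, hi = to_odds_ratio(wr.theta, wr.se, ci_level)
        rows.append(
            {"SNP": wr.variant_id, "BETA": wr.theta, "SE": wr.se,
             "OR": or_, "CI_LOW": lo, "CI_HIGH": hi}
        )
    pooled = ivw(inst, "fixed", ci_level)
    rows.append(
        {"SNP": "All (IVW)", "BETA": pooled.beta, "SE": pooled.se,
         "OR": pooled.odds_ratio, "CI_LOW": pooled.ci_low, "CI_HIGH": pooled.ci_high}
    )
    return pd.DataFrame(rows)


def scatter_data(
    instruments: list[HarmonizedInstrument],
    fits: list[MrEstimate],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scatter-plot points and fitted lines.

    Points are (beta_X, beta_Y) with their SEs, oriented so beta_X >= 0 (the
    MR-Egger convention; both betas of an instrument flip together). Lines
    carry one (slope, intercept) per slope-type fit: intercept 0 for IVW and
    the weighted median, the Egger intercept estimate for the Egger slope.
    """
    if not fits:
        raise AnalysisError("scatter data requires at least one fitted estimate")
    bx, sx, by, sy, ids = _arrays(instruments)
    flip = np.where(bx < 0, -1.0, 1.0)
    points = pd.DataFrame(
        {"SNP": ids, "BETA_EXP": bx * flip, "BETA_OUT": by * flip,
         "SE_EXP": sx, "SE_OUT": sy}
    )
    egger_intercept = next(
        (f.beta for f in fits if f.method is Method.EGGER_INTERCEPT), 0.0
    )
    lines = []
    for f in fits:
        if f.method is Method.EGGER_INTERCEPT:
            continue
        intercept = egger_intercept if f.method is Method.EGGER_SLOPE else 0.0
        lines.append({"METHOD": f.method.value, "SLOPE": f.beta, "INTERCEPT": intercept})
    return points, pd.DataFrame(lines, columns=["METHOD", "SLOPE", "INTERCEPT"])


def funnel_data(instruments: list[HarmonizedInstrument]) -> pd.DataFrame:
    """Per-SNP Wald ratios against their precision (1/se), for funnel plots."""
    rows = []
    for h in instruments:
        wr = wald_ratio(h)
        rows.append({"SNP": wr.variant_id, "BETA": wr.theta, "PRECISION": 1.0 / wr.se})
    return pd.DataFrame(rows)
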