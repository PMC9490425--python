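"""Independent brute-force oracles for the pooled estimators.

Deliberately written differently from the package implementation: explicit
Python loops for the summations and the median interpolation, and statsmodels
WLS for the Egger normal equations. Used only to cross-check results; never
imported by the package.
"""

from __future__ import annotations

import math

import numpy as np
import statsmodels.api as sm


def ivw_oracle(bx, by, sy) -> tuple[float, float]:
    """Fixed-effect IVW via an explicit term-by-term loop."""
    num = 0.0
    den = 0.0
    for x, y, s in zip(bx, by, sy):
        num += x * y / s**2
        den += x * x / s**2
    return num / den, 1.0 / math.sqrt(den)


def cochran_q_oracle(bx, by, sy) -> float:
    """Term-by-term Q about the loop-computed IVW centre."""
    beta, _ = ivw_oracle(bx, by, sy)
    q = 0.0
    for x, y, s in zip(bx, by, sy):
        theta = y / x
        se = s / abs(x)
        q += ((theta - beta) / se) ** 2
    return q


def weighted_median_oracle(theta, weights) -> float:
    """Interpolated weighted median by explicit bracket search."""
    pairs = sorted(zip(theta, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    ps, ts = [], []
    for t, w in pairs:
        cum += w
        ps.append((cum - w / 2.0) / total)
        ts.append(t)
    if 0.5 <= ps[0]:
        return ts[0]
    if 0.5 >= ps[-1]:
        return ts[-1]
    for j in range(1, len(ps)):
        if ps[j - 1] <= 0.5 <= ps[j]:
            frac = (0.5 - ps[j - 1]) / (ps[j] - ps[j - 1])
            return ts[j - 1] + frac * (ts[j] - ts[j - 1])
    raise AssertionError("unreachable")


def egger_oracle(bx, by, sy) -> dict:
    """Weighted normal equations via statsmodels WLS, with the sigma floor.

    statsmodels reports SEs scaled by the estimated residual sigma; the MR
    convention floors sigma at 1, so the oracle rescales by 1/min(1, sigma).
    """
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    sigma = math.sqrt(fit.scale)
    inflate = 1.0 / min(1.0, sigma)
    return {
        "intercept": fit.params[0],
        "slope": fit.params[1],
        "se_intercept": fit.bse[0] * inflate,
        "se_slope": fit.bse[1] * inflate,
    }


def ivw_via_wls(bx, by, sy) -> float:
    """Through-origin WLS point estimate (the Egger fit with intercept 0)."""
    fit = sm.WLS(by, np.asarray(bx, dtype=float), weights=1.0 / np.asarray(sy) ** 2).fit()
    return float(fit.params[0])
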