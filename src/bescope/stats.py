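"""Shared statistical utilities: Pearson R with Fisher-z confidence
intervals and Steiger's Z test for two dependent correlations sharing
one variable (used to compare predictors against the same observations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.stats


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n: int
    p_value: float


def pearson_with_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson R with a Fisher-z 95% confidence interval."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3 for a correlation")
    r, p = scipy.stats.pearsonr(x, y)
    z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    se = 1.0 / math.sqrt(x.size - 3)
    zcrit = scipy.stats.norm.ppf(1 - alpha / 2)
    return CorrelationResult(
        r=float(r),
        ci_low=math.tanh(z - zcrit * se),
        ci_high=math.tanh(z + zcrit * se),
        n=int(x.size),
        p_value=float(p),
    )


def steiger_z(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing variable j.

    ``r_jk`` and ``r_jh`` are the correlations being compared (e.g. two
    models' predictions k, h against the same observations j) and
    ``r_kh`` the correlation between the non-shared variables.  Returns
    (Z, two-sided p).
    """
    if n < 4:
        raise ValueError("need n >= 4 for Steiger's Z")
    z_jk = math.atanh(r_jk)
    z_jh = math.atanh(r_jh)
    rbar = 0.5 * (r_jk + r_jh)
    rbar2 = rbar * rbar
    psi = r_kh * (1 - 2 * rbar2) - 0.5 * rbar2 * (1 - 2 * rbar2 - r_kh * r_kh)
    s = psi / ((1 - rbar2) ** 2)
    z = math.sqrt(n - 3) * (z_jk - z_jh) / math.sqrt(2 - 2 * s)
    p = 2 * scipy.stats.norm.sf(abs(z))
    return z, p


def steiger_z_from_samples(obs, pred_a, pred_b) -> tuple[float, float]:
    """Steiger's Z comparing two predictors against shared observations."""
    obs = np.asarray(obs, float)
    r_jk = float(np.corrcoef(obs, pred_a)[0, 1])
    r_jh = float(np.corrcoef(obs, pred_b)[0, 1])
    r_kh = float(np.corrcoef(pred_a, pred_b)[0, 1])
    return steiger_z(r_jk, r_jh, r_kh, obs.size)


def geometric_mean(values) -> float:
    """exp(mean(log x)) for strictly positive values."""
    x = np.asarray(values, float)
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(x))))
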