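"""Publication-bias diagnostics: Egger's regression and Begg's rank test.

Both are funnel-plot asymmetry tests. Egger's test regresses the
standardized effect ``theta_i / se_i`` on precision ``1 / se_i`` by
ordinary least squares and tests the intercept against zero with a
two-sided t test on k-2 degrees of freedom: small studies with
systematically larger effects pull the intercept away from zero.
Begg's test computes Kendall's rank correlation between the
variance-standardized deviations from the pooled estimate and the
per-study variances, with the normal approximation and continuity
correction; it is nonparametric and known to be conservative at small
k. Neither test is meaningful below k = 3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .contingency import GeneticModel
from .pooling import EffectEstimate, PooledResult, pool_fixed_iv

__all__ = ["BiasReport", "egger_test", "begg_test", "funnel_data"]

logger = logging.getLogger(__name__)

#: Floor for the sampling-variance difference v_i - v_pooled in Begg's
#: standardization; a study whose variance does not exceed the pooled
#: variance would otherwise yield a non-positive denominator.
BEGG_VARIANCE_FLOOR = 1e-10


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se: float
    t: float
    p: float
    k: int


@dataclass(frozen=True)
class BeggResult:
    tau: float
    z: float
    p: float
    k: int


@dataclass(frozen=True)
class BiasReport:
    """Both publication-bias tests for one genetic-model contrast."""

    model: GeneticModel
    egger: EggerResult
    begg: BeggResult

    @property
    def k(self) -> int:
        return self.egger.k


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's linear regression test for funnel-plot asymmetry.

    OLS of ``theta_i / se_i`` on ``1 / se_i``; the intercept estimates
    the asymmetry and is tested two-sided against zero with k-2 df.
    Raises when k < 3 or when all standard errors are equal (the
    precision regressor is then constant and the fit degenerate).
    """
    k = len(effects)
    if k < 3:
        raise ValueError(f"Egger's test requires k >= 3 studies, got {k}")
    se = np.array([e.se for e in effects])
    theta = np.array([e.log_or for e in effects])
    precision = 1.0 / se
    if np.ptp(precision) < 1e-12:
        raise ValueError(
            "Egger's test is degenerate: all studies have equal standard errors"
        )
    design = sm.add_constant(precision)
    fit = sm.OLS(theta / se, design).fit()
    intercept = float(fit.params[0])
    intercept_se = float(fit.bse[0])
    t = intercept / intercept_se
    p = 2.0 * float(stats.t.sf(abs(t), k - 2))
    return EggerResult(intercept=intercept, se=intercept_se, t=t, p=p, k=k)


def begg_test(
    effects: Sequence[EffectEstimate], pooled: PooledResult | None = None
) -> BeggResult:
    """Begg-Mazumdar rank-correlation test for funnel-plot asymmetry.

    Kendall's tau between the standardized deviations
    ``(theta_i - theta_pooled) / sqrt(v_i - v_pooled)`` and the
    variances ``v_i``, where the pooled quantities come from the fixed
    inverse-variance pass (recomputed when ``pooled`` is omitted or was
    produced by a different method). z uses the normal approximation
    ``var(S) = k(k-1)(2k+5)/18`` with continuity correction.
    """
    k = len(effects)
    if k < 3:
        raise ValueError(f"Begg's test requires k >= 3 studies, got {k}")
    iv = pool_fixed_iv(effects)
    theta_hat = iv.log_or
    v_hat = iv.se**2
    v = np.array([e.variance for e in effects])
    theta = np.array([e.log_or for e in effects])
    denom = v - v_hat
    if np.any(denom <= 0):
        logger.warning(
            "Begg standardization: %d studies have variance <= pooled variance; "
            "flooring at %g",
            int(np.sum(denom <= 0)),
            BEGG_VARIANCE_FLOOR,
        )
        denom = np.maximum(denom, BEGG_VARIANCE_FLOOR)
    standardized = (theta - theta_hat) / np.sqrt(denom)

    # Kendall score S over all pairs; tau-b denominator corrects for ties.
    s_x = np.sign(standardized[:, None] - standardized[None, :])
    s_y = np.sign(v[:, None] - v[None, :])
    upper = np.triu_indices(k, 1)
    S = float(np.sum(s_x[upper] * s_y[upper]))
    n_pairs = k * (k - 1) / 2
    tied_x = n_pairs - np.count_nonzero(s_x[upper])
    tied_y = n_pairs - np.count_nonzero(s_y[upper])
    denom_tau = math.sqrt((n_pairs - tied_x) * (n_pairs - tied_y))
    tau = S / denom_tau if denom_tau > 0 else 0.0
    var_S = k * (k - 1) * (2 * k + 5) / 18.0
    z = max(0.0, abs(S) - 1.0) / math.sqrt(var_S)
    p = 2.0 * float(stats.norm.sf(z))
    return BeggResult(tau=tau, z=z, p=p, k=k)


def funnel_data(effects: Sequence[EffectEstimate]) -> pd.DataFrame:
    """Per-study funnel-plot coordinates as a DataFrame.

    Columns: study, log_or, se, precision (1/se) and standardized
    effect (log_or/se) — sufficient to draw a funnel or Egger plot with
    any external plotting tool.
    """
    rows = []
    for i, e in enumerate(effects):
        source = e.source.source if e.source is not None else None
        rows.append(
            {
                "study": source.study_id if source is not None else f"study_{i + 1}",
                "log_or": e.log_or,
                "se": e.se,
                "precision": 1.0 / e.se,
                "standardized_effect": e.log_or / e.se,
            }
        )
    return pd.DataFrame(rows)
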