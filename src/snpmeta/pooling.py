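"""Per-study and pooled odds-ratio estimation.

Implements the classical meta-analysis toolkit for 2x2 tables on the
log odds-ratio scale:

* per-study log OR with the usual large-sample standard error
  ``sqrt(1/a + 1/b + 1/c + 1/d)``;
* fixed-effect pooling by Mantel-Haenszel (variance by the
  Robins-Breslow-Greenland formula) or by inverse variance;
* DerSimonian-Laird random effects with the moment estimator of the
  between-study variance tau^2, truncated at zero;
* Cochran's Q (inverse-variance weights around the inverse-variance
  fixed estimate, so heterogeneity does not depend on the MH/IV
  choice), I^2 = max(0, (Q - df)/Q) * 100, and the chi-squared p-value;
* the conventional model-selection rule: random effects when the Q test
  gives p < 0.1 or I^2 > 50%, fixed effects otherwise.

Confidence intervals are Wald intervals on the log scale at the
two-sided 95% level (z = 1.959964).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .contingency import FourfoldTable

__all__ = [
    "PoolingMethod",
    "EffectEstimate",
    "PooledResult",
    "study_effect",
    "pool_fixed_mh",
    "pool_fixed_iv",
    "pool_random_dl",
    "select_model",
    "meta_analyse",
]

Z_975 = stats.norm.ppf(0.975)  # 1.959964...


class PoolingMethod(Enum):
    FIXED_MH = "Mantel-Haenszel fixed"
    FIXED_IV = "inverse-variance fixed"
    RANDOM_DL = "DerSimonian-Laird random"

    @property
    def is_fixed(self) -> bool:
        return self is not PoolingMethod.RANDOM_DL

    @property
    def short(self) -> str:
        return "Fixed" if self.is_fixed else "Random"


@dataclass(frozen=True)
class EffectEstimate:
    """One study's log odds ratio and its standard error."""

    log_or: float
    se: float
    source: FourfoldTable | None = None

    @property
    def or_value(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci95(self) -> tuple[float, float]:
        half = Z_975 * self.se
        return math.exp(self.log_or - half), math.exp(self.log_or + half)

    @property
    def variance(self) -> float:
        return self.se**2


@dataclass(frozen=True)
class PooledResult:
    """A pooled odds ratio with its heterogeneity statistics."""

    method: PoolingMethod
    k: int
    log_or: float
    se: float
    Q: float
    tau2: float = 0.0

    @property
    def or_value(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci95(self) -> tuple[float, float]:
        half = Z_975 * self.se
        return math.exp(self.log_or - half), math.exp(self.log_or + half)

    @property
    def z(self) -> float:
        return self.log_or / self.se

    @property
    def p(self) -> float:
        return 2.0 * stats.norm.sf(abs(self.z))

    @property
    def df(self) -> int:
        return self.k - 1

    @property
    def p_Q(self) -> float:
        if self.df < 1:
            return float("nan")
        return float(stats.chi2.sf(self.Q, self.df))

    @property
    def I2(self) -> float:
        """Percent of total variation attributable to heterogeneity."""
        if self.Q <= 0.0:
            return 0.0
        return max(0.0, (self.Q - self.df) / self.Q) * 100.0


def study_effect(table: FourfoldTable) -> EffectEstimate:
    """Log odds ratio and SE for a single 2x2 table.

    The table must be informative with any continuity policy already
    applied; a remaining zero cell leaves the log OR or its SE undefined
    and raises.
    """
    if not table.informative:
        raise ValueError("cannot estimate an effect from a non-informative table")
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) <= 0.0:
        raise ValueError(
            "zero cell present; apply a continuity correction before estimating"
        )
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return EffectEstimate(log_or=log_or, se=se, source=table)


def _check_k(k: int, minimum: int) -> None:
    if k < minimum:
        raise ValueError(f"pooling requires at least {minimum} informative studies, got {k}")


def _iv_q(effects: Sequence[EffectEstimate]) -> tuple[float, float, float, float]:
    """Inverse-variance fixed pass: (pooled log OR, pooled var, Q, sum of weights)."""
    theta = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.variance for e in effects])
    pooled = float(np.sum(w * theta) / np.sum(w))
    Q = float(np.sum(w * (theta - pooled) ** 2))
    return pooled, 1.0 / float(np.sum(w)), Q, float(np.sum(w))


def pool_fixed_iv(effects: Sequence[EffectEstimate]) -> PooledResult:
    """Inverse-variance fixed-effect pooling of per-study log odds ratios."""
    _check_k(len(effects), 1)
    pooled, var, Q, _ = _iv_q(effects)
    return PooledResult(
        method=PoolingMethod.FIXED_IV,
        k=len(effects),
        log_or=pooled,
        se=math.sqrt(var),
        Q=Q,
    )


def pool_fixed_mh(tables: Sequence[FourfoldTable]) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled odds ratio.

    The point estimate is ``sum(a_i d_i / n_i) / sum(b_i c_i / n_i)``;
    the variance of its log is the Robins-Breslow-Greenland estimator.
    Q (and hence I^2) is computed from the inverse-variance pass so that
    heterogeneity is identical between the two fixed estimators.
    """
    _check_k(len(tables), 1)
    a = np.array([t.a for t in tables])
    b = np.array([t.b for t in tables])
    c = np.array([t.c for t in tables])
    d = np.array([t.d for t in tables])
    n = a + b + c + d
    R = a * d / n
    S = b * c / n
    sum_R, sum_S = float(np.sum(R)), float(np.sum(S))
    log_or = math.log(sum_R / sum_S)
    # Robins-Breslow-Greenland variance of the log MH odds ratio.
    P = (a + d) / n
    Qv = (b + c) / n
    var = (
        float(np.sum(P * R)) / (2.0 * sum_R**2)
        + float(np.sum(P * S + Qv * R)) / (2.0 * sum_R * sum_S)
        + float(np.sum(Qv * S)) / (2.0 * sum_S**2)
    )
    effects = [study_effect(t) for t in tables]
    _, _, Q, _ = _iv_q(effects)
    return PooledResult(
        method=PoolingMethod.FIXED_MH,
        k=len(tables),
        log_or=log_or,
        se=math.sqrt(var),
        Q=Q,
    )


def pool_random_dl(effects: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    tau^2 is the moment estimator ``max(0, (Q - (k-1)) / (sum w - sum
    w^2 / sum w))`` from the inverse-variance fixed pass; studies are
    then re-weighted by ``1 / (se_i^2 + tau^2)``. With homogeneous
    effects (Q <= k-1) the result coincides with fixed inverse-variance
    pooling.
    """
    _check_k(len(effects), 2)
    _, _, Q, sum_w = _iv_q(effects)
    w = np.array([1.0 / e.variance for e in effects])
    denom = sum_w - float(np.sum(w**2)) / sum_w
    k = len(effects)
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    theta = np.array([e.log_or for e in effects])
    w_star = 1.0 / (np.array([e.variance for e in effects]) + tau2)
    pooled = float(np.sum(w_star * theta) / np.sum(w_star))
    se = math.sqrt(1.0 / float(np.sum(w_star)))
    return PooledResult(
        method=PoolingMethod.RANDOM_DL,
        k=k,
        log_or=pooled,
        se=se,
        Q=Q,
        tau2=tau2,
    )


def select_model(
    p_Q: float, I2: float, alpha_Q: float = 0.1, I2_cut: float = 50.0
) -> PoolingMethod:
    """Heterogeneity-driven choice between fixed and random effects.

    Random effects iff the Q test gives p < ``alpha_Q`` or I^2 exceeds
    ``I2_cut`` percent; both inequalities strict.
    """
    if (not math.isnan(p_Q) and p_Q < alpha_Q) or I2 > I2_cut:
        return PoolingMethod.RANDOM_DL
    return PoolingMethod.FIXED_IV


def meta_analyse(
    tables: Sequence[FourfoldTable],
    fixed_method: PoolingMethod = PoolingMethod.FIXED_MH,
    force_method: PoolingMethod | None = None,
) -> PooledResult:
    """Pool a set of informative 2x2 tables with model selection.

    Computes the fixed-effect result (MH by default, IV on request),
    then applies :func:`select_model` on its heterogeneity statistics;
    when heterogeneity calls for random effects and k >= 2, re-pools
    with DerSimonian-Laird. ``force_method`` bypasses the selection rule
    (used by subgroup reports that want method comparability).
    """
    _check_k(len(tables), 1)
    effects = [study_effect(t) for t in tables]
    if fixed_method is PoolingMethod.FIXED_MH:
        fixed = pool_fixed_mh(tables)
    elif fixed_method is PoolingMethod.FIXED_IV:
        fixed = pool_fixed_iv(effects)
    else:
        raise ValueError("fixed_method must be FIXED_MH or FIXED_IV")

    if force_method is not None:
        chosen = force_method
    else:
        chosen = select_model(fixed.p_Q, fixed.I2)
    if chosen is PoolingMethod.RANDOM_DL and len(effects) >= 2:
        return pool_random_dl(effects)
    if chosen is PoolingMethod.FIXED_IV and fixed.method is PoolingMethod.FIXED_MH:
        return fixed if force_method is None else pool_fixed_iv(effects)
    if chosen is PoolingMethod.FIXED_MH and fixed.method is PoolingMethod.FIXED_IV:
        return pool_fixed_mh(tables)
    return fixed
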