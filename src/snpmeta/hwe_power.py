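"""Hardy-Weinberg equilibrium testing and meta-analysis power.

Departure from Hardy-Weinberg equilibrium (HWE) in the *controls* of a
case-control genetic study flags genotyping error or population
stratification, so each cohort's control genotypes are tested with the
plain Pearson chi-squared goodness-of-fit test (1 df: one free allele
frequency, no continuity correction). A monomorphic control sample
carries no information about equilibrium and is reported as not
assessable rather than passed or failed.

Power of the pooled allele-contrast comparison is computed with the
standard normal approximation: the expected case allele frequency is
derived from the assumed odds ratio and the control frequency, the
standard error of the log odds ratio from the expected 2x2 allele
table at the given sample sizes, and

    power = Phi(|ln OR|/SE - z_{1-alpha/2}) + Phi(-|ln OR|/SE - z_{1-alpha/2}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .study_io import StudyTable

__all__ = [
    "HweResult",
    "PowerResult",
    "hwe_test",
    "hwe_table",
    "pooled_control_maf",
    "power_analysis",
]


@dataclass(frozen=True)
class HweResult:
    """Pearson HWE test on one control sample.

    ``maf`` is the frequency of the effect (C) allele; ``chi2`` and
    ``p`` are None when the sample is monomorphic (not assessable).
    """

    chi2: float | None
    p: float | None
    assessable: bool
    maf: float
    df: int = 1


@dataclass(frozen=True)
class PowerResult:
    """Power of a two-sided allele-contrast test at the given design."""

    power: float
    assumed_or: float
    alpha: float
    n_cases: int
    n_controls: int
    control_maf: float
    method: str = "allele-contrast normal approximation"


def hwe_test(ctrl_tt: int, ctrl_tc: int, ctrl_cc: int) -> HweResult:
    """Pearson chi-squared test of Hardy-Weinberg equilibrium.

    Expected genotype counts under HWE at the observed allele frequency
    q are ``n(1-q)^2, 2nq(1-q), nq^2`` for TT/TC/CC; the statistic is
    referred to chi-squared with 1 df.
    """
    n = ctrl_tt + ctrl_tc + ctrl_cc
    if n < 1:
        raise ValueError("HWE test requires at least one genotyped control")
    q = (2 * ctrl_cc + ctrl_tc) / (2 * n)
    if q == 0.0 or q == 1.0:
        return HweResult(chi2=None, p=None, assessable=False, maf=q)
    expected = (n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q**2)
    observed = (ctrl_tt, ctrl_tc, ctrl_cc)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HweResult(
        chi2=chi2, p=float(stats.chi2.sf(chi2, 1)), assessable=True, maf=q
    )


def hwe_table(table: StudyTable, alpha: float = 0.05) -> pd.DataFrame:
    """Recompute HWE for every cohort and compare with any reported flag.

    The returned frame carries the recomputed verdict (Y/N at ``alpha``,
    NA when not assessable) next to the flag the source publication
    reported, with a ``discrepant`` column where the two disagree —
    reported flags are carried but never trusted.
    """
    rows = []
    for record in table:
        result = hwe_test(record.ctrl_tt, record.ctrl_tc, record.ctrl_cc)
        if not result.assessable:
            recomputed = "NA"
        else:
            recomputed = "N" if result.p < alpha else "Y"
        reported = record.hwe_flag_reported
        rows.append(
            {
                "study": record.study_id,
                "maf": result.maf,
                "chi2": result.chi2,
                "p": result.p,
                "assessable": result.assessable,
                "hwe_recomputed": recomputed,
                "hwe_reported": reported,
                "discrepant": reported is not None and reported != recomputed,
            }
        )
    return pd.DataFrame(rows)


def pooled_control_maf(table: StudyTable) -> float:
    """Effect-allele frequency over all control genotypes combined."""
    alleles = sum(2 * r.ctrl_cc + r.ctrl_tc for r in table)
    total = sum(2 * r.n_controls for r in table)
    return alleles / total


def power_analysis(
    n_cases: int,
    n_controls: int,
    control_maf: float,
    assumed_or: float,
    alpha: float = 0.05,
) -> PowerResult:
    """Power of the pooled allele-contrast test at a hypothesised OR.

    The case allele frequency q' solves ``odds(q') = OR * odds(q)`` for
    the control frequency q; each subject contributes two alleles. At
    OR = 1 the power equals alpha (the two-sided type-I error).
    """
    if not 0.0 < control_maf < 1.0:
        raise ValueError(f"control MAF must lie strictly in (0, 1), got {control_maf}")
    if assumed_or <= 0.0:
        raise ValueError(f"assumed OR must be positive, got {assumed_or}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    q = control_maf
    q_case = assumed_or * q / (1.0 - q + assumed_or * q)
    se = math.sqrt(
        1.0 / (2 * n_cases * q_case)
        + 1.0 / (2 * n_cases * (1.0 - q_case))
        + 1.0 / (2 * n_controls * q)
        + 1.0 / (2 * n_controls * (1.0 - q))
    )
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    shift = abs(math.log(assumed_or)) / se
    power = float(stats.norm.cdf(shift - z_crit) + stats.norm.cdf(-shift - z_crit))
    return PowerResult(
        power=power,
        assumed_or=assumed_or,
        alpha=alpha,
        n_cases=n_cases,
        n_controls=n_controls,
        control_maf=control_maf,
    )
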