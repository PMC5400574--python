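"""Synthetic case-control study generation for testing and calibration.

The generator emulates the structure of a published multi-cohort SNP
association dataset: k independent case-control cohorts, control
genotypes drawn under Hardy-Weinberg equilibrium at a cohort-specific
allele frequency, and case genotypes drawn under HWE at the frequency
implied by a study-level allele odds ratio. Between-study heterogeneity
enters as a normal perturbation of the log odds ratio with standard
deviation tau. Metadata (ethnicity, source of controls) is assigned
round-robin so every subgroup stratum is populated once k >= 6.

Defaults mirror the glaucoma rs1063192 evidence base the package ships
as its fixture: 16 cohorts, a protective allele odds ratio of 0.76,
control minor-allele frequencies between 0.05 and 0.45, and per-arm
sample sizes in the few-hundreds-to-few-thousands range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .bias import begg_test, egger_test
from .contingency import ContinuityPolicy, GeneticModel, model_tables
from .pooling import pool_fixed_mh, study_effect
from .study_io import SOC_CATEGORIES, StudyRecord, StudyTable

__all__ = ["SyntheticConfig", "simulate_study_table", "simulate_null_meta"]

_METADATA_CYCLE = tuple(
    (ethnicity, soc)
    for ethnicity in ("Caucasian", "Asian", "African")
    for soc in SOC_CATEGORIES
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic study table.

    ``true_allele_or`` is the allele-contrast odds ratio shared by all
    studies (up to heterogeneity); ``tau`` is the between-study SD of
    the log odds ratio; ``maf_law`` bounds the uniform law of the
    control effect-allele frequency; ``n_case_law``/``n_ctrl_law`` are
    inclusive integer ranges for per-arm sample sizes. The same seed
    always yields the same table.
    """

    k: int = 16
    true_allele_or: float = 0.76
    tau: float = 0.0
    maf_law: tuple[float, float] = (0.05, 0.45)
    n_case_law: tuple[int, int] = (200, 2500)
    n_ctrl_law: tuple[int, int] = (200, 2500)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.true_allele_or <= 0:
            raise ValueError("true_allele_or must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        low, high = self.maf_law
        if not (0.0 < low <= high < 1.0):
            raise ValueError("maf_law bounds must satisfy 0 < low <= high < 1")
        for name in ("n_case_law", "n_ctrl_law"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be a non-empty positive range")


def _hwe_genotypes(rng: np.random.Generator, n: int, q: float) -> tuple[int, int, int]:
    """(TT, TC, CC) multinomial draw under HWE at effect-allele freq q."""
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
    tt, tc, cc = rng.multinomial(n, probs)
    return int(tt), int(tc), int(cc)


def simulate_study_table(config: SyntheticConfig) -> StudyTable:
    """Draw a study table under the generative model of ``config``.

    Per study: control frequency q ~ U(maf_law); study log OR = ln(true
    OR) + N(0, tau^2); case frequency solves odds(q') = OR * odds(q);
    both arms' genotypes are multinomial under HWE at their frequency.
    A degenerate draw (an arm with zero subjects of any genotype cannot
    occur, but a cohort whose case or control counts are all in one
    cell can) is kept — downstream informativeness screening handles it
    exactly as it does real data.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.k):
        q = float(rng.uniform(*config.maf_law))
        log_or = math.log(config.true_allele_or)
        if config.tau > 0:
            log_or += float(rng.normal(0.0, config.tau))
        or_i = math.exp(log_or)
        q_case = or_i * q / (1.0 - q + or_i * q)
        n_case = int(rng.integers(config.n_case_law[0], config.n_case_law[1] + 1))
        n_ctrl = int(rng.integers(config.n_ctrl_law[0], config.n_ctrl_law[1] + 1))
        case_tt, case_tc, case_cc = _hwe_genotypes(rng, n_case, q_case)
        ctrl_tt, ctrl_tc, ctrl_cc = _hwe_genotypes(rng, n_ctrl, q)
        ethnicity, soc = _METADATA_CYCLE[i % len(_METADATA_CYCLE)]
        records.append(
            StudyRecord(
                study_id=f"Sim{i + 1:03d}",
                year=2000 + i % 20,
                ethnicity=ethnicity,
                soc=soc,
                case_tt=case_tt,
                case_tc=case_tc,
                case_cc=case_cc,
                ctrl_tt=ctrl_tt,
                ctrl_tc=ctrl_tc,
                ctrl_cc=ctrl_cc,
            )
        )
    return StudyTable(
        tuple(records),
        provenance=f"synthetic (k={config.k}, OR={config.true_allele_or}, "
        f"tau={config.tau}, seed={config.seed})",
    )


def simulate_null_meta(
    config: SyntheticConfig,
    replicates: int,
    alpha: float = 0.05,
    alpha_Q: float = 0.1,
    model: GeneticModel = GeneticModel.ALLELE,
) -> dict[str, dict[str, float]]:
    """Empirical rejection rates of the pipeline's tests under ``config``.

    For type-I error runs the config must have ``true_allele_or = 1``
    (the function enforces this; use a copy with a different OR for
    power experiments via the per-test helpers instead). Each replicate
    draws a fresh table (seeded from ``config.seed``), pools the chosen
    contrast with the Mantel-Haenszel fixed estimator, and records
    whether the pooled z-test (at ``alpha``), the Q test (at
    ``alpha_Q``), Egger's and Begg's tests (at ``alpha``) reject.

    Returns a mapping test name -> {"rate": ..., "mc_se": ..., "n": ...}
    with the binomial Monte-Carlo standard error; empty when
    ``replicates`` is 0.
    """
    if replicates < 0:
        raise ValueError("replicates must be non-negative")
    if replicates == 0:
        return {}
    if config.true_allele_or != 1.0:
        raise ValueError("type-I error calibration requires true_allele_or = 1")
    counts = {"pooled_z": 0, "cochran_q": 0, "egger": 0, "begg": 0}
    valid = {name: 0 for name in counts}
    seeds = np.random.SeedSequence(config.seed).generate_state(replicates) % (2**31)
    for rep in range(replicates):
        table = simulate_study_table(replace(config, seed=int(seeds[rep])))
        informative, _ = model_tables(table, model, ContinuityPolicy.ADD_HALF)
        if len(informative) < 3:
            continue
        pooled = pool_fixed_mh(informative)
        effects = [study_effect(t) for t in informative]
        valid["pooled_z"] += 1
        counts["pooled_z"] += pooled.p < alpha
        valid["cochran_q"] += 1
        counts["cochran_q"] += pooled.p_Q < alpha_Q
        try:
            egger = egger_test(effects)
        except ValueError:
            pass
        else:
            valid["egger"] += 1
            counts["egger"] += egger.p < alpha
        begg = begg_test(effects, pooled)
        valid["begg"] += 1
        counts["begg"] += begg.p < alpha
    report = {}
    for name, hits in counts.items():
        n = valid[name]
        rate = hits / n if n else float("nan")
        mc_se = math.sqrt(rate * (1 - rate) / n) if n else float("nan")
        report[name] = {"rate": rate, "mc_se": mc_se, "n": n}
    return report
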