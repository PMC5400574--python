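"""Report assembly: run the full pipeline and emit tabular products.

``run_pipeline`` drives the whole analysis on one study table and
writes, per run:

* ``overall.tsv``   — one row per genetic model: pooled OR, CI, p,
  heterogeneity (Q, p_Q, I^2, tau^2) and the Fixed/Random label;
* ``subgroups.tsv`` — per model x grouping label x stratum, same
  columns plus k;
* ``sensitivity.tsv`` — leave-one-out re-pooled results;
* ``bias.tsv`` and ``funnel_<model>.tsv`` — Egger/Begg statistics and
  funnel-plot coordinates;
* ``hwe.tsv``      — per-cohort Hardy-Weinberg recomputation;
* ``summary.json`` — machine-readable digest of all of the above.

Numeric columns are written at full precision with companion
``*_2dp`` columns rounded to the two-decimal convention of the
published tables, so any comparison against printed values is explicit
rather than hidden in formatting. Subgroup strata are pooled with the
method selected on the overall analysis of the same model (the
behaviour of running one subgroup meta-analysis command), which the
library's :func:`snpmeta.stratify.subgroup_analysis` exposes as
``force_method``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .bias import BiasReport, begg_test, egger_test, funnel_data
from .contingency import ContinuityPolicy, GeneticModel, model_tables
from .hwe_power import hwe_table
from .pooling import PooledResult, PoolingMethod, meta_analyse, study_effect
from .stratify import leave_one_out, subgroup_analysis
from .study_io import StudyTable, read_study_table, table_totals

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_GROUP_BY = ("ethnicity", "soc")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str | Path
    output_dir: str | Path
    models: tuple[GeneticModel, ...] = tuple(GeneticModel)
    group_by: tuple[str, ...] = DEFAULT_GROUP_BY
    continuity: ContinuityPolicy = ContinuityPolicy.ADD_HALF
    fixed_method: PoolingMethod = PoolingMethod.FIXED_MH
    dialect: str | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one genetic model must be selected")


def _result_row(res: PooledResult) -> dict:
    lo, hi = res.ci95
    return {
        "method": res.method.short,
        "k": res.k,
        "or": res.or_value,
        "ci_low": lo,
        "ci_high": hi,
        "or_2dp": round(res.or_value, 2),
        "ci_low_2dp": round(lo, 2),
        "ci_high_2dp": round(hi, 2),
        "z": res.z,
        "p": res.p,
        "Q": res.Q,
        "df": res.df,
        "p_Q": res.p_Q,
        "I2": res.I2,
        "tau2": res.tau2,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full meta-analysis and write all tabular products.

    Returns the in-memory report bundle (the same content as
    ``summary.json``). Models with no informative study are logged and
    skipped; every excluded study is logged once per model with the
    reason.
    """
    table = read_study_table(config.input_path, dialect=config.dialect)
    return analyse_and_write(table, config)


def analyse_and_write(table: StudyTable, config: RunConfig) -> dict:
    """As :func:`run_pipeline`, but on an already-loaded table."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases, controls, n_rows = table_totals(table)
    logger.info("loaded %d rows: %d cases, %d controls", n_rows, cases, controls)

    overall_rows: list[dict] = []
    subgroup_rows: list[dict] = []
    sensitivity_rows: list[dict] = []
    bias_rows: list[dict] = []
    summary: dict = {
        "input": str(table.provenance),
        "totals": {"cases": cases, "controls": controls, "rows": n_rows},
        "models": {},
    }

    for model in config.models:
        informative, excluded = model_tables(table, model, config.continuity)
        for tab in excluded:
            logger.info(
                "model %s: excluding %s (non-informative: no events or no "
                "non-events in both arms)",
                model.name,
                tab.source.study_id if tab.source else "<unknown>",
            )
        if not informative:
            logger.warning("model %s: no informative studies, skipped", model.name)
            continue
        overall = meta_analyse(informative, fixed_method=config.fixed_method)
        row = {"model": model.label, **_result_row(overall)}
        overall_rows.append(row)
        model_summary: dict = {
            "overall": row,
            "excluded": [
                t.source.study_id if t.source else "<unknown>" for t in excluded
            ],
            "subgroups": {},
        }

        # Subgroups share the overall model's selected method, mirroring a
        # single subgroup meta-analysis command.
        for label in config.group_by:
            try:
                report = subgroup_analysis(
                    table,
                    model,
                    label,
                    policy=config.continuity,
                    fixed_method=config.fixed_method,
                    force_method=overall.method,
                )
            except KeyError:
                logger.warning("label %r missing on some rows; subgroup skipped", label)
                continue
            model_summary["subgroups"][label] = {}
            for category, res in report.strata.items():
                if res is None:
                    logger.info(
                        "model %s, %s=%s: no informative studies",
                        model.name,
                        label,
                        category,
                    )
                    model_summary["subgroups"][label][category] = None
                    continue
                srow = {
                    "model": model.label,
                    "group_by": label,
                    "stratum": category,
                    **_result_row(res),
                }
                subgroup_rows.append(srow)
                model_summary["subgroups"][label][category] = srow

        if len(informative) >= 2:
            sens = leave_one_out(
                table, model, policy=config.continuity, fixed_method=config.fixed_method
            )
            for omitted, res in sens.omissions:
                sensitivity_rows.append(
                    {
                        "model": model.label,
                        "omitted": (
                            omitted.source.study_id if omitted.source else "<unknown>"
                        ),
                        **_result_row(res),
                    }
                )

        effects = [study_effect(t) for t in informative]
        if len(effects) >= 3:
            try:
                egger = egger_test(effects)
                begg = begg_test(effects, overall)
                bias = BiasReport(model=model, egger=egger, begg=begg)
                bias_rows.append(
                    {
                        "model": model.label,
                        "k": bias.k,
                        "egger_intercept": egger.intercept,
                        "egger_se": egger.se,
                        "egger_t": egger.t,
                        "egger_p": egger.p,
                        "begg_tau": begg.tau,
                        "begg_z": begg.z,
                        "begg_p": begg.p,
                    }
                )
                model_summary["bias"] = bias_rows[-1]
            except ValueError as err:
                logger.warning("model %s: bias tests skipped (%s)", model.name, err)
            funnel = funnel_data(effects)
            funnel.to_csv(
                out_dir / f"funnel_{model.name.lower()}.tsv", sep="\t", index=False
            )
        summary["models"][model.name] = model_summary

    if not overall_rows:
        raise ValueError("no model produced an informative analysis")

    pd.DataFrame(overall_rows).to_csv(out_dir / "overall.tsv", sep="\t", index=False)
    if subgroup_rows:
        pd.DataFrame(subgroup_rows).to_csv(
            out_dir / "subgroups.tsv", sep="\t", index=False
        )
    if sensitivity_rows:
        pd.DataFrame(sensitivity_rows).to_csv(
            out_dir / "sensitivity.tsv", sep="\t", index=False
        )
    if bias_rows:
        pd.DataFrame(bias_rows).to_csv(out_dir / "bias.tsv", sep="\t", index=False)
    hwe = hwe_table(table)
    hwe.to_csv(out_dir / "hwe.tsv", sep="\t", index=False)
    summary["hwe"] = json.loads(hwe.to_json(orient="records"))

    with open(out_dir / "summary.json", "w", encoding="utf-8") as handle:
        json.dump(summary, handle, indent=2, allow_nan=True)
    return summary
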