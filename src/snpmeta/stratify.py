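"""Subgroup meta-analysis and leave-one-out sensitivity analysis.

Subgroup analysis re-runs the full contingency -> pooling pipeline
inside each category of a grouping label (ethnicity, source of
controls, or any extra label carried by the table), including
per-stratum informativeness screening and per-stratum fixed/random
model selection. Sensitivity analysis re-pools the table k times,
omitting each informative study in turn, to show whether any single
cohort drives the pooled estimate or the heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .contingency import ContinuityPolicy, FourfoldTable, GeneticModel, model_tables
from .pooling import PooledResult, PoolingMethod, meta_analyse
from .study_io import StudyTable

__all__ = ["SubgroupReport", "SensitivityReport", "subgroup_analysis", "leave_one_out"]


@dataclass(frozen=True)
class SubgroupReport:
    """Per-stratum pooled results for one contrast and one grouping label.

    ``strata`` maps each category (in order of first appearance in the
    table) to its pooled result, or to ``None`` when the stratum has no
    informative study for this contrast.
    """

    model: GeneticModel
    group_by: str
    strata: Mapping[str, PooledResult | None]

    @property
    def total_k(self) -> int:
        return sum(r.k for r in self.strata.values() if r is not None)


@dataclass(frozen=True)
class SensitivityReport:
    """Leave-one-out re-pooling results for one contrast.

    One entry per informative study, pairing the omitted study's 2x2
    table with the pooled result over the remaining k-1 studies (method
    re-selected per subset).
    """

    model: GeneticModel
    omissions: tuple[tuple[FourfoldTable, PooledResult], ...]


def subgroup_analysis(
    table: StudyTable,
    model: GeneticModel,
    group_by: str,
    policy: ContinuityPolicy = ContinuityPolicy.ADD_HALF,
    fixed_method: PoolingMethod = PoolingMethod.FIXED_MH,
    force_method: PoolingMethod | None = None,
) -> SubgroupReport:
    """Pool each stratum of ``group_by`` separately under one contrast.

    Every record must carry the label. Model selection (fixed vs random
    by the heterogeneity rule) runs independently per stratum unless
    ``force_method`` pins one method for cross-stratum comparability.
    An empty stratum (no informative studies) is reported as ``None``
    rather than raising.
    """
    strata: dict[str, PooledResult | None] = {}
    for category in table.categories(group_by):
        subset = table.filter(group_by, category)
        informative, _ = model_tables(subset, model, policy)
        if not informative:
            strata[category] = None
            continue
        strata[category] = meta_analyse(
            informative, fixed_method=fixed_method, force_method=force_method
        )
    return SubgroupReport(model=model, group_by=group_by, strata=strata)


def leave_one_out(
    table: StudyTable,
    model: GeneticModel,
    policy: ContinuityPolicy = ContinuityPolicy.ADD_HALF,
    fixed_method: PoolingMethod = PoolingMethod.FIXED_MH,
) -> SensitivityReport:
    """Re-pool omitting each informative study in turn.

    Requires at least two informative studies overall. Each omission
    re-runs model selection on the remaining subset, mirroring how a
    reviewer would re-analyse the reduced evidence base.
    """
    informative, _ = model_tables(table, model, policy)
    if len(informative) < 2:
        raise ValueError(
            "leave-one-out requires at least 2 informative studies, "
            f"got {len(informative)}"
        )
    omissions = []
    for i, omitted in enumerate(informative):
        remaining = informative[:i] + informative[i + 1 :]
        pooled = meta_analyse(remaining, fixed_method=fixed_method)
        omissions.append((omitted, pooled))
    return SensitivityReport(model=model, omissions=tuple(omissions))
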