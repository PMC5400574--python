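"""Genetic-model contrasts: collapsing a 3-genotype table to a 2x2.

Each of the five standard contrasts turns a cohort's TT/TC/CC genotype
counts into a case/control 2x2 event table with cells

    a = case events     b = case non-events
    c = control events  d = control non-events

from which the odds ratio ``(a*d)/(b*c)`` is estimated downstream. The
effect allele is C throughout. A table is *informative* when it can
yield a finite, non-degenerate odds ratio: events present in at least
one arm and non-events present in at least one arm. Non-informative
tables are flagged (never rejected) and excluded from pooling for that
contrast only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

from .study_io import StudyRecord, StudyTable

__all__ = [
    "GeneticModel",
    "FourfoldTable",
    "ContinuityPolicy",
    "build_fourfold",
    "apply_continuity",
    "model_tables",
]


class GeneticModel(Enum):
    """The five genetic-model contrasts for a biallelic SNP (effect allele C)."""

    ALLELE = "C vs. T"
    DOMINANT = "CC + TC vs. TT"
    RECESSIVE = "CC vs. TT + TC"
    HOMOZYGOTE = "CC vs. TT"
    HETEROZYGOTE = "TC vs. TT"

    @property
    def label(self) -> str:
        return self.value


class ContinuityPolicy(Enum):
    """Zero-cell handling before taking logs.

    ``ADD_HALF`` adds 0.5 to all four cells of any study whose 2x2 has a
    zero cell (the convention of the mainstream meta-analysis software
    family); ``NONE`` leaves counts untouched, in which case a remaining
    zero cell makes the study effect undefined.
    """

    ADD_HALF = "add_half_all_cells_if_any_zero"
    NONE = "none"


@dataclass(frozen=True)
class FourfoldTable:
    """A 2x2 case/control event table for one study under one contrast."""

    a: float
    b: float
    c: float
    d: float
    model: GeneticModel
    corrected: bool = False
    informative: bool = True
    source: StudyRecord | None = None

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "FourfoldTable":
        """Swap the case and control rows (inverts the odds ratio)."""
        return replace(self, a=self.c, b=self.d, c=self.a, d=self.b)


_CONTRASTS = {
    # (a, b) from (tt, tc, cc); same map applies to the control row.
    GeneticModel.ALLELE: lambda tt, tc, cc: (2 * cc + tc, 2 * tt + tc),
    GeneticModel.DOMINANT: lambda tt, tc, cc: (cc + tc, tt),
    GeneticModel.RECESSIVE: lambda tt, tc, cc: (cc, tc + tt),
    GeneticModel.HOMOZYGOTE: lambda tt, tc, cc: (cc, tt),
    GeneticModel.HETEROZYGOTE: lambda tt, tc, cc: (tc, tt),
}


def build_fourfold(record: StudyRecord, model: GeneticModel) -> FourfoldTable:
    """Collapse one cohort's genotype counts under a genetic-model contrast.

    The homozygote contrast drops TC carriers and the heterozygote
    contrast drops CC carriers entirely, so those margins are smaller
    than the cohort size.
    """
    contrast = _CONTRASTS[model]
    a, b = contrast(record.case_tt, record.case_tc, record.case_cc)
    c, d = contrast(record.ctrl_tt, record.ctrl_tc, record.ctrl_cc)
    informative = not ((a == 0 and c == 0) or (b == 0 and d == 0))
    return FourfoldTable(
        a=float(a),
        b=float(b),
        c=float(c),
        d=float(d),
        model=model,
        informative=informative,
        source=record,
    )


def apply_continuity(
    table: FourfoldTable, policy: ContinuityPolicy = ContinuityPolicy.ADD_HALF
) -> FourfoldTable:
    """Apply the zero-cell continuity policy to an informative table."""
    if not table.informative:
        raise ValueError("continuity correction applies to informative tables only")
    if policy is ContinuityPolicy.NONE:
        return table
    if math.isclose(min(table.a, table.b, table.c, table.d), 0.0):
        return replace(
            table,
            a=table.a + 0.5,
            b=table.b + 0.5,
            c=table.c + 0.5,
            d=table.d + 0.5,
            corrected=True,
        )
    return table


def model_tables(
    table: StudyTable,
    model: GeneticModel,
    policy: ContinuityPolicy = ContinuityPolicy.ADD_HALF,
) -> tuple[list[FourfoldTable], list[FourfoldTable]]:
    """Build all 2x2 tables for a contrast and split by informativeness.

    Returns ``(informative, excluded)``; informative tables come back
    with the continuity policy already applied, in row order.
    """
    informative: list[FourfoldTable] = []
    excluded: list[FourfoldTable] = []
    for record in table:
        fourfold = build_fourfold(record, model)
        if fourfold.informative:
            informative.append(apply_continuity(fourfold, policy))
        else:
            excluded.append(fourfold)
    return informative, excluded
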