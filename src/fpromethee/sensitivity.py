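"""Criterion-omission sensitivity analysis.

Dropping criteria from the study (e.g. the low-weight specimen-volume and
specimen-type criteria), renormalizing the surviving weights, re-running
the full outranking pipeline and comparing the perturbed ranking against
the baseline quantifies how much the complete order depends on those
criteria.  Agreement is summarised with Kendall's tau on rank positions
plus per-alternative signed rank displacements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau

from .outranking import (
    DEFAULT_EPSILON,
    AnalysisResult,
    DecisionMatrix,
    DecisionMatrixError,
    Ranking,
    run_full_analysis,
)

__all__ = ["SensitivityReport", "omit_criteria", "compare_rankings", "omission_analysis"]


@dataclass(frozen=True)
class SensitivityReport:
    """Outcome of a ranking-stability comparison.

    ``displacement`` maps each alternative to (baseline rank - perturbed
    rank): positive means the alternative moved up after the
    perturbation.  ``tau`` is Kendall's tau-b of the two rank vectors
    (1 means identical order, -1 a full reversal).
    """

    omitted: tuple[str, ...]
    baseline: Ranking
    perturbed: Ranking
    displacement: dict[str, int]
    tau: float

    @property
    def unchanged(self) -> bool:
        return all(d == 0 for d in self.displacement.values())


def omit_criteria(m: DecisionMatrix, ids: list[str] | tuple[str, ...]) -> DecisionMatrix:
    """Return the matrix without the given criterion columns.

    The surviving criteria keep their fuzzy weights (renormalization to
    sum 1 happens inside the analysis, as always) and data-driven spreads
    are recomputed from the surviving columns.  Omitting everything, or
    an unknown id, is an error; an empty omission list returns an
    equivalent matrix.
    """
    drop = {i.strip() for i in ids if i.strip()}
    known = set(m.criterion_ids)
    unknown = drop - known
    if unknown:
        raise DecisionMatrixError(
            f"unknown criterion id(s) {sorted(unknown)}; matrix has {sorted(known)}"
        )
    keep = [j for j, c in enumerate(m.criteria) if c.id not in drop]
    if not keep:
        raise DecisionMatrixError("cannot omit every criterion")
    return DecisionMatrix(
        alternatives=m.alternatives,
        criteria=tuple(m.criteria[j] for j in keep),
        values=m.values[:, keep],
        sd_mode=m.sd_mode,
    )


def compare_rankings(base: Ranking, perturbed: Ranking) -> SensitivityReport:
    """Kendall tau and per-alternative displacement between two rankings."""
    labels = sorted(lab for _, lab, _ in base.rows)
    labels_p = sorted(lab for _, lab, _ in perturbed.rows)
    if labels != labels_p:
        raise ValueError(
            "rankings cover different alternative sets: "
            f"{labels} vs {labels_p}"
        )
    base_rank = {lab: r for r, lab, _ in base.rows}
    pert_rank = {lab: r for r, lab, _ in perturbed.rows}
    disp = {lab: base_rank[lab] - pert_rank[lab] for lab in labels}
    tau, _ = kendalltau(
        [base_rank[lab] for lab in labels], [pert_rank[lab] for lab in labels]
    )
    return SensitivityReport(
        omitted=(),
        baseline=base,
        perturbed=perturbed,
        displacement=disp,
        tau=float(tau),
    )


def omission_analysis(
    m: DecisionMatrix,
    ids: list[str] | tuple[str, ...],
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[SensitivityReport, AnalysisResult, AnalysisResult]:
    """Run baseline and criterion-omitted analyses and compare rankings."""
    base = run_full_analysis(m, epsilon)
    reduced = omit_criteria(m, ids)
    pert = run_full_analysis(reduced, epsilon)
    report = compare_rankings(base.ranking, pert.ranking)
    report = SensitivityReport(
        omitted=tuple(sorted({i.strip() for i in ids if i.strip()})),
        baseline=report.baseline,
        perturbed=report.perturbed,
        displacement=report.displacement,
        tau=report.tau,
    )
    return report, base, pert
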