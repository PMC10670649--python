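"""Synthetic decision-matrix generator for the UTI diagnostic-test study.

The original 16 x 15 expert evaluation matrix behind the UTI test ranking
was never published, so end-to-end behaviour is exercised on synthetic
matrices with the same statistical structure: performance criteria
(sensitivity, specificity, PPV, NPV) as percentages in [50, 100],
right-skewed positive cost and turnaround-time criteria to be minimized,
five-level linguistic criteria defuzzified with the Yager centroid, and
binary capability criteria (point-of-care, direct-from-sample, AST).
:func:`replicate_uti_design` reproduces the study design exactly: the 16
test alternatives and the 15 criteria C1-C15 with their published
linguistic weight terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fuzzy import default_scale, resolve_term, yager_defuzzify
from .outranking import DecisionMatrix, DecisionMatrixError
from .preference import Criterion, PreferenceFunctionSpec

__all__ = [
    "CriterionSpec",
    "SyntheticStudyConfig",
    "replicate_uti_design",
    "uti_study_config",
    "generate_matrix",
    "plant_dominant_alternative",
]

_CLASSES = ("percentage", "cost_like", "time_like", "linguistic5", "binary")


@dataclass(frozen=True)
class CriterionSpec:
    """Generator-side description of one criterion.

    ``cls`` picks the cell distribution; ``weight_label`` is a term on
    the active linguistic scale; ``direction`` follows the usual MCDA
    convention (costs and times are minimized).
    """

    id: str
    name: str
    cls: str
    direction: str = "maximize"
    weight_label: str = "High"

    def __post_init__(self) -> None:
        if self.cls not in _CLASSES:
            raise ValueError(
                f"criterion {self.id}: unknown class {self.cls!r}; choose from {_CLASSES}"
            )

    def to_criterion(self) -> Criterion:
        return Criterion(
            id=self.id,
            name=self.name,
            direction=self.direction,  # type: ignore[arg-type]
            weight=resolve_term(self.weight_label),
            pf=PreferenceFunctionSpec(family="gaussian"),
        )


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Configuration for one synthetic study draw."""

    criteria: tuple[CriterionSpec, ...]
    alternatives: tuple[str, ...]
    seed: int = 0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.alternatives) < 2:
            raise ValueError("need at least 2 alternatives")
        if self.noise_scale <= 0:
            raise ValueError(f"noise_scale must be > 0, got {self.noise_scale}")
        scale = default_scale()
        for spec in self.criteria:
            if spec.weight_label not in scale:
                raise ValueError(
                    f"criterion {spec.id}: weight label {spec.weight_label!r} "
                    f"not on the linguistic scale {list(scale.labels)}"
                )

    @property
    def n_alternatives(self) -> int:
        return len(self.alternatives)


#: The 16 UTI diagnostic tests of the study design (A1-A16).
UTI_ALTERNATIVES: tuple[str, ...] = (
    "Nitrite",
    "Leucocyte esterase",
    "Combined LE and nitrite",
    "Catalase",
    "Microscopy",
    "Conventional culture",
    "Chromogenic agar",
    "Multiplex PCR",
    "MALDI-TOF-MS",
    "Biosensor",
    "Urine flow cytometry",
    "Microfluidics",
    "Sequence-based diagnostics",
    "Real-time microscopy systems",
    "FISH",
    "Immunologically based assay",
)

# C1-C15 with their elicited weight terms; directions and distribution
# classes are modelling assumptions (see docs/methods.md), not published
# facts: specimen volume, cost and result time are minimized, everything
# else maximized.
_UTI_CRITERIA: tuple[CriterionSpec, ...] = (
    CriterionSpec("C1", "Specimen volume", "cost_like", "minimize", "Very Low"),
    CriterionSpec("C2", "Specimen type", "linguistic5", "maximize", "Low"),
    CriterionSpec("C3", "Cost", "cost_like", "minimize", "High"),
    CriterionSpec("C4", "Efficiency", "linguistic5", "maximize", "High"),
    CriterionSpec("C5", "Result time", "time_like", "minimize", "Very High"),
    CriterionSpec("C6", "Point of care testing", "binary", "maximize", "Very High"),
    CriterionSpec("C7", "Applicability/direct from sample", "binary", "maximize", "Moderate"),
    CriterionSpec("C8", "Practicality for patients", "linguistic5", "maximize", "Moderate"),
    CriterionSpec("C9", "Practicality for personnel", "linguistic5", "maximize", "Moderate"),
    CriterionSpec("C10", "Limitation/pathogen identification", "linguistic5", "maximize", "High"),
    CriterionSpec("C11", "Sensitivity", "percentage", "maximize", "High"),
    CriterionSpec("C12", "Specificity", "percentage", "maximize", "High"),
    CriterionSpec("C13", "PPV", "percentage", "maximize", "High"),
    CriterionSpec("C14", "NPV", "percentage", "maximize", "High"),
    CriterionSpec("C15", "AST capability", "binary", "maximize", "High"),
)


def replicate_uti_design() -> tuple[tuple[CriterionSpec, ...], tuple[str, ...]]:
    """The UTI study design: 15 weighted criteria and 16 test alternatives."""
    return _UTI_CRITERIA, UTI_ALTERNATIVES


def uti_study_config(seed: int = 0, noise_scale: float = 1.0) -> SyntheticStudyConfig:
    """Convenience: a :class:`SyntheticStudyConfig` for the full UTI design."""
    criteria, alternatives = replicate_uti_design()
    return SyntheticStudyConfig(
        criteria=criteria, alternatives=alternatives, seed=seed, noise_scale=noise_scale
    )


def _draw_column(spec: CriterionSpec, n: int, rng: np.random.Generator, ns: float) -> np.ndarray:
    if spec.cls == "percentage":
        # Beta(5, 2) stretched onto [50, 100]: mode near 85, left tail to 50,
        # the typical spread of published diagnostic accuracy figures.
        return 50.0 + 50.0 * rng.beta(5.0 / ns, 2.0 / ns, size=n)
    if spec.cls == "cost_like":
        # right-skewed positive, ~an order of magnitude between cheap
        # dipsticks and instrument-bound platforms
        return rng.lognormal(mean=2.0, sigma=0.6 * ns, size=n)
    if spec.cls == "time_like":
        # minutes-to-result, heavy right tail (culture-style waits)
        return rng.lognormal(mean=3.5, sigma=0.9 * ns, size=n)
    if spec.cls == "linguistic5":
        scale = default_scale()
        crisp = np.array([yager_defuzzify(t) for _, t in scale.terms])
        return crisp[rng.integers(0, len(crisp), size=n)]
    if spec.cls == "binary":
        return rng.integers(0, 2, size=n).astype(float)
    raise ValueError(f"unknown criterion class {spec.cls!r}")  # pragma: no cover


def generate_matrix(cfg: SyntheticStudyConfig) -> DecisionMatrix:
    """Draw a complete crisp decision matrix; pure function of the config.

    Linguistic cells are drawn uniformly over the five scale terms and
    defuzzified, so the matrix is already crisp and ready for analysis.
    """
    rng = np.random.default_rng(cfg.seed)
    cols = [
        _draw_column(spec, cfg.n_alternatives, rng, cfg.noise_scale)
        for spec in cfg.criteria
    ]
    return DecisionMatrix(
        alternatives=cfg.alternatives,
        criteria=tuple(spec.to_criterion() for spec in cfg.criteria),
        values=np.column_stack(cols),
    )


def plant_dominant_alternative(m: DecisionMatrix, label: str) -> DecisionMatrix:
    """Make one alternative weakly dominant: best observed value on every
    criterion, strictly better by a tiny margin on the first positively
    weighted criterion.

    Refuses to plant when a *different* alternative already matches the
    per-criterion optimum everywhere — dominance must stay unique for the
    fixture to be meaningful.
    """
    if label not in m.alternatives:
        raise DecisionMatrixError(f"alternative {label!r} not in matrix")
    target = m.alternatives.index(label)

    best = np.empty(m.k)
    for j, c in enumerate(m.criteria):
        col = m.values[:, j]
        best[j] = col.min() if c.direction == "minimize" else col.max()

    for i, lab in enumerate(m.alternatives):
        if i == target:
            continue
        if all(
            (m.values[i, j] <= best[j] if c.direction == "minimize" else m.values[i, j] >= best[j])
            for j, c in enumerate(m.criteria)
        ):
            raise DecisionMatrixError(
                f"alternative {lab!r} is already weakly dominant; "
                "cannot plant a second dominant alternative"
            )

    new_vals = m.values.copy()
    new_vals[target, :] = best

    margin_j = next(
        (j for j, c in enumerate(m.criteria) if c.crisp_weight() > 0), None
    )
    if margin_j is None:
        raise DecisionMatrixError("no positively weighted criterion to break ties on")
    eps = 1e-9 * max(1.0, abs(best[margin_j]))
    if m.criteria[margin_j].direction == "minimize":
        new_vals[target, margin_j] = best[margin_j] - eps
    else:
        new_vals[target, margin_j] = best[margin_j] + eps

    return replace(m, values=new_vals)
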