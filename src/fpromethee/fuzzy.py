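"""Triangular fuzzy numbers, linguistic scales and Yager defuzzification.

Experts express criterion weights (and vague criterion evaluations) as
verbal terms on a five-level linguistic scale; each term maps to a
triangular fuzzy number (a, b, c) whose membership rises linearly from a
to the mode b and falls to c.  Before the outranking analysis every fuzzy
quantity is collapsed to a crisp value with the Yager index — the centroid
of the triangular membership surface, (a + b + c) / 3 — and the crisp
weights are normalized to sum to one so that the weighted preference index
stays in the unit interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TriangularFuzzyNumber",
    "LinguisticScale",
    "WeightVector",
    "make_tfn",
    "resolve_term",
    "yager_defuzzify",
    "normalize_weights",
    "default_scale",
    "FuzzyValidationError",
]


class FuzzyValidationError(ValueError):
    """Raised for malformed fuzzy numbers, scales or weight vectors."""


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """A triangular fuzzy number (a, b, c) with a <= b <= c.

    ``a`` and ``c`` bound the support; membership equals 1 exactly at the
    modal point ``b`` and 0 outside [a, c].  The degenerate case
    a == b == c represents a crisp number.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("b", self.b), ("c", self.c)):
            if not np.isfinite(v):
                raise FuzzyValidationError(f"TFN component {name}={v!r} is not finite")
        if not (self.a <= self.b <= self.c):
            raise FuzzyValidationError(
                f"TFN ordering violated: need a <= b <= c, got ({self.a}, {self.b}, {self.c})"
            )

    def defuzzify(self) -> float:
        return yager_defuzzify(self)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


def make_tfn(a: float, b: float, c: float) -> TriangularFuzzyNumber:
    """Validate and build a triangular fuzzy number."""
    return TriangularFuzzyNumber(float(a), float(b), float(c))


def yager_defuzzify(t: TriangularFuzzyNumber) -> float:
    """Crisp value of a TFN: the centroid of its membership surface.

    For a triangular membership function the centre of weight is the mean
    of the three defining points, (a + b + c) / 3.  A crisp TFN (x, x, x)
    maps to x exactly.
    """
    return (t.a + t.b + t.c) / 3.0


@dataclass(frozen=True)
class LinguisticScale:
    """An ordered verbal scale, each term bound to a TFN.

    Terms must defuzzify to strictly increasing values from the weakest
    to the strongest label; lookups are case-insensitive after trimming.
    """

    terms: tuple[tuple[str, TriangularFuzzyNumber], ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise FuzzyValidationError("linguistic scale must contain at least one term")
        labels = [lab.strip().lower() for lab, _ in self.terms]
        if len(set(labels)) != len(labels):
            raise FuzzyValidationError(f"duplicate labels in linguistic scale: {labels}")
        vals = [yager_defuzzify(t) for _, t in self.terms]
        if any(v2 <= v1 for v1, v2 in zip(vals, vals[1:])):
            raise FuzzyValidationError(
                "scale terms must defuzzify to strictly increasing values, "
                f"got {vals} for labels {[lab for lab, _ in self.terms]}"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.terms)

    def __contains__(self, label: str) -> bool:
        key = label.strip().lower()
        return any(lab.strip().lower() == key for lab, _ in self.terms)

    def __getitem__(self, label: str) -> TriangularFuzzyNumber:
        return resolve_term(label, self)


#: Five-level evaluation scale used for both criterion weights and vague
#: (linguistic) criterion evaluations.
_DEFAULT_TERMS = (
    ("Very Low", TriangularFuzzyNumber(0.0, 0.0, 0.25)),
    ("Low", TriangularFuzzyNumber(0.0, 0.25, 0.50)),
    ("Moderate", TriangularFuzzyNumber(0.25, 0.50, 0.75)),
    ("High", TriangularFuzzyNumber(0.50, 0.75, 1.0)),
    ("Very High", TriangularFuzzyNumber(0.75, 1.0, 1.0)),
)


def default_scale() -> LinguisticScale:
    """The built-in five-level Very Low ... Very High scale."""
    return LinguisticScale(_DEFAULT_TERMS)


def resolve_term(label: str, scale: LinguisticScale | None = None) -> TriangularFuzzyNumber:
    """Look up a verbal term on a linguistic scale (default: built-in 5-level).

    Matching trims whitespace and ignores case.  Unknown labels raise with
    the list of valid labels.
    """
    if scale is None:
        scale = default_scale()
    key = label.strip().lower()
    for lab, tfn in scale.terms:
        if lab.strip().lower() == key:
            return tfn
    raise KeyError(
        f"unknown linguistic term {label!r}; valid labels: {list(scale.labels)}"
    )


@dataclass(frozen=True)
class WeightVector:
    """Crisp per-criterion weights w_k, optionally normalized to sum 1."""

    values: tuple[float, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise FuzzyValidationError("weight vector must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise FuzzyValidationError(f"non-finite weight in {self.values}")
        if np.any(arr < 0):
            raise FuzzyValidationError(f"negative weight in {self.values}")
        if self.normalized and abs(arr.sum() - 1.0) > 1e-12:
            raise FuzzyValidationError(
                f"weights flagged normalized but sum to {arr.sum()!r}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def normalize_weights(raw: Sequence[float] | Iterable[float]) -> WeightVector:
    """Divide non-negative raw weights by their sum.

    With weights summing to one the weighted preference index is a convex
    combination of per-criterion degrees and therefore lies in [0, 1].
    All-zero or negative input is rejected.
    """
    arr = np.asarray(list(raw), dtype=float)
    if arr.size == 0:
        raise FuzzyValidationError("cannot normalize an empty weight vector")
    if np.any(arr < 0):
        raise FuzzyValidationError(f"negative weight in {arr.tolist()}")
    total = arr.sum()
    if total <= 0:
        raise FuzzyValidationError("all-zero weight vector cannot be normalized")
    out = arr / total
    # guard against accumulated rounding: renormalize the tiny residual
    out = out / out.sum()
    return WeightVector(tuple(float(v) for v in out), normalized=True)
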