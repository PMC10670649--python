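"""Criterion specification and pairwise preference functions.

Each criterion has a direction (maximize or minimize), a fuzzy weight, and
a preference function P(d) mapping the signed difference d between two
alternatives into a preference degree in [0, 1].  The default family is
the Gaussian function

    P(d) = 0                       for d <= 0
    P(d) = 1 - exp(-d^2 / (2 s^2)) for d > 0

with the spread s taken, unless overridden, as the population standard
deviation of the criterion's column across all alternatives — so tiny
differences yield near-zero preference and the function saturates
smoothly.  The other standard PROMETHEE families (usual, U-shape, V-shape,
level, linear) are available behind explicit configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .fuzzy import TriangularFuzzyNumber, yager_defuzzify

__all__ = [
    "Direction",
    "PreferenceFunctionSpec",
    "Criterion",
    "signed_difference",
    "criterion_sd",
    "gaussian_preference",
    "preference_degree",
    "PreferenceConfigError",
]

Direction = Literal["maximize", "minimize"]

_FAMILIES = ("usual", "u_shape", "v_shape", "level", "linear", "gaussian")


class PreferenceConfigError(ValueError):
    """Raised for invalid preference-function or criterion configuration."""


@dataclass(frozen=True)
class PreferenceFunctionSpec:
    """A preference-function family with its thresholds.

    ``q`` is the indifference threshold, ``p`` the strict-preference
    threshold, ``s`` the Gaussian spread; each in the criterion's units.
    Only the thresholds the family uses need to be set; the Gaussian
    spread may be left None to be estimated from the data.
    """

    family: str = "gaussian"
    q: float | None = None
    p: float | None = None
    s: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise PreferenceConfigError(
                f"unknown preference family {self.family!r}; choose from {_FAMILIES}"
            )
        if self.q is not None and self.q < 0:
            raise PreferenceConfigError(f"indifference threshold q={self.q} < 0")
        if self.p is not None and self.p < 0:
            raise PreferenceConfigError(f"preference threshold p={self.p} < 0")
        if self.q is not None and self.p is not None and self.q > self.p:
            raise PreferenceConfigError(f"need q <= p, got q={self.q}, p={self.p}")
        if self.s is not None and self.s < 0:
            raise PreferenceConfigError(f"gaussian spread s={self.s} < 0")

    def _require(self, name: str) -> float:
        v = getattr(self, name)
        if v is None:
            raise PreferenceConfigError(
                f"family {self.family!r} requires threshold {name!r}"
            )
        return float(v)


@dataclass(frozen=True)
class Criterion:
    """One evaluation criterion: direction, fuzzy weight, preference spec.

    ``weight`` is the fuzzy weight as elicited; its crisp (defuzzified)
    value is exposed via :meth:`crisp_weight` and normalized at the
    decision-matrix level.  ``pf.s`` overrides the data-driven Gaussian
    spread when set.
    """

    id: str
    name: str = ""
    direction: Direction = "maximize"
    weight: TriangularFuzzyNumber = TriangularFuzzyNumber(0.5, 0.75, 1.0)
    pf: PreferenceFunctionSpec = field(default_factory=PreferenceFunctionSpec)

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize"):
            raise PreferenceConfigError(
                f"criterion {self.id}: direction must be 'maximize' or 'minimize', "
                f"got {self.direction!r}"
            )

    def crisp_weight(self) -> float:
        return yager_defuzzify(self.weight)


def signed_difference(va: float, vb: float, direction: Direction) -> float:
    """Direction-signed difference d between two evaluations.

    Positive d means alternative ``a`` is preferred on this criterion:
    for a maximized criterion d = va - vb, for a minimized one (cost,
    turnaround time) the sign flips so that the lower value wins.
    """
    if direction == "maximize":
        return va - vb
    if direction == "minimize":
        return vb - va
    raise PreferenceConfigError(f"unknown direction {direction!r}")


def criterion_sd(values: Sequence[float]) -> float:
    """Population standard deviation (divisor n) of a criterion column."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("criterion_sd needs at least one value")
    return float(np.std(arr))


def gaussian_preference(d, s: float):
    """Gaussian preference degree: 0 for d <= 0, else 1 - exp(-d^2/(2 s^2)).

    Accepts scalars or arrays in ``d``.  The degenerate spread s = 0 (a
    criterion on which all alternatives coincide) yields preference 0
    everywhere: the criterion cannot discriminate.  Negative s is an error.
    """
    if s < 0:
        raise PreferenceConfigError(f"gaussian spread must be >= 0, got {s}")
    d_arr = np.asarray(d, dtype=float)
    if s == 0:
        out = np.zeros_like(d_arr)
    else:
        # -expm1 keeps precision for tiny d/s where 1 - exp(-x) underflows
        out = np.where(d_arr > 0, -np.expm1(-np.square(d_arr) / (2.0 * s * s)), 0.0)
    if np.isscalar(d) or d_arr.ndim == 0:
        return float(out)
    return out


def preference_degree(d, spec: PreferenceFunctionSpec, s_data: float | None = None):
    """Preference degree P(d) for any supported family.

    ``s_data`` supplies the data-driven Gaussian spread when the spec does
    not fix one.  All families return 0 for d <= 0, are nondecreasing in d
    and bounded by 1.  Scalar in, scalar out; arrays are vectorized.
    """
    d_arr = np.asarray(d, dtype=float)
    fam = spec.family
    if fam == "gaussian":
        s = spec.s if spec.s is not None else s_data
        if s is None:
            raise PreferenceConfigError(
                "gaussian preference needs a spread: set pf.s or pass s_data"
            )
        out = np.asarray(gaussian_preference(d_arr, s))
    elif fam == "usual":
        out = np.where(d_arr > 0, 1.0, 0.0)
    elif fam == "u_shape":
        q = spec._require("q")
        out = np.where(d_arr > q, 1.0, 0.0)
    elif fam == "v_shape":
        p = spec._require("p")
        if p == 0:
            out = np.where(d_arr > 0, 1.0, 0.0)
        else:
            out = np.clip(d_arr / p, 0.0, 1.0)
            out = np.where(d_arr > 0, out, 0.0)
    elif fam == "level":
        q = spec._require("q")
        p = spec._require("p")
        out = np.where(d_arr > p, 1.0, np.where(d_arr > q, 0.5, 0.0))
    elif fam == "linear":
        q = spec._require("q")
        p = spec._require("p")
        if p == q:
            out = np.where(d_arr > p, 1.0, 0.0)
        else:
            out = np.clip((d_arr - q) / (p - q), 0.0, 1.0)
            out = np.where(d_arr > q, out, 0.0)
    else:  # pragma: no cover - guarded in PreferenceFunctionSpec
        raise PreferenceConfigError(f"unknown family {fam!r}")
    if np.isscalar(d) or d_arr.ndim == 0:
        return float(out)
    return out
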