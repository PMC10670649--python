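"""The PROMETHEE outranking core.

Given a crisp decision matrix f_k(a_t) (n alternatives x K criteria),
normalized weights w_k and per-criterion preference functions P_k, the
method computes

    pi(a, b)   = sum_k w_k P_k(d_k(a, b))          (preference index)
    Phi+(a)    = (1/(n-1)) sum_{b != a} pi(a, b)   (leaving flow)
    Phi-(a)    = (1/(n-1)) sum_{b != a} pi(b, a)   (entering flow)
    Phi_net(a) = Phi+(a) - Phi-(a)                 (net flow)

PROMETHEE I classifies every ordered pair as preference / indifference /
incomparability from the two partial flows; PROMETHEE II ranks completely
by net flow.  The unicriterion decomposition splits the net flow into
per-criterion contributions phi_k with sum_k w_k phi_k = Phi_net,
exposing each alternative's strengths (phi_k > 0) and weaknesses
(phi_k < 0) criterion by criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fuzzy import WeightVector, normalize_weights
from .preference import Criterion, criterion_sd, preference_degree

__all__ = [
    "DecisionMatrix",
    "FlowTable",
    "PartialOrder",
    "Ranking",
    "AnalysisResult",
    "preference_index",
    "preference_matrix",
    "leaving_flow",
    "entering_flow",
    "net_flow",
    "promethee1",
    "promethee2",
    "unicriterion_net_flows",
    "run_full_analysis",
    "DecisionMatrixError",
]

DEFAULT_EPSILON = 1e-9


class DecisionMatrixError(ValueError):
    """Raised for incomplete or inconsistent decision matrices."""


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives x criteria table of crisp evaluations f_k(a_t).

    ``values`` is an (n, K) float array aligned with ``alternatives`` and
    ``criteria``.  Weights are normalized lazily over the criteria's
    defuzzified fuzzy weights; ``sd_mode`` selects the spread estimator
    for data-driven Gaussian criteria ("population" divisor n, the
    default, or "sample" divisor n-1).
    """

    alternatives: tuple[str, ...]
    criteria: tuple[Criterion, ...]
    values: np.ndarray
    sd_mode: str = "population"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n, k = len(self.alternatives), len(self.criteria)
        if n < 2:
            raise DecisionMatrixError(f"need at least 2 alternatives, got {n}")
        if k < 1:
            raise DecisionMatrixError("need at least 1 criterion")
        if vals.shape != (n, k):
            raise DecisionMatrixError(
                f"values shape {vals.shape} does not match "
                f"{n} alternatives x {k} criteria"
            )
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise DecisionMatrixError(
                f"non-finite cell at alternative {self.alternatives[bad[0]]!r}, "
                f"criterion {self.criteria[bad[1]].id!r}"
            )
        if len(set(self.alternatives)) != n:
            raise DecisionMatrixError("alternative labels must be unique")
        ids = [c.id for c in self.criteria]
        if len(set(ids)) != k:
            raise DecisionMatrixError(f"criterion ids must be unique, got {ids}")
        if self.sd_mode not in ("population", "sample"):
            raise DecisionMatrixError(
                f"sd_mode must be 'population' or 'sample', got {self.sd_mode!r}"
            )

    @property
    def n(self) -> int:
        return len(self.alternatives)

    @property
    def k(self) -> int:
        return len(self.criteria)

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    def normalized_weights(self) -> WeightVector:
        return normalize_weights([c.crisp_weight() for c in self.criteria])

    def column(self, cid: str) -> np.ndarray:
        idx = self.criterion_ids.index(cid)
        return self.values[:, idx]

    def spreads(self) -> np.ndarray:
        """Per-criterion Gaussian spread: override if set, else column sd."""
        ddof = 0 if self.sd_mode == "population" else 1
        out = np.empty(self.k)
        for j, c in enumerate(self.criteria):
            if c.pf.family == "gaussian" and c.pf.s is not None:
                out[j] = c.pf.s
            else:
                col = self.values[:, j]
                out[j] = float(np.std(col, ddof=ddof)) if col.size > ddof else 0.0
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.alternatives), columns=list(self.criterion_ids)
        )


@dataclass(frozen=True)
class FlowTable:
    """Per-alternative leaving (Phi+), entering (Phi-) and net flows."""

    alternatives: tuple[str, ...]
    phi_plus: np.ndarray
    phi_minus: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi_plus", np.asarray(self.phi_plus, dtype=float))
        object.__setattr__(self, "phi_minus", np.asarray(self.phi_minus, dtype=float))
        n = len(self.alternatives)
        if self.phi_plus.shape != (n,) or self.phi_minus.shape != (n,):
            raise ValueError("flow arrays must match the alternative labels")

    @property
    def phi_net(self) -> np.ndarray:
        return self.phi_plus - self.phi_minus

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phi_plus": self.phi_plus,
                "phi_minus": self.phi_minus,
                "phi_net": self.phi_net,
            },
            index=list(self.alternatives),
        )


@dataclass(frozen=True)
class PartialOrder:
    """PROMETHEE I pairwise relations.

    ``relations`` holds, for each ordered pair, one of ``"P"`` (row
    preferred over column), ``"P-"`` (column preferred), ``"I"``
    (indifferent), ``"R"`` (incomparable: crossed dominance of the two
    partial flows) or ``"self"`` on the diagonal.
    """

    alternatives: tuple[str, ...]
    relations: np.ndarray  # dtype object / str

    def relation(self, a: str, b: str) -> str:
        i = self.alternatives.index(a)
        j = self.alternatives.index(b)
        return str(self.relations[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.relations, index=list(self.alternatives), columns=list(self.alternatives)
        )


@dataclass(frozen=True)
class Ranking:
    """PROMETHEE II complete order: (rank, alternative, net flow) rows.

    Sorted by net flow descending; net flows equal within the comparison
    tolerance share a rank (competition ranking: 1, 2, 2, 4).
    """

    rows: tuple[tuple[int, str, float], ...]

    @property
    def order(self) -> tuple[str, ...]:
        return tuple(label for _, label, _ in self.rows)

    def rank_of(self, label: str) -> int:
        for rank, lab, _ in self.rows:
            if lab == label:
                return rank
        raise KeyError(f"alternative {label!r} not in ranking")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r, lab, phi) for r, lab, phi in self.rows],
            columns=["rank", "alternative", "phi_net"],
        )


@dataclass(frozen=True)
class AnalysisResult:
    """Bundle returned by :func:`run_full_analysis`."""

    matrix: DecisionMatrix
    weights: WeightVector
    pi: np.ndarray
    flows: FlowTable
    partial_order: PartialOrder
    ranking: Ranking
    profile: pd.DataFrame  # alternatives x criteria unicriterion net flows


def _pairwise_degrees(m: DecisionMatrix, j: int, spreads: np.ndarray) -> np.ndarray:
    """n x n matrix of P_j(d) for criterion j, direction-signed."""
    col = m.values[:, j]
    diff = col[:, None] - col[None, :]
    if m.criteria[j].direction == "minimize":
        diff = -diff
    return np.asarray(
        preference_degree(diff, m.criteria[j].pf, s_data=float(spreads[j]))
    )


def preference_matrix(m: DecisionMatrix, w: WeightVector | None = None) -> np.ndarray:
    """Full n x n preference-index matrix pi(a_t, a_t').

    Weighted sum over criteria of pairwise preference degrees; the
    diagonal is zero and, with normalized weights, every entry lies in
    [0, 1].
    """
    if w is None:
        w = m.normalized_weights()
    if not w.normalized:
        raise DecisionMatrixError(
            "weights must be normalized (sum 1); use normalize_weights"
        )
    if len(w) != m.k:
        raise DecisionMatrixError(
            f"weight vector length {len(w)} != number of criteria {m.k}"
        )
    spreads = m.spreads()
    warr = w.as_array()
    pi = np.zeros((m.n, m.n))
    for j in range(m.k):
        pi += warr[j] * _pairwise_degrees(m, j, spreads)
    np.fill_diagonal(pi, 0.0)
    return pi


def preference_index(
    t: str, t_prime: str, m: DecisionMatrix, w: WeightVector | None = None
) -> float:
    """pi(t, t'): degree to which t is preferred over t' across criteria."""
    if t == t_prime:
        raise DecisionMatrixError("preference index is defined for distinct alternatives")
    pi = preference_matrix(m, w)
    i = m.alternatives.index(t)
    j = m.alternatives.index(t_prime)
    return float(pi[i, j])


def _check_pi(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.ndim != 2 or pi.shape[0] != pi.shape[1]:
        raise ValueError(f"preference matrix must be square, got shape {pi.shape}")
    if pi.shape[0] < 2:
        raise ValueError("outranking flows need at least 2 alternatives")
    return pi


def leaving_flow(pi: np.ndarray) -> np.ndarray:
    """Phi+ for every alternative: row mean of pi excluding the diagonal."""
    pi = _check_pi(pi)
    n = pi.shape[0]
    return (pi.sum(axis=1) - np.diag(pi)) / (n - 1)


def entering_flow(pi: np.ndarray) -> np.ndarray:
    """Phi- for every alternative: column mean of pi excluding the diagonal."""
    pi = _check_pi(pi)
    n = pi.shape[0]
    return (pi.sum(axis=0) - np.diag(pi)) / (n - 1)


def net_flow(phi_plus, phi_minus):
    """Phi_net = Phi+ - Phi- (scalar or elementwise)."""
    out = np.asarray(phi_plus, dtype=float) - np.asarray(phi_minus, dtype=float)
    if out.ndim == 0:
        return float(out)
    return out


def compute_flows(m: DecisionMatrix, w: WeightVector | None = None) -> FlowTable:
    """Leaving/entering/net flows of a decision matrix."""
    pi = preference_matrix(m, w)
    return FlowTable(m.alternatives, leaving_flow(pi), entering_flow(pi))


def promethee1(flows: FlowTable, epsilon: float = DEFAULT_EPSILON) -> PartialOrder:
    """PROMETHEE I partial order from the two partial flows.

    With equality judged to absolute tolerance ``epsilon``: a P b when a's
    leaving flow is higher and its entering flow not higher (or leaving
    equal and entering strictly lower); a I b when both flows are equal;
    a R b (incomparable) when the flows disagree — both higher or both
    lower.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    n = len(flows.alternatives)
    rel = np.full((n, n), "", dtype=object)
    plus, minus = flows.phi_plus, flows.phi_minus
    for i in range(n):
        rel[i, i] = "self"
        for j in range(i + 1, n):
            dp = plus[i] - plus[j]
            dm = minus[i] - minus[j]
            p_eq = abs(dp) <= epsilon
            m_eq = abs(dm) <= epsilon
            if p_eq and m_eq:
                rij = rji = "I"
            elif (dp > 0 and (m_eq or dm < 0)) or (p_eq and dm < 0):
                rij, rji = "P", "P-"
            elif (dp < 0 and (m_eq or dm > 0)) or (p_eq and dm > 0):
                rij, rji = "P-", "P"
            else:  # crossed dominance
                rij = rji = "R"
            rel[i, j], rel[j, i] = rij, rji
    return PartialOrder(flows.alternatives, rel)


def promethee2(flows: FlowTable, epsilon: float = DEFAULT_EPSILON) -> Ranking:
    """PROMETHEE II complete ranking by net flow, descending.

    Net flows within ``epsilon`` of the current tie-group leader share a
    rank; ranks use the competition convention (1, 2, 2, 4).
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    net = flows.phi_net
    order = sorted(
        range(len(net)), key=lambda i: (-net[i], flows.alternatives[i])
    )
    rows: list[tuple[int, str, float]] = []
    group_rank = 1
    group_value = None
    for pos, idx in enumerate(order, start=1):
        v = float(net[idx])
        if group_value is None or abs(v - group_value) > epsilon:
            group_rank = pos
            group_value = v
        rows.append((group_rank, flows.alternatives[idx], v))
    return Ranking(tuple(rows))


def unicriterion_net_flows(m: DecisionMatrix) -> pd.DataFrame:
    """Per-criterion net flows phi_k(a_t) (alternatives x criteria frame).

    phi_k(a) = (1/(n-1)) sum_{b != a} [P_k(a, b) - P_k(b, a)]; the
    weighted sum over criteria reproduces each alternative's net flow, so
    positive entries are the strengths a criterion contributes and
    negative entries the weaknesses.
    """
    spreads = m.spreads()
    n = m.n
    cols = {}
    for j, c in enumerate(m.criteria):
        deg = _pairwise_degrees(m, j, spreads)
        np.fill_diagonal(deg, 0.0)
        cols[c.id] = (deg.sum(axis=1) - deg.sum(axis=0)) / (n - 1)
    return pd.DataFrame(cols, index=list(m.alternatives))


def run_full_analysis(
    m: DecisionMatrix, epsilon: float = DEFAULT_EPSILON
) -> AnalysisResult:
    """End-to-end pipeline: weights -> pi -> flows -> orders -> profile."""
    try:
        w = m.normalized_weights()
    except Exception as exc:
        raise DecisionMatrixError(f"weight normalization failed: {exc}") from exc
    pi = preference_matrix(m, w)
    flows = FlowTable(m.alternatives, leaving_flow(pi), entering_flow(pi))
    order1 = promethee1(flows, epsilon)
    ranking = promethee2(flows, epsilon)
    profile = unicriterion_net_flows(m)
    return AnalysisResult(
        matrix=m,
        weights=w,
        pi=pi,
        flows=flows,
        partial_order=order1,
        ranking=ranking,
        profile=profile,
    )
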