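import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fpromethee import Criterion, DecisionMatrix, make_tfn
from fpromethee.preference import PreferenceFunctionSpec

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def naive_preference_matrix(m: DecisionMatrix):
    """Independent plain-Python triple-loop oracle for pi(a, b).

    Normalizes the defuzzified weights, estimates each criterion's
    population sd, and accumulates w_k * P_k(d) pair by pair with scalar
    math — no numpy, no shared code path with the vectorized engine.
    """
    n, K = m.n, m.k
    w = [c.crisp_weight() for c in m.criteria]
    tot = sum(w)
    w = [x / tot for x in w]
    spreads = []
    for j in range(K):
        col = [float(m.values[i, j]) for i in range(n)]
        mean = sum(col) / n
        spreads.append(math.sqrt(sum((x - mean) ** 2 for x in col) / n))
    pi = [[0.0] * n for _ in range(n)]
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            total = 0.0
            for j, c in enumerate(m.criteria):
                d = float(m.values[a, j]) - float(m.values[b, j])
                if c.direction == "minimize":
                    d = -d
                s = spreads[j]
                if d <= 0 or s == 0:
                    p = 0.0
                else:
                    p = -math.expm1(-d * d / (2 * s * s))
                total += w[j] * p
            pi[a][b] = total
    return pi


def naive_flows(pi):
    """Row/column means of pi excluding the diagonal, scalar loops."""
    n = len(pi)
    plus = [sum(pi[a][b] for b in range(n) if b != a) / (n - 1) for a in range(n)]
    minus = [sum(pi[b][a] for b in range(n) if b != a) / (n - 1) for a in range(n)]
    return plus, minus


def random_matrix(rng: np.random.Generator, n: int = 6, k: int = 4) -> DecisionMatrix:
    """A random Gaussian-preference decision matrix with mixed directions."""
    criteria = []
    for j in range(k):
        wv = float(rng.uniform(0.1, 1.0))
        criteria.append(
            Criterion(
                id=f"C{j + 1}",
                direction="minimize" if rng.random() < 0.5 else "maximize",
                weight=make_tfn(wv, wv, wv),
                pf=PreferenceFunctionSpec(family="gaussian"),
            )
        )
    values = rng.normal(loc=10.0, scale=3.0, size=(n, k))
    alts = tuple(f"A{i + 1}" for i in range(n))
    return DecisionMatrix(alternatives=alts, criteria=tuple(criteria), values=values)


@pytest.fixture
def toy_matrix() -> DecisionMatrix:
    """3 alternatives x 2 criteria, one maximized and one minimized."""
    criteria = (
        Criterion(id="acc", direction="maximize", weight=make_tfn(0.6, 0.6, 0.6)),
        Criterion(id="cost", direction="minimize", weight=make_tfn(0.4, 0.4, 0.4)),
    )
    values = np.array([[0.90, 30.0], [0.80, 10.0], [0.70, 20.0]])
    return DecisionMatrix(
        alternatives=("A", "B", "C"), criteria=criteria, values=values
    )
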