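# Methods

## Problem and model

`fpromethee` ranks a finite set of alternatives — in the motivating
application, 16 urinary-tract-infection (UTI) diagnostic tests — under
K weighted criteria using the fuzzy-PROMETHEE outranking method.

Criterion importance is elicited verbally on a five-level linguistic
scale of triangular fuzzy numbers (TFNs):

| term      | TFN (a, b, c)      | Yager centroid |
|-----------|--------------------|----------------|
| Very Low  | (0, 0, 0.25)       | 0.0833         |
| Low       | (0, 0.25, 0.50)    | 0.25           |
| Moderate  | (0.25, 0.50, 0.75) | 0.50           |
| High      | (0.50, 0.75, 1)    | 0.75           |
| Very High | (0.75, 1, 1)       | 0.9167         |

A TFN is defuzzified with the Yager index, implemented as the centroid
of the triangular membership surface, `(a + b + c) / 3`. The method is
often described only as "centre of weight"; for triangular membership
the centroid is the standard closed form, and the unit tests cross-check
it against numeric integration of `x·mu(x) / mu(x)`. Linguistic cell
values in the decision matrix (e.g. efficiency rated "High") are
defuzzified with the same index before analysis.

Crisp weights are normalized to sum to one. Sources describing the
method leave normalization implicit; we normalize because the preference
index below is then a convex combination of per-criterion degrees and is
guaranteed to lie in [0, 1]. `preference_matrix` refuses unnormalized
weight vectors rather than silently rescaling.

For each ordered pair of alternatives (a, b) and criterion k the signed
difference is `d_k = f_k(a) - f_k(b)` for maximized criteria and the
negation for minimized ones (cost, turnaround time) — the universal
PROMETHEE convention; without the flip, cheaper tests would be
penalized. The default preference function is Gaussian:

    P_k(d) = 0                          d <= 0
    P_k(d) = 1 - exp(-d^2 / (2 s_k^2))  d > 0

with spread `s_k` equal to the population standard deviation (divisor n)
of criterion k's column unless overridden per criterion. Sample sd
(divisor n - 1) is available via `DecisionMatrix(sd_mode="sample")`; at
n = 16 the two differ by ~3%. A data-driven spread makes the analysis
invariant under per-criterion affine rescaling (positive scale, any
shift) — a property the test suite asserts to 1e-10. The degenerate
case `s_k = 0` (all alternatives identical on k) yields preference 0
everywhere: a constant column cannot discriminate, which is also the
limit of the Gaussian form. The other standard PROMETHEE families
(usual, U-shape, V-shape, level, linear) are implemented behind explicit
configuration; only the Gaussian is used by default.

The outranking machinery is then classical:

    pi(a, b)   = sum_k w_k P_k(d_k(a, b))
    Phi+(a)    = 1/(n-1) sum_{b != a} pi(a, b)
    Phi-(a)    = 1/(n-1) sum_{b != a} pi(b, a)
    Phi_net(a) = Phi+(a) - Phi-(a)

PROMETHEE I classifies each pair from the two partial flows as
preference (P), indifference (I) or incomparability (R: crossed
dominance — higher on both flows or lower on both). PROMETHEE II ranks
completely by net flow. Because each pi(a, b) enters one leaving and one
entering flow, net flows always sum to zero; the suite enforces this to
1e-10 across 500 random studies.

## Numerical choices

- **Flow-equality tolerance.** The partial-order and ranking relations
  compare real flows for equality. We use a configurable absolute
  epsilon, default 1e-9; the method definitions are silent on this.
- **Tie ranks.** Competition ranking (1, 2, 2, 4). Equal net flows are
  broken deterministically by label for a stable output order.
- **Tiny preferences.** `1 - exp(-x)` is computed as `-expm1(-x)`, so a
  planted dominance margin of ~1e-9 still produces a strictly positive
  preference degree instead of underflowing to zero.
- **Report rounding.** Emitted tables round half-even to 4 decimals,
  matching the precision of the published flow tables; JSON reports and
  all internal arithmetic keep full precision.

## Unicriterion decomposition

The per-criterion profile uses the standard PROMETHEE decomposition

    phi_k(a) = 1/(n-1) sum_{b != a} [P_k(a, b) - P_k(b, a)]

which satisfies `sum_k w_k phi_k(a) = Phi_net(a)` exactly (asserted to
1e-12). Positive `phi_k` entries are an alternative's strengths,
negative entries its weaknesses — the quantity behind strength/weakness
profile plots.

## Criterion-omission sensitivity

`omit_criteria` removes columns, keeps the surviving fuzzy weights and
renormalizes them inside the next analysis (preserving the [0, 1]
codomain of pi), and lets the data-driven spreads recompute from the
surviving columns. Removing a zero-weight criterion provably leaves pi,
flows and ranking unchanged, and the suite checks it. Ranking agreement
is reported as Kendall's tau-b on rank positions plus signed
per-alternative displacements rather than a binary "changed/unchanged"
verdict, because a reduced criteria set can reorder mid-table
alternatives even when the extremes are stable.

## The synthetic study generator

The expert 16 x 15 decision matrix of the UTI study was never
published, so the generator emulates its statistical structure instead;
it defines the study conditions for every end-to-end test:

- **Design replica.** `replicate_uti_design()` reproduces the published
  design exactly: 16 named test alternatives and criteria C1–C15 with
  their elicited weight terms (C5 result time and C6 point-of-care
  Very High; C3, C4, C10–C15 High; C7–C9 Moderate; C2 Low; C1 Very Low).
- **Directions** are modelling assumptions, not published facts: C1
  specimen volume, C3 cost and C5 result time are minimized, the rest
  maximized.
- **Cell distributions** (modelling choices; the original cells came
  from literature values and expert opinion): percentage criteria
  (C11–C14: sensitivity, specificity, PPV, NPV) as `50 + 50·Beta(5, 2)`,
  i.e. bounded in [50, 100] with mode near 85 like published diagnostic
  accuracy figures; cost-like columns (C1, C3) lognormal(2.0, 0.6);
  time-like (C5) lognormal(3.5, 0.9), a minutes-scale heavy right tail;
  linguistic columns (C2, C4, C8–C10) uniform over the five scale terms,
  defuzzified; binary capabilities (C6, C7, C15) fair coin flips.
  `noise_scale` multiplies the lognormal sigmas and flattens the Beta.
- **Planted dominance.** `plant_dominant_alternative` sets one row to
  the per-criterion optimum plus a ~1e-9 relative margin on the first
  positively weighted criterion, giving a weakly dominant alternative
  that any correct implementation must rank first; planting a second
  dominant row is refused.

Generation is a pure function of (config, seed). What passing tests on
these matrices do **not** show: agreement with the published flow
magnitudes (impossible without the original matrix — and indeed the two
published tables differ ~30-fold in flow magnitude between the full and
the reduced run, which the publication does not explain), or realism of
between-criteria correlations (cells are drawn independently, whereas
real diagnostic accuracy metrics co-vary).

## Published-table fixtures

The two published flow tables ship as data (`load_reference_flows`).
They are used only for arithmetic-consistency checks: recomputing
`Phi_net = Phi+ - Phi-` from the printed partial flows reproduces the
printed net column for 14 of 16 rows in each table exactly at 4
decimals, with the remaining rows off by one unit in the last printed
digit, and both printed net columns sum to zero at printed precision.
The package makes no claim of regenerating these flows from first
principles.

## Known limitations

- The published study's claim that the reduced-criteria ranking "has
  not changed" is inconsistent with its own reduced-run table, whose
  order differs substantially from the headline table; this package
  surfaces tau and displacements and makes no robustness claim.
- No GAIA plane, no PROMETHEE III–VI, no group aggregation, no fuzzy
  arithmetic beyond defuzzification (TFNs are collapsed before the
  pairwise stage, the common "defuzzify-first" F-PROMETHEE variant).
- Weight-interval stability analysis is out of scope; sensitivity is
  omission-based only.
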