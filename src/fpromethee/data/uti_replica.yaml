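# Criteria configuration replicating the UTI diagnostic-test study design:
# 15 criteria C1-C15 with their elicited linguistic weight terms on the
# built-in five-level triangular fuzzy scale.  Directions are modelling
# assumptions (the study does not state them): specimen volume, cost and
# result time are minimized, everything else maximized.  All criteria use
# the Gaussian preference function with a data-driven spread.
scale: default
criteria:
  - id: C1
    name: Specimen volume
    direction: minimize
    weight: Very Low
    pf: {family: gaussian}
  - id: C2
    name: Specimen type
    direction: maximize
    weight: Low
    pf: {family: gaussian}
  - id: C3
    name: Cost
    direction: minimize
    weight: High
    pf: {family: gaussian}
  - id: C4
    name: Efficiency
    direction: maximize
    weight: High
    pf: {family: gaussian}
  - id: C5
    name: Result time
    direction: minimize
    weight: Very High
    pf: {family: gaussian}
  - id: C6
    name: Point of care testing
    direction: maximize
    weight: Very High
    pf: {family: gaussian}
  - id: C7
    name: Applicability/direct from sample
    direction: maximize
    weight: Moderate
    pf: {family: gaussian}
  - id: C8
    name: Practicality for patients
    direction: maximize
    weight: Moderate
    pf: {family: gaussian}
  - id: C9
    name: Practicality for personnel
    direction: maximize
    weight: Moderate
    pf: {family: gaussian}
  - id: C10
    name: Limitation/pathogen identification
    direction: maximize
    weight: High
    pf: {family: gaussian}
  - id: C11
    name: Sensitivity
    direction: maximize
    weight: High
    pf: {family: gaussian}
  - id: C12
    name: Specificity
    direction: maximize
    weight: High
    pf: {family: gaussian}
  - id: C13
    name: PPV
    direction: maximize
    weight: High
    pf: {family: gaussian}
  - id: C14
    name: NPV
    direction: maximize
    weight: High
    pf: {family: gaussian}
  - id: C15
    name: AST capability
    direction: maximize
    weight: High
    pf: {family: gaussian}
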