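# Benefit-risk value tree for adjunctive herbal therapy plus chemotherapy
# vs. chemotherapy alone in non-small cell lung cancer. Swing weights are
# on the 0-100 convention within each category; anchors are in the units
# of each outcome (optimal -> preference 100, worst -> preference 0).
version: 1
benefit_weight: 0.75
risk_weight: 0.25
criteria:
  - id: kps
    label: KPS score
    category: benefit
    swing_weight: 80
    optimal: 11
    worst: 2
    direction: higher_is_better
  - id: ca211
    label: CA211
    category: benefit
    swing_weight: 60
    optimal: 6
    worst: 3
    direction: higher_is_better
  - id: cea
    label: CEA
    category: benefit
    swing_weight: 60
    optimal: 12
    worst: 6
    direction: higher_is_better
  - id: fatigue
    label: Cancer Fatigue Scale score
    category: benefit
    swing_weight: 100
    optimal: 18
    worst: 0
    direction: higher_is_better
  - id: gi_adverse
    label: Gastrointestinal adverse reactions
    category: risk
    swing_weight: 100
    optimal: 0
    worst: 1
    direction: lower_is_better
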