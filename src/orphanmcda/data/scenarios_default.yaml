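# Built-in weight scenarios for sensitivity testing of the nine-criterion
# framework. Scenario 1 weights all criteria equally (exact ninths; printed
# tables usually round this to 11.1%). Scenario 2 excludes the four criteria
# HTA bodies are unlikely to weigh (research level, effectiveness uncertainty,
# manufacturing complexity, unique indication). Scenario 3 re-admits research
# level and effectiveness uncertainty, excluding only manufacturing complexity
# and unique indication. Percentages are normalised to fractions on load.
- name: "Scenario 1 (Base Case)"
  weights:
    rarity: 11.111111
    research_level: 11.111111
    effectiveness_uncertainty: 11.111111
    manufacturing_complexity: 11.111111
    follow_up_measures: 11.111111
    disease_severity: 11.111111
    available_alternatives: 11.111111
    treatment_impact: 11.111111
    unique_indication: 11.111111
- name: "Scenario 2"
  weights:
    rarity: 14.0
    research_level: 0.0
    effectiveness_uncertainty: 0.0
    manufacturing_complexity: 0.0
    follow_up_measures: 6.0
    disease_severity: 30.0
    available_alternatives: 20.0
    treatment_impact: 30.0
    unique_indication: 0.0
- name: "Scenario 3"
  weights:
    rarity: 10.0
    research_level: 20.0
    effectiveness_uncertainty: 10.0
    manufacturing_complexity: 0.0
    follow_up_measures: 15.0
    disease_severity: 15.0
    available_alternatives: 10.0
    treatment_impact: 20.0
    unique_indication: 0.0
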