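# Default nine-criterion orphan-drug MCDA framework (Hughes-Wilson et al., 2012).
# Each criterion has exactly three ordinal levels scored 1 (lowest) to 3 (highest).
version_tag: hughes-wilson-2012
criteria:
  - id: rarity
    name: Rarity
    levels:
      - score: 1
        label: "1:2,000-1:20,000"
        definition: "Based on published prevalence data: prevalence between 1 per 2,000 and 1 per 20,000 population"
      - score: 2
        label: "1:20,000-1:200,000"
        definition: "Based on published prevalence data: prevalence between 1 per 20,000 and 1 per 200,000 population"
      - score: 3
        label: "<1:200,000"
        definition: "Based on published prevalence data: prevalence rarer than 1 per 200,000 population"
  - id: research_level
    name: Level of research undertaken
    levels:
      - score: 1
        label: "Blue sky"
        definition: "Blue sky research"
      - score: 2
        label: "Building on previous knowledge"
        definition: "Building on previous knowledge"
      - score: 3
        label: "Literature review"
        definition: "Literature review"
  - id: effectiveness_uncertainty
    name: Level of uncertainty of effectiveness
    levels:
      - score: 1
        label: "Immature but promising data"
        definition: "Immature but promising data"
      - score: 2
        label: "Appropriate surrogate endpoints"
        definition: "Appropriate surrogate endpoints"
      - score: 3
        label: "Robust clinical endpoints"
        definition: "Robust clinical endpoints"
  - id: manufacturing_complexity
    name: Manufacturing complexity
    levels:
      - score: 1
        label: "Not complex; small molecule"
        definition: "Not complex; small molecule"
      - score: 2
        label: "Moderately complex"
        definition: "Moderately complex"
      - score: 3
        label: "Highly complex, biological and galenic form"
        definition: "Highly complex, biological and galenic form"
  - id: follow_up_measures
    name: Follow-up measures
    levels:
      - score: 1
        label: "Safety and efficacy studies, and size and duration of study"
        definition: "Safety and efficacy studies, and size and duration of study"
      - score: 2
        label: "Designed to answer specific, defined delineated question"
        definition: "Designed to answer specific, defined delineated question"
      - score: 3
        label: "Moderate to none"
        definition: "Moderate to none"
  - id: disease_severity
    name: Disease severity
    levels:
      - score: 1
        label: "Morbidity"
        definition: "Morbidity"
      - score: 2
        label: "Mortality, severe invalidity in adulthood"
        definition: "Mortality, severe invalidity in adulthood"
      - score: 3
        label: "Mortality/severe invalidity as an infant"
        definition: "Mortality/severe invalidity as an infant"
  - id: available_alternatives
    name: Available alternatives/Unmet needs
    levels:
      - score: 1
        label: "Alternatives with similar characteristics"
        definition: "Alternatives with similar characteristics"
      - score: 2
        label: "Alternatives - but this offer strong innovation to disease treatment"
        definition: "Alternatives exist, but this drug offers strong innovation to disease treatment"
      - score: 3
        label: "No alternative"
        definition: "No alternative"
  - id: treatment_impact
    name: Treatment impact on disease
    levels:
      - score: 1
        label: "Low"
        definition: "Low impact on the disease"
      - score: 2
        label: "Medium"
        definition: "Medium impact on the disease"
      - score: 3
        label: "Strong"
        definition: "Strong impact on the disease"
  - id: unique_indication
    name: Unique indication or not
    levels:
      - score: 1
        label: "Existing orphan or non-orphan indication for the same molecule"
        definition: "Existing orphan or non-orphan indication for the same molecule"
      - score: 2
        label: "Potential for multiple indications"
        definition: "Potential for multiple indications"
      - score: 3
        label: "Unique indication. No other possible use"
        definition: "Unique indication. No other possible use"
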