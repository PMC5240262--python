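# SYNTHETIC ILLUSTRATIVE DATA: scores and costs are invented for demonstration
# of the pipeline. They are NOT the evaluation values of any real drug.
drug_id,indication,rarity,research_level,effectiveness_uncertainty,manufacturing_complexity,follow_up_measures,disease_severity,available_alternatives,treatment_impact,unique_indication,annual_cost_eur
DRUG-PAH,Pulmonary arterial hypertension,1,2,3,1,2,2,1,2,1,24000
DRUG-MDS,Myelodysplastic syndromes,1,2,2,2,1,2,2,2,2,36000
DRUG-LGS,Lennox-Gastaut syndrome,1,2,2,1,3,2,2,2,1,18000
DRUG-MPS2,Mucopolysaccharidosis II,3,1,2,3,1,3,3,2,3,310000
DRUG-MPS6,Mucopolysaccharidosis VI,3,1,2,3,1,3,3,3,3,290000
DRUG-PNH,Paroxysmal nocturnal haemoglobinuria,2,2,2,3,2,2,3,3,3,250000
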