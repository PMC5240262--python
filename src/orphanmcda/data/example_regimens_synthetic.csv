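# SYNTHETIC ILLUSTRATIVE DATA: dosing and prices are invented for
# demonstration of the annual-cost calculator, not taken from any formulary.
drug_id,dose_amount,dose_unit,dose_basis,administrations_per_year,body_weight_kg,price_per_unit,price_currency,vial_size
DRUG-PAH,125,mg,flat,730,,0.11,GBP,
DRUG-MDS,75,mg,flat,196,,1.10,GBP,
DRUG-LGS,400,mg,flat,365,,0.05,GBP,
DRUG-MPS2,0.5,mg,per_kg,52,35,280.00,GBP,6
DRUG-MPS6,1,mg,per_kg,52,25,190.00,GBP,5
DRUG-PNH,900,mg,flat,26,,8.80,GBP,300
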