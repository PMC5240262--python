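"""Build an average annual drug cost per patient from dosing and price.

A weight-based biologic: 5 mg/kg every two weeks at an assumed 35 kg body
weight, priced in GBP per mg and converted to EUR. Vial rounding is off by
default (average-dose costing); turning it on shows the wastage premium of
billing whole 100 mg vials.
"""

from orphanmcda import DoseRegimen, FxRate, PriceSpec, annual_cost

regimen = DoseRegimen(
    dose_amount=5.0,               # mg per kg per administration
    dose_basis="per_kg",
    assumed_body_weight_kg=35.0,
    administrations_per_year=26.0,  # every two weeks
)
price = PriceSpec(price_per_unit=10.0, currency="GBP", vial_size=100.0)
fx = FxRate("GBP", "EUR", 1.21)

exact = annual_cost(regimen, price, fx)
vials = annual_cost(regimen, price, fx, vial_rounding=True)

print(f"dose per administration : {regimen.dose_per_administration:.0f} mg")
print(f"annual cost (average dose): EUR {exact:,.0f}")
print(f"annual cost (whole vials) : EUR {vials:,.0f}")
print("\nThe vial-rounded figure is never lower: partial vials are billed whole.")
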