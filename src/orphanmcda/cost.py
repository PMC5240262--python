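"""Average annual drug cost per patient from a dosing regimen and unit price.

The construction mirrors how annual orphan-drug acquisition costs are built
from public sources: the average dose per administration comes from the
product's SPC (either a flat dose or weight-based dosing at an assumed body
weight), the unit price from a published formulary, and the result is
converted to the target currency at a stated exchange rate. Continuous,
on-label use for a full year is assumed. Administration, monitoring and
ancillary costs are out of scope.

Vial-level billing (rounding each administration up to whole vials) is
opt-in; the default bills the exact average dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InputError

__all__ = ["DoseRegimen", "PriceSpec", "FxRate", "annual_cost"]


@dataclass(frozen=True)
class DoseRegimen:
    """Dosing schedule for one drug.

    ``dose_amount`` is the quantity per administration in the pricing unit
    (e.g. mg); with ``dose_basis="per_kg"`` it is per kilogram of body
    weight and ``assumed_body_weight_kg`` must be set.
    """

    dose_amount: float
    administrations_per_year: float
    dose_basis: str = "flat"  # "flat" or "per_kg"
    assumed_body_weight_kg: float | None = None

    def __post_init__(self) -> None:
        if self.dose_basis not in ("flat", "per_kg"):
            raise InputError(f"dose_basis must be 'flat' or 'per_kg', got {self.dose_basis!r}")
        if not self.dose_amount > 0:
            raise InputError(f"dose_amount must be > 0, got {self.dose_amount!r}")
        if not (self.administrations_per_year > 0 and math.isfinite(self.administrations_per_year)):
            raise InputError(
                f"administrations_per_year must be positive and finite, got {self.administrations_per_year!r}"
            )
        if self.dose_basis == "per_kg":
            if self.assumed_body_weight_kg is None or not self.assumed_body_weight_kg > 0:
                raise InputError("per_kg dosing requires a positive assumed_body_weight_kg")

    @property
    def dose_per_administration(self) -> float:
        if self.dose_basis == "per_kg":
            return self.dose_amount * float(self.assumed_body_weight_kg)
        return self.dose_amount


@dataclass(frozen=True)
class PriceSpec:
    """Published price per unit of the dosing quantity, with currency tag.

    ``vial_size`` is the quantity per indivisible pack, used only when vial
    rounding is enabled.
    """

    price_per_unit: float
    currency: str = "GBP"
    vial_size: float | None = None

    def __post_init__(self) -> None:
        if self.price_per_unit < 0:
            raise InputError(f"price_per_unit must be >= 0, got {self.price_per_unit!r}")
        if self.vial_size is not None and not self.vial_size > 0:
            raise InputError(f"vial_size must be > 0, got {self.vial_size!r}")


@dataclass(frozen=True)
class FxRate:
    """Exchange rate multiplier: amount_in_to = amount_in_from * rate."""

    from_currency: str
    to_currency: str
    rate: float

    def __post_init__(self) -> None:
        if not (self.rate > 0 and math.isfinite(self.rate)):
            raise InputError(f"fx rate must be positive and finite, got {self.rate!r}")

    @classmethod
    def identity(cls, currency: str = "EUR") -> "FxRate":
        return cls(currency, currency, 1.0)


def annual_cost(
    regimen: DoseRegimen,
    price: PriceSpec,
    fx: FxRate | None = None,
    *,
    vial_rounding: bool = False,
) -> float:
    """Average annual drug cost per patient in ``fx.to_currency``.

    annual cost = administrations/year x billed quantity/administration
    x price per unit x fx rate, assuming routine use for a full year. With
    ``vial_rounding`` each administration is rounded up to whole vials
    (requires ``price.vial_size``); otherwise the exact average dose is
    billed, matching a construction that uses average doses and excludes
    wastage and ancillary costs.
    """
    if fx is None:
        fx = FxRate.identity(price.currency)
    if price.currency != fx.from_currency:
        raise InputError(
            f"price currency {price.currency!r} does not match fx.from_currency {fx.from_currency!r}"
        )
    quantity = regimen.dose_per_administration
    if vial_rounding:
        if price.vial_size is None:
            raise InputError("vial_rounding requires price.vial_size")
        quantity = math.ceil(quantity / price.vial_size) * price.vial_size
    return regimen.administrations_per_year * quantity * price.price_per_unit * fx.rate
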