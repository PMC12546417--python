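"""Coproduct allocation of fresh-organism NPPU to fishmeal and fish oil.

Reduction of one kg of fresh fish yields Y_meal kg of meal and Y_oil kg of
oil.  The fresh burden is split between the two coproducts by

* energy allocation:  factor_meal = Y_m·E_m / (Y_m·E_m + Y_o·E_o),
  then NPPU_meal = (NPPU_fresh / Y_m) · factor_meal (and likewise for oil);
* mass allocation:  both coproducts receive NPPU_fresh / (Y_m + Y_o) per kg;
* custom allocation: the energy algebra with the energy densities replaced
  by user weights (e.g. prices) — equal weights recover mass allocation.

Every method satisfies the mass balance
Y_m·NPPU_meal + Y_o·NPPU_oil = NPPU_fresh: the non-meal, non-oil residual
(stickwater, evaporation losses) carries no burden.

Combining the specificity tiers with generic vs. specific yields gives the
tier x yield variant matrix: six values (T11..T32) for marine species,
four (T11..T22) for freshwater species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .errors import InvalidInputError, MissingDataError
from .trophic import GenericDefaults, SpeciesRecord, nppu_for_class, tiers_for_class
from .value import NPPUValue

_BALANCE_RTOL = 1e-9


@dataclass(frozen=True)
class CoproductSpec:
    """Meal/oil yields (kg per kg fresh fish) and gross energy densities (MJ/kg)."""

    yield_meal: float
    yield_oil: float
    energy_meal: float
    energy_oil: float
    yield_source: str = "generic"  # {generic, specific}

    def __post_init__(self) -> None:
        for name in ("yield_meal", "yield_oil", "energy_meal", "energy_oil"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be strictly positive")
        if self.yield_meal >= 1 or self.yield_oil >= 1:
            raise InvalidInputError("yields must be fractions below 1")
        if self.yield_meal + self.yield_oil > 1:
            raise InvalidInputError(
                "yield_meal + yield_oil cannot exceed 1 kg per kg fresh fish"
            )
        if self.yield_source not in ("generic", "specific"):
            raise InvalidInputError("yield_source must be 'generic' or 'specific'")


#: Package-default generic reduction yields and gross energy densities.
GENERIC_COPRODUCTS = CoproductSpec(
    yield_meal=0.225, yield_oil=0.05, energy_meal=20.0, energy_oil=39.5,
    yield_source="generic",
)


@dataclass(frozen=True)
class AllocationResult:
    """Allocated per-kg NPPU of the two coproducts plus the factors used."""

    nppu_meal: NPPUValue
    nppu_oil: NPPUValue
    method: str
    factor_meal: float
    factor_oil: float


def _factors(y_m: float, y_o: float, w_m: float, w_o: float) -> Tuple[float, float]:
    denom = y_m * w_m + y_o * w_o
    if denom <= 0:
        raise InvalidInputError("allocation weights must not both vanish")
    return y_m * w_m / denom, y_o * w_o / denom


def energy_allocation_factors(spec: CoproductSpec) -> Tuple[float, float]:
    """Energy-share allocation factors (factor_meal, factor_oil); they sum to 1."""
    return _factors(spec.yield_meal, spec.yield_oil, spec.energy_meal, spec.energy_oil)


def _allocate(
    fresh: NPPUValue, spec: CoproductSpec, w_m: float, w_o: float, method: str
) -> AllocationResult:
    if fresh.basis != "fresh":
        raise InvalidInputError(
            f"allocation requires a fresh-basis NPPU, got basis {fresh.basis!r}"
        )
    f_m, f_o = _factors(spec.yield_meal, spec.yield_oil, w_m, w_o)
    meal = NPPUValue(
        value_g=fresh.value_g / spec.yield_meal * f_m,
        basis="ingredient",
        tier_label=fresh.tier_label,
        allocation_label=method,
    )
    oil = NPPUValue(
        value_g=fresh.value_g / spec.yield_oil * f_o,
        basis="ingredient",
        tier_label=fresh.tier_label,
        allocation_label=method,
    )
    return AllocationResult(
        nppu_meal=meal, nppu_oil=oil, method=method, factor_meal=f_m, factor_oil=f_o
    )


def allocate_energy(fresh: NPPUValue, spec: CoproductSpec) -> AllocationResult:
    """Allocate a fresh NPPU to meal and oil by energy shares."""
    return _allocate(fresh, spec, spec.energy_meal, spec.energy_oil, "energy")


def allocate_mass(fresh: NPPUValue, spec: CoproductSpec) -> AllocationResult:
    """Allocate a fresh NPPU to meal and oil by mass shares.

    Both coproducts receive the same per-kg value NPPU_fresh / (Y_m + Y_o),
    the unique mass-proportional split obeying the coproduct mass balance.
    """
    return _allocate(fresh, spec, 1.0, 1.0, "mass")


def allocate_custom(
    fresh: NPPUValue, spec: CoproductSpec, weight_meal: float, weight_oil: float
) -> AllocationResult:
    """Allocate by user-supplied per-kg weights (e.g. economic values).

    Uses the energy-allocation algebra with the energy densities replaced by
    the weights; weights must be strictly positive.
    """
    if weight_meal <= 0 or weight_oil <= 0:
        raise InvalidInputError("allocation weights must be strictly positive")
    return _allocate(fresh, spec, weight_meal, weight_oil, "custom")


def allocate(
    fresh: NPPUValue,
    spec: CoproductSpec,
    method: str,
    weight_meal: float | None = None,
    weight_oil: float | None = None,
) -> AllocationResult:
    """Dispatch to one of the allocation methods by name."""
    if method == "energy":
        return allocate_energy(fresh, spec)
    if method == "mass":
        return allocate_mass(fresh, spec)
    if method == "custom":
        if weight_meal is None or weight_oil is None:
            raise InvalidInputError("custom allocation requires both weights")
        return allocate_custom(fresh, spec, weight_meal, weight_oil)
    raise InvalidInputError(f"unknown allocation method {method!r}")


def tier_yield_matrix(
    record: SpeciesRecord,
    defaults: GenericDefaults,
    spec_generic: CoproductSpec,
    spec_specific: CoproductSpec,
    method: str = "energy",
    ingredient_class: str = "marine",
) -> Dict[str, AllocationResult]:
    """The tier x yield variant matrix of allocated NPPU values.

    Keys are "T{tier}{yield}" with yield 1 = generic, 2 = specific: six
    entries (T11..T32) for marine records, four (T11..T22) for freshwater.

    Raises
    ------
    MissingDataError
        Naming the tier whose specific inputs the record lacks.
    """
    if ingredient_class not in ("marine", "freshwater"):
        raise InvalidInputError(
            "tier_yield_matrix applies to marine or freshwater records"
        )
    out: Dict[str, AllocationResult] = {}
    for policy in tiers_for_class(ingredient_class):
        try:
            fresh = nppu_for_class(record, policy, defaults)
        except MissingDataError as exc:
            raise MissingDataError(
                f"tier {policy.tier_label}: {exc}"
            ) from exc
        for yield_idx, spec in ((1, spec_generic), (2, spec_specific)):
            label = f"{policy.tier_label}{yield_idx}"
            result = allocate(fresh.relabel(tier_label=label), spec, method)
            out[label] = result
    return out
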