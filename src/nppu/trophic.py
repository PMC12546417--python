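"""Trophic amplification of carbon content and tier-based parameter policies.

The core of the indicator is the Pauly–Christensen relation: producing one
unit of biomass at trophic level TL requires (1/TE)^(TL−1) units of primary
production, where TE is the trophic transfer efficiency (generically 10 %).
The NPPU of a fresh organism is therefore

    NPPU [g C/kg] = C_content [g C/kg fresh mass] × (1/TE)^(TL−1)

Different specificity tiers decide where C_content and TE come from:

* marine     T1 (generic TE, generic C), T2 (specific TE, generic C),
             T3 (specific TE, specific C)
* freshwater T1 (generic TE, generic C), T2 (generic TE, specific C)
* other animals: one tier (generic TE, specific C, specific TL)
* milk: trophic level fixed at 2, generic TE, carbon from composition
* plant: trophic level fixed at 1 (no amplification)

A record that lacks a value the requested tier marks "specific" raises
MissingDataError — tiers never silently downgrade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

from .composition import ProximateComposition, carbon_content, plant_nppu
from .errors import InvalidInputError, MissingDataError
from .value import NPPUValue

INGREDIENT_CLASSES = ("marine", "freshwater", "other_animal", "milk", "plant")


@dataclass(frozen=True)
class TrophicParameters:
    """Trophic level (with SD) and transfer efficiency of a species.

    TE is stored as a fraction in (0, 1]; percent is an I/O representation
    only.  TL of 1 denotes a primary producer.
    """

    TL: float
    TL_SD: float = 0.0
    TE: float = 0.10
    ecosystem: str = ""

    def __post_init__(self) -> None:
        if self.TL < 1:
            raise InvalidInputError(f"trophic level must be >= 1, got {self.TL}")
        if not 0.0 < self.TE <= 1.0:
            raise InvalidInputError(f"TE must lie in (0, 1], got {self.TE}")
        if self.TL_SD < 0:
            raise InvalidInputError(f"TL_SD must be non-negative, got {self.TL_SD}")


@dataclass(frozen=True)
class GenericDefaults:
    """Generic parameter values used by the lowest tiers.

    TE_generic : generic transfer efficiency (10 %).
    C_generic  : carbon content of 1 kg of fresh fish, 111.1 g.
    TE_range   : plausible ecosystem-specific TE span (3.51 %–38.1 %),
                 with mean TE_mean (11.9 %).
    """

    TE_generic: float = 0.10
    C_generic: float = 111.1
    TE_range: Tuple[float, float] = (0.0351, 0.381)
    TE_mean: float = 0.119

    def __post_init__(self) -> None:
        lo, hi = self.TE_range
        if not lo <= self.TE_generic <= hi:
            raise InvalidInputError("TE_generic must lie within TE_range")
        if self.C_generic <= 0:
            raise InvalidInputError("C_generic must be positive")


@dataclass(frozen=True)
class TierPolicy:
    """Declarative source selection for (C_content, TE, TL).

    te_source / c_source choose between the generic defaults and the
    species record; tl_source is "specific" (record TL) or "fixed"
    (fixed_TL overrides, e.g. plant = 1, milk = 2).
    """

    ingredient_class: str
    tier_label: str
    te_source: str = "generic"  # {generic, specific}
    c_source: str = "generic"  # {generic, specific}
    tl_source: str = "specific"  # {specific, fixed}
    fixed_TL: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ingredient_class not in INGREDIENT_CLASSES:
            raise InvalidInputError(
                f"ingredient_class must be one of {INGREDIENT_CLASSES}"
            )
        if self.te_source not in ("generic", "specific"):
            raise InvalidInputError("te_source must be 'generic' or 'specific'")
        if self.c_source not in ("generic", "specific"):
            raise InvalidInputError("c_source must be 'generic' or 'specific'")
        if self.tl_source not in ("specific", "fixed"):
            raise InvalidInputError("tl_source must be 'specific' or 'fixed'")
        if self.tl_source == "fixed" and self.fixed_TL is None:
            raise InvalidInputError("fixed tl_source requires fixed_TL")
        if self.ingredient_class == "milk" and self.fixed_TL != 2:
            raise InvalidInputError("milk policy must fix TL = 2")
        if self.ingredient_class == "plant" and self.fixed_TL != 1:
            raise InvalidInputError("plant policy must fix TL = 1")


# Tier presets.
MARINE_T1 = TierPolicy("marine", "T1", te_source="generic", c_source="generic")
MARINE_T2 = TierPolicy("marine", "T2", te_source="specific", c_source="generic")
MARINE_T3 = TierPolicy("marine", "T3", te_source="specific", c_source="specific")
FRESHWATER_T1 = TierPolicy("freshwater", "T1", te_source="generic", c_source="generic")
FRESHWATER_T2 = TierPolicy("freshwater", "T2", te_source="generic", c_source="specific")
OTHER_ANIMAL_T1 = TierPolicy(
    "other_animal", "T1", te_source="generic", c_source="specific"
)
MILK = TierPolicy(
    "milk", "milk", te_source="generic", c_source="specific",
    tl_source="fixed", fixed_TL=2.0,
)
PLANT = TierPolicy(
    "plant", "plant", te_source="generic", c_source="specific",
    tl_source="fixed", fixed_TL=1.0,
)

_PRESETS = {
    ("marine", "T1"): MARINE_T1,
    ("marine", "T2"): MARINE_T2,
    ("marine", "T3"): MARINE_T3,
    ("freshwater", "T1"): FRESHWATER_T1,
    ("freshwater", "T2"): FRESHWATER_T2,
    ("other_animal", "T1"): OTHER_ANIMAL_T1,
    ("milk", "milk"): MILK,
    ("plant", "plant"): PLANT,
}


def tier_policy(ingredient_class: str, tier_label: Optional[str] = None) -> TierPolicy:
    """Look up a preset tier policy; tier_label defaults to the class's only tier."""
    if tier_label is None:
        tier_label = {"milk": "milk", "plant": "plant", "other_animal": "T1"}.get(
            ingredient_class, "T1"
        )
    try:
        return _PRESETS[(ingredient_class, tier_label)]
    except KeyError:
        valid = sorted(t for c, t in _PRESETS if c == ingredient_class)
        raise InvalidInputError(
            f"no tier {tier_label!r} for class {ingredient_class!r}; valid: {valid}"
        ) from None


def tiers_for_class(ingredient_class: str) -> Tuple[TierPolicy, ...]:
    """All tier presets of a class, most generic first."""
    return tuple(
        _PRESETS[key] for key in sorted(_PRESETS) if key[0] == ingredient_class
    )


@dataclass(frozen=True)
class SpeciesRecord:
    """One species (or ingredient organism) with its raw parameters.

    ``C_specific`` is the measured carbon content in g C per kg fresh mass;
    when absent but a composition is present, specific-C policies derive it
    stoichiometrically from the composition.
    """

    species: str
    trophic: TrophicParameters
    common_name: str = ""
    common_name_fr: str = ""
    C_specific: Optional[float] = None
    composition: Optional[ProximateComposition] = None
    source_tl: str = ""
    source_body_composition: str = ""
    source_te: str = ""
    comment: str = ""

    def __post_init__(self) -> None:
        if self.C_specific is not None and self.C_specific < 0:
            raise InvalidInputError("C_specific must be non-negative")


def amplification_factor(TE: float, TL: float) -> float:
    """Trophic amplification (1/TE)^(TL−1).

    Equals 1 at TL = 1 and grows geometrically with each trophic step;
    at the generic TE of 10 % each full level multiplies the primary
    production requirement by 10.
    """
    if not 0.0 < TE <= 1.0:
        raise InvalidInputError(f"TE must lie in (0, 1], got {TE}")
    if TL < 1:
        raise InvalidInputError(f"trophic level must be >= 1, got {TL}")
    return (1.0 / TE) ** (TL - 1.0)


def nppu_fresh(
    C_content: float, TE: float, TL: float, tier_label: str = ""
) -> NPPUValue:
    """NPPU of one kg of fresh organism: C_content × (1/TE)^(TL−1)."""
    if C_content < 0:
        raise InvalidInputError(f"C_content must be non-negative, got {C_content}")
    return NPPUValue(
        value_g=C_content * amplification_factor(TE, TL),
        basis="fresh",
        tier_label=tier_label,
    )


def resolve_parameters(
    record: SpeciesRecord,
    policy: TierPolicy,
    defaults: GenericDefaults = GenericDefaults(),
) -> Tuple[float, float, float]:
    """Resolve the effective (C_content, TE, TL) triple for a record and tier.

    Raises
    ------
    MissingDataError
        Naming the missing field, if the policy marks a source "specific"
        and the record does not carry it.
    """
    if policy.te_source == "generic":
        TE = defaults.TE_generic
    else:
        TE = record.trophic.TE

    if policy.c_source == "generic":
        C = defaults.C_generic
    elif record.C_specific is not None:
        C = record.C_specific
    elif record.composition is not None:
        C = carbon_content(record.composition)
    else:
        raise MissingDataError(
            f"tier {policy.tier_label} demands specific carbon content but "
            f"record {record.species!r} carries neither C_specific nor a composition"
        )

    if policy.tl_source == "fixed":
        TL = float(policy.fixed_TL)
    else:
        TL = record.trophic.TL

    return C, TE, TL


def nppu_for_class(
    record: SpeciesRecord,
    policy: TierPolicy,
    defaults: GenericDefaults = GenericDefaults(),
) -> NPPUValue:
    """NPPU of a record under a tier policy.

    Plant policies delegate to the composition-based plant calculation
    (basis "ingredient"); every other class amplifies the resolved carbon
    content (basis "fresh" for animals, "ingredient" for milk, which is
    computed directly on the final ingredient).
    """
    if policy.ingredient_class == "plant":
        if record.composition is None:
            raise MissingDataError(
                f"plant record {record.species!r} carries no composition"
            )
        return plant_nppu(record.composition)
    C, TE, TL = resolve_parameters(record, policy, defaults)
    out = nppu_fresh(C, TE, TL, tier_label=policy.tier_label)
    if policy.ingredient_class == "milk":
        out = out.relabel(basis="ingredient")
    return out
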