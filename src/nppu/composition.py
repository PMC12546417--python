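"""Carbon stoichiometry of proximate composition and plant-ingredient NPPU.

The carbon content of a feed ingredient is estimated from its proximate
composition (crude protein, lipid, ash, moisture, carbohydrate, in g per kg
as-fed) via the carbon mass fractions of representative empirical formulas:

* protein       C5H7O2N   -> 0.531
* lipid (trigl.) C57H104O6 -> 0.774
* carbohydrate  C6H10O5   -> 0.444  (anhydroglucose repeat unit, 72/162)

computed with integer molar masses C=12, H=1, O=16, N=14 so the published
three-decimal constants reproduce exactly.  A plant ingredient sits at
trophic level 1, so its NPPU in g C/kg equals its carbon content: no trophic
amplification applies.

The carbohydrate fraction of composition tables is usually reported "by
difference" — the as-fed remainder after protein, lipid, ash and moisture,
floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import InvalidInputError
from .value import NPPUValue

#: closure target for as-fed proximate composition, g/kg.
_CLOSURE = 1000.0
#: closure tolerance, g/kg.
_CLOSURE_TOL = 1.0


@dataclass(frozen=True)
class MolarMassTable:
    """Atomic molar masses in g/mol.

    Defaults are the integer values (12/1/16/14) used to derive the
    published carbon coefficients, deliberately not the IUPAC standard
    atomic weights.
    """

    M_C: float = 12.0
    M_H: float = 1.0
    M_O: float = 16.0
    M_N: float = 14.0

    def __post_init__(self) -> None:
        for name in ("M_C", "M_H", "M_O", "M_N"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class EmpiricalFormula:
    """Atom counts of a CxHyOzNw empirical formula (non-negative integers)."""

    n_C: int
    n_H: int = 0
    n_O: int = 0
    n_N: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_C, self.n_H, self.n_O, self.n_N)
        if any(c < 0 for c in counts):
            raise InvalidInputError("atom counts must be non-negative")
        if self.n_C < 1:
            raise InvalidInputError("empirical formula must contain carbon (n_C >= 1)")


#: Representative empirical formulas behind the default coefficients.
PROTEIN_FORMULA = EmpiricalFormula(n_C=5, n_H=7, n_O=2, n_N=1)
LIPID_FORMULA = EmpiricalFormula(n_C=57, n_H=104, n_O=6)
#: anhydroglucose unit; its carbon fraction is the published 0.444
ANHYDROGLUCOSE_FORMULA = EmpiricalFormula(n_C=6, n_H=10, n_O=5)
#: alternative 5-carbon carbohydrate unit sometimes quoted (fraction 0.4545)
PENTOSAN_FORMULA = EmpiricalFormula(n_C=5, n_H=8, n_O=4)


@dataclass(frozen=True)
class CarbonCoefficients:
    """Carbon mass fractions applied to each proximate fraction."""

    c_protein: float = 0.531
    c_lipid: float = 0.774
    c_carbohydrate: float = 0.444

    def __post_init__(self) -> None:
        for name in ("c_protein", "c_lipid", "c_carbohydrate"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InvalidInputError(f"{name} must lie strictly in (0, 1), got {v}")


@dataclass(frozen=True)
class ProximateComposition:
    """Proximate composition in g per kg of ingredient, as-fed basis.

    ``dry_matter`` is redundant with moisture (dry_matter = 1000 − moisture)
    and is validated against it when supplied; some source tables carry both.
    """

    protein: float = 0.0
    lipid: float = 0.0
    ash: float = 0.0
    moisture: float = 0.0
    carbohydrate: float = 0.0
    dry_matter: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("protein", "lipid", "ash", "moisture", "carbohydrate"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        total = self.protein + self.lipid + self.ash + self.moisture + self.carbohydrate
        if total > _CLOSURE + _CLOSURE_TOL:
            raise InvalidInputError(
                f"proximate fractions sum to {total:.1f} g/kg, above the "
                f"{_CLOSURE:.0f} g/kg closure (tolerance {_CLOSURE_TOL} g/kg)"
            )
        if self.dry_matter is not None:
            if abs(self.dry_matter - (_CLOSURE - self.moisture)) > _CLOSURE_TOL:
                raise InvalidInputError(
                    f"dry_matter {self.dry_matter} inconsistent with moisture "
                    f"{self.moisture} (expected {_CLOSURE - self.moisture})"
                )


def carbon_mass_fraction(
    formula: EmpiricalFormula, masses: MolarMassTable = MolarMassTable()
) -> float:
    """Carbon mass fraction of an empirical formula.

    Returns n_C·M_C / (n_C·M_C + n_H·M_H + n_O·M_O + n_N·M_N), in (0, 1].
    Scale-invariant: multiplying every atom count by k leaves it unchanged.
    """
    carbon = formula.n_C * masses.M_C
    total = (
        carbon
        + formula.n_H * masses.M_H
        + formula.n_O * masses.M_O
        + formula.n_N * masses.M_N
    )
    return carbon / total


def default_carbon_coefficients() -> CarbonCoefficients:
    """The published coefficient triple (0.531, 0.774, 0.444).

    These are the printed three-decimal constants, not recomputed values;
    use :func:`carbon_mass_fraction` to rederive them at full precision.
    """
    return CarbonCoefficients(c_protein=0.531, c_lipid=0.774, c_carbohydrate=0.444)


def carbohydrate_by_difference(
    protein: float, lipid: float, ash: float, moisture: float
) -> float:
    """Carbohydrate content (g/kg) as the as-fed remainder, floored at 0.

    Raises
    ------
    InvalidInputError
        If the four supplied fractions already exceed the 1000 g/kg closure.
    """
    # construct to run the closure validation
    ProximateComposition(protein=protein, lipid=lipid, ash=ash, moisture=moisture)
    return max(0.0, _CLOSURE - protein - lipid - ash - moisture)


def carbon_content(
    comp: ProximateComposition,
    coeffs: CarbonCoefficients = default_carbon_coefficients(),
) -> float:
    """Carbon content in g C per kg ingredient.

    Linear combination of the protein, lipid and carbohydrate fractions with
    their carbon coefficients; ash and moisture carry no carbon.
    """
    return (
        coeffs.c_protein * comp.protein
        + coeffs.c_lipid * comp.lipid
        + coeffs.c_carbohydrate * comp.carbohydrate
    )


def plant_nppu(
    comp: ProximateComposition,
    coeffs: CarbonCoefficients = default_carbon_coefficients(),
) -> NPPUValue:
    """NPPU of a plant-based ingredient.

    Primary producers have trophic level 1, so the amplification factor is 1
    and NPPU in g C/kg equals the carbon content exactly.
    """
    return NPPUValue(
        value_g=carbon_content(comp, coeffs),
        basis="ingredient",
        tier_label="plant",
        allocation_label="none",
    )
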