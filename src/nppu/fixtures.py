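"""Synthetic fixtures with the statistical structure the method assumes.

The generator emulates the input side of the reference tables: species with
trophic levels, trophic-level SDs and ecosystem transfer efficiencies drawn
uniformly from plausible published ranges (TE spans 3.51 %–38.1 %), whole-
body proximate compositions with fish-like moisture (60–80 %) whose
protein/lipid/ash partition closes the 1000 g/kg as-fed budget exactly, and
reduction coproduct specs (meal/oil yields and gross energy densities).

Uniform sampling is deliberate: the literature gives ranges, not fitted
distributions.  Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .allocation import CoproductSpec
from .composition import (
    CarbonCoefficients,
    MolarMassTable,
    ProximateComposition,
    carbohydrate_by_difference,
    carbon_content,
    default_carbon_coefficients,
)
from .errors import InvalidInputError
from .trophic import GenericDefaults, SpeciesRecord, TrophicParameters

_ECOSYSTEMS = (
    "Upwelling", "Temperate shelf", "Tropical shelf", "Open ocean", "Lake/river"
)


@dataclass(frozen=True)
class FixtureConfig:
    """Sampling ranges for the synthetic-species generator.

    Composition ranges are g/kg as-fed; energies MJ/kg; yields are kg of
    coproduct per kg fresh fish.
    """

    n_species: int = 20
    seed: int = 0
    TL_range: Tuple[float, float] = (2.0, 4.5)
    TE_range: Tuple[float, float] = (0.0351, 0.381)
    TL_SD_range: Tuple[float, float] = (0.0, 0.5)
    moisture_range: Tuple[float, float] = (600.0, 800.0)
    yield_meal_range: Tuple[float, float] = (0.15, 0.30)
    yield_oil_range: Tuple[float, float] = (0.02, 0.12)
    energy_meal_range: Tuple[float, float] = (18.0, 22.0)
    energy_oil_range: Tuple[float, float] = (35.0, 42.0)

    def __post_init__(self) -> None:
        if self.n_species < 0:
            raise InvalidInputError("n_species must be non-negative")
        for name in (
            "TL_range", "TE_range", "TL_SD_range", "moisture_range",
            "yield_meal_range", "yield_oil_range",
            "energy_meal_range", "energy_oil_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidInputError(f"{name} must be ordered (lo <= hi)")
        if not (0.0 < self.TE_range[0] and self.TE_range[1] < 1.0):
            raise InvalidInputError("TE_range must lie within (0, 1)")


def _uniform(rng: np.random.Generator, bounds: Tuple[float, float]) -> float:
    return float(rng.uniform(*bounds))


def generate_species(config: FixtureConfig = FixtureConfig()) -> List[SpeciesRecord]:
    """Draw reproducible synthetic SpeciesRecord fixtures.

    Each record's composition closes to 1000 g/kg as-fed by construction
    (carbohydrate by difference is exercised at its boundary), and carries a
    stoichiometric C_specific so every tier policy is satisfiable.
    """
    rng = np.random.default_rng(config.seed)
    records: List[SpeciesRecord] = []
    for i in range(config.n_species):
        trophic = TrophicParameters(
            TL=_uniform(rng, config.TL_range),
            TL_SD=_uniform(rng, config.TL_SD_range),
            TE=_uniform(rng, config.TE_range),
            ecosystem=str(rng.choice(_ECOSYSTEMS)),
        )
        moisture = _uniform(rng, config.moisture_range)
        # protein-heavy partition of the dry remainder, fish-like on average
        parts = rng.dirichlet((6.0, 3.0, 1.5)) * (1000.0 - moisture)
        protein, lipid, ash = (float(p) for p in parts)
        carbohydrate = carbohydrate_by_difference(protein, lipid, ash, moisture)
        comp = ProximateComposition(
            protein=protein,
            lipid=lipid,
            ash=ash,
            moisture=moisture,
            carbohydrate=carbohydrate,
        )
        records.append(
            SpeciesRecord(
                species=f"Synthichthys simulatus {i:03d}",
                common_name=f"synthetic fish {i:03d}",
                common_name_fr=f"poisson synthetique {i:03d}",
                trophic=trophic,
                C_specific=carbon_content(comp),
                composition=comp,
                source_tl="synthetic fixture",
                source_body_composition="synthetic fixture",
                source_te="synthetic fixture",
            )
        )
    return records


def generate_coproduct_specs(
    n: int, seed: int = 0, config: FixtureConfig = FixtureConfig()
) -> List[CoproductSpec]:
    """Draw n reproducible synthetic CoproductSpec fixtures."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        specs.append(
            CoproductSpec(
                yield_meal=_uniform(rng, config.yield_meal_range),
                yield_oil=_uniform(rng, config.yield_oil_range),
                energy_meal=_uniform(rng, config.energy_meal_range),
                energy_oil=_uniform(rng, config.energy_oil_range),
                yield_source="specific",
            )
        )
    return specs


@dataclass(frozen=True)
class ReferenceConstants:
    """The published constant bundle, for tests, docs and worked examples."""

    TE_generic: float
    C_generic: float
    TE_range: Tuple[float, float]
    TE_mean: float
    coefficients: CarbonCoefficients
    molar_masses: MolarMassTable
    plant_TL: float
    milk_TL: float

    @property
    def defaults(self) -> GenericDefaults:
        return GenericDefaults(
            TE_generic=self.TE_generic,
            C_generic=self.C_generic,
            TE_range=self.TE_range,
            TE_mean=self.TE_mean,
        )


def worked_example_fixture() -> ReferenceConstants:
    """The generic defaults and stoichiometric constants of the method."""
    d = GenericDefaults()
    return ReferenceConstants(
        TE_generic=d.TE_generic,
        C_generic=d.C_generic,
        TE_range=d.TE_range,
        TE_mean=d.TE_mean,
        coefficients=default_carbon_coefficients(),
        molar_masses=MolarMassTable(),
        plant_TL=1.0,
        milk_TL=2.0,
    )
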