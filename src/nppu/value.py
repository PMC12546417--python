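"""The NPPU indicator value and its unit conventions.

NPPU (Net Primary Production Use, also called Biotic Resource Use) is the
mass of primary-production carbon appropriated per kilogram of product.  It
is carried internally in g C/kg; the kg C/kg representation is derived by an
exact /1000 so the two unit columns of the published tables can never drift
apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import InvalidInputError

#: basis labels: "fresh" = per kg of fresh (wet) organism, "ingredient" =
#: per kg of processed feed ingredient (meal, oil, plant meal, ...).
BASES = ("fresh", "ingredient")

ALLOCATION_LABELS = ("none", "mass", "energy", "custom")


@dataclass(frozen=True)
class NPPUValue:
    """A characterization-factor value with its provenance labels.

    Parameters
    ----------
    value_g : float
        NPPU in g C per kg of product; must be non-negative.
    basis : str
        "fresh" or "ingredient".
    tier_label : str
        Specificity tier that produced the value ("T1", "T2", "T3",
        "plant", "milk", or a tier x yield label such as "T31").
    allocation_label : str
        "none" for unallocated values, otherwise the coproduct-allocation
        method ("mass", "energy", "custom").
    """

    value_g: float
    basis: str = "fresh"
    tier_label: str = ""
    allocation_label: str = "none"

    def __post_init__(self) -> None:
        if self.value_g < 0:
            raise InvalidInputError(f"NPPU must be non-negative, got {self.value_g}")
        if self.basis not in BASES:
            raise InvalidInputError(f"basis must be one of {BASES}, got {self.basis!r}")
        if self.allocation_label not in ALLOCATION_LABELS:
            raise InvalidInputError(
                f"allocation_label must be one of {ALLOCATION_LABELS}, "
                f"got {self.allocation_label!r}"
            )

    @property
    def value_kg(self) -> float:
        """NPPU in kg C per kg of product (exactly value_g / 1000)."""
        return self.value_g / 1000.0

    def relabel(self, **changes) -> "NPPUValue":
        """Return a copy with updated labels (basis/tier/allocation)."""
        return replace(self, **changes)
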