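"""Species registry: molar masses and carbon counts for Cmol bookkeeping.

Every carbon-containing stream in the reactor balance (substrates, secreted
products, biomass, off-gas CO2) is reduced to moles of carbon ("Cmol") so that
yields of chemically different species are comparable and their sum can be
checked against the carbon supplied.  A :class:`SpeciesCard` carries the two
numbers needed for that conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

__all__ = ["SpeciesCard", "SpeciesRegistry", "default_registry"]


@dataclass(frozen=True)
class SpeciesCard:
    """Molar mass [g/mol] and carbon atoms per molecule of one species."""

    name: str
    molar_mass: float
    carbon_atoms: int

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar_mass must be > 0")
        if self.carbon_atoms < 0:
            raise ValueError(f"{self.name}: carbon_atoms must be >= 0")

    @property
    def cmol_per_gram(self) -> float:
        return self.carbon_atoms / self.molar_mass


class SpeciesRegistry:
    """Name -> SpeciesCard lookup with strict unknown-species errors."""

    def __init__(self, cards: dict[str, SpeciesCard] | None = None):
        self._cards: dict[str, SpeciesCard] = dict(cards or {})

    def add(self, card: SpeciesCard) -> None:
        self._cards[card.name] = card

    def __contains__(self, name: str) -> bool:
        return name in self._cards

    def __getitem__(self, name: str) -> SpeciesCard:
        try:
            return self._cards[name]
        except KeyError:
            known = ", ".join(sorted(self._cards)) or "<empty registry>"
            raise KeyError(f"unknown species {name!r}; registered: {known}") from None

    def names(self) -> list[str]:
        return sorted(self._cards)

    @classmethod
    def from_yaml(cls, path) -> "SpeciesRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        reg = cls()
        for name, spec in raw.items():
            reg.add(SpeciesCard(name, float(spec["molar_mass"]), int(spec["carbon_atoms"])))
        return reg


#: Biomass is handled on a per-Cmol basis: one "Cmol" of generic biomass
#: (CH1.8O0.5N0.2) weighs 24.6 g.  Configurable because the strain-level
#: elemental composition of the organism is rarely measured.
DEFAULT_BIOMASS_CMOL_MASS = 24.6

_DEFAULTS = {
    "glucose": (180.16, 6),
    "msg": (169.11, 5),  # monosodium glutamate, C5H8NNaO4
    "glutamate": (147.13, 5),
    "trehalose": (342.30, 12),
    "co2": (44.01, 1),
    # amino acids observed as secretion products
    "valine": (117.15, 5),
    "glycine": (75.07, 2),
    "alanine": (89.09, 3),
    "serine": (105.09, 3),
    "leucine": (131.17, 6),
    "isoleucine": (131.17, 6),
    "threonine": (119.12, 4),
    "proline": (115.13, 5),
}


def default_registry(biomass_cmol_mass: float = DEFAULT_BIOMASS_CMOL_MASS) -> SpeciesRegistry:
    """Registry preloaded with the species the chemostat pipeline tracks."""
    reg = SpeciesRegistry()
    for name, (mm, c) in _DEFAULTS.items():
        reg.add(SpeciesCard(name, mm, c))
    reg.add(SpeciesCard("biomass", biomass_cmol_mass, 1))
    return reg
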