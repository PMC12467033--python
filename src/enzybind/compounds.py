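"""Compound registry and concentration-unit conversion.

Dose-response and kinetic constants for the six porphyrins are reported in
mass concentration (μg/mL) while binding constants Ka carry molar units
(L/mol), so every quencher concentration must be converted through the
compound's molecular weight.  The default registry is computed from the
molecular formulas of the six porphyrins studied: the three free-base
macrocycles TAPP (5,10,15,20-tetrakis(4-aminophenyl)porphyrin), THPP
(tetrakis(4-hydroxyphenyl)porphyrin) and TCPP
(tetrakis(4-carboxyphenyl)porphyrin), and the Fe/Ni/Cu metal complexes of
TCPP modelled as neutral M(II) chelates (the metal replaces the two inner
pyrrole protons).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .errors import InvariantError, UnknownCompoundError

# Standard atomic weights (IUPAC 2021, g/mol) for the elements appearing in
# the default registry.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Fe": 55.845,
    "Ni": 58.693,
    "Cu": 63.546,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_weight(formula: str) -> float:
    """Molecular weight (g/mol) of a Hill-notation molecular formula."""
    pos = 0
    total = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise InvariantError(f"unparsable molecular formula: {formula!r}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in ATOMIC_MASS:
            raise InvariantError(f"no atomic mass for element {element!r}")
        total += ATOMIC_MASS[element] * (int(count) if count else 1)
    if pos != len(formula) or total == 0.0:
        raise InvariantError(f"unparsable molecular formula: {formula!r}")
    return total


@dataclass(frozen=True)
class CompoundInfo:
    """A named compound with the molecular weight used for unit conversion."""

    name: str
    molecular_weight: float  # g/mol
    notes: str | None = None

    def __post_init__(self):
        if not self.name:
            raise InvariantError("compound name must be non-empty")
        if not (math.isfinite(self.molecular_weight) and self.molecular_weight > 0):
            raise InvariantError(
                f"molecular_weight must be positive and finite, got "
                f"{self.molecular_weight!r} for {self.name!r}"
            )


@dataclass
class CompoundRegistry:
    """Name-unique collection of :class:`CompoundInfo`."""

    compounds: dict[str, CompoundInfo] = field(default_factory=dict)

    def add(self, compound: CompoundInfo, overwrite: bool = False) -> None:
        if compound.name in self.compounds and not overwrite:
            raise InvariantError(f"compound {compound.name!r} already registered")
        self.compounds[compound.name] = compound

    def get(self, name: str) -> CompoundInfo:
        try:
            return self.compounds[name]
        except KeyError:
            raise UnknownCompoundError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self.compounds

    def __iter__(self):
        return iter(self.compounds.values())


_DEFAULT_FORMULAS = {
    "TAPP": "C44H34N8",
    "THPP": "C44H30N4O4",
    "TCPP": "C48H30N4O8",
    "Fe-TCPP": "C48H28FeN4O8",
    "Ni-TCPP": "C48H28N4NiO8",
    "Cu-TCPP": "C48H28CuN4O8",
}


def default_registry() -> CompoundRegistry:
    """Registry of the six porphyrins with formula-derived molecular weights."""
    registry = CompoundRegistry()
    for name, formula in _DEFAULT_FORMULAS.items():
        registry.add(CompoundInfo(name, formula_weight(formula), notes=formula))
    return registry


def ug_per_ml_to_mol_per_l(value: float, compound: CompoundInfo) -> float:
    """Convert a mass concentration in μg/mL to mol/L.

    μg/mL equals mg/L, so the molar concentration is ``value · 1e-3 / MW``.
    """
    return value * 1e-3 / compound.molecular_weight


def mol_per_l_to_ug_per_ml(value: float, compound: CompoundInfo) -> float:
    """Inverse of :func:`ug_per_ml_to_mol_per_l`."""
    return value * 1e3 * compound.molecular_weight
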