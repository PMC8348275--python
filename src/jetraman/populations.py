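"""Equilibrium and jet-relaxed conformer population models.

Before the expansion the conformer ensemble is Boltzmann distributed over
relative energies (ΔE0 or ΔG°, kJ/mol) with a degeneracy factor g — 2 for
chiral enantiomeric pairs, 1 for achiral conformers. Collisional cooling in
the jet funnels conformers across low barriers: below ~5 kJ/mol a barrier
is easily overcome, above ~10 kJ/mol it is essentially frozen. Full
relaxation of a soft torsion is modelled by pooling conformer families
(summing the members' pre-expansion fractions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import R_KJ_MOL_K

__all__ = [
    "ConformerEnergetics",
    "boltzmann_populations",
    "pool_families",
    "classify_relaxation",
]


@dataclass
class ConformerEnergetics:
    """Relative energies (kJ/mol, any common reference) and degeneracy of a conformer."""

    name: str
    degeneracy: int = 1
    energies: dict[str, float] = field(default_factory=dict)
    family: str | None = None

    def __post_init__(self) -> None:
        if self.degeneracy < 1:
            raise ValueError(f"{self.name}: degeneracy must be >= 1")


def boltzmann_populations(
    confs: list[ConformerEnergetics], energy_key: str, T: float
) -> dict[str, float]:
    """Equilibrium fractions p_i ∝ g_i·exp(−ΔE_i/RT) at temperature T (K)."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    names, w = [], []
    for c in confs:
        if energy_key not in c.energies:
            raise KeyError(f"conformer {c.name!r} has no energy value {energy_key!r}")
        names.append(c.name)
        w.append(c.degeneracy * np.exp(-c.energies[energy_key] / (R_KJ_MOL_K * T)))
    w = np.asarray(w)
    return dict(zip(names, w / w.sum()))


def pool_families(
    populations: dict[str, float], family_map: dict[str, str]
) -> dict[str, float]:
    """Sum member fractions into family fractions (full torsional relaxation)."""
    pooled: dict[str, float] = {}
    for name, p in populations.items():
        if name not in family_map:
            raise KeyError(f"conformer {name!r} has no family mapping")
        fam = family_map[name]
        pooled[fam] = pooled.get(fam, 0.0) + p
    return pooled


def classify_relaxation(barrier: float, easy: float = 5.0, hard: float = 10.0) -> str:
    """Classify an interconversion barrier (kJ/mol): 'relaxes', 'partial' or 'frozen'."""
    if barrier < 0:
        raise ValueError("barrier must be >= 0")
    if barrier < easy:
        return "relaxes"
    if barrier > hard:
        return "frozen"
    return "partial"
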