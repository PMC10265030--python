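"""Foraging-capability statements from biomechanical state.

Whether a worker can cut a leaf is a ratio of two forces: its maximum bite
force and the minimum force needed to initiate and propagate a cut through
lamina and veins.  Against a population of leaf cutting forces this gives an
empirical-CDF "cuttable fraction".  Load carriage and the muscle force
budget complete the picture: carrying is gravitationally cheap (a 15 mg
fragment weighs 0.15 mN) while the closer muscle can deliver hundreds of mN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import LeafPopulation
from .units import STANDARD_GRAVITY, weight_mn

__all__ = [
    "ForagingAssessment",
    "cuttable_fraction",
    "carriage_force",
    "muscle_force_budget",
    "assess_foraging",
]


@dataclass(frozen=True)
class ForagingAssessment:
    cuttable_fraction: float
    cuttable_fraction_at_median: bool  # bite force reaches the population median
    carriage_force_mN: float
    muscle_force_total_mN: float
    weight_multiple: float


def cuttable_fraction(bite_force_mN: float, leaves: LeafPopulation) -> float:
    """Fraction of leaves whose cutting force is ≤ the bite force.

    Ties count as cuttable: the cutting force is the minimum force that must
    be reached to start a cut.
    """
    if bite_force_mN <= 0:
        raise ValueError("bite force must be positive")
    forces = np.asarray(leaves.cutting_forces_mN, dtype=float)
    if forces.size == 0:
        raise ValueError("empty leaf population")
    return float(np.mean(forces <= bite_force_mN))


def carriage_force(fragment_mass_mg: float, g: float = STANDARD_GRAVITY) -> float:
    """Gravitational force (mN) to be overcome when carrying a fragment."""
    if fragment_mass_mg < 0:
        raise ValueError("mass must be non-negative")
    return weight_mn(fragment_mass_mg, g)


def muscle_force_budget(n_fibres: int, force_per_fibre_mN: float,
                        body_mass_mg: float, g: float = STANDARD_GRAVITY):
    """Total closer-muscle force (mN) and its multiple of body weight."""
    if n_fibres < 0 or force_per_fibre_mN < 0 or body_mass_mg <= 0:
        raise ValueError("fibre count/force must be >= 0 and body mass > 0")
    total = n_fibres * force_per_fibre_mN
    return total, total / weight_mn(body_mass_mg, g)


def assess_foraging(
    bite_force_mN: float,
    leaves: LeafPopulation,
    fragment_mass_mg: float = 15.0,
    n_fibres: int = 1000,
    force_per_fibre_mN: float = 0.70,
    body_mass_mg: float = 5.0,
    g: float = STANDARD_GRAVITY,
) -> ForagingAssessment:
    """Full capability statement for one ant against a leaf population."""
    frac = cuttable_fraction(bite_force_mN, leaves)
    total, mult = muscle_force_budget(n_fibres, force_per_fibre_mN, body_mass_mg, g)
    median = float(np.median(leaves.cutting_forces_mN))
    return ForagingAssessment(
        cuttable_fraction=frac,
        cuttable_fraction_at_median=bite_force_mN >= median,
        carriage_force_mN=carriage_force(fragment_mass_mg, g),
        muscle_force_total_mN=total,
        weight_multiple=mult,
    )
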