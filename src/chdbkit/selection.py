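"""Deterministic one-locus, two-allele viability selection under random mating.

Zygotes form in Hardy–Weinberg proportions each generation and survive with
genotype-specific relative viabilities w = (w11, w12, w22).  Writing q for
the frequency of allele 2 and p = 1 - q, the next-generation frequency is

    q' = (q^2 * w22 + p*q * w12) / wbar,
    wbar = p^2 * w11 + 2*p*q * w12 + q^2 * w22.

With the viabilities estimated from the goldfish F2 segregants the minor
chdB2 allele declines toward loss from any starting frequency below 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .datatypes import FitnessTriple

#: Sentinel returned when a trajectory never crosses the queried threshold.
NOT_REACHED = None


@dataclass(frozen=True)
class SelectionModel:
    fitness: FitnessTriple
    q0: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError(f"initial frequency must be in [0, 1], got {self.q0}")


@dataclass(frozen=True)
class Trajectory:
    """Per-generation allele-2 frequency and mean fitness; index = generation."""

    q: np.ndarray
    mean_fitness: np.ndarray

    @property
    def generations(self) -> int:
        return len(self.q) - 1


class Equilibrium(Enum):
    ALLELE1_FIXES = "allele1_fixes"
    ALLELE2_FIXES = "allele2_fixes"
    STABLE_POLYMORPHISM = "stable_polymorphism"
    UNSTABLE_POLYMORPHISM = "unstable_polymorphism"
    NEUTRAL = "neutral"


def mean_fitness(q: float, w: FitnessTriple) -> float:
    p = 1.0 - q
    return p * p * w.w11 + 2.0 * p * q * w.w12 + q * q * w.w22


def step(q: float, w: FitnessTriple) -> float:
    """One generation of viability selection; q is the allele-2 frequency."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"frequency must be in [0, 1], got {q}")
    wbar = mean_fitness(q, w)
    if wbar <= 0.0:
        raise ValueError("mean fitness is zero: all present genotypes are inviable")
    p = 1.0 - q
    return (q * q * w.w22 + p * q * w.w12) / wbar


def project(model: SelectionModel, generations: int) -> Trajectory:
    """Iterate the recursion; q[0] is the initial frequency."""
    if generations < 0:
        raise ValueError("generations must be non-negative")
    q = np.empty(generations + 1)
    wbar = np.empty(generations + 1)
    q[0] = model.q0
    wbar[0] = mean_fitness(model.q0, model.fitness)
    for g in range(generations):
        q[g + 1] = step(q[g], model.fitness)
        wbar[g + 1] = mean_fitness(q[g + 1], model.fitness)
    return Trajectory(q=q, mean_fitness=wbar)


def generations_until_below(
    model: SelectionModel, threshold: float, cap: int = 1000
) -> int | None:
    """Smallest generation g <= cap with q[g] < threshold, else NOT_REACHED."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be strictly between 0 and 1")
    if cap < 1:
        raise ValueError("cap must be at least 1")
    q = model.q0
    if q < threshold:
        return 0
    for g in range(1, cap + 1):
        q = step(q, model.fitness)
        if q < threshold:
            return g
    return NOT_REACHED


def equilibrium_check(w: FitnessTriple) -> Equilibrium:
    """Classify the long-run behavior implied by a viability triple.

    Overdominance (heterozygote fittest) gives a stable interior equilibrium
    at q* = (w11 - w12) / (w11 + w22 - 2*w12); underdominance gives the same
    point but unstable.  Otherwise the fitter homozygote's allele fixes.
    """
    w11, w12, w22 = w.as_tuple()
    if w11 == w12 == w22:
        return Equilibrium.NEUTRAL
    if w12 > w11 and w12 > w22:
        return Equilibrium.STABLE_POLYMORPHISM
    if w12 < w11 and w12 < w22:
        return Equilibrium.UNSTABLE_POLYMORPHISM
    # directional: ordering with at least one strict inequality
    if w11 >= w22:
        return Equilibrium.ALLELE1_FIXES
    return Equilibrium.ALLELE2_FIXES


def polymorphic_equilibrium(w: FitnessTriple) -> float | None:
    """Interior equilibrium allele-2 frequency, if one exists."""
    kind = equilibrium_check(w)
    if kind not in (Equilibrium.STABLE_POLYMORPHISM, Equilibrium.UNSTABLE_POLYMORPHISM):
        return None
    w11, w12, w22 = w.as_tuple()
    return (w11 - w12) / (w11 + w22 - 2.0 * w12)
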