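"""Shared containers for genotype counts and relative viabilities.

The goldfish chdB locus carries two alleles (chdB1, the major allele, and
chdB2, the minor one), so every cross produces three genotype classes:
1/1, 1/2 and 2/2.  Counts of those classes are the unit of all segregation
inference, and relative viabilities (w11, w12, w22) are both the output of
viability estimation and the input to the selection recursion.
"""

from __future__ import annotations

from dataclasses import dataclass

GENOTYPES = ("11", "12", "22")


@dataclass(frozen=True)
class GenotypeCounts:
    """Tallies of the three genotype classes in one sample or cross."""

    n11: int
    n12: int
    n22: int
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("n11", "n12", "n22"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n22

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n11, self.n12, self.n22)


@dataclass(frozen=True)
class FitnessTriple:
    """Relative viabilities of the three genotypes (reference genotype = 1)."""

    w11: float
    w12: float
    w22: float

    def __post_init__(self) -> None:
        values = self.as_tuple()
        if any(w < 0 for w in values):
            raise ValueError(f"viabilities must be non-negative, got {values}")
        if all(w == 0 for w in values):
            raise ValueError("at least one viability must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w11, self.w12, self.w22)

    def scaled(self, factor: float) -> "FitnessTriple":
        if factor <= 0:
            raise ValueError("scaling factor must be positive")
        return FitnessTriple(self.w11 * factor, self.w12 * factor, self.w22 * factor)
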