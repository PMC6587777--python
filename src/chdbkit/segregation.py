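"""Genotype/allele frequencies, Mendelian segregation tests, and viability estimation.

An F2 cross of two chdB heterozygotes should segregate 1:2:1.  Observed
deviations from that ratio, with all fish raised under identical conditions,
are read as genotype-dependent viability: dividing each observed genotype
proportion by its Mendelian expectation and normalizing to a reference
genotype gives relative viabilities (w11, w12, w22).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import GENOTYPES, FitnessTriple, GenotypeCounts

MENDELIAN_F2 = (0.25, 0.5, 0.25)


@dataclass(frozen=True)
class FrequencyEstimate:
    """Genotype proportions and the frequency of allele 2."""

    genotype_freqs: tuple[float, float, float]
    allele2_freq: float
    n: int


@dataclass(frozen=True)
class SegregationTest:
    chi_square: float
    df: int
    p_value: float
    expected: tuple[float, float, float]


def _check_expected(expected) -> tuple[float, float, float]:
    expected = tuple(float(e) for e in expected)
    if len(expected) != 3:
        raise ValueError("expected must have three entries")
    if any(e <= 0 for e in expected):
        raise ValueError("expected probabilities must all be positive")
    total = sum(expected)
    return tuple(e / total for e in expected)


def estimate_frequencies(counts: GenotypeCounts) -> FrequencyEstimate:
    """Genotype proportions and allele-2 frequency (n12 + 2*n22)/(2N)."""
    n = counts.total
    if n == 0:
        raise ValueError("cannot estimate frequencies from zero counts")
    freqs = tuple(c / n for c in counts.as_tuple())
    q = (counts.n12 + 2 * counts.n22) / (2 * n)
    return FrequencyEstimate(genotype_freqs=freqs, allele2_freq=q, n=n)


def pool(tables: list[GenotypeCounts], label: str = "pooled") -> GenotypeCounts:
    """Elementwise sum of genotype tables (e.g. strains or crosses)."""
    if not tables:
        raise ValueError("cannot pool an empty list of tables")
    return GenotypeCounts(
        n11=sum(t.n11 for t in tables),
        n12=sum(t.n12 for t in tables),
        n22=sum(t.n22 for t in tables),
        label=label,
    )


def mendelian_test(
    counts: GenotypeCounts, expected=MENDELIAN_F2
) -> SegregationTest:
    """Pearson chi-square test of observed counts against expected proportions.

    No continuity correction; the p-value comes from the chi-square
    distribution with df = 2.
    """
    expected = _check_expected(expected)
    n = counts.total
    if n == 0:
        raise ValueError("cannot test zero counts")
    f_exp = np.asarray(expected) * n
    chi2, p = stats.chisquare(f_obs=np.asarray(counts.as_tuple()), f_exp=f_exp)
    return SegregationTest(
        chi_square=float(chi2), df=len(expected) - 1, p_value=float(p), expected=expected
    )


def estimate_viability(
    counts: GenotypeCounts,
    expected=MENDELIAN_F2,
    reference: str | int = "11",
) -> FitnessTriple:
    """Relative viabilities from segregant counts.

    Each genotype's observed proportion is divided by its expected Mendelian
    proportion, then the triple is normalized so the reference genotype
    (chdB 1/1 by default) has viability 1.
    """
    expected = _check_expected(expected)
    reference = str(reference)
    if reference not in GENOTYPES:
        raise ValueError(f"reference must be one of {GENOTYPES}")
    n = counts.total
    if n == 0:
        raise ValueError("cannot estimate viability from zero counts")
    ref_index = GENOTYPES.index(reference)
    if counts.as_tuple()[ref_index] == 0:
        raise ValueError(f"reference genotype {reference} has zero observed count")
    ratios = [obs / n / e for obs, e in zip(counts.as_tuple(), expected)]
    w = [r / ratios[ref_index] for r in ratios]
    return FitnessTriple(*w)


def round_triple(values, decimals: int = 3) -> tuple[float, ...]:
    """Presentation rounding; estimation itself keeps full precision."""
    seq = values.as_tuple() if hasattr(values, "as_tuple") else tuple(values)
    return tuple(round(float(v), decimals) for v in seq)


def viability_ci(
    counts: GenotypeCounts,
    replicates: int = 2000,
    seed: int = 0,
    expected=MENDELIAN_F2,
    reference: str | int = "11",
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Percentile-bootstrap confidence intervals for the relative viabilities.

    Resamples N fish multinomially from the observed genotype proportions
    and re-estimates the viability triple per replicate.  Replicates in which
    the reference genotype draws zero fish cannot be normalized and are
    dropped (vanishingly rare at the sample sizes this assay uses).
    """
    if replicates < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    expected = _check_expected(expected)
    reference = str(reference)
    ref_index = GENOTYPES.index(reference)
    n = counts.total
    obs_props = np.asarray(counts.as_tuple()) / n
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, obs_props, size=replicates).astype(float)

    keep = draws[:, ref_index] > 0
    draws = draws[keep]
    ratios = draws / n / np.asarray(expected)
    w = ratios / ratios[:, [ref_index]]
    alpha = (1 - level) / 2
    lo = np.quantile(w, alpha, axis=0)
    hi = np.quantile(w, 1 - alpha, axis=0)
    return {g: (float(lo[i]), float(hi[i])) for i, g in enumerate(GENOTYPES)}
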