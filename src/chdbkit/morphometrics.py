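"""Caudal-fin ray indices, phenotype grouping, and left–right symmetry statistics.

Twin-tail goldfish carry bifurcated caudal fins whose rays are counted in
three blocks: midline non-bifurcated rays (cfrM) and the left and right
bifurcated lobes (cfrL, cfrR).  The maximum caudal fin ray index,
cfrM + max(cfrL, cfrR), separates a "less" ray-count group (index below a
threshold, 20 by default) from the "normal" group, and Spearman rank
correlation of (cfrL, cfrR) per genotype quantifies left–right symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .datatypes import GENOTYPES

DEFAULT_THRESHOLD = 20

SINGLE = "single"
BIFURCATED = "bifurcated"
LESS = "less"
NORMAL = "normal"


@dataclass(frozen=True)
class FinRayRecord:
    fish_id: str
    genotype: str
    cfrM: int
    cfrL: int
    cfrR: int

    def __post_init__(self) -> None:
        if str(self.genotype) not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        object.__setattr__(self, "genotype", str(self.genotype))
        for name in ("cfrM", "cfrL", "cfrR"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class MorphoClassification:
    tail_type: str
    fin_count_group: str
    max_caudal_index: int


@dataclass(frozen=True)
class SymmetryResult:
    """Spearman rho of (cfrL, cfrR) for one genotype; rho None when undefined."""

    rho: float | None
    p_value: float | None
    n: int


def max_caudal_index(rec: FinRayRecord) -> int:
    """cfrM + max(cfrL, cfrR): maximal ray count along the dorsal–ventral axis."""
    return rec.cfrM + max(rec.cfrL, rec.cfrR)


def classify(rec: FinRayRecord, threshold: int = DEFAULT_THRESHOLD) -> MorphoClassification:
    """Tail type and ray-count group for one fish.

    A fish is single-tailed when it has no bifurcated lobe rays at all
    (cfrL = cfrR = 0).  Indices at or above the threshold count as normal;
    the boundary value itself is assigned to the normal group.
    """
    index = max_caudal_index(rec)
    tail = SINGLE if rec.cfrL == 0 and rec.cfrR == 0 else BIFURCATED
    group = LESS if index < threshold else NORMAL
    return MorphoClassification(tail_type=tail, fin_count_group=group, max_caudal_index=index)


def symmetry_by_genotype(
    records: list[FinRayRecord],
    bifurcated_only: bool = True,
    min_n: int = 3,
) -> dict[str, SymmetryResult]:
    """Per-genotype Spearman rank correlation between left and right lobe rays.

    Ties are handled by average ranks (scipy's default).  Genotypes with
    fewer than ``min_n`` usable fish, or with a constant variable, get
    rho = None with the sample size still reported.
    """
    out: dict[str, SymmetryResult] = {}
    for genotype in GENOTYPES:
        subset = [r for r in records if r.genotype == genotype]
        if bifurcated_only:
            subset = [r for r in subset if classify(r).tail_type == BIFURCATED]
        n = len(subset)
        if n < min_n:
            out[genotype] = SymmetryResult(rho=None, p_value=None, n=n)
            continue
        left = [r.cfrL for r in subset]
        right = [r.cfrR for r in subset]
        if len(set(left)) == 1 or len(set(right)) == 1:
            out[genotype] = SymmetryResult(rho=None, p_value=None, n=n)
            continue
        res = stats.spearmanr(left, right)
        out[genotype] = SymmetryResult(
            rho=float(res.statistic), p_value=float(res.pvalue), n=n
        )
    return out


@dataclass(frozen=True)
class GroupSummary:
    group_counts: dict[str, int]
    tail_counts: dict[str, int]
    mean_index_by_group: dict[str, float]


def group_summary(
    records: list[FinRayRecord],
    classifications: list[MorphoClassification] | None = None,
    threshold: int = DEFAULT_THRESHOLD,
) -> GroupSummary:
    """Counts per ray-count group and tail type, with mean index per group."""
    if classifications is None:
        classifications = [classify(r, threshold) for r in records]
    if len(classifications) != len(records):
        raise ValueError("records and classifications must be parallel lists")
    group_counts = {LESS: 0, NORMAL: 0}
    tail_counts = {SINGLE: 0, BIFURCATED: 0}
    index_sums = {LESS: 0.0, NORMAL: 0.0}
    for c in classifications:
        group_counts[c.fin_count_group] += 1
        tail_counts[c.tail_type] += 1
        index_sums[c.fin_count_group] += c.max_caudal_index
    means = {
        g: (index_sums[g] / group_counts[g]) if group_counts[g] else float("nan")
        for g in (LESS, NORMAL)
    }
    return GroupSummary(
        group_counts=group_counts, tail_counts=tail_counts, mean_index_by_group=means
    )
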