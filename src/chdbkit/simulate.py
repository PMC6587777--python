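"""Seeded generators emulating every input the chdB pipeline consumes.

Each generator is a pure function of its spec and seed and returns, besides
the dataset, a truth record sufficient to score the downstream analysis:

* F2 het x het crosses with genotype-dependent viability (one multinomial
  draw with category probabilities proportional to Mendelian ratio x fitness);
* Wright–Fisher allele-frequency trajectories (deterministic selection step,
  then binomial resampling of 2N allele copies);
* allele coding-sequence pairs with planted synonymous/nonsynonymous SNP
  counts, an allele-specific ClaI site, and genotyping templates that
  amplify to the assay's 334-bp product;
* bivariate left/right fin-ray counts with genotype-specific rank
  correlation (Gaussian copula over negative-binomial marginals, plus a
  low-count mode and a single-tail mode);
* embryo stage measurements spanning the blastopore-closure window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import FitnessTriple, GenotypeCounts
from .embryo import TREATMENTS, EmbryoMeasurement, blastopore_closure, szl_proportion
from .morphometrics import FinRayRecord
from .selection import step
from .sequence import (
    CHDB_PRIMERS,
    CLAI,
    CodingSequence,
    PrimerPair,
    RestrictionEnzyme,
    SnpRecord,
    _codon_map,
    find_sites,
    reverse_complement,
)
from .sequence import NONSYNONYMOUS, SYNONYMOUS

#: Viabilities estimated from the goldfish F2 segregants; the study condition
#: most generators default to.
CHDB_FITNESS = FitnessTriple(1.0, 0.732, 0.507)

_AA_OF = _codon_map(1)
_SENSE_CODONS = sorted(c for c, aa in _AA_OF.items() if aa != "*")

#: Assay geometry: 334-bp product, ClaI site starting 100 bases into it,
#: giving the 102 + 232 cut fragments.
AMPLICON_LENGTH = 334
SITE_OFFSET_IN_AMPLICON = 100


# --- F2 crosses -------------------------------------------------------------


@dataclass(frozen=True)
class CrossSpec:
    """An F2 het x het cross with genotype-dependent survival."""

    n_offspring: int = 205
    fitness: FitnessTriple = CHDB_FITNESS
    mendelian: tuple[float, float, float] = (0.25, 0.5, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_offspring <= 0:
            raise ValueError("n_offspring must be positive")
        if any(p < 0 for p in self.mendelian) or abs(sum(self.mendelian) - 1) > 1e-9:
            raise ValueError("mendelian probabilities must be non-negative and sum to 1")


def simulate_f2_genotypes(spec: CrossSpec) -> GenotypeCounts:
    """One multinomial draw of surviving genotypes.

    Category probabilities are the Mendelian zygote ratios weighted by the
    genotype viabilities and renormalized.
    """
    w = np.asarray(spec.fitness.as_tuple())
    probs = np.asarray(spec.mendelian) * w
    probs = probs / probs.sum()
    rng = np.random.default_rng(spec.seed)
    n11, n12, n22 = rng.multinomial(spec.n_offspring, probs)
    return GenotypeCounts(
        n11=int(n11), n12=int(n12), n22=int(n22), label=f"sim-seed{spec.seed}"
    )


# --- Wright–Fisher ----------------------------------------------------------


def wright_fisher(
    N: int,
    q0: float,
    w: FitnessTriple,
    generations: int,
    replicates: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Finite-population trajectories: selection step, then binomial drift.

    Returns an array of shape (replicates, generations + 1); column g is the
    allele-2 frequency at generation g.  Frequencies 0 and 1 are absorbing.
    """
    if N < 1:
        raise ValueError("population size must be at least 1")
    if not 0.0 <= q0 <= 1.0:
        raise ValueError("q0 must be in [0, 1]")
    if generations < 0 or replicates < 1:
        raise ValueError("generations must be >= 0 and replicates >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty((replicates, generations + 1))
    out[:, 0] = q0
    q = np.full(replicates, q0)
    w11, w12, w22 = w.as_tuple()
    for g in range(1, generations + 1):
        p = 1.0 - q
        wbar = p * p * w11 + 2.0 * p * q * w12 + q * q * w22
        q_sel = np.where(wbar > 0, (q * q * w22 + p * q * w12) / np.where(wbar > 0, wbar, 1.0), q)
        q = rng.binomial(2 * N, q_sel) / (2.0 * N)
        out[:, g] = q
    return out


# --- allele sequence pairs --------------------------------------------------


@dataclass(frozen=True)
class SequencePlantSpec:
    """Plan for a synthetic allele pair with known SNP content.

    At most one SNP is planted per codon so every planted label is
    unambiguous; one of the nonsynonymous SNPs toggles the ClaI site carried
    by ``site_allele``.  Defaults mirror the chdB comparison: 929 codons
    (2787 coding sites) with 42 SNPs, 14 of them nonsynonymous.
    """

    n_codons: int = 929
    n_synonymous: int = 28
    n_nonsynonymous: int = 14
    site_allele: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_allele not in (1, 2):
            raise ValueError("site_allele must be 1 or 2")
        if self.n_synonymous < 0 or self.n_nonsynonymous < 0:
            raise ValueError("planted SNP counts must be non-negative")
        if self.n_codons < self.n_synonymous + self.n_nonsynonymous + 3:
            raise ValueError("too few codons for the requested SNP plant")


@dataclass(frozen=True)
class AllelePairTruth:
    snps: tuple[SnpRecord, ...]
    site_allele: int | None
    site_start: int | None  # ClaI site start in the site allele's coding sequence
    n_synonymous: int
    n_nonsynonymous: int


@dataclass(frozen=True)
class AllelePair:
    allele1: CodingSequence
    allele2: CodingSequence
    truth: AllelePairTruth
    primers: PrimerPair
    enzyme: RestrictionEnzyme
    templates: dict[int, str] = field(default_factory=dict)


def _classify(codon_ref: str, pos_in_codon: int, alt: str) -> str:
    mutated = codon_ref[:pos_in_codon] + alt + codon_ref[pos_in_codon + 1 :]
    return SYNONYMOUS if _AA_OF[mutated] == _AA_OF[codon_ref] else NONSYNONYMOUS


def _has_site_near(seq: str, pos: int, site: str) -> bool:
    lo = max(0, pos - len(site) + 1)
    return site in seq[lo : pos + len(site)]


def _scrub_sites(
    codons: list[str], protected: set[int], site: str, rng, allowed: set[int] = frozenset()
) -> None:
    """Resample unprotected codons until `site` occurs only at `allowed` starts."""
    for _ in range(10_000):
        seq = "".join(codons)
        hits = find_sites(seq, RestrictionEnzyme("tmp", site, 0))
        hits = [h for h in hits if h not in allowed]
        fixed = False
        for h in hits:
            for ci in range(h // 3, (h + len(site) - 1) // 3 + 1):
                if ci not in protected and ci < len(codons):
                    codons[ci] = rng.choice(_SENSE_CODONS)
                    fixed = True
                    break
            if fixed:
                break
        if not hits:
            return
        if not fixed:
            raise RuntimeError("restriction site overlaps only protected codons")
    raise RuntimeError("failed to scrub restriction sites")


def generate_allele_pair(
    spec: SequencePlantSpec, include_templates: bool = True
) -> AllelePair:
    """Build two coding sequences differing by exactly the planted SNPs.

    Allele 1 is the reference.  The site-bearing allele carries ATC|GAT
    (Ile-Asp) across two adjacent codons, forming the ClaI site; the other
    allele carries ATC|CAT (Ile-His), so the site-toggling SNP is a
    nonsynonymous Asp/His exchange.  Optionally builds, per allele, a
    genomic-style genotyping template whose amplicon with the published
    primers is exactly 334 bp with the ClaI site 100 bases in.
    """
    rng = np.random.default_rng(spec.seed)
    last_error: Exception | None = None
    for _ in range(20):  # rare unluckly draws are retried with the same stream
        try:
            return _generate_allele_pair_once(spec, rng, include_templates)
        except RuntimeError as exc:
            last_error = exc
    raise RuntimeError(f"allele-pair generation failed: {last_error}")


def _generate_allele_pair_once(
    spec: SequencePlantSpec, rng: np.random.Generator, include_templates: bool
) -> AllelePair:
    n = spec.n_codons
    site = CLAI.recognition_site

    # reference backbone: ATG start, random sense codons elsewhere
    codons1 = ["ATG"] + [rng.choice(_SENSE_CODONS) for _ in range(n - 1)]
    has_site = spec.n_nonsynonymous >= 1  # the site-toggling SNP is nonsynonymous

    if has_site:
        c0 = int(rng.integers(1, n - 1))  # engineered pair occupies codons c0, c0+1
        if spec.site_allele == 1:
            codons1[c0], codons1[c0 + 1] = "ATC", "GAT"  # spells ATCGAT
        else:
            codons1[c0], codons1[c0 + 1] = "ATC", "CAT"
        protected = {0, c0, c0 + 1}

        # remove every accidental ClaI site from both sequence variants
        def _variant_hits(variant_codon: str) -> list[int]:
            trial = list(codons1)
            trial[c0 + 1] = variant_codon
            allowed = {3 * c0} if variant_codon == "GAT" else set()
            return [h for h in find_sites("".join(trial), CLAI) if h not in allowed]

        for _ in range(100):
            for variant_codon in ("GAT", "CAT"):
                trial = list(codons1)
                trial[c0 + 1] = variant_codon
                allowed = {3 * c0} if variant_codon == "GAT" else set()
                _scrub_sites(trial, protected, site, rng, allowed=allowed)
                for i, c in enumerate(trial):
                    if i != c0 + 1:
                        codons1[i] = c
            # a repair for one variant can re-create a site in the other
            if not _variant_hits("GAT") and not _variant_hits("CAT"):
                break
        else:
            raise RuntimeError("could not build a site-clean backbone")

        codons2 = list(codons1)
        codons2[c0 + 1] = "GAT" if spec.site_allele == 2 else "CAT"
        n_extra = spec.n_synonymous + spec.n_nonsynonymous - 1
    else:
        # no nonsynonymous SNPs requested: no polymorphic site to engineer
        c0 = None
        protected = {0}
        _scrub_sites(codons1, protected, site, rng)
        codons2 = list(codons1)
        n_extra = spec.n_synonymous

    # plant the remaining SNPs, one per codon, away from the engineered pair
    available = [i for i in range(n) if i not in protected]
    chosen = rng.choice(len(available), size=n_extra, replace=False)
    targets = [available[i] for i in chosen]
    effects = [SYNONYMOUS] * spec.n_synonymous + [NONSYNONYMOUS] * max(
        0, spec.n_nonsynonymous - 1
    )

    for ci, wanted in zip(targets, effects):
        for _ in range(1000):
            codon = codons1[ci]
            pos = int(rng.integers(3))
            alt = rng.choice([b for b in "ACGT" if b != codon[pos]])
            mutated = codon[:pos] + alt + codon[pos + 1 :]
            if _AA_OF[mutated] == "*":
                continue
            if _classify(codon, pos, alt) != wanted:
                # ATG/TGG have no synonymous neighbors: swap in a codon that does
                if wanted == SYNONYMOUS and codon in ("ATG", "TGG"):
                    replacement = rng.choice(
                        [c for c in _SENSE_CODONS if c not in ("ATG", "TGG")]
                    )
                    trial1 = list(codons1)
                    trial1[ci] = replacement
                    seq_pos = 3 * ci
                    if not _has_site_near("".join(trial1), seq_pos, site):
                        codons1[ci] = replacement
                        codons2[ci] = replacement
                continue
            trial2 = list(codons2)
            trial2[ci] = mutated
            seq2 = "".join(trial2)
            if _has_site_near(seq2, 3 * ci + pos, site):
                continue
            codons2[ci] = mutated
            break
        else:
            raise RuntimeError(f"could not plant a {wanted} SNP in codon {codons1[ci]}")

    seq1, seq2 = "".join(codons1), "".join(codons2)
    allele1 = CodingSequence(id="chdB1-synthetic", residues=seq1)
    allele2 = CodingSequence(id="chdB2-synthetic", residues=seq2)

    snps = []
    for pos, (ra, rb) in enumerate(zip(seq1, seq2)):
        if ra == rb:
            continue
        ci, cp = pos // 3, pos % 3
        codon_a = seq1[3 * ci : 3 * ci + 3]
        snps.append(
            SnpRecord(
                position=pos,
                ref_base=ra,
                alt_base=rb,
                codon_index=ci,
                codon_position=cp,
                effect=_classify(codon_a, cp, rb),
            )
        )
    expect1 = [3 * c0] if has_site and spec.site_allele == 1 else []
    expect2 = [3 * c0] if has_site and spec.site_allele == 2 else []
    if find_sites(seq1, CLAI) != expect1 or find_sites(seq2, CLAI) != expect2:
        raise RuntimeError("planting created or destroyed a restriction site")

    n_nonsyn = sum(1 for s in snps if s.effect == NONSYNONYMOUS)
    truth = AllelePairTruth(
        snps=tuple(snps),
        site_allele=spec.site_allele if has_site else None,
        site_start=3 * c0 if has_site else None,
        n_synonymous=len(snps) - n_nonsyn,
        n_nonsynonymous=n_nonsyn,
    )
    if len(snps) != spec.n_synonymous + spec.n_nonsynonymous:
        raise RuntimeError("planted SNP bookkeeping failed")

    templates: dict[int, str] = {}
    if include_templates:
        anchor = 3 * c0 if has_site else 3 * (n // 2)
        templates = _build_templates(seq1, seq2, anchor, rng)
    return AllelePair(
        allele1=allele1,
        allele2=allele2,
        truth=truth,
        primers=CHDB_PRIMERS,
        enzyme=CLAI,
        templates=templates,
    )


def _random_bases(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n else ""


def _build_templates(seq1: str, seq2: str, site_start: int, rng) -> dict[int, str]:
    """Per-allele genotyping templates: flank + primer + interior + primer + flank.

    The interior is a window of the coding sequence placed so the
    (potential) ClaI site starts 100 bases into the 334-bp amplicon, padded
    with shared random bases where the coding sequence runs out.
    """
    fwd = CHDB_PRIMERS.forward
    rc_rev = reverse_complement(CHDB_PRIMERS.reverse)
    interior_len = AMPLICON_LENGTH - len(fwd) - len(rc_rev)
    site_in_interior = SITE_OFFSET_IN_AMPLICON - len(fwd)
    window_start = site_start - site_in_interior

    for _ in range(200):
        left_pad = _random_bases(rng, max(0, -window_start))
        start = max(0, window_start)
        core1 = seq1[start : start + interior_len - len(left_pad)]
        core2 = seq2[start : start + interior_len - len(left_pad)]
        right_pad = _random_bases(rng, interior_len - len(left_pad) - len(core1))
        flank5 = _random_bases(rng, 40)
        flank3 = _random_bases(rng, 40)
        out = {}
        ok = True
        for allele, core in ((1, core1), (2, core2)):
            interior = left_pad + core + right_pad
            template = flank5 + fwd + interior + rc_rev + flank3
            amplicon = fwd + interior + rc_rev
            sites = find_sites(amplicon, CLAI)
            # exactly one primer match each, and the expected site layout
            if (
                template.count(fwd) != 1
                or template.count(rc_rev) != 1
                or len(amplicon) != AMPLICON_LENGTH
                or sites not in ([], [SITE_OFFSET_IN_AMPLICON])
            ):
                ok = False
                break
            out[allele] = template
        if ok and len(out) == 2:
            return out
    raise RuntimeError("failed to assemble genotyping templates")


# --- fin rays ---------------------------------------------------------------


@dataclass(frozen=True)
class FinRaySpec:
    """Cohort plan for bivariate left/right fin-ray counts.

    Marginals are negative binomial (overdispersed counts) linked by a
    Gaussian copula whose latent correlation is chosen so the target Spearman
    rho is attained for continuous marginals (r = 2 sin(pi*rho/6)).  A
    ``p_less`` fraction of bifurcated fish comes from a low-count mode
    (guaranteed below the index threshold); a ``p_single`` fraction has no
    bifurcated lobes at all.  Defaults emulate the 205-fish F2 cohort.
    """

    n_per_genotype: tuple[int, int, int] = (69, 101, 35)
    rho_per_genotype: tuple[float, float, float] = (0.631, 0.580, 0.678)
    mean_rays: float = 20.0
    dispersion: float = 30.0
    p_less: float = 33 / 205
    p_single: float = 13 / 205
    mean_rays_less: float = 6.0
    mean_cfrM: float = 7.0
    mean_cfrM_less: float = 3.0
    mean_cfrM_single: float = 26.0
    threshold: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_genotype):
            raise ValueError("cohort sizes must be non-negative")
        if any(not -1 < r < 1 for r in self.rho_per_genotype):
            raise ValueError("rho must lie in (-1, 1)")
        if not 0 <= self.p_less <= 1 or not 0 <= self.p_single <= 1:
            raise ValueError("mode probabilities must be in [0, 1]")
        if self.p_less + self.p_single > 1:
            raise ValueError("p_less + p_single must not exceed 1")


@dataclass(frozen=True)
class FinRayTruth:
    n_per_genotype: tuple[int, int, int]
    target_rho: tuple[float, float, float]
    n_single: int
    n_less: int
    n_normal: int


def _nb_ppf(u: np.ndarray, mean: float, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return stats.nbinom.ppf(u, dispersion, p).astype(int)


def generate_finray_dataset(spec: FinRaySpec) -> tuple[list[FinRayRecord], FinRayTruth]:
    """Draw a fin-ray cohort; deterministic given the spec's seed.

    Low-mode fish are redrawn until their index cfrM + max(cfrL, cfrR) falls
    below the threshold, normal-mode fish until it does not, so the truth
    record's group counts are exact by construction.
    """
    rng = np.random.default_rng(spec.seed)
    genotypes = ("11", "12", "22")
    records: list[FinRayRecord] = []
    n_single = n_less = n_normal = 0
    fish = 0
    for g_index, genotype in enumerate(genotypes):
        n = spec.n_per_genotype[g_index]
        if n == 0:
            continue
        rho = spec.rho_per_genotype[g_index]
        r_latent = 2.0 * np.sin(np.pi * rho / 6.0)
        cov = np.array([[1.0, r_latent], [r_latent, 1.0]])
        modes = rng.choice(
            3, size=n, p=[spec.p_single, spec.p_less, 1 - spec.p_single - spec.p_less]
        )
        for mode in modes:
            fish += 1
            fid = f"F2-{fish:04d}"
            if mode == 0:  # single caudal fin: medial rays only
                cfrm = int(rng.poisson(spec.mean_cfrM_single))
                records.append(FinRayRecord(fid, genotype, cfrm, 0, 0))
                n_single += 1
                if cfrm < spec.threshold:
                    n_less += 1
                else:
                    n_normal += 1
                continue
            low = mode == 1
            mean_lobe = spec.mean_rays_less if low else spec.mean_rays
            mean_m = spec.mean_cfrM_less if low else spec.mean_cfrM
            for _ in range(1000):
                z = rng.multivariate_normal([0.0, 0.0], cov)
                u = stats.norm.cdf(z)
                cfrl, cfrr = _nb_ppf(np.asarray(u), mean_lobe, spec.dispersion)
                cfrm = int(rng.poisson(mean_m))
                index = cfrm + max(cfrl, cfrr)
                if low and index < spec.threshold:
                    break
                if not low and index >= spec.threshold:
                    break
            else:
                raise RuntimeError("could not draw a fish in the requested mode")
            # ensure at least one lobe ray so the fish reads as bifurcated
            cfrl, cfrr = int(cfrl), int(cfrr)
            if cfrl == 0 and cfrr == 0:
                cfrl = 1
            records.append(FinRayRecord(fid, genotype, cfrm, cfrl, cfrr))
            if low:
                n_less += 1
            else:
                n_normal += 1
    truth = FinRayTruth(
        n_per_genotype=spec.n_per_genotype,
        target_rho=spec.rho_per_genotype,
        n_single=n_single,
        n_less=n_less,
        n_normal=n_normal,
    )
    return records, truth


# --- embryo measurements ----------------------------------------------------


@dataclass(frozen=True)
class EmbryoTruth:
    arm_means: dict[str, float]
    planted_proportions: tuple[float, ...]
    planted_closures: tuple[float, ...]
    n_in_window: int


def generate_embryo_measurements(
    n_per_arm: int = 50,
    effect: tuple[float, float, float] = (60.0, 30.0, 45.0),
    noise_sd: float = 8.0,
    seed: int = 0,
    closure_range: tuple[float, float] = (5.0, 95.0),
    window: tuple[float, float] = (20.0, 80.0),
) -> tuple[list[EmbryoMeasurement], EmbryoTruth]:
    """Per-arm embryo measurements with planted szl-proportion means.

    ``effect`` gives the mean szl proportion for (control, chdB1_mRNA,
    chdB2_mRNA); the defaults encode the observed ordering chdB1 < chdB2 <
    control.  Noise is normal, clipped into (0.5, 99.5) so the measurement
    invariants always hold; closures are uniform over ``closure_range`` so a
    known subset falls inside the staging window.
    """
    if n_per_arm <= 0:
        raise ValueError("n_per_arm must be positive")
    if any(not 0 < m < 100 for m in effect):
        raise ValueError("arm means must lie in (0, 100)")
    rng = np.random.default_rng(seed)
    measurements: list[EmbryoMeasurement] = []
    proportions: list[float] = []
    closures: list[float] = []
    n_in = 0
    for arm, mean in zip(TREATMENTS, effect):
        for i in range(n_per_arm):
            prop = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            prop = float(np.clip(prop, 0.5, 99.5))
            closure = float(rng.uniform(*closure_range))
            emb = float(rng.uniform(0.65, 0.75))
            bp = emb / (1.0 + closure / 100.0)
            m = EmbryoMeasurement(
                embryo_id=f"{arm}-{i:03d}",
                treatment=arm,
                szl_dv=prop / 100.0 * emb,
                emb_dv=emb,
                bp_dv=bp,
            )
            measurements.append(m)
            proportions.append(prop)
            closures.append(closure)
            if window[0] < closure < window[1]:
                n_in += 1
    truth = EmbryoTruth(
        arm_means=dict(zip(TREATMENTS, effect)),
        planted_proportions=tuple(proportions),
        planted_closures=tuple(closures),
        n_in_window=n_in,
    )
    return measurements, truth
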