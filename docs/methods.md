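# Methods

This note documents the models, numerical choices and limitations behind
chdbkit, in the order a dataset flows through the package.

## Allele comparison

**Positional comparison, no alignment.** The two *chdB* allele coding
sequences differ by substitutions only, so alleles are compared position by
position in frame 0. Unequal lengths raise an error rather than triggering
trimming or alignment; indel-bearing inputs are out of scope by design.

**SNP classification.** Each differing position is labeled synonymous iff
substituting the alternate base into the *reference* allele's codon —
holding the other two positions at the reference bases — conserves the
amino acid under the standard genetic code (tables from
`Bio.Data.CodonTable`). Codons with more than one difference therefore
classify each SNP deterministically against the reference background; the
evolutionary interpretation of multi-hit codons is handled separately by
the NG86 pathway average, not by the labels.

**NG86 dN/dS.** Synonymous site counts per codon are the per-position
fractions of single-base changes that conserve the amino acid (changes to
stop codons count as nonsynonymous), averaged over the two sequences.
Codons differing at k positions average their per-step classifications over
all k! minimal mutational pathways, all weighted equally (pathways through
stop codons are not excluded; with ≤ 2 differences per codon in realistic
allele pairs this choice is almost never exercised). Proportions are
corrected for multiple hits with Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3);
p ≥ 3/4 raises a saturation error. The estimator is symmetric in its
arguments, and dN = dS = 0 exactly when the sequences are identical. It is
a pairwise surrogate only: branch-model codon likelihoods and phylogenetic
estimation are out of scope.

## In-silico PCR-RFLP

Primer matching is exact (the assay's primers are long and unique; a
mismatch-tolerant mode is a non-goal). The forward primer must occur once
on the plus strand and the reverse primer once, as its reverse complement,
downstream and non-overlapping; zero products raise a no-amplification
error and multiple products an ambiguity error. The amplicon includes both
primers. ClaI is modeled as ATCGAT with cut offset 2 (AT^CGAT); the site is
its own reverse complement, so a plus-strand scan finds all sites, and
overlapping occurrences are all reported. Digestion cuts after the offset
at every site; fragment lengths always sum to the amplicon length.

Genotype calling compares an observed fragment-length multiset with the
scheme's predictions — uncut product only → homozygous no-site allele, cut
fragments only → homozygous site allele, the union → heterozygote, anything
else → ambiguous. Band lengths match within an integer tolerance
(default 0, i.e. exact); a few base pairs of tolerance emulate the limited
resolution of agarose gels. Which allele carries the site is a parameter of
the scheme (default: allele 2), since the assay itself does not identify
the cut allele without sequence knowledge.

## Segregation and viability

Allele-2 frequency is (n₁₂ + 2n₂₂)/2N. The segregation test is Pearson's
chi-square with expected counts N·(expected ratio), df = 2, p from the
continuous chi-square distribution with no continuity correction —
conventional at these sample sizes (N ≈ 200). Viabilities are observed/
expected proportion ratios normalized to the chdB¹/¹ homozygote (the
reference is a parameter; re-normalizing to another genotype preserves all
pairwise fitness ratios). Estimation keeps full precision; a presentation
helper rounds to 3 decimals. Note that a printed three-decimal genotype
ratio can disagree with rounding in the last digit (35/205 = 0.17073 →
0.171), so comparisons of printed ratios should allow ±0.001.

Uncertainty comes from a percentile bootstrap: resample N fish from the
observed genotype proportions (multinomial), re-estimate the viability
triple, take the 2.5%/97.5% quantiles over ≥ 100 seeded replicates.
Replicates in which the reference genotype draws zero fish cannot be
normalized and are dropped; at the cohort sizes involved this is a
< 10⁻³⁰-probability event. A profile-likelihood interval would be the main
alternative; the bootstrap was chosen as the simplest defensible method
given only count data.

## Selection dynamics

The recursion is the standard diploid viability-selection update with
Hardy–Weinberg zygote formation (see the README). Generation 0 is the
initial frequency; plain double precision throughout (the dynamics' scale
dwarfs ulp effects); fitness triples are invariant under positive scaling.
Queries for the first generation below a threshold return a sentinel
(`None`) rather than raising when the cap is reached, so scans compose.

One analytic property is worth recording: in the directional case
w₁₁ > w₁₂ > w₂₂ the per-generation ratio satisfies q′/q ≥ w₁₂/w₁₁, so
q[g] ≥ q0·(w₁₂/w₁₁)^g. With w = (1, 0.732, 0.507) and q0 = 0.9 this bound
is ≈ 0.0013 at generation 21 — the allele cannot fall below 0.001 by then
under this recursion (it does so at generation 29, as the package
computes). The square of the frequency (the chdB²/² genotype frequency)
does cross 0.001 around generation 21, which is the natural quantity to
check when reconciling against genotype-level expectations.

Equilibrium classification follows textbook theory: overdominance gives a
stable interior equilibrium at q* = (w₁₁ − w₁₂)/(w₁₁ + w₂₂ − 2w₁₂),
underdominance the same point but unstable, otherwise the fitter
homozygote's allele fixes.

## Wright–Fisher simulator

Each generation applies the deterministic selection step to the current
frequency and then resamples 2N allele copies binomially (allele-level
sampling; genotype-level sampling is out of scope). Frequencies 0 and 1 are
absorbing. The mean of many replicates tracks the deterministic recursion
closely at N = 1000 (within 0.02 over 10 generations in the test suite),
while N ≈ 10 lets drift fix the disfavored allele in a small fraction
(~10⁻³) of replicates — the qualitative mechanism by which a deleterious
allele can persist in small segregated subpopulations.

## Morphometrics

The maximum caudal fin ray index is cfrM + max(cfrL, cfrR). Two
conventions are fixed here because the source assay leaves them open:
(1) a fish is "single-tailed" iff it has no bifurcated lobe rays at all
(cfrL = cfrR = 0), the natural reading of medial-only ray anatomy, and
(2) an index of exactly 20 — unassigned by a "less than 20" vs "more than
20" dichotomy — goes to the *normal* group (the rule is index < threshold →
less). Both are parameterizable. Left–right symmetry is Spearman rank
correlation with average-rank tie handling (scipy), computed per genotype
over bifurcated fish by default (single-tailed fish have no lobes to
correlate); groups under 3 usable fish or with a constant variable report
an undefined correlation with n. Normality checks, where wanted, should use
a standard Shapiro–Wilk implementation; they are not re-derived here.

## Embryo expression

The ventral-marker extent is szl.DV/emb.DV × 100. Blastopore closure is
(emb.DV − bp.DV)/bp.DV × 100 — implemented exactly as the assay defines it,
although this denominator exceeds 100% for blastopores smaller than half
the embryo; a variant dividing by emb.DV (bounded by 100) is available
behind an explicit flag, default off. Staging windows use strict bounds:
a closure of exactly 20% or 80% is excluded from a 20–80 window.
Measurements are unitless ratios, so the pixel/µm calibration of the images
never enters.

## Synthetic data generators

All generators are pure functions of (spec, seed) via
`numpy.random.default_rng`; reruns are bit-identical, and each returns a
truth record sufficient to score the downstream stage.

**F2 crosses.** Survivors are one multinomial draw with category
probabilities ∝ Mendelian ratio × fitness. Defaults are the study
conditions: 205 offspring, w = (1, 0.732, 0.507). At n = 10⁵ the viability
estimator recovers the truth within ±0.03 (the 3σ multinomial envelope).

**Allele pairs.** A random sense-codon backbone (ATG start, no stops) gets
exactly the requested numbers of synonymous and nonsynonymous single-base
codon changes, at most one per codon so every planted label is unambiguous
(multi-hit codons are exercised separately in unit tests). When at least
one nonsynonymous SNP is requested, one of them is the engineered ClaI
toggle: the site-bearing allele carries ATC|GAT (Ile-Asp) across two
adjacent codons and the other ATC|CAT (Ile-His) — a nonsynonymous Asp/His
exchange that creates ATCGAT in exactly one allele. Accidental ClaI sites
anywhere else are scrubbed by codon resampling, and planted changes that
would create one are re-drawn. Defaults mirror the real comparison: 929
codons (2787 sites), 42 SNPs, 14 nonsynonymous, site on allele 2.
Genotyping templates embed a window of the coding sequence around the site
between the published primers, flanked by random sequence, so that the
amplicon is exactly 334 bp with the site starting 100 bases in (cut
fragments 102 + 232).

**Fin rays.** Per genotype, (cfrL, cfrR) come from a Gaussian copula over
negative-binomial marginals; the latent correlation is 2·sin(πρ/6), the
value that yields Spearman ρ for continuous marginals. Ties in the discrete
marginals attenuate the realized rank correlation below the target (about
0.575 realized for a 0.631 target at the default marginals, mean 20,
dispersion 30) — tests therefore compare cohorts against the discrete
model's own large-sample value. cfrM is independent Poisson. A p_less
fraction of bifurcated fish comes from a low-count mode and a p_single
fraction has medial rays only; low/normal draws are rejected-resampled to
land on their side of the index threshold, so the truth record's group
counts are exact by construction. Defaults emulate the 205-fish cohort
(69/101/35 genotype split, ρ = 0.631/0.580/0.678, ~16% low-count, ~6%
single-tailed, normal-group mean index ≈ 29). The marginal shapes are
stated modeling assumptions — the real cohort's count distribution is
unpublished — so passing tests show internal consistency, not
distributional realism; mixing modes also raises the pooled correlation
above the within-mode targets, as any bimodal cohort would.

**Embryos.** Arm means of the szl proportion (defaults 60/30/45% for
control/chdB¹/chdB² — the observed ordering chdB¹ < chdB² < control) plus
normal noise clipped into (0.5, 99.5); closures are uniform over (5, 95) so
a known subset falls in the 20–80% staging window; embryo diameters jitter
around 0.7 length units and bp.DV is back-computed from the planted
closure. With zero noise the arm means are recovered exactly. The generator
does not emulate stage-dependent trends within an arm (the real data show
expression changing along the closure axis), only between-arm contrasts.

## Problem sizes and tests

The test suite runs the full property battery at modest sizes: 10⁵-offspring
crosses for viability recovery, 2000 Wright–Fisher replicates at N = 1000
over 10 generations, 20 000 replicates at N = 10 for the drift-fixation
check, 1000 random SNP plantings at 40 codons, and exhaustive Spearman
oracle comparisons at n ≤ 7. These sizes keep the whole suite under half a
minute while leaving the stochastic assertions with comfortable margins
(3σ or wider).

## Known limitations

* No indel handling or alignment; alleles must be same-length coding
  sequences.
* The NG86 surrogate does not replicate branch-model codon analyses.
* Primer matching is exact; degenerate or mismatched primers are not
  modeled.
* The fin-ray and embryo generators encode plausible, stated distributions,
  not fitted ones.
* The deterministic recursion assumes random mating, constant viabilities,
  no mutation/migration/inbreeding; the Wright–Fisher model samples alleles,
  not genotypes.
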