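# chdbkit

A Python toolkit for analyzing allelic variation at the goldfish *chdB*
locus — one of the two *chordin* paralogues (BMP antagonists that organize
dorsal–ventral patterning) in *Carassius auratus*. The locus carries a major
allele (*chdB¹*) and a rare minor allele (*chdB²*) that differ by dozens of
coding SNPs, one of which creates/destroys a ClaI restriction site and so
supports PCR-RFLP genotyping. The package is aimed at molecular and
population geneticists who want to run — or stress-test on synthetic fish —
the full chain from allele sequences to evolutionary prediction:

* **Codon-aware allele comparison** — SNP enumeration with
  synonymous/nonsynonymous labels, and pairwise dN/dS by Nei–Gojobori (1986)
  counting with the Jukes–Cantor multiple-hit correction.
* **In-silico PCR-RFLP genotyping** — exact primer matching, ClaI digestion
  (AT^CGAT), and genotype calls from band patterns.
* **Segregation genetics** — genotype/allele frequencies, Pearson chi-square
  tests against Mendelian ratios, and relative-viability estimation from F2
  segregant counts with bootstrap confidence intervals.
* **Selection dynamics** — the deterministic one-locus viability-selection
  recursion under random mating, plus a Wright–Fisher simulator for drift.
* **Morphometrics and embryology** — caudal-fin ray indices and left–right
  symmetry statistics; ventral-marker expression extent and blastopore-
  closure staging.
* **Synthetic data generators** — seeded, truth-tracking emulators for every
  input, so each stage is testable without any sequencing or fish.

## The core model

An F2 cross of two heterozygotes produces zygotes at 1:2:1. If the three
genotypes survive with relative viabilities *w₁₁, w₁₂, w₂₂*, the surviving
genotype proportions are distorted accordingly, so dividing observed
proportions by Mendelian expectations and normalizing to the reference
genotype estimates the viabilities:

    ŵ_g = (observed proportion of g) / (expected proportion of g),  ŵ₁₁ ≡ 1.

Those viabilities drive the standard random-mating recursion for the
frequency *q* of allele 2 (with *p* = 1 − *q*):

    q' = (q²·w₂₂ + p·q·w₁₂) / w̄,   w̄ = p²·w₁₁ + 2pq·w₁₂ + q²·w₂₂,

which projects how fast a disfavored allele is purged; the Wright–Fisher
simulator adds binomial sampling of 2N allele copies per generation to ask
when drift can rescue it.

## Worked example

```python
from chdbkit import (GenotypeCounts, estimate_frequencies, mendelian_test,
                     estimate_viability, round_triple)

counts = GenotypeCounts(n11=69, n12=101, n22=35, label="F2")
print(round_triple(estimate_frequencies(counts).genotype_freqs))
test = mendelian_test(counts)
print(round(test.chi_square, 2), round(test.p_value, 4))
print(round_triple(estimate_viability(counts)))
```

prints

```
(0.337, 0.493, 0.171)
11.32 0.0035
(1.0, 0.732, 0.507)
```

— the F2 genotype ratio departs from 1:2:1 (chi-square 11.32, df 2,
p ≈ 0.0035), and read as differential survival this means each *chdB²* copy
costs roughly a quarter of viability relative to the *chdB¹* homozygote.
Feeding those viabilities into the recursion
(`examples/selection_projection.py`) shows *q* falling from 0.9 below the
observed Oranda strain frequency (0.214) by generation 11 and below 0.001 by
generation 29.

The `examples/` directory holds one short script per capability
(segregation, selection projection, RFLP genotyping, SNP annotation and
dN/dS, fin-ray symmetry, embryo staging); each builds or simulates a small
input, runs the method and prints annotated results.

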