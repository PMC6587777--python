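"""In-silico PCR-RFLP genotyping on a synthetic allele pair.

Builds a synthetic pair of chdB-like alleles whose ClaI site is carried by
allele 2 only, amplifies the 334-bp genotyping fragment from each template
with the published primers, digests with ClaI, and calls genotypes from the
resulting band patterns.
"""

from chdbkit import (
    GenotypeScheme,
    call_genotype,
    digest,
    in_silico_pcr,
)
from chdbkit.simulate import SequencePlantSpec, generate_allele_pair

pair = generate_allele_pair(
    SequencePlantSpec(n_codons=200, n_synonymous=6, n_nonsynonymous=3, seed=42)
)
amp1 = in_silico_pcr(pair.templates[1], pair.primers)
amp2 = in_silico_pcr(pair.templates[2], pair.primers)
print(f"amplicon lengths: allele1 = {len(amp1)} bp, allele2 = {len(amp2)} bp")

pat1 = digest(amp1, pair.enzyme)
pat2 = digest(amp2, pair.enzyme)
print(f"ClaI digestion  : allele1 -> {pat1.fragment_lengths}, allele2 -> {pat2.fragment_lengths}")

scheme = GenotypeScheme.from_amplicons(amp1, amp2, pair.enzyme)
band_sets = {
    "uncut only": (334,),
    "cut only": (102, 232),
    "both": (334, 102, 232),
    "unexpected": (300,),
}
for label, bands in band_sets.items():
    print(f"bands {bands!s:>17} ({label:10s}) -> {call_genotype(bands, scheme).value}")

print()
print("The uncut 334-bp band marks the site-free allele, the 102+232 pair the")
print("site-bearing allele, and the union of the three bands a heterozygote.")
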