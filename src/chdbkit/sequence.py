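"""Codon-aware allele comparison and in-silico PCR-RFLP genotyping.

The two chdB coding sequences differ only by single-nucleotide substitutions
(no indels), so alleles are compared positionally, codon by codon.  This
module enumerates the SNPs and labels each as synonymous or nonsynonymous,
estimates per-site substitution rates with Nei–Gojobori (1986) counting plus
the Jukes–Cantor correction, and reproduces the wet-lab genotyping assay in
silico: amplify a fragment with the published primer pair, digest with ClaI
(whose recognition site is polymorphic between the alleles), and read the
genotype off the band pattern.

Coordinates are 0-based and half-open throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum

from Bio.Data import CodonTable
from Bio.Seq import Seq

_VALID_BASES = frozenset("ACGT")

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"


class NoAmplificationError(RuntimeError):
    """A primer has no perfect match on the template."""


class AmbiguousProductError(RuntimeError):
    """The primer pair supports more than one amplification product."""


class SaturationError(ValueError):
    """Observed proportion of differences >= 3/4; Jukes–Cantor correction undefined."""


def _check_bases(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"{what} contains non-ACGT symbols: {sorted(bad)}")


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding nucleotide sequence read in a fixed frame."""

    id: str
    residues: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("coding sequence must be non-empty")
        _check_bases(self.residues, f"sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def codons(self) -> list[str]:
        seq = self.residues[self.frame_offset :]
        if len(seq) % 3:
            raise ValueError(
                f"sequence {self.id!r}: in-frame length {len(seq)} not divisible by 3"
            )
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]


@dataclass(frozen=True)
class SnpRecord:
    """One coding-sequence substitution with its codon context and effect."""

    position: int
    ref_base: str
    alt_base: str
    codon_index: int
    codon_position: int
    effect: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")
        if self.codon_index != self.position // 3 or self.codon_position != self.position % 3:
            raise ValueError("codon coordinates inconsistent with position")
        if self.effect not in (SYNONYMOUS, NONSYNONYMOUS):
            raise ValueError(f"unknown effect {self.effect!r}")


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both written 5'->3'."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        _check_bases(self.forward, "forward primer")
        _check_bases(self.reverse, "reverse primer")


#: Published genotyping primers flanking the polymorphic ClaI site (334 bp product).
CHDB_PRIMERS = PrimerPair(
    forward="AGTGGGGTCGGCTGTCTTCACT",
    reverse="ATCCATTCCGTTGTACGGCAGCATTT",
)


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self) -> None:
        _check_bases(self.recognition_site, f"{self.name} site")
        if not 0 <= self.cut_offset <= len(self.recognition_site):
            raise ValueError("cut_offset must lie within the recognition site")


#: ClaI cuts AT^CGAT; the site is its own reverse complement.
CLAI = RestrictionEnzyme(name="ClaI", recognition_site="ATCGAT", cut_offset=2)


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    template_start: int
    template_end: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.template_end - self.template_start:
            raise ValueError("amplicon length inconsistent with template coordinates")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestPattern:
    """Multiset of restriction fragment lengths, stored sorted."""

    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragment_lengths", tuple(sorted(self.fragment_lengths)))
        if any(f <= 0 for f in self.fragment_lengths):
            raise ValueError("fragment lengths must be positive")

    @property
    def total_length(self) -> int:
        return sum(self.fragment_lengths)


class GenotypeCall(Enum):
    HOM_ALLELE1 = "hom_allele1"
    HET = "het"
    HOM_ALLELE2 = "hom_allele2"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SubstitutionEstimate:
    """NG86 pairwise estimate: substitutions per synonymous / nonsynonymous site."""

    dN: float
    dS: float
    sites_N: float
    sites_S: float
    nonsyn_differences: float
    syn_differences: float


# --- genetic code -----------------------------------------------------------


def _codon_map(code: int | CodonTable.CodonTable = 1) -> dict[str, str]:
    """Codon -> amino acid (one letter, '*' for stop) for an NCBI table id."""
    table = (
        CodonTable.unambiguous_dna_by_id[code] if isinstance(code, int) else code
    )
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def _check_comparable(a: CodingSequence, b: CodingSequence) -> None:
    if len(a) != len(b):
        raise ValueError(
            f"sequences must align positionally: {a.id!r} has {len(a)} nt, "
            f"{b.id!r} has {len(b)} nt (indels are not modeled)"
        )
    if len(a.residues) % 3:
        raise ValueError(f"aligned length {len(a)} not divisible by 3")


# --- SNP enumeration --------------------------------------------------------


def enumerate_snps(
    a: CodingSequence, b: CodingSequence, code: int | CodonTable.CodonTable = 1
) -> list[SnpRecord]:
    """List every substitution between two same-length coding sequences.

    Each SNP is labeled synonymous iff substituting the alternate base into
    sequence ``a``'s codon (holding the other two positions at ``a``'s bases)
    leaves the encoded amino acid unchanged.  Codons carrying more than one
    difference therefore classify each SNP independently against ``a``'s
    codon background.
    """
    _check_comparable(a, b)
    aa_of = _codon_map(code)
    records: list[SnpRecord] = []
    for pos, (ra, rb) in enumerate(zip(a.residues, b.residues)):
        if ra == rb:
            continue
        ci, cp = pos // 3, pos % 3
        codon_a = a.residues[3 * ci : 3 * ci + 3]
        mutated = codon_a[:cp] + rb + codon_a[cp + 1 :]
        effect = SYNONYMOUS if aa_of[mutated] == aa_of[codon_a] else NONSYNONYMOUS
        records.append(
            SnpRecord(
                position=pos,
                ref_base=ra,
                alt_base=rb,
                codon_index=ci,
                codon_position=cp,
                effect=effect,
            )
        )
    return records


# --- NG86 -------------------------------------------------------------------


def _syn_site_count(codon: str, aa_of: dict[str, str]) -> float:
    """Fraction of the codon's three sites that are synonymous.

    Each position contributes (synonymous single-base changes)/3; changes to
    stop codons count as nonsynonymous.
    """
    aa = aa_of[codon]
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if aa_of[alt] == aa:
                syn += 1
    return syn / 3.0


def _pathway_differences(
    codon_a: str, codon_b: str, aa_of: dict[str, str]
) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) step counts over all minimal pathways.

    For codons differing at k positions, every one of the k! substitution
    orders is a minimal pathway; each single-base step is classified by
    whether it changes the encoded amino acid.  All pathways are weighted
    equally, including those passing through stop codons.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_positions):
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if aa_of[nxt] == aa_of[current]:
                syn_total += 1
            else:
                nonsyn_total += 1
            current = nxt
        n_paths += 1
    return syn_total / n_paths, nonsyn_total / n_paths


def jukes_cantor(p: float) -> float:
    """Correct an observed difference proportion for multiple hits."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise SaturationError(
            f"difference proportion {p:.4f} >= 3/4: Jukes–Cantor correction undefined"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pairwise(
    a: CodingSequence, b: CodingSequence, code: int | CodonTable.CodonTable = 1
) -> SubstitutionEstimate:
    """Nei–Gojobori (1986) pairwise dN/dS with Jukes–Cantor correction.

    Synonymous and nonsynonymous site counts are averaged over the two
    sequences; multi-hit codons average differences over all minimal
    mutational pathways.
    """
    _check_comparable(a, b)
    aa_of = _codon_map(code)
    codons_a = a.codons()
    codons_b = b.codons()

    sites_s = 0.0
    syn_d = 0.0
    nonsyn_d = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sites_s += 0.5 * (_syn_site_count(ca, aa_of) + _syn_site_count(cb, aa_of))
        sd, nd = _pathway_differences(ca, cb, aa_of)
        syn_d += sd
        nonsyn_d += nd
    total_sites = 3.0 * len(codons_a)
    sites_n = total_sites - sites_s

    p_s = syn_d / sites_s if syn_d else 0.0
    p_n = nonsyn_d / sites_n if nonsyn_d else 0.0
    return SubstitutionEstimate(
        dN=jukes_cantor(p_n),
        dS=jukes_cantor(p_s),
        sites_N=sites_n,
        sites_S=sites_s,
        nonsyn_differences=nonsyn_d,
        syn_differences=syn_d,
    )


# --- restriction digestion and PCR ------------------------------------------


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All (possibly overlapping) recognition-site start offsets, ascending.

    Plus-strand scan only; palindromic sites such as ClaI's ATCGAT are their
    own reverse complement, so one strand suffices for them.
    """
    _check_bases(seq)
    site = enzyme.recognition_site
    hits: list[int] = []
    start = seq.find(site)
    while start != -1:
        hits.append(start)
        start = seq.find(site, start + 1)
    return hits


def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    start = haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def in_silico_pcr(template: str, primers: PrimerPair) -> Amplicon:
    """Amplify the unique product delimited by the primer pair.

    The forward primer must match the plus strand exactly; the reverse primer
    anneals to the plus strand as its reverse complement, downstream of (and
    not overlapping) the forward primer.  The amplicon includes both primers.
    """
    _check_bases(template, "template")
    fwd_hits = _find_all(template, primers.forward)
    rc_rev = reverse_complement(primers.reverse)
    rev_hits = _find_all(template, rc_rev)
    if not fwd_hits:
        raise NoAmplificationError("forward primer not found on template")
    if not rev_hits:
        raise NoAmplificationError("reverse primer (as reverse complement) not found")
    products = [
        (f, r + len(rc_rev))
        for f in fwd_hits
        for r in rev_hits
        if r >= f + len(primers.forward)
    ]
    if not products:
        raise NoAmplificationError("no primer orientation yields a product")
    if len(products) > 1:
        raise AmbiguousProductError(f"{len(products)} possible products")
    start, end = products[0]
    return Amplicon(sequence=template[start:end], template_start=start, template_end=end)


def digest(amplicon: Amplicon | str, enzyme: RestrictionEnzyme) -> DigestPattern:
    """Cut the amplicon at every recognition site; fragment lengths sum to its length."""
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon
    cuts = sorted(s + enzyme.cut_offset for s in find_sites(seq, enzyme))
    bounds = [0, *cuts, len(seq)]
    fragments = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return DigestPattern(fragment_lengths=tuple(fragments))


# --- genotype calling -------------------------------------------------------


@dataclass(frozen=True)
class GenotypeScheme:
    """Expected band patterns of the RFLP assay.

    ``site_allele`` names the allele carrying the polymorphic restriction
    site (1 or 2); the other allele yields only the uncut product.
    """

    uncut_length: int
    cut_fragments: tuple[int, ...]
    site_allele: int = 2
    tolerance: int = 0

    def __post_init__(self) -> None:
        if self.site_allele not in (1, 2):
            raise ValueError("site_allele must be 1 or 2")
        if self.uncut_length <= 0 or any(f <= 0 for f in self.cut_fragments):
            raise ValueError("band lengths must be positive")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        object.__setattr__(self, "cut_fragments", tuple(sorted(self.cut_fragments)))

    @classmethod
    def from_amplicons(
        cls,
        amplicon_allele1: Amplicon | str,
        amplicon_allele2: Amplicon | str,
        enzyme: RestrictionEnzyme = CLAI,
        tolerance: int = 0,
    ) -> "GenotypeScheme":
        """Derive the scheme by digesting both allele amplicons in silico."""
        pat1 = digest(amplicon_allele1, enzyme)
        pat2 = digest(amplicon_allele2, enzyme)
        cut1, cut2 = len(pat1.fragment_lengths) > 1, len(pat2.fragment_lengths) > 1
        if cut1 == cut2:
            raise ValueError(
                "exactly one allele must carry the restriction site "
                f"(fragments: {pat1.fragment_lengths} vs {pat2.fragment_lengths})"
            )
        site_allele = 2 if cut2 else 1
        cut_pat, uncut_pat = (pat2, pat1) if cut2 else (pat1, pat2)
        return cls(
            uncut_length=uncut_pat.fragment_lengths[0],
            cut_fragments=cut_pat.fragment_lengths,
            site_allele=site_allele,
            tolerance=tolerance,
        )

    def expected_bands(self, genotype: str) -> tuple[int, ...]:
        """Band multiset predicted for genotype '11', '12' or '22'."""
        hom_site = ("22",) if self.site_allele == 2 else ("11",)
        if genotype in hom_site:
            return self.cut_fragments
        if genotype == "12":
            return tuple(sorted((self.uncut_length, *self.cut_fragments)))
        if genotype in ("11", "22"):
            return (self.uncut_length,)
        raise ValueError(f"unknown genotype {genotype!r}")


def _bands_match(observed: tuple[int, ...], expected: tuple[int, ...], tol: int) -> bool:
    if len(observed) != len(expected):
        return False
    return all(abs(o - e) <= tol for o, e in zip(sorted(observed), sorted(expected)))


def call_genotype(bands, scheme: GenotypeScheme) -> GenotypeCall:
    """Map an observed fragment-length multiset to a genotype call.

    Uncut product only -> homozygous for the no-site allele; cut fragments
    only -> homozygous for the site allele; both -> heterozygote; anything
    else -> ambiguous.  Band lengths compare within ``scheme.tolerance``.
    """
    observed = tuple(sorted(int(b) for b in bands))
    if not observed:
        raise ValueError("empty band set")
    tol = scheme.tolerance
    calls = {
        "11": GenotypeCall.HOM_ALLELE1,
        "12": GenotypeCall.HET,
        "22": GenotypeCall.HOM_ALLELE2,
    }
    for genotype, call in calls.items():
        if _bands_match(observed, scheme.expected_bands(genotype), tol):
            return call
    return GenotypeCall.AMBIGUOUS
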