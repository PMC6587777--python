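"""Unit and property tests for SNP enumeration, NG86, and in-silico PCR-RFLP."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chdbkit.sequence import (
    CHDB_PRIMERS,
    CLAI,
    Amplicon,
    AmbiguousProductError,
    CodingSequence,
    GenotypeCall,
    GenotypeScheme,
    NoAmplificationError,
    PrimerPair,
    RestrictionEnzyme,
    SaturationError,
    call_genotype,
    digest,
    enumerate_snps,
    find_sites,
    in_silico_pcr,
    ng86_pairwise,
    reverse_complement,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=200)


# --- SNP enumeration --------------------------------------------------------


def test_identical_sequences_have_no_snps():
    a = CodingSequence("a", "ATGGATCCC")
    assert enumerate_snps(a, a) == []


@pytest.mark.parametrize(
    "seq_a, seq_b, position, effect",
    [
        ("GAT", "GAC", 2, "synonymous"),  # Asp -> Asp
        ("AAA", "AGA", 1, "nonsynonymous"),  # Lys -> Arg
    ],
)
def test_single_codon_snp_classification(seq_a, seq_b, position, effect):
    snps = enumerate_snps(CodingSequence("a", seq_a), CodingSequence("b", seq_b))
    assert len(snps) == 1
    rec = snps[0]
    assert (rec.position, rec.effect) == (position, effect)
    assert rec.codon_index == position // 3 and rec.codon_position == position % 3


def test_multi_hit_codon_classified_against_reference_background():
    # AAA vs AGG: each SNP judged with the other positions held at AAA's bases
    snps = enumerate_snps(CodingSequence("a", "AAA"), CodingSequence("b", "AGG"))
    assert [s.effect for s in snps] == ["nonsynonymous", "synonymous"]  # AGA=Arg, AAG=Lys


def test_unequal_lengths_are_a_structural_error():
    with pytest.raises(ValueError, match="align"):
        enumerate_snps(CodingSequence("a", "ATGAAA"), CodingSequence("b", "ATG"))


def test_ambiguous_symbols_rejected():
    with pytest.raises(ValueError, match="non-ACGT"):
        CodingSequence("a", "ATGN")


# --- NG86 -------------------------------------------------------------------


def test_ng86_identical_sequences_are_zero():
    a = CodingSequence("a", "ATGGGAGGTCCA")
    est = ng86_pairwise(a, a)
    assert est.dN == 0.0 and est.dS == 0.0
    assert est.sites_N + est.sites_S == pytest.approx(len(a))


def test_ng86_single_synonymous_difference_hand_counted():
    # Hand-counted sites: GGA, GGT, CCA each have 1 synonymous site (fourfold
    # third position), GAT/GAC have 1/3, so S = 10/3, pS = 1/S = 0.3.
    a = CodingSequence("a", "GGAGGTCCAGAT")
    b = CodingSequence("b", "GGAGGTCCAGAC")
    est = ng86_pairwise(a, b)
    assert est.sites_S == pytest.approx(10 / 3)
    assert est.syn_differences == 1.0 and est.nonsyn_differences == 0.0
    assert est.dS == pytest.approx(-0.75 * math.log(1 - 4 * 0.3 / 3))
    assert est.dN == 0.0


def test_ng86_two_difference_codon_averages_both_pathways():
    # TTT vs GTA: pathway via GTT gives (nonsyn, syn), via TTA gives
    # (nonsyn, nonsyn); the average is 0.5 synonymous, 1.5 nonsynonymous.
    a = CodingSequence("a", "GGAGGTCCATTT")
    b = CodingSequence("b", "GGAGGTCCAGTA")
    est = ng86_pairwise(a, b)
    assert est.syn_differences == pytest.approx(0.5)
    assert est.nonsyn_differences == pytest.approx(1.5)
    # sites: 3 fourfold codons + mean(1/3 for TTT, 1 for GTA) = 11/3
    assert est.sites_S == pytest.approx(11 / 3)
    p_s = 0.5 / (11 / 3)
    p_n = 1.5 / (12 - 11 / 3)
    assert est.dS == pytest.approx(-0.75 * math.log(1 - 4 * p_s / 3))
    assert est.dN == pytest.approx(-0.75 * math.log(1 - 4 * p_n / 3))


def test_ng86_saturation_raises():
    # one codon, one synonymous difference: pS = 1 / (1/3) = 3 >= 3/4
    with pytest.raises(SaturationError):
        ng86_pairwise(CodingSequence("a", "GAT"), CodingSequence("b", "GAC"))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.sampled_from(["GGA", "GGT", "CCA", "GAT", "TTT", "AAA", "CTG"]),
                min_size=6, max_size=20))
def test_ng86_symmetric_and_zero_iff_identical(codons):
    import numpy as np

    rng = np.random.default_rng(sum(map(len, codons)))
    seq_a = "".join(codons)
    # mutate one codon third position sometimes
    seq_b = list(seq_a)
    if rng.random() < 0.7:
        seq_b[5] = "ACGT"[rng.integers(4)]
    seq_b = "".join(seq_b)
    a, b = CodingSequence("a", seq_a), CodingSequence("b", seq_b)
    try:
        ab = ng86_pairwise(a, b)
        ba = ng86_pairwise(b, a)
    except SaturationError:
        return
    assert ab.dN == pytest.approx(ba.dN) and ab.dS == pytest.approx(ba.dS)
    if seq_a == seq_b:
        assert ab.dN == 0.0 and ab.dS == 0.0
    else:
        assert ab.dN > 0 or ab.dS > 0


# --- restriction site scan --------------------------------------------------


@pytest.mark.parametrize(
    "seq, expected",
    [("GGGG", []), ("AAATCGATAA", [2]), ("ATCGATCGAT", [0, 4])],
)
def test_find_sites_examples(seq, expected):
    assert find_sites(seq, CLAI) == expected


@settings(deadline=None, derandomize=True, max_examples=200)
@given(dna)
def test_find_sites_agrees_with_naive_scan(seq):
    site = CLAI.recognition_site
    naive = [i for i in range(len(seq) - len(site) + 1) if seq[i : i + len(site)] == site]
    assert find_sites(seq, CLAI) == naive


def test_find_sites_agrees_with_biopython():
    from Bio.Restriction import ClaI
    from Bio.Seq import Seq

    import numpy as np

    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=5000)) + "ATCGAT" + "ATCGAT"
    # Biopython reports 1-based cut positions: site start = cut - 1 - cut_offset
    bio = [p - 2 - 1 for p in ClaI.search(Seq(seq))]
    assert find_sites(seq, CLAI) == sorted(bio)


# --- PCR and digestion ------------------------------------------------------


def test_pcr_product_spans_both_primers():
    fwd, rev = "ACGTACGTAC", "TTGGCCAATT"
    template = fwd + "A" * 50 + reverse_complement(rev)
    amp = in_silico_pcr(template, PrimerPair(fwd, rev))
    assert len(amp) == len(fwd) + 50 + len(rev)
    assert amp.sequence == template
    assert (amp.template_start, amp.template_end) == (0, len(template))


def test_pcr_published_primers_give_334bp_product():
    import numpy as np

    rng = np.random.default_rng(7)
    interior = "".join(rng.choice(list("ACGT"), size=286))
    template = (
        "TTTT" + CHDB_PRIMERS.forward + interior
        + reverse_complement(CHDB_PRIMERS.reverse) + "GGGG"
    )
    amp = in_silico_pcr(template, CHDB_PRIMERS)
    assert len(amp) == 334


def test_pcr_errors():
    fwd, rev = "ACGTACGTAC", "TTGGCCAATT"
    with pytest.raises(NoAmplificationError):
        in_silico_pcr("A" * 100, PrimerPair(fwd, rev))
    rc = reverse_complement(rev)
    doubled = fwd + "A" * 20 + rc + "C" * 20 + rc
    with pytest.raises(AmbiguousProductError):
        in_silico_pcr(doubled, PrimerPair(fwd, rev))


def test_digest_examples():
    amp = Amplicon("G" * 334, 0, 334)
    assert digest(amp, CLAI).fragment_lengths == (334,)
    seq = "A" * 100 + "ATCGAT" + "A" * 228
    assert digest(Amplicon(seq, 0, 334), CLAI).fragment_lengths == (102, 232)


def test_digest_two_sites_three_fragments():
    seq = "C" * 10 + "ATCGAT" + "C" * 20 + "ATCGAT" + "C" * 8
    pattern = digest(Amplicon(seq, 0, len(seq)), CLAI)
    # cuts after AT at 10+2 and 36+2
    assert pattern.fragment_lengths == tuple(sorted((12, 26, len(seq) - 38)))
    assert pattern.total_length == len(seq)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(dna.filter(lambda s: len(s) > 0))
def test_digest_conserves_length(seq):
    pattern = digest(Amplicon(seq, 0, len(seq)), CLAI)
    assert pattern.total_length == len(seq)
    assert len(pattern.fragment_lengths) == len(find_sites(seq, CLAI)) + 1


# --- genotype calling -------------------------------------------------------


@pytest.fixture
def scheme():
    return GenotypeScheme(uncut_length=334, cut_fragments=(102, 232), site_allele=2)


@pytest.mark.parametrize(
    "bands, expected",
    [
        ((334,), GenotypeCall.HOM_ALLELE1),
        ((102, 232), GenotypeCall.HOM_ALLELE2),
        ((334, 102, 232), GenotypeCall.HET),
        ((300,), GenotypeCall.AMBIGUOUS),
    ],
)
def test_band_patterns_map_to_genotypes(bands, expected, scheme):
    assert call_genotype(bands, scheme) == expected


def test_empty_band_set_is_an_error(scheme):
    with pytest.raises(ValueError, match="empty"):
        call_genotype((), scheme)


def test_site_on_allele1_flips_homozygote_calls():
    flipped = GenotypeScheme(uncut_length=334, cut_fragments=(102, 232), site_allele=1)
    assert call_genotype((334,), flipped) == GenotypeCall.HOM_ALLELE2
    assert call_genotype((102, 232), flipped) == GenotypeCall.HOM_ALLELE1


def test_band_tolerance_absorbs_gel_resolution():
    tol = GenotypeScheme(uncut_length=334, cut_fragments=(102, 232), site_allele=2, tolerance=3)
    assert call_genotype((332, 104, 230), tol) == GenotypeCall.HET
    exact = GenotypeScheme(uncut_length=334, cut_fragments=(102, 232), site_allele=2)
    assert call_genotype((332, 104, 230), exact) == GenotypeCall.AMBIGUOUS


@pytest.mark.parametrize("site_allele", [1, 2])
@pytest.mark.parametrize("genotype", ["11", "12", "22"])
def test_genotype_roundtrip_through_predicted_bands(site_allele, genotype):
    scheme = GenotypeScheme(334, (102, 232), site_allele=site_allele)
    call = call_genotype(scheme.expected_bands(genotype), scheme)
    assert call.value == {"11": "hom_allele1", "12": "het", "22": "hom_allele2"}[genotype]
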